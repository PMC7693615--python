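"""Inference stage: mixed repeated-measures ANOVA with Greenhouse-Geisser
correction and generalized eta squared, planned baseline contrasts,
pairwise Welch comparisons of estimated marginal means, and forced-entry
multiple regression.

The ANOVA handles one between-subjects factor (group) crossed with up to
three within-subjects factors on complete cases, using the classical
split-plot stratum decomposition: subjects nested in groups form the
between stratum; each within-factor combination S defines a stratum
whose error term is the subject(group) x S interaction.  On balanced
group sizes the sums of squares coincide with Type I/II/III.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# sphericity

def gg_epsilon(within_cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the k x k covariance of the
    within-factor level measures (double-centered form), clamped to
    [1/(k-1), 1]."""
    cov = np.asarray(within_cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise StatsError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise StatsError("covariance must be symmetric")
    k = cov.shape[0]
    if k < 2:
        raise StatsError("need at least 2 within levels")
    eig = np.linalg.eigvalsh((cov + cov.T) / 2.0)
    if eig.min() < -1e-8 * max(1.0, abs(eig).max()):
        raise StatsError("covariance must be positive semi-definite")
    c = np.eye(k) - np.ones((k, k)) / k
    s = c @ cov @ c
    denom = (k - 1) * np.sum(s * s)
    if denom <= 0:
        return 1.0
    eps = np.trace(s) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _contrast_basis(k: int) -> np.ndarray:
    """Orthonormal columns spanning the complement of the constant vector."""
    a = np.eye(k) - np.ones((k, k)) / k
    u, svals, _ = np.linalg.svd(a)
    return u[:, : k - 1]


def _mauchly(m: np.ndarray, n_error: int) -> tuple[float, float]:
    """Mauchly's sphericity test on the orthonormalized contrast
    covariance ``m`` (d x d) with ``n_error`` error degrees of freedom."""
    d = m.shape[0]
    if d < 2:
        return 1.0, 1.0
    eig = np.linalg.eigvalsh((m + m.T) / 2.0)
    if np.any(eig <= 0):
        return 0.0, 0.0
    w = float(np.exp(np.sum(np.log(eig)) - d * np.log(eig.mean())))
    df = d * (d + 1) // 2 - 1
    factor = n_error - (2 * d * d + d + 2) / (6.0 * d)
    chi2 = -factor * np.log(max(w, 1e-300))
    return w, float(sps.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA

@dataclass
class AnovaResult:
    """Per-effect F table with sphericity correction and effect sizes."""

    table: pd.DataFrame
    n_subjects: int
    n_dropped: int
    within_levels: dict

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def mixed_rm_anova(data: pd.DataFrame, dv: str, subject: str,
                   between: str | None = None,
                   within: tuple[str, ...] = ()) -> AnovaResult:
    """Mixed repeated-measures ANOVA on a long table.

    ``between`` names the group column (or None for a pure within
    design); ``within`` names up to three fully crossed within-subject
    factors.  Subjects with incomplete within cells are dropped listwise.
    Each within effect carries a Greenhouse-Geisser epsilon estimated
    from the pooled covariance of its orthonormalized contrasts, a
    GG-corrected p, Mauchly's test, and generalized eta squared
    (SS_effect / (SS_effect + sum of all error SS)).
    """
    within = tuple(within)
    if not within:
        raise StatsError("at least one within factor is required")
    if len(within) > 3:
        raise StatsError("at most three within factors are supported")

    levels = {w: list(pd.unique(data[w])) for w in within}
    cells = list(itertools.product(*[levels[w] for w in within]))
    wide = data.pivot_table(index=subject, columns=list(within), values=dv,
                            aggfunc="mean")
    full_cols = cells if len(within) > 1 else [c[0] for c in cells]
    wide = wide.reindex(columns=full_cols)
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)

    if between is not None:
        gmap = data.drop_duplicates(subject).set_index(subject)[between]
        groups = gmap.reindex(complete.index)
        if groups.isna().any():
            raise StatsError("subjects with missing group label")
        glabels = list(pd.unique(groups))
    else:
        groups = pd.Series("all", index=complete.index)
        glabels = ["all"]

    y = complete.to_numpy(dtype=float)
    n = y.shape[0]
    g = len(glabels)
    if n < 2 * max(1, g):
        raise StatsError("need at least 2 complete subjects per group")
    gcodes = np.array([glabels.index(v) for v in groups])
    n_g = np.bincount(gcodes, minlength=g).astype(float)

    lcounts = [len(levels[w]) for w in within]
    bases = {w: _contrast_basis(k) for w, k in zip(within, lcounts)}
    means = {w: np.full((k, 1), 1.0 / np.sqrt(k)) for w, k in zip(within, lcounts)}

    rows = []
    error_ss_total = 0.0
    strata = []
    # iterate strata: empty subset = between-subjects stratum
    for r in range(len(within) + 1):
        for s_fac in itertools.combinations(within, r):
            b = np.ones((1, 1))
            for w in within:
                b = np.kron(b, bases[w] if w in s_fac else means[w])
            z = y @ b                                  # (n, d)
            d = z.shape[1]
            zbar = z.mean(axis=0)
            zbar_g = np.vstack([z[gcodes == i].mean(axis=0) for i in range(g)])
            resid = z - zbar_g[gcodes]
            ss_mean = n * float(zbar @ zbar)
            ss_group = float((n_g[:, None] * (zbar_g - zbar) ** 2).sum())
            ss_err = float((resid ** 2).sum())
            df_err = (n - g) * d
            error_ss_total += ss_err
            if r == 0:
                eps, w_mauchly, p_mauchly, cov = 1.0, 1.0, 1.0, None
            else:
                cov = (resid.T @ resid) / (n - g)
                tr = np.trace(cov)
                tr2 = np.sum(cov * cov)
                eps = 1.0 if (d < 2 or tr2 <= 0) else float(
                    np.clip(tr ** 2 / (d * tr2), 1.0 / d, 1.0))
                w_mauchly, p_mauchly = _mauchly(cov, n - g)
            strata.append({
                "factors": s_fac, "d": d, "ss_mean": ss_mean, "ss_group": ss_group,
                "ss_err": ss_err, "df_err": df_err, "eps": eps,
                "mauchly_W": w_mauchly, "mauchly_p": p_mauchly,
            })

    def add_effect(name, ss, df_num, st):
        ms_err = st["ss_err"] / st["df_err"] if st["df_err"] > 0 else np.nan
        degenerate = not np.isfinite(ms_err) or ms_err <= 0
        f = np.inf if degenerate and ss > 0 else (ss / df_num) / ms_err
        p = float(sps.f.sf(f, df_num, st["df_err"])) if np.isfinite(f) else 0.0
        eps = st["eps"]
        p_gg = (float(sps.f.sf(f, df_num * eps, st["df_err"] * eps))
                if np.isfinite(f) else 0.0)
        rows.append({
            "effect": name, "SS": ss, "df_num": df_num, "df_den": st["df_err"],
            "SS_error": st["ss_err"], "F": f, "p": p, "eps": eps, "p_gg": p_gg,
            "mauchly_W": st["mauchly_W"], "mauchly_p": st["mauchly_p"],
            "degenerate_error": degenerate,
        })

    for st in strata:
        s_fac = st["factors"]
        if not s_fac:
            if between is not None:
                add_effect(between, st["ss_group"], g - 1, st)
        else:
            name = ":".join(s_fac)
            add_effect(name, st["ss_mean"], st["d"], st)
            if between is not None:
                add_effect(f"{between}:{name}", st["ss_group"], (g - 1) * st["d"], st)

    table = pd.DataFrame(rows).set_index("effect")
    table["eta2_ges"] = table["SS"] / (table["SS"] + error_ss_total)
    return AnovaResult(table=table, n_subjects=n, n_dropped=n_dropped,
                       within_levels=levels)


# ---------------------------------------------------------------------------
# planned contrasts

def planned_contrasts(data: pd.DataFrame, dv: str, subject: str,
                      group_col: str = "group", time_col: str = "time_point",
                      baseline: str = "pre", followups: tuple[str, ...] | None = None,
                      family_size: int | None = None) -> pd.DataFrame:
    """Paired baseline-vs-follow-up contrasts within each group.

    For each group and each follow-up time point, computes the paired
    difference against ``baseline`` with a paired t statistic and a
    Bonferroni-adjusted p over the per-group family (default m = number
    of follow-ups).  Zero-variance differences are flagged degenerate.
    """
    times = list(pd.unique(data[time_col]))
    if baseline not in times:
        raise StatsError(f"baseline {baseline!r} not among time points {times}")
    followups = tuple(followups) if followups else tuple(t for t in times if t != baseline)
    m = family_size or len(followups)
    rows = []
    for grp, sub in data.groupby(group_col, sort=True):
        wide = sub.pivot_table(index=subject, columns=time_col, values=dv, aggfunc="mean")
        for fu in followups:
            pair = wide[[baseline, fu]].dropna()
            n = len(pair)
            if n < 2:
                raise StatsError(f"contrast {baseline} vs {fu} in {grp}: fewer than 2 pairs")
            diff = pair[fu] - pair[baseline]
            est = float(diff.mean())
            sd = float(diff.std(ddof=1))
            degenerate = sd == 0.0
            if degenerate:
                t = 0.0 if est == 0 else np.inf * np.sign(est)
                p = 1.0 if est == 0 else 0.0
                se = 0.0
            else:
                se = sd / np.sqrt(n)
                t = est / se
                p = float(2 * sps.t.sf(abs(t), n - 1))
            rows.append({
                "group": grp, "contrast": f"{baseline} vs {fu}", "estimate": est,
                "se": se, "t": t, "df": n - 1, "p": p,
                "p_bonf": min(1.0, m * p), "n": n, "degenerate": degenerate,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Welch pairwise comparisons of estimated marginal means

def welch_pairwise_emmeans(data: pd.DataFrame, dv: str, cell_col: str,
                           subject: str | None = None) -> pd.DataFrame:
    """Pairwise Welch t-tests between the cells of ``cell_col``.

    When ``subject`` is given, observations are first averaged within
    subject per cell (estimated marginal means over the remaining
    factors), so each subject contributes one value per cell.
    Satterthwaite degrees of freedom; Bonferroni correction over the
    k(k-1)/2 pair family.
    """
    if subject is not None:
        agg = data.groupby([subject, cell_col], sort=False)[dv].mean().reset_index()
    else:
        agg = data[[cell_col, dv]]
    cells = list(pd.unique(agg[cell_col]))
    pairs = list(itertools.combinations(cells, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        xa = agg.loc[agg[cell_col] == a, dv].dropna().to_numpy(dtype=float)
        xb = agg.loc[agg[cell_col] == b, dv].dropna().to_numpy(dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            raise StatsError(f"cells {a!r}/{b!r} need >= 2 observations")
        va, vb = xa.var(ddof=1), xb.var(ddof=1)
        degenerate = (va == 0 and vb == 0)
        if degenerate:
            diff = xa.mean() - xb.mean()
            t, df, p = (0.0, len(xa) + len(xb) - 2, 1.0) if diff == 0 else (
                np.inf * np.sign(diff), len(xa) + len(xb) - 2, 0.0)
        else:
            res = sps.ttest_ind(xa, xb, equal_var=False)
            t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        rows.append({
            "cell_a": a, "cell_b": b, "mean_a": float(xa.mean()),
            "mean_b": float(xb.mean()), "t": t, "df": df, "p": p,
            "p_bonf": min(1.0, m * p), "n_a": len(xa), "n_b": len(xb),
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# forced-entry regression

@dataclass
class RegressionResult:
    """OLS with all predictors entered simultaneously."""

    table: pd.DataFrame      # per predictor: B, beta, t, p
    f: float
    df_model: int
    df_resid: int
    p: float
    r2: float
    adj_r2: float
    n: int


def forced_entry_regression(data: pd.DataFrame, response: str,
                            predictors: tuple[str, ...]) -> RegressionResult:
    """Multiple regression with all predictors entered at once.

    Reports unstandardized B, standardized beta (B scaled by sample SD
    ratio), t and p per predictor, plus model F, df, p, and adjusted R^2
    over the complete cases.
    """
    cols = [response, *predictors]
    d = data[cols].dropna()
    n = len(d)
    k = len(predictors)
    if n <= k + 1:
        raise StatsError(f"n={n} too small for {k} predictors")
    x = d[list(predictors)].to_numpy(dtype=float)
    yv = d[response].to_numpy(dtype=float)
    xc = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(xc) < xc.shape[1]:
        # name the collinear set: predictors whose removal restores full rank
        collinear = [p for i, p in enumerate(predictors)
                     if np.linalg.matrix_rank(np.delete(xc, i + 1, axis=1))
                     == np.linalg.matrix_rank(xc)]
        raise StatsError(f"rank-deficient design; collinear predictors: {collinear}")
    fit = sm.OLS(yv, xc).fit()
    sd_y = yv.std(ddof=1)
    sd_x = x.std(axis=0, ddof=1)
    b = fit.params[1:]
    beta = b * sd_x / sd_y if sd_y > 0 else np.full(k, np.nan)
    table = pd.DataFrame({
        "B": b, "beta": beta, "t": fit.tvalues[1:], "p": fit.pvalues[1:],
    }, index=list(predictors))
    return RegressionResult(
        table=table, f=float(fit.fvalue), df_model=int(fit.df_model),
        df_resid=int(fit.df_resid), p=float(fit.f_pvalue),
        r2=float(fit.rsquared), adj_r2=float(fit.rsquared_adj), n=n,
    )
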