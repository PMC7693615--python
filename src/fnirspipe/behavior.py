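"""Behavioral scoring for the n-back task: trial filters, inclusion
criterion, and the rate-correct score (RCS).

The RCS combines speed and accuracy into a single measure: the number of
correct responses divided by the summed response times of *all* responses
(correct and incorrect), interpreted directly as correct responses per
second.  Higher is better.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

CONDITIONS = ("0-back", "1-back", "2-back")
TIME_POINTS = ("pre", "post15", "post30", "post45")

#: response-window bounds in milliseconds
PREMATURE_RT_MS = 200.0
OMISSION_RT_MS = 2000.0
#: trials discarded at the start of each block
N_DISCARD_PER_BLOCK = 2
TRIALS_PER_BLOCK = 15
BLOCKS_PER_CONDITION = 2
#: two-sided z cutoff for score exclusion (0.9995 standard-normal quantile)
Z_CUTOFF = 3.29

TRIAL_COLUMNS = [
    "participant_id", "group", "time_point", "condition", "block", "trial",
    "onset_s", "is_target", "response", "rt_ms",
]


class TrialTableError(ValueError):
    """Raised for structurally malformed trial tables."""


class UndefinedScoreError(ValueError):
    """Raised when a score cannot be computed (no responded trials)."""


def _check_blocks(trials: pd.DataFrame) -> None:
    counts = trials.groupby(["participant_id", "time_point", "condition", "block"]).size()
    bad = counts[counts != TRIALS_PER_BLOCK]
    if len(bad):
        raise TrialTableError(
            f"malformed blocks (expected {TRIALS_PER_BLOCK} trials): {bad.index.tolist()[:5]}"
        )


def filter_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Apply the trial filters and classify every trial.

    Adds/overwrites the columns ``discarded`` (first two trials of every
    block) and ``error_class`` in {correct, wrong-key, premature,
    omission}.  Responses faster than 200 ms count as premature errors;
    missing responses (no key press within the 2000 ms window) count as
    omissions.  Idempotent.
    """
    _check_blocks(trials)
    out = trials.copy()
    out["discarded"] = out["trial"] <= N_DISCARD_PER_BLOCK

    rt = out["rt_ms"].to_numpy(dtype=float)
    responded = out["response"].isin(["match", "non-match"]).to_numpy()
    if np.any(responded & ~np.isfinite(rt)):
        raise TrialTableError("responded trial without RT")
    correct_key = np.where(out["is_target"].to_numpy(), "match", "non-match")
    is_correct = responded & (out["response"].to_numpy() == correct_key)

    error_class = np.full(len(out), "wrong-key", dtype=object)
    error_class[is_correct] = "correct"
    error_class[~responded] = "omission"
    with np.errstate(invalid="ignore"):
        error_class[responded & (rt < PREMATURE_RT_MS)] = "premature"
        error_class[responded & (rt > OMISSION_RT_MS)] = "omission"
    out["error_class"] = error_class
    return out


def inclusion_threshold(n_trials: int = 26, p: float = 0.5, quantile: float = 0.99) -> int:
    """Smallest number of correct trials k such that the Binomial(n, p)
    CDF at k reaches ``quantile``.

    Participants below this count in the 1-back condition at pretest are
    excluded (performance not distinguishable from guessing).
    """
    if not (0 < p < 1) or not (0 < quantile < 1) or n_trials < 1:
        raise ValueError("require 0<p<1, 0<quantile<1, n_trials>=1")
    k = int(sps.binom.ppf(quantile, n_trials, p))
    # ppf returns the smallest k with CDF >= quantile
    return k


def compute_rcs(trials: pd.DataFrame, condition: str | None = None,
                time_point: str | None = None) -> float:
    """Rate-correct score: correct responses divided by the sum of RTs
    (seconds) over all responded trials, correct and incorrect.

    Omissions contribute to neither numerator nor denominator; premature
    responses are errors but their RT stays in the denominator.  Expects
    a filtered table; discarded trials are ignored.
    """
    t = trials
    if "discarded" not in t.columns or "error_class" not in t.columns:
        raise TrialTableError("compute_rcs requires a filtered trial table")
    if condition is not None:
        t = t[t["condition"] == condition]
    if time_point is not None:
        t = t[t["time_point"] == time_point]
    t = t[~t["discarded"]]
    responded = t[t["response"].isin(["match", "non-match"]) & t["rt_ms"].notna()]
    if len(responded) == 0:
        raise UndefinedScoreError("no responded trials; RCS undefined")
    n_correct = int((responded["error_class"] == "correct").sum())
    rt_sum_s = float(responded["rt_ms"].sum()) / 1000.0
    return n_correct / rt_sum_s


def zscore_exclude(values: np.ndarray | pd.Series, cutoff: float = Z_CUTOFF) -> np.ndarray:
    """Boolean exclusion mask for extreme values, |z| > cutoff.

    Standardization uses the sample mean and SD (ddof=1) across the given
    values (one condition x time-point cell).  Zero variance yields no
    exclusions (with a logged warning).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values for z-score exclusion")
    sd = v.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        log.warning("zero variance in z-score exclusion cell; no exclusions")
        return np.zeros(v.shape, dtype=bool)
    z = (v - v.mean()) / sd
    return np.abs(z) > cutoff


@dataclass
class ScoringResult:
    """Per-cell scores plus the applied exclusions."""

    scores: pd.DataFrame          # participant_id, group, time_point, condition, n_valid,
                                  # n_correct, accuracy, mean_rt_ms, rcs, included, excluded_reason
    excluded_participants: list   # failed the pretest 1-back inclusion criterion


def score_sessions(trials: pd.DataFrame, *, apply_inclusion: bool = True,
                   apply_z_exclusion: bool = True, z_cutoff: float = Z_CUTOFF) -> ScoringResult:
    """Filter, score, and apply exclusion rules across a cohort.

    The inclusion criterion screens at the participant level: anyone below
    the binomial threshold (19/26 correct at Binomial(26, 0.5), 99%
    quantile) in the 1-back condition at pretest is excluded from all
    cells.  Extreme RCS values (|z| > 3.29 within each condition x time
    cell) drop that cell only.
    """
    filt = filter_trials(trials)
    analyzed = filt[~filt["discarded"]]
    rows = []
    for (pid, grp, tp, cond), cell in analyzed.groupby(
            ["participant_id", "group", "time_point", "condition"], sort=True):
        n_valid = len(cell)
        n_correct = int((cell["error_class"] == "correct").sum())
        correct_rts = cell.loc[cell["error_class"] == "correct", "rt_ms"]
        try:
            rcs = compute_rcs(filt[(filt["participant_id"] == pid)
                                   & (filt["time_point"] == tp)
                                   & (filt["condition"] == cond)])
            undefined = False
        except UndefinedScoreError:
            rcs, undefined = np.nan, True
        rows.append({
            "participant_id": pid, "group": grp, "time_point": tp, "condition": cond,
            "n_valid": n_valid, "n_correct": n_correct,
            "accuracy": n_correct / n_valid if n_valid else np.nan,
            "mean_rt_ms": float(correct_rts.mean()) if len(correct_rts) else np.nan,
            "rcs": rcs,
            "included": True,
            "excluded_reason": "undefined-score" if undefined else "none",
        })
    scores = pd.DataFrame(rows)

    excluded_participants: list = []
    if apply_inclusion:
        thresh = inclusion_threshold(26, 0.5, 0.99)
        pre1 = scores[(scores["time_point"] == "pre") & (scores["condition"] == "1-back")]
        excluded_participants = sorted(pre1.loc[pre1["n_correct"] < thresh, "participant_id"])
        mask = scores["participant_id"].isin(excluded_participants)
        scores.loc[mask, "included"] = False
        scores.loc[mask, "excluded_reason"] = "inclusion-criterion"

    if apply_z_exclusion:
        for (tp, cond), cell in scores[scores["included"]].groupby(["time_point", "condition"]):
            vals = cell["rcs"].to_numpy()
            ok = np.isfinite(vals)
            if ok.sum() < 3:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mask = zscore_exclude(vals[ok], cutoff=z_cutoff)
            idx = cell.index[ok][mask]
            scores.loc[idx, "included"] = False
            scores.loc[idx, "excluded_reason"] = "z-outlier"

    return ScoringResult(scores=scores, excluded_participants=excluded_participants)
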