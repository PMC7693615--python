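"""ROI pooling over the fronto-parietal montage.

Channel-level HBdiff summaries are pooled hierarchically: channels ->
sub-ROI (DLPFC / VLPFC / IPL / SPL per hemisphere) -> region (frontal =
mean of DLPFC and VLPFC sub-ROI means; parietal likewise) -> hemisphere.
Sub-ROI means rather than flat channel means keep regions comparable
when sub-ROIs contribute different channel counts; a flat mean is
available as a switch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .montage import MontageSpec, map_channels_to_rois


class RoiError(ValueError):
    pass


def pool_roi(summaries: pd.DataFrame, mapping: pd.DataFrame,
             level: str = "region", flat: bool = False) -> pd.DataFrame:
    """Pool per-channel scalar summaries to ROI activations.

    ``summaries`` needs columns ``channel, value`` plus any identifying
    columns (participant_id, time_point, ...) that are carried through;
    excluded/missing channels are simply absent (dropped, not imputed).
    ``level`` is one of ``subroi`` (sub-ROI x hemisphere), ``region``
    (frontal/parietal x hemisphere), or ``hemisphere``.  Returns a long
    table with ``value`` means and ``n_channels_used``.
    """
    if level not in ("subroi", "region", "hemisphere"):
        raise RoiError(f"unknown pooling level {level!r}")
    id_cols = [c for c in summaries.columns if c not in ("channel", "value")]
    df = summaries.merge(mapping, on="channel", how="inner")
    if df.empty:
        cols = id_cols + {"subroi": ["subroi"], "region": ["region"],
                          "hemisphere": []}[level] + ["hemisphere", "value",
                                                      "n_channels_used"]
        return pd.DataFrame(columns=list(dict.fromkeys(cols)))

    sub = (df.groupby(id_cols + ["region", "subroi", "hemisphere"], dropna=False)
             .agg(value=("value", "mean"), n_channels_used=("value", "size"))
             .reset_index())
    if level == "subroi":
        return sub
    if flat:
        out = (df.groupby(id_cols + ["region", "hemisphere"], dropna=False)
                 .agg(value=("value", "mean"), n_channels_used=("value", "size"))
                 .reset_index())
    else:
        out = (sub.groupby(id_cols + ["region", "hemisphere"], dropna=False)
                  .agg(value=("value", "mean"), n_channels_used=("n_channels_used", "sum"))
                  .reset_index())
    if level == "region":
        return out
    hemi = (out.groupby(id_cols + ["hemisphere"], dropna=False)
               .agg(value=("value", "mean"), n_channels_used=("n_channels_used", "sum"))
               .reset_index())
    return hemi


def roi_correlations(activations: pd.DataFrame, value_col: str = "value",
                     unit_cols: tuple = ("participant_id", "time_point"),
                     cell_col: str = "subroi") -> pd.DataFrame:
    """Pairwise Pearson correlations between ROI summaries across
    participant x time observations (used to justify pooling).

    Returns a table with columns ``roi_a, roi_b, r, p, n``.  Pairs with
    fewer than 3 complete observations raise :class:`RoiError`.
    """
    wide = activations.pivot_table(index=list(unit_cols), columns=cell_col,
                                   values=value_col, aggfunc="mean")
    cells = list(wide.columns)
    rows = []
    for i, a in enumerate(cells):
        for b in cells[i + 1:]:
            pair = wide[[a, b]].dropna()
            if len(pair) < 3:
                raise RoiError(f"fewer than 3 complete pairs for ({a}, {b})")
            r, p = sps.pearsonr(pair[a], pair[b])
            rows.append({"roi_a": a, "roi_b": b, "r": float(r), "p": float(p),
                         "n": len(pair)})
    return pd.DataFrame(rows)


def channel_summaries_to_activations(per_channel: pd.DataFrame, montage: MontageSpec,
                                     flat: bool = False) -> pd.DataFrame:
    """Convenience: map channels to ROIs and pool to region x hemisphere."""
    mapping = map_channels_to_rois(montage)
    return pool_roi(per_channel, mapping, level="region", flat=flat)
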