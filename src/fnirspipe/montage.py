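"""Fronto-parietal fNIRS montage: channel geometry and ROI assignment.

The default montage is a 16-source / 16-detector layout with 38 nominal
channels at ~3 cm source-detector separation.  18 channels cover the
bilateral dorsolateral and ventrolateral prefrontal cortex (DLPFC, VLPFC),
14 channels cover the bilateral inferior and superior parietal lobe
(IPL, SPL), and 6 lateral-posterior channels fall outside the
fronto-parietal working-memory network and are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SUB_ROIS = ("DLPFC", "VLPFC", "IPL", "SPL")
REGION_OF_SUBROI = {"DLPFC": "frontal", "VLPFC": "frontal", "IPL": "parietal", "SPL": "parietal"}
HEMISPHERES = ("left", "right")
DEFAULT_SD_DISTANCE_M = 0.03

MONTAGE_COLUMNS = ["channel", "source", "detector", "label_1020", "hemisphere", "roi"]

# channel, source, detector, nominal 10-20 label, hemisphere, ROI
# The channel -> ROI assignment is fixed by the montage design; 10-20 labels
# are nominal position markers only and are never used for computation.
_DEFAULT_ROWS = [
    (1, "S1", "D1", "F3", "left", "DLPFC"),
    (2, "S1", "D2", "F1", "left", "DLPFC"),
    (3, "S2", "D1", "AF3", "left", "DLPFC"),
    (4, "S2", "D2", "FC3", "left", "DLPFC"),
    (5, "S3", "D3", "F7", "left", "VLPFC"),
    (6, "S3", "D4", "F5", "left", "VLPFC"),
    (7, "S4", "D3", "FC5", "left", "VLPFC"),
    (8, "S4", "D4", "AF7", "left", "VLPFC"),
    (9, "S4", "D2", "FT7", "left", "VLPFC"),
    (10, "S5", "D5", "F8", "right", "VLPFC"),
    (11, "S5", "D6", "F6", "right", "VLPFC"),
    (12, "S6", "D5", "FC6", "right", "VLPFC"),
    (13, "S6", "D6", "AF8", "right", "VLPFC"),
    (14, "S7", "D7", "F4", "right", "DLPFC"),
    (15, "S8", "D7", "F2", "right", "DLPFC"),
    (16, "S6", "D7", "FT8", "right", "VLPFC"),
    (17, "S8", "D8", "AF4", "right", "DLPFC"),
    (18, "S7", "D8", "FC4", "right", "DLPFC"),
    (19, "S9", "D9", "CP5", "left", "IPL"),
    (20, "S9", "D10", "P1", "left", "SPL"),
    (21, "S10", "D9", "P5", "left", "IPL"),
    (22, "S10", "D10", "P3", "left", "IPL"),
    (23, "S11", "D11", "CP3", "left", "IPL"),
    (24, "S10", "D11", "CP1", "left", "SPL"),
    (25, "S11", "D10", "P7", "left", "IPL"),
    (26, "S11", "D12", "P9", "left", "excluded"),
    (27, "S12", "D11", "PO7", "left", "excluded"),
    (28, "S12", "D12", "PO3", "left", "excluded"),
    (29, "S13", "D13", "CP6", "right", "IPL"),
    (30, "S13", "D14", "P2", "right", "SPL"),
    (31, "S14", "D13", "P6", "right", "IPL"),
    (32, "S14", "D14", "P4", "right", "IPL"),
    (33, "S15", "D15", "CP4", "right", "IPL"),
    (34, "S14", "D15", "CP2", "right", "SPL"),
    (35, "S15", "D14", "P8", "right", "IPL"),
    (36, "S15", "D16", "P10", "right", "excluded"),
    (37, "S16", "D15", "PO8", "right", "excluded"),
    (38, "S16", "D16", "PO4", "right", "excluded"),
]


class MontageError(ValueError):
    """Raised for malformed or inconsistent montage definitions."""


@dataclass
class MontageSpec:
    """Channel table of a source-detector montage.

    ``table`` has columns ``channel, source, detector, label_1020,
    hemisphere, roi`` with ``roi`` in {DLPFC, VLPFC, IPL, SPL, excluded}.
    """

    table: pd.DataFrame
    distance_m: float = DEFAULT_SD_DISTANCE_M

    def __post_init__(self) -> None:
        missing = [c for c in MONTAGE_COLUMNS if c not in self.table.columns]
        if missing:
            raise MontageError(f"montage table missing columns: {missing}")
        bad_roi = set(self.table["roi"]) - set(SUB_ROIS) - {"excluded"}
        if bad_roi:
            raise MontageError(f"unknown ROI labels in montage: {sorted(bad_roi)}")
        bad_hemi = set(self.table["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise MontageError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        if self.table["channel"].duplicated().any():
            raise MontageError("duplicate channel ids in montage")
        self.table = self.table.reset_index(drop=True)

    @property
    def channels(self) -> list[int]:
        return list(self.table["channel"])

    @property
    def n_channels(self) -> int:
        return len(self.table)

    def roi_of(self, channel: int) -> str:
        row = self.table[self.table["channel"] == channel]
        if row.empty:
            raise MontageError(f"channel {channel} not in montage")
        return str(row["roi"].iloc[0])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, distance_m: float = DEFAULT_SD_DISTANCE_M) -> "MontageSpec":
        return cls(pd.read_csv(path), distance_m=distance_m)


def default_montage() -> MontageSpec:
    """The default 38-channel fronto-parietal montage (18 frontal, 14
    parietal, 6 excluded channels)."""
    table = pd.DataFrame(_DEFAULT_ROWS, columns=MONTAGE_COLUMNS)
    return MontageSpec(table)


def map_channels_to_rois(montage: MontageSpec) -> pd.DataFrame:
    """Channel -> (sub-ROI, region, hemisphere) mapping with excluded
    channels removed.

    Returns a DataFrame with columns ``channel, subroi, region,
    hemisphere``.
    """
    tab = montage.table
    kept = tab[tab["roi"] != "excluded"].copy()
    unknown = set(kept["roi"]) - set(SUB_ROIS)
    if unknown:
        raise MontageError(f"channels with unknown ROI label: {sorted(unknown)}")
    mapping = pd.DataFrame(
        {
            "channel": kept["channel"].to_numpy(),
            "subroi": kept["roi"].to_numpy(),
            "region": [REGION_OF_SUBROI[r] for r in kept["roi"]],
            "hemisphere": kept["hemisphere"].to_numpy(),
        }
    )
    return mapping.reset_index(drop=True)
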