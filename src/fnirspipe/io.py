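"""File IO: SNIRF-style HDF5 containers for fNIRS recordings, delimited
trial/score tables, and JSON reports.

The SNIRF writer stores intensity data as ``/nirs/data1`` with one
measurement-list entry per channel x wavelength, stimulus blocks as
``/nirs/stim*``, and the montage plus participant metadata under
``metaDataTags`` so a written recording round-trips losslessly through
:func:`read_snirf`.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import CONDITIONS, TRIAL_COLUMNS
from .montage import MontageSpec
from .preprocess import RawIntensityRecording


class SnirfFormatError(ValueError):
    pass


class SchemaError(ValueError):
    pass


def write_snirf(rec: RawIntensityRecording, path: str | Path) -> None:
    """Write a recording to a SNIRF-compatible HDF5 container."""
    n_ch = rec.intensity.shape[0]
    n_t = rec.n_samples
    data = rec.intensity.reshape(n_ch * 2, n_t).T  # (n_t, n_meas)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.participant_id)
        meta.create_dataset("Group", data=rec.group)
        meta.create_dataset("TimePoint", data=rec.time_point)
        meta.create_dataset("Age", data=float(rec.age_years))
        buf = _io.StringIO()
        rec.montage.table.to_csv(buf, index=False)
        meta.create_dataset("MontageTable", data=buf.getvalue())
        meta.create_dataset("SourceDetectorDistance", data=float(rec.montage.distance_m))

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths, float))

        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=rec.time)
        for i in range(n_ch):
            for wl in range(2):
                ml = d1.create_group(f"measurementList{i * 2 + wl + 1}")
                ml.create_dataset("sourceIndex", data=i + 1)
                ml.create_dataset("detectorIndex", data=i + 1)
                ml.create_dataset("wavelengthIndex", data=wl + 1)
                ml.create_dataset("dataType", data=1)
                ml.create_dataset("dataTypeIndex", data=1)
        for k, (cond, sub) in enumerate(rec.events.groupby("condition", sort=True)):
            st = nirs.create_group(f"stim{k + 1}")
            st.create_dataset("name", data=str(cond))
            arr = np.column_stack([sub["onset_s"], sub["duration_s"],
                                   np.ones(len(sub))])
            st.create_dataset("data", data=arr)


def _read_str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def read_snirf(path: str | Path) -> RawIntensityRecording:
    """Read a recording written by :func:`write_snirf`."""
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise SnirfFormatError(f"{path}: missing /nirs group")
        nirs = f["nirs"]
        meta = nirs["metaDataTags"]
        montage = MontageSpec(pd.read_csv(_io.StringIO(_read_str(meta["MontageTable"]))),
                              distance_m=float(meta["SourceDetectorDistance"][()]))
        wavelengths = tuple(np.asarray(nirs["probe/wavelengths"][()], float))
        d1 = nirs["data1"]
        data = np.asarray(d1["dataTimeSeries"][()], float)
        time = np.asarray(d1["time"][()], float)
        n_meas = data.shape[1]
        ml_keys = sorted((k for k in d1 if k.startswith("measurementList")),
                         key=lambda k: int(k[len("measurementList"):]))
        if len(ml_keys) != n_meas:
            raise SnirfFormatError(f"{path}: measurement list does not match data columns")
        wl_seen: dict[int, set] = {}
        for j, k in enumerate(ml_keys):
            src = int(d1[k]["sourceIndex"][()])
            wl = int(d1[k]["wavelengthIndex"][()])
            wl_seen.setdefault(src, set()).add(wl)
        for src, wls in wl_seen.items():
            if wls != {1, 2}:
                raise SnirfFormatError(
                    f"{path}: channel {src} missing wavelength "
                    f"{({1, 2} - wls)} in measurement list")
        n_ch = len(wl_seen)
        intensity = data.T.reshape(n_ch, 2, -1)
        ev_rows = []
        for k in sorted((k for k in nirs if k.startswith("stim")),
                        key=lambda k: int(k[4:])):
            name = _read_str(nirs[k]["name"])
            arr = np.atleast_2d(np.asarray(nirs[k]["data"][()], float))
            for onset, dur, _ in arr:
                ev_rows.append({"onset_s": onset, "duration_s": dur, "condition": name})
        events = pd.DataFrame(ev_rows).sort_values("onset_s").reset_index(drop=True)
        fs = 1.0 / np.median(np.diff(time)) if len(time) > 1 else 1.0
        return RawIntensityRecording(
            intensity=intensity, sample_rate=float(round(fs, 6)), montage=montage,
            events=events, age_years=float(meta["Age"][()]),
            wavelengths=wavelengths, participant_id=_read_str(meta["SubjectID"]),
            group=_read_str(meta["Group"]), time_point=_read_str(meta["TimePoint"]),
        )


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")
    trials.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: trial table missing columns: {missing}")
    bad = ~df["condition"].isin(CONDITIONS)
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(
            f"{path}: unknown condition {df.loc[row, 'condition']!r} at row {row}")
    return df


def write_ground_truth(truth, path: str | Path) -> None:
    """Serialize a :class:`~fnirspipe.simulate.GroundTruth` sidecar as JSON."""
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def write_json_report(report: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(report, indent=1, default=default))
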