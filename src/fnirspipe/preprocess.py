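"""fNIRS preprocessing chain: raw intensity -> optical density -> channel
quality control -> wavelet motion correction -> band-pass filtering ->
modified Beer-Lambert inversion -> block averaging -> channel outlier
exclusion -> hemoglobin difference.

Concentration changes are expressed in molar x 1e-8 throughout (so a
value of 1.0 means 10 nM).  The chain order is fixed; the orchestrator
:func:`preprocess_recording` refuses out-of-order stage requests, while
the individual stage functions remain pure and callable on their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pywt
from scipy import signal as spsig

from .montage import MontageSpec

log = logging.getLogger(__name__)

SAMPLE_RATE_HZ = 3.47
WAVELENGTHS_NM = (760.0, 850.0)
BLOCK_WINDOW_S = (-2.0, 45.0)
Z_CUTOFF = 3.29
CARDIAC_BAND_HZ = (0.5, 1.6)


class DataError(ValueError):
    """Raised for invalid signal data (e.g. non-positive intensities)."""


class ConfigurationError(ValueError):
    """Raised for invalid stage parameters."""


class PipelineOrderError(RuntimeError):
    """Raised when preprocessing stages are requested out of order."""


class QcNotEvaluableError(ValueError):
    """Raised when a recording is too short for spectral quality control."""


# ---------------------------------------------------------------------------
# containers

@dataclass
class RawIntensityRecording:
    """Dual-wavelength raw intensity time series for one session.

    ``intensity`` has shape (n_channels, 2, n_samples) with the wavelength
    axis ordered as ``wavelengths``.  ``events`` is a DataFrame with
    columns ``onset_s, duration_s, condition``.
    """

    intensity: np.ndarray
    sample_rate: float
    montage: MontageSpec
    events: pd.DataFrame
    age_years: float
    wavelengths: tuple[float, float] = WAVELENGTHS_NM
    participant_id: str = ""
    group: str = ""
    time_point: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
            raise DataError("intensity must have shape (n_channels, 2, n_samples)")
        if self.intensity.shape[0] != self.montage.n_channels:
            raise DataError("intensity channel count does not match montage")
        dur = self.intensity.shape[2] / self.sample_rate
        if len(self.events) and (self.events["onset_s"].min() < 0
                                 or self.events["onset_s"].max() > dur):
            raise DataError("event onsets outside the recording span")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    @property
    def channels(self) -> list[int]:
        return self.montage.channels


@dataclass
class OpticalDensitySeries:
    """Per channel x wavelength optical-density change (unitless)."""

    od: np.ndarray                      # (n_channels, 2, n_samples)
    sample_rate: float
    channels: list[int]
    events: pd.DataFrame
    age_years: float
    montage: MontageSpec | None = None
    wavelengths: tuple[float, float] = WAVELENGTHS_NM
    qc_passed: np.ndarray | None = None  # boolean per channel, set by QC
    motion_corrected: bool = False
    filtered: bool = False
    participant_id: str = ""
    group: str = ""
    time_point: str = ""


@dataclass
class HemoglobinSeries:
    """Per channel hemoglobin concentration changes in molar x 1e-8."""

    hbo: np.ndarray                     # (n_channels, n_samples)
    hhb: np.ndarray
    sample_rate: float
    channels: list[int]
    events: pd.DataFrame
    participant_id: str = ""
    group: str = ""
    time_point: str = ""

    def __post_init__(self) -> None:
        if self.hbo.shape != self.hhb.shape:
            raise DataError("O2Hb and HHb series must be aligned")

    @property
    def hbt(self) -> np.ndarray:
        return self.hbo + self.hhb

    @property
    def hbdiff(self) -> np.ndarray:
        return self.hbo - self.hhb


@dataclass
class BlockAverage:
    """Block-averaged hemodynamic response per channel x condition.

    Each entry of ``hbo``/``hhb`` maps condition -> array of shape
    (n_channels, n_window_samples); epochs are baseline-corrected by the
    mean over the pre-onset window before averaging.
    """

    hbo: dict
    hhb: dict
    time: np.ndarray
    channels: list[int]
    n_epochs: dict
    window_s: tuple[float, float] = BLOCK_WINDOW_S

    @property
    def hbdiff(self) -> dict:
        return {c: self.hbo[c] - self.hhb[c] for c in self.hbo}

    @property
    def hbt(self) -> dict:
        return {c: self.hbo[c] + self.hhb[c] for c in self.hbo}


@dataclass
class ExtinctionTable:
    """Molar extinction coefficients in 1/(M*cm) at the two wavelengths.

    Defaults are the standard compiled values for human hemoglobin
    (Prahl's tabulation) at 760 and 850 nm.
    """

    wavelengths: tuple[float, float] = WAVELENGTHS_NM
    eps_hbo: tuple[float, float] = (586.0, 1058.0)
    eps_hhb: tuple[float, float] = (1548.52, 691.32)

    def matrix(self) -> np.ndarray:
        m = np.array([[self.eps_hbo[0], self.eps_hhb[0]],
                      [self.eps_hbo[1], self.eps_hhb[1]]], dtype=float)
        if abs(np.linalg.det(m)) < 1e-12:
            raise ConfigurationError("extinction matrix is singular")
        if np.linalg.cond(m) > 1e6:
            raise ConfigurationError("extinction matrix is ill-conditioned")
        return m


@dataclass
class DpfModel:
    """Age-dependent differential pathlength factor, referenced to 807 nm:
    DPF(A) = a + b * A**c with A in years."""

    a: float = 4.99
    b: float = 0.067
    c: float = 0.814
    reference_wavelength_nm: float = 807.0

    def __call__(self, age_years: float) -> float:
        return compute_dpf(age_years, self)


def compute_dpf(age_years: float, model: DpfModel | None = None) -> float:
    """Differential pathlength factor for a participant of the given age."""
    if age_years < 0:
        raise ConfigurationError("age must be non-negative")
    m = model or DpfModel()
    return m.a + m.b * age_years ** m.c


# ---------------------------------------------------------------------------
# stages

def intensity_to_od(rec: RawIntensityRecording) -> OpticalDensitySeries:
    """Convert raw intensities to optical-density changes,
    dOD(t) = -ln(I(t) / mean(I)), per channel and wavelength."""
    inten = rec.intensity
    if np.any(inten <= 0):
        ch, wl, t = np.argwhere(inten <= 0)[0]
        raise DataError(
            f"non-positive intensity at channel {rec.channels[ch]}, "
            f"wavelength {rec.wavelengths[wl]:g} nm, sample {t}"
        )
    od = -np.log(inten / inten.mean(axis=2, keepdims=True))
    return OpticalDensitySeries(
        od=od, sample_rate=rec.sample_rate, channels=list(rec.channels),
        events=rec.events.copy(), age_years=rec.age_years, montage=rec.montage,
        wavelengths=rec.wavelengths, participant_id=rec.participant_id,
        group=rec.group, time_point=rec.time_point,
    )


def cardiac_quality_check(od: OpticalDensitySeries,
                          band: tuple[float, float] = CARDIAC_BAND_HZ,
                          prominence_factor: float = 3.0,
                          nperseg: int = 256) -> np.ndarray:
    """Per-channel scalp-contact check via the cardiac spectral peak.

    A channel passes if the Welch power spectrum of its 850 nm (O2Hb
    dominant) OD series has a maximum inside the cardiac band exceeding
    ``prominence_factor`` times the median broadband power.  Returns a
    boolean pass mask and stores it on ``od.qc_passed``.
    """
    n = od.od.shape[2]
    if n / od.sample_rate < 60.0:
        raise QcNotEvaluableError("recording shorter than 60 s; cardiac QC not evaluable")
    idx_850 = int(np.argmin(np.abs(np.asarray(od.wavelengths) - 850.0)))
    x = od.od[:, idx_850, :]
    nps = min(nperseg, n)
    freqs, pxx = spsig.welch(x, fs=od.sample_rate, nperseg=nps, axis=-1)
    band_mask = (freqs >= band[0]) & (freqs <= band[1])
    if not band_mask.any():
        raise ConfigurationError("cardiac band outside resolvable frequencies")
    broadband = np.median(pxx[:, freqs > 0], axis=1)
    peak = pxx[:, band_mask].max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        passed = peak > prominence_factor * broadband
    passed = np.where(np.isfinite(peak) & (broadband > 0), passed, False)
    od.qc_passed = passed
    n_fail = int((~passed).sum())
    if n_fail:
        log.info("cardiac QC: %d/%d channels failed", n_fail, len(passed))
    return passed


#: smallest number of coefficients per detail level for quartile statistics;
#: caps the decomposition depth so the slow hemodynamic band stays in the
#: untouched approximation
MIN_COEFFS_PER_LEVEL = 32


def _wavelet_correct_1d(x: np.ndarray, iqr_factor: float, wavelet: str) -> np.ndarray:
    n = len(x)
    max_level = min(pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len),
                    int(np.log2(max(n / MIN_COEFFS_PER_LEVEL, 1.0))))
    if max_level < 1:
        return x.copy()
    coeffs = pywt.wavedec(x, wavelet, mode="symmetric", level=max_level)
    out = [coeffs[0]]
    for detail in coeffs[1:]:
        q1, q3 = np.percentile(detail, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
        d = detail.copy()
        d[(d < lo) | (d > hi)] = 0.0
        out.append(d)
    rec = pywt.waverec(out, wavelet, mode="symmetric")
    return rec[:n]


def wavelet_motion_correct(od: OpticalDensitySeries, iqr_factor: float = 0.1,
                           wavelet: str = "db2") -> OpticalDensitySeries:
    """Wavelet-domain motion-artifact removal.

    Each channel x wavelength series is decomposed with a Daubechies-2
    discrete wavelet transform; detail coefficients falling outside
    [Q1 - f*IQR, Q3 + f*IQR] of their level's distribution (spikes and
    abrupt shifts) are zeroed before reconstruction.  Output length
    equals input length.
    """
    if not np.all(np.isfinite(od.od)):
        raise DataError("non-finite values in OD series")
    corrected = np.empty_like(od.od)
    for ch in range(od.od.shape[0]):
        for wl in range(od.od.shape[1]):
            corrected[ch, wl] = _wavelet_correct_1d(od.od[ch, wl], iqr_factor, wavelet)
    out = replace(od, od=corrected)
    out.motion_corrected = True
    return out


def bandpass_filter(od: OpticalDensitySeries, low: float = 0.01, high: float = 0.08,
                    lp_order: int = 3, hp_order: int = 5) -> OpticalDensitySeries:
    """Zero-phase Butterworth band-pass (high-pass order 5 at ``low``,
    low-pass order 3 at ``high``), applied forward-backward."""
    nyq = od.sample_rate / 2.0
    if not (0 < low < high < nyq):
        raise ConfigurationError(
            f"require 0 < low < high < Nyquist ({nyq:.3f} Hz); got {low}, {high}")
    sos_hp = spsig.butter(hp_order, low, btype="highpass", fs=od.sample_rate, output="sos")
    sos_lp = spsig.butter(lp_order, high, btype="lowpass", fs=od.sample_rate, output="sos")
    x = spsig.sosfiltfilt(sos_hp, od.od, axis=-1)
    x = spsig.sosfiltfilt(sos_lp, x, axis=-1)
    out = replace(od, od=x)
    out.filtered = True
    return out


def mbll_invert(od: OpticalDensitySeries, distance_m: float | None = None,
                ext: ExtinctionTable | None = None,
                dpf: float | None = None) -> HemoglobinSeries:
    """Modified Beer-Lambert inversion to concentration changes.

    Solves, per channel and sample, dOD(lambda) = eps(lambda, chromophore)
    . dc * d * DPF for (dHbO, dHHb), with d the source-detector distance
    in cm and DPF the (age-dependent) differential pathlength factor.
    Output is scaled to molar x 1e-8.
    """
    ext = ext or ExtinctionTable()
    if tuple(ext.wavelengths) != tuple(od.wavelengths):
        raise ConfigurationError("extinction table wavelengths do not match recording")
    if distance_m is None:
        if od.montage is None:
            raise ConfigurationError("source-detector distance required")
        distance_m = od.montage.distance_m
    d_cm = distance_m * 100.0
    if dpf is None:
        dpf = compute_dpf(od.age_years)
    e = ext.matrix()
    e_inv = np.linalg.inv(e)
    # od: (n_ch, 2, n_t); concentrations in molar, then rescale
    conc = np.einsum("ij,cjt->cit", e_inv, od.od) / (d_cm * dpf)
    scale = 1e8
    return HemoglobinSeries(
        hbo=conc[:, 0, :] * scale, hhb=conc[:, 1, :] * scale,
        sample_rate=od.sample_rate, channels=list(od.channels),
        events=od.events.copy(), participant_id=od.participant_id,
        group=od.group, time_point=od.time_point,
    )


def mbll_forward(hbo: np.ndarray, hhb: np.ndarray, distance_m: float, dpf: float,
                 ext: ExtinctionTable | None = None) -> np.ndarray:
    """Forward Beer-Lambert map: concentrations (molar x 1e-8, shape
    (n_ch, n_t)) to dOD of shape (n_ch, 2, n_t).  Inverse of
    :func:`mbll_invert` up to numerical precision."""
    ext = ext or ExtinctionTable()
    e = ext.matrix()
    conc = np.stack([hbo, hhb], axis=1) / 1e8
    return np.einsum("ij,cjt->cit", e, conc) * (distance_m * 100.0) * dpf


def block_average(hb: HemoglobinSeries, events: pd.DataFrame | None = None,
                  window_s: tuple[float, float] = BLOCK_WINDOW_S) -> BlockAverage:
    """Epoch and average the hemodynamic response per channel x condition.

    Epochs run over ``window_s`` relative to each event onset (closed on
    the left, open on the right in samples); each epoch is corrected by
    the mean of its pre-onset baseline before averaging.  Epochs whose
    window exceeds the recording are dropped with a warning.
    """
    ev = hb.events if events is None else events
    fs = hb.sample_rate
    n_pre = int(round(-window_s[0] * fs))
    n_win = int(round((window_s[1] - window_s[0]) * fs))
    n_t = hb.hbo.shape[1]
    t = (np.arange(n_win) - n_pre) / fs
    hbo_avg, hhb_avg, n_epochs = {}, {}, {}
    for cond, sub in ev.groupby("condition"):
        ep_hbo, ep_hhb = [], []
        for onset in sub["onset_s"]:
            i0 = int(round(onset * fs)) - n_pre
            if i0 < 0 or i0 + n_win > n_t:
                log.warning("epoch at %.1f s exceeds recording bounds; dropped", onset)
                continue
            for src, dst in ((hb.hbo, ep_hbo), (hb.hhb, ep_hhb)):
                epoch = src[:, i0:i0 + n_win]
                baseline = epoch[:, :n_pre].mean(axis=1, keepdims=True) if n_pre else 0.0
                dst.append(epoch - baseline)
        if not ep_hbo:
            log.warning("condition %s: zero usable epochs; cell missing", cond)
            continue
        hbo_avg[cond] = np.mean(ep_hbo, axis=0)
        hhb_avg[cond] = np.mean(ep_hhb, axis=0)
        n_epochs[cond] = len(ep_hbo)
    return BlockAverage(hbo=hbo_avg, hhb=hhb_avg, time=t, channels=list(hb.channels),
                        n_epochs=n_epochs, window_s=window_s)


def hemoglobin_difference(hb: HemoglobinSeries | BlockAverage):
    """HBdiff = O2Hb - HHb, the composite oxygenation index."""
    return hb.hbdiff


def channel_summary(avg: BlockAverage, condition: str,
                    window_s: tuple[float, float] = (0.0, 45.0),
                    measure: str = "hbdiff") -> np.ndarray:
    """Scalar per-channel summary of the block average: the mean of the
    baseline-corrected response over ``window_s`` (default 0-45 s)."""
    data = getattr(avg, measure)[condition]
    mask = (avg.time >= window_s[0]) & (avg.time < window_s[1])
    return data[:, mask].mean(axis=1)


def channel_outlier_filter(values: np.ndarray, cutoff: float = Z_CUTOFF) -> np.ndarray:
    """Exclusion mask for channels whose scalar summary is extreme
    (|z| > cutoff) across channels within one condition x time cell."""
    v = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(v)) < 3:
        raise ValueError("need at least 3 finite channel values")
    sd = np.nanstd(v, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        log.warning("zero variance across channels; no outlier exclusions")
        return np.zeros(v.shape, dtype=bool)
    z = (v - np.nanmean(v)) / sd
    return np.abs(z) > cutoff


# ---------------------------------------------------------------------------
# orchestrator

STAGE_ORDER = ("od", "qc", "wavelet", "bandpass", "mbll", "block_average")


@dataclass
class PreprocessParams:
    """All tunable preprocessing parameters with the study defaults."""

    low_hz: float = 0.01
    high_hz: float = 0.08
    lp_order: int = 3
    hp_order: int = 5
    iqr_factor: float = 0.1
    wavelet: str = "db2"
    cardiac_band_hz: tuple[float, float] = CARDIAC_BAND_HZ
    qc_prominence: float = 3.0
    z_cutoff: float = Z_CUTOFF
    window_s: tuple[float, float] = BLOCK_WINDOW_S
    summary_window_s: tuple[float, float] = (0.0, 45.0)
    extinction: ExtinctionTable = field(default_factory=ExtinctionTable)
    dpf_model: DpfModel = field(default_factory=DpfModel)
    run_qc: bool = True


@dataclass
class PreprocessResult:
    od_raw: OpticalDensitySeries
    od_clean: OpticalDensitySeries
    hb: HemoglobinSeries
    block_avg: BlockAverage
    qc_passed: np.ndarray
    dropped_channels: list


def preprocess_recording(rec: RawIntensityRecording,
                         params: PreprocessParams | None = None,
                         stages: tuple[str, ...] = STAGE_ORDER) -> PreprocessResult:
    """Run the full preprocessing chain in its fixed order.

    ``stages`` must be an in-order subsequence of ``STAGE_ORDER`` starting
    at ``od``; anything else raises :class:`PipelineOrderError`.
    """
    params = params or PreprocessParams()
    order = {s: i for i, s in enumerate(STAGE_ORDER)}
    unknown = [s for s in stages if s not in order]
    if unknown:
        raise PipelineOrderError(f"unknown stages: {unknown}")
    idx = [order[s] for s in stages]
    if idx != sorted(idx) or len(set(idx)) != len(idx) or (stages and stages[0] != "od"):
        raise PipelineOrderError(
            f"stages must follow the fixed order {STAGE_ORDER}, got {stages}")

    od_raw = intensity_to_od(rec)
    od = od_raw
    qc_passed = np.ones(rec.montage.n_channels, dtype=bool)
    if "qc" in stages and params.run_qc:
        qc_passed = cardiac_quality_check(od, band=params.cardiac_band_hz,
                                          prominence_factor=params.qc_prominence)
    if "wavelet" in stages:
        od = wavelet_motion_correct(od, iqr_factor=params.iqr_factor,
                                    wavelet=params.wavelet)
    if "bandpass" in stages:
        od = bandpass_filter(od, low=params.low_hz, high=params.high_hz,
                             lp_order=params.lp_order, hp_order=params.hp_order)
    od.qc_passed = qc_passed
    dpf = compute_dpf(rec.age_years, params.dpf_model)
    hb = mbll_invert(od, ext=params.extinction, dpf=dpf) if "mbll" in stages else None
    avg = block_average(hb, window_s=params.window_s) if (hb is not None and
                                                          "block_average" in stages) else None
    dropped = [ch for ch, ok in zip(rec.channels, qc_passed) if not ok]
    return PreprocessResult(od_raw=od_raw, od_clean=od, hb=hb, block_avg=avg,
                            qc_passed=qc_passed, dropped_channels=dropped)
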