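"""Synthetic fNIRS recordings and n-back behavioral sessions with known
ground truth.

The simulator emulates a two-group (experimental / control), four
time-point (pre, post15, post30, post45) study in which participants
perform a letter n-back task (0-, 1-, 2-back) while dual-wavelength fNIRS
is recorded over a fronto-parietal montage.  Every generated dataset
carries a :class:`GroundTruth` sidecar that downstream pipeline stages
never consume -- it exists purely so tests can verify recovery.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .montage import MontageSpec, REGION_OF_SUBROI, SUB_ROIS, default_montage
from .preprocess import (
    DpfModel,
    ExtinctionTable,
    RawIntensityRecording,
    SAMPLE_RATE_HZ,
    compute_dpf,
    mbll_forward,
)

GROUPS = ("experimental", "control")
TIME_POINTS = ("pre", "post15", "post30", "post45")
CONDITIONS = ("0-back", "1-back", "2-back")

# n-back schedule: 6 task blocks of 45 s (2 per condition, 15 trials each)
# separated by 27 s rests; total task time 6 * 45 + 5 * 27 = 405 s = 6:45.
BLOCK_DURATION_S = 45.0
REST_DURATION_S = 27.0
N_BLOCKS = 6
TRIALS_PER_BLOCK = 15
TARGETS_PER_BLOCK = 5
STIMULUS_MS = 500.0
RESPONSE_WINDOW_MS = 1500.0
JITTER_MS = (800.0, 1200.0)

#: evoked response scaling per load condition (2-back defines the unit)
LOAD_SCALE = {"0-back": 0.4, "1-back": 0.7, "2-back": 1.0}


class SimulationConfigError(ValueError):
    """Raised for invalid simulation configurations."""


def task_duration_s() -> float:
    """Total task duration: blocks plus rests between consecutive blocks."""
    return N_BLOCKS * BLOCK_DURATION_S + (N_BLOCKS - 1) * REST_DURATION_S


def expected_trial_time_ms() -> float:
    """Mean trial time: stimulus + response interval + mean onset jitter."""
    return STIMULUS_MS + RESPONSE_WINDOW_MS + 0.5 * (JITTER_MS[0] + JITTER_MS[1])


# ---------------------------------------------------------------------------
# configuration

@dataclass
class NoiseSpec:
    """Physiological and instrumental noise amplitudes (molar x 1e-8 on
    the O2Hb trace) and center frequencies (Hz)."""

    cardiac_amp: float = 1.0
    cardiac_freq: float = 1.1
    respiratory_amp: float = 0.5
    respiratory_freq: float = 0.3
    mayer_amp: float = 0.8
    mayer_freq: float = 0.1
    drift_amp: float = 2.0
    drift_freq: float = 0.004
    white_sd: float = 0.3
    hhb_noise_ratio: float = 0.4

    def validate(self) -> None:
        for name in ("cardiac_amp", "respiratory_amp", "mayer_amp", "drift_amp", "white_sd"):
            if getattr(self, name) < 0:
                raise SimulationConfigError(f"noise amplitude {name} must be >= 0")


@dataclass
class ArtifactSpec:
    """Motion-artifact injection: one-sample spikes and step baseline
    shifts (persisting to the end of the recording), both in OD units."""

    spike_rate_hz: float = 0.005
    spike_od_amp: float = 0.005
    shift_rate_hz: float = 0.0005
    shift_od_amp: float = 0.002

    def validate(self) -> None:
        if min(self.spike_rate_hz, self.shift_rate_hz) < 0:
            raise SimulationConfigError("artifact rates must be >= 0")


@dataclass
class BehaviorCell:
    """Response distribution for one group x time x condition cell."""

    accuracy: float
    rt_median_ms: float
    rt_sigma: float = 0.25          # log-normal shape
    omission_p: float = 0.02
    premature_p: float = 0.01

    def validate(self) -> None:
        if not 0 <= self.accuracy <= 1:
            raise SimulationConfigError("accuracy must be in [0, 1]")
        if self.rt_sigma <= 0 or self.rt_median_ms <= 0:
            raise SimulationConfigError("RT scale parameters must be > 0")
        if not (0 <= self.omission_p <= 1 and 0 <= self.premature_p <= 1):
            raise SimulationConfigError("probabilities must be in [0, 1]")


# study-like 2-back response profiles per group x time point
_2BACK_PROFILE = {
    ("experimental", "pre"): (0.8462, 837.34),
    ("experimental", "post15"): (0.9170, 788.38),
    ("experimental", "post30"): (0.8887, 809.00),
    ("experimental", "post45"): (0.9170, 796.57),
    ("control", "pre"): (0.8662, 885.07),
    ("control", "post15"): (0.8846, 857.52),
    ("control", "post30"): (0.8880, 847.58),
    ("control", "post45"): (0.8930, 846.37),
}


def default_behavior_spec() -> dict:
    """Per (group, time_point, condition) response distributions.

    The 2-back cells follow the study-like accuracy/RT profile; 0- and
    1-back are near ceiling, as observed for low loads in older adults.
    """
    spec = {}
    for g in GROUPS:
        for tp in TIME_POINTS:
            acc2, rt2 = _2BACK_PROFILE[(g, tp)]
            spec[(g, tp, "0-back")] = BehaviorCell(accuracy=0.98, rt_median_ms=550.0)
            spec[(g, tp, "1-back")] = BehaviorCell(accuracy=0.95, rt_median_ms=650.0)
            spec[(g, tp, "2-back")] = BehaviorCell(accuracy=acc2, rt_median_ms=rt2)
    return spec


#: study-like per-cell mean and SE of the 2-back rate-correct score
RCS_CELL_MEANS = {
    ("experimental", "pre"): 1.05, ("experimental", "post15"): 1.24,
    ("experimental", "post30"): 1.15, ("experimental", "post45"): 1.22,
    ("control", "pre"): 1.05, ("control", "post15"): 1.12,
    ("control", "post30"): 1.13, ("control", "post45"): 1.13,
}
RCS_CELL_SES = {
    ("experimental", "pre"): 0.05, ("experimental", "post15"): 0.08,
    ("experimental", "post30"): 0.06, ("experimental", "post45"): 0.07,
    ("control", "pre"): 0.07, ("control", "post15"): 0.07,
    ("control", "post30"): 0.07, ("control", "post45"): 0.07,
}
N_PER_GROUP = {"experimental": 19, "control": 23}
#: within-participant correlation of repeated scores (test-retest)
DEFAULT_SCORE_ICC = 0.75


@dataclass
class SimulationConfig:
    """Everything the simulator needs for one cohort."""

    n_per_group: int = 20
    group_labels: tuple[str, str] = GROUPS
    time_points: tuple[str, ...] = TIME_POINTS
    age_mean: float = 69.18
    age_sd: float = 3.92
    #: evoked O2Hb amplitude (molar x 1e-8) per region, or per
    #: (group, time_point, region) for group/time-specific effects
    hrf_amplitude: dict = field(default_factory=lambda: {"frontal": 1.0, "parietal": 1.6})
    hrf_hhb_ratio: float = -1.0 / 3.0
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    behavior: dict = field(default_factory=default_behavior_spec)
    roi_correlation: float = 0.8
    amplitude_sigma: float = 0.3     # participant-level lognormal spread per sub-ROI
    channel_sigma: float = 0.2       # channel-level lognormal spread
    sample_rate: float = SAMPLE_RATE_HZ
    pre_baseline_s: float = 12.0
    post_baseline_s: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.time_points) != 4:
            raise SimulationConfigError("time_points must have exactly 4 ordered labels")
        if self.n_per_group < 1:
            raise SimulationConfigError("n_per_group must be >= 1")
        if not -1 <= self.roi_correlation <= 1:
            raise SimulationConfigError("roi_correlation must be in [-1, 1]")
        self.noise.validate()
        self.artifacts.validate()
        for key, cell in self.behavior.items():
            if key[2] not in CONDITIONS:
                raise SimulationConfigError(f"unknown condition in behavior spec: {key}")
            cell.validate()

    def amplitude(self, group: str, time_point: str, region: str) -> float:
        amp = self.hrf_amplitude
        if isinstance(amp, (int, float)):
            return float(amp)
        if (group, time_point, region) in amp:
            return float(amp[(group, time_point, region)])
        if region in amp:
            return float(amp[region])
        raise SimulationConfigError(
            f"no evoked amplitude for ({group}, {time_point}, {region})")


@dataclass
class Participant:
    participant_id: str
    group: str
    age_years: float
    mmse: float = 29.0


@dataclass
class GroundTruth:
    """Generating quantities stored next to each simulated recording;
    consumed only by tests, never by pipeline stages."""

    channel_amplitude: np.ndarray          # evoked O2Hb peak per channel (1e-8 M, 2-back)
    hbo_clean: np.ndarray                  # evoked-only concentration series
    hhb_clean: np.ndarray
    spike_times_s: list
    shift_times_s: list
    events: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "channel_amplitude": self.channel_amplitude.tolist(),
            "spike_times_s": list(map(float, self.spike_times_s)),
            "shift_times_s": list(map(float, self.shift_times_s)),
            "events": self.events.to_dict(orient="list"),
        }


# ---------------------------------------------------------------------------
# hemodynamics

def canonical_hrf(t, peak_time: float = 6.0, undershoot_time: float = 16.0,
                  undershoot_ratio: float = 1.0 / 6.0):
    """Canonical double-gamma hemodynamic impulse response.

    A gamma density peaking at ``peak_time`` minus ``undershoot_ratio``
    times a gamma density peaking at ``undershoot_time`` (unit scale, so
    shape = peak + 1).  Zero at the origin and for t < 0; integrates to
    1 - undershoot_ratio.
    """
    if peak_time <= 0 or undershoot_time <= 0:
        raise SimulationConfigError("shape parameters must be positive")
    if undershoot_ratio < 0:
        raise SimulationConfigError("undershoot_ratio must be >= 0")
    if peak_time >= undershoot_time:
        raise SimulationConfigError("peak_time must precede undershoot_time")
    t = np.asarray(t, dtype=float)
    h = sps.gamma.pdf(t, peak_time + 1.0) - undershoot_ratio * sps.gamma.pdf(
        t, undershoot_time + 1.0)
    return np.where(t >= 0, h, 0.0)


def block_onsets_s(pre_baseline_s: float = 0.0) -> np.ndarray:
    """Onsets of the six task blocks relative to recording start."""
    return pre_baseline_s + np.arange(N_BLOCKS) * (BLOCK_DURATION_S + REST_DURATION_S)


def _block_order(rng: np.random.Generator) -> list[str]:
    order = list(CONDITIONS) * (N_BLOCKS // len(CONDITIONS))
    rng.shuffle(order)
    return order


def _seed_for(config_seed: int, *labels) -> np.random.SeedSequence:
    parts = [int(config_seed) & 0x7FFFFFFF]
    for lab in labels:
        parts.append(zlib.crc32(str(lab).encode()) & 0x7FFFFFFF)
    return np.random.SeedSequence(parts)


# ---------------------------------------------------------------------------
# behavioral sessions

def generate_behavioral_session(config: SimulationConfig, participant: Participant,
                                time_point: str, seed=None) -> pd.DataFrame:
    """One n-back session: 3 conditions x 2 blocks x 15 trials.

    Each block contains exactly five target trials.  Stimulus onsets
    accumulate 500 ms stimulus + 1500 ms response interval + U(800, 1200)
    ms jitter.  Responses are drawn from the participant's group x time x
    condition behavior cell; the same seed reproduces the table exactly.
    """
    config.validate()
    if time_point not in config.time_points:
        raise SimulationConfigError(f"unknown time point {time_point!r}")
    if seed is None:
        seed = _seed_for(config.seed, "behavior", participant.participant_id, time_point)
    rng = np.random.default_rng(seed)

    order = _block_order(rng)
    onsets = block_onsets_s()
    block_index = {c: 0 for c in CONDITIONS}
    rows = []
    for b, cond in enumerate(order):
        block_index[cond] += 1
        cell: BehaviorCell = config.behavior[(participant.group, time_point, cond)]
        target_pos = set(rng.choice(TRIALS_PER_BLOCK, size=TARGETS_PER_BLOCK, replace=False))
        t_cursor = onsets[b]
        for trial in range(TRIALS_PER_BLOCK):
            jitter = rng.uniform(*JITTER_MS) / 1000.0
            onset = t_cursor + jitter
            t_cursor = onset + (STIMULUS_MS + RESPONSE_WINDOW_MS) / 1000.0
            is_target = trial in target_pos
            correct_key = "match" if is_target else "non-match"
            wrong_key = "non-match" if is_target else "match"
            u = rng.uniform()
            if u < cell.omission_p:
                response, rt = "none", np.nan
            elif u < cell.omission_p + cell.premature_p:
                response = correct_key if rng.uniform() < 0.5 else wrong_key
                rt = rng.uniform(80.0, 199.0)
            else:
                response = correct_key if rng.uniform() < cell.accuracy else wrong_key
                rt = float(np.exp(rng.normal(np.log(cell.rt_median_ms), cell.rt_sigma)))
                rt = float(np.clip(rt, 200.0, 2000.0))
            rows.append({
                "participant_id": participant.participant_id,
                "group": participant.group,
                "time_point": time_point,
                "condition": cond,
                "block": block_index[cond],
                "trial": trial + 1,
                "onset_s": onset,
                "is_target": is_target,
                "response": response,
                "rt_ms": rt,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fNIRS recordings

def draw_participant_amplitudes(config: SimulationConfig, rng: np.random.Generator) -> dict:
    """Per-participant multiplicative evoked-amplitude factor for each
    sub-ROI, log-normal with target between-ROI correlation."""
    rho = config.roi_correlation
    k = len(SUB_ROIS)
    cov = np.full((k, k), rho)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(k), cov, method="cholesky")
    s = config.amplitude_sigma
    return {roi: float(np.exp(s * z[i] - s * s / 2.0)) for i, roi in enumerate(SUB_ROIS)}


def generate_nirs_recording(config: SimulationConfig, montage: MontageSpec | None,
                            participant: Participant, time_point: str, seed=None,
                            ext: ExtinctionTable | None = None,
                            dpf_model: DpfModel | None = None,
                            ) -> tuple[RawIntensityRecording, GroundTruth]:
    """Forward-model one fNIRS session.

    Per-channel O2Hb/HHb concentration series (evoked block design
    convolved with the canonical double-gamma response, plus cardiac /
    respiratory / Mayer / drift / white noise) are pushed through the
    forward Beer-Lambert relation at both wavelengths with the
    participant's age-dependent pathlength factor, converted to
    intensities about a unit per-channel baseline, and contaminated with
    spike and baseline-shift artifacts.
    """
    config.validate()
    if time_point not in config.time_points:
        raise SimulationConfigError(f"unknown time point {time_point!r}")
    montage = montage or default_montage()
    if seed is None:
        seed = _seed_for(config.seed, "nirs", participant.participant_id, time_point)
    rng = np.random.default_rng(seed)
    fs = config.sample_rate

    duration = config.pre_baseline_s + task_duration_s() + config.post_baseline_s
    n_t = int(round(duration * fs))
    t = np.arange(n_t) / fs

    onsets = block_onsets_s(config.pre_baseline_s)
    order = _block_order(rng)
    events = pd.DataFrame({"onset_s": onsets, "duration_s": BLOCK_DURATION_S,
                           "condition": order})

    # unit-peak response of a single 45 s block
    hrf = canonical_hrf(np.arange(0, 32.0, 1.0 / fs), config.hrf_peak_s,
                        config.hrf_undershoot_s, config.hrf_undershoot_ratio)
    regressors = {}
    unit = None
    for cond in CONDITIONS:
        box = np.zeros(n_t)
        for onset, c in zip(onsets, order):
            if c == cond:
                i0 = int(round(onset * fs))
                box[i0:i0 + int(round(BLOCK_DURATION_S * fs))] = 1.0
        conv = np.convolve(box, hrf)[:n_t]
        if unit is None:
            single = np.zeros(n_t)
            single[int(round(onsets[0] * fs)):int(round(onsets[0] * fs))
                   + int(round(BLOCK_DURATION_S * fs))] = 1.0
            unit = np.convolve(single, hrf)[:n_t].max()
        regressors[cond] = conv / unit

    roi_factor = draw_participant_amplitudes(config, rng)
    n_ch = montage.n_channels
    amp = np.zeros(n_ch)
    for i, (_, row) in enumerate(montage.table.iterrows()):
        roi = row["roi"]
        if roi == "excluded":
            continue
        base = config.amplitude(participant.group, time_point, REGION_OF_SUBROI[roi])
        ch_jit = float(np.exp(config.channel_sigma * rng.normal()
                              - config.channel_sigma ** 2 / 2.0))
        amp[i] = base * roi_factor[roi] * ch_jit

    evoked = sum(LOAD_SCALE[c] * regressors[c] for c in CONDITIONS)
    hbo_clean = amp[:, None] * evoked[None, :]
    hhb_clean = config.hrf_hhb_ratio * hbo_clean

    def physiological_noise() -> np.ndarray:
        ns = config.noise
        out = np.zeros((n_ch, n_t))
        for a, f in ((ns.cardiac_amp, ns.cardiac_freq),
                     (ns.respiratory_amp, ns.respiratory_freq),
                     (ns.mayer_amp, ns.mayer_freq),
                     (ns.drift_amp, ns.drift_freq)):
            if a <= 0:
                continue
            freq = f * (1.0 + 0.05 * rng.standard_normal((n_ch, 1)))
            phase = rng.uniform(0, 2 * np.pi, (n_ch, 1))
            out += a * np.sin(2 * np.pi * freq * t[None, :] + phase)
        if ns.white_sd > 0:
            out += ns.white_sd * rng.standard_normal((n_ch, n_t))
        return out

    hbo = hbo_clean + physiological_noise()
    hhb = hhb_clean + config.noise.hhb_noise_ratio * physiological_noise()

    dpf = compute_dpf(participant.age_years, dpf_model)
    od = mbll_forward(hbo, hhb, montage.distance_m, dpf, ext=ext)

    art = config.artifacts
    spike_times, shift_times = [], []
    n_spikes = rng.poisson(art.spike_rate_hz * duration, size=n_ch)
    n_shifts = rng.poisson(art.shift_rate_hz * duration, size=n_ch)
    for ch in range(n_ch):
        for _ in range(n_spikes[ch]):
            i = int(rng.integers(0, n_t))
            a = art.spike_od_amp * rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
            od[ch, :, i] += a
            spike_times.append(i / fs)
        for _ in range(n_shifts[ch]):
            i = int(rng.integers(0, n_t))
            a = art.shift_od_amp * rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
            od[ch, :, i:] += a
            shift_times.append(i / fs)

    intensity = 1.0 * np.exp(-od)
    rec = RawIntensityRecording(
        intensity=intensity, sample_rate=fs, montage=montage, events=events,
        age_years=participant.age_years, participant_id=participant.participant_id,
        group=participant.group, time_point=time_point,
    )
    truth = GroundTruth(channel_amplitude=amp, hbo_clean=hbo_clean, hhb_clean=hhb_clean,
                        spike_times_s=spike_times, shift_times_s=shift_times,
                        events=events.copy())
    return rec, truth


# ---------------------------------------------------------------------------
# cohorts

def make_participants(config: SimulationConfig) -> list[Participant]:
    """Draw a cohort with group labels, ages, and an MMSE-like covariate."""
    rng = np.random.default_rng(_seed_for(config.seed, "participants"))
    out = []
    for group in config.group_labels:
        tag = "EG" if group == "experimental" else "CG"
        for i in range(config.n_per_group):
            age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 60.0, 80.0))
            mmse = float(np.clip(rng.normal(29.2, 1.0), 26.0, 30.0))
            out.append(Participant(f"{tag}{i + 1:02d}", group, age, mmse))
    return out


def simulate_score_cohort(cell_means: dict | None = None, cell_sds: dict | None = None,
                          n_per_group: dict | None = None, icc: float = DEFAULT_SCORE_ICC,
                          seed: int = 0, time_points=TIME_POINTS) -> pd.DataFrame:
    """Cohort of per-participant 2-back scores drawn from per-cell
    means/SDs with a subject random intercept (within-subject correlation
    ``icc``).

    Defaults reproduce the study-like cell means with SD = SE * sqrt(n)
    and group sizes 19 / 23.  Returns a long table with columns
    ``participant_id, group, time_point, rcs``.
    """
    means = cell_means or RCS_CELL_MEANS
    npg = n_per_group or N_PER_GROUP
    if cell_sds is None:
        # cell SDs are a population property: derived from the reference
        # SEs at the reference group sizes, independent of the simulated n
        cell_sds = {k: RCS_CELL_SES[k] * np.sqrt(N_PER_GROUP[k[0]]) for k in means}
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in npg.items():
        for i in range(n):
            pid = f"{group[:2].upper()}{i + 1:02d}"
            u = rng.standard_normal()
            for tp in time_points:
                e = rng.standard_normal()
                val = means[(group, tp)] + cell_sds[(group, tp)] * (
                    np.sqrt(icc) * u + np.sqrt(1.0 - icc) * e)
                rows.append({"participant_id": pid, "group": group,
                             "time_point": tp, "rcs": val})
    return pd.DataFrame(rows)
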