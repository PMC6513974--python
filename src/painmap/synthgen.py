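"""Synthetic multimodal heat-pain datasets.

The generator emulates the statistical structure of a per-subject-calibrated
heat-pain study: each subject contributes 20 trials at each of five stimulus
levels (baseline B at 32 °C, pain threshold T1, two intermediate levels T2/T3,
pain tolerance T4), with the physiological response recorded for 5.5 s on five
synchronized channels — three surface EMG sites (zygomaticus ``zEMG``,
corrugator ``cEMG``, trapezius ``tEMG``, arbitrary amplified units), skin
conductance ``SCL`` (µS), and ``ECG`` (mV).

Injected level effects follow the known direction of the sympathetic pain
response: EMG envelope amplitude and the phasic skin-conductance response grow
with stimulus level (facial sites more strongly than the trapezius), while
mean heart rate decreases slightly.  All channels carry additive 50 Hz
power-line contamination.  A null mode (all level effects zero) produces
exchangeable levels for type-I-error experiments.

Everything is deterministic given a single master seed.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy import signal as sps

EMG_CHANNELS = ("zEMG", "cEMG", "tEMG")
CHANNELS = ("zEMG", "cEMG", "tEMG", "SCL", "ECG")


class PainLevel(enum.Enum):
    """Stimulus level: baseline plus four calibrated pain intensities."""

    B = 0
    T1 = 1
    T2 = 2
    T3 = 3
    T4 = 4

    @property
    def ordinal(self) -> int:
        return self.value


ALL_LEVELS = tuple(PainLevel)


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable generator parameters.

    Level effects are expressed as the within-subject Cohen's d between B and
    T4 on the driving parameter of each channel (EMG envelope amplitude, SCL
    phasic response amplitude, heart rate); intermediate levels interpolate
    linearly in the ordinal.  Defaults sit mid-band of the small / medium
    effect categories reported for these modalities (facial EMG medium,
    trapezius small, SCL medium, heart rate a small decrease).
    """

    fs: float = 512.0
    duration: float = 5.5
    emg_band: tuple[float, float] = (20.0, 250.0)
    emg_effects: tuple[float, float, float] = (0.65, 0.65, 0.35)  # z, c, t
    scl_effect: float = 0.6
    hr_effect: float = -0.35
    trial_cv: float = 0.25          # trial-to-trial relative SD of driving params
    gain_sigma: float = 0.25        # log-normal subject gain spread (median 1)
    hr_trial_sd: float = 2.0        # bpm
    rr_jitter: float = 0.02         # relative beat-to-beat RR variability
    emg_base_amp: float = 1.0       # a.u.
    scr_base_amp: float = 0.3       # µS
    scr_rise_s: float = 0.75
    scr_decay_s: float = 2.0
    scr_latency_s: float = 0.7
    powerline_freq: float = 50.0
    powerline_amp: float = 1.0      # scale multiplier; 0 disables contamination

    # stimulus onset is fixed at t = 0: the recording IS the 5.5 s response window
    stimulus_onset: float = 0.0

    def null(self) -> "GeneratorConfig":
        """Copy with all level effects off (levels become exchangeable)."""
        return replace(self, emg_effects=(0.0, 0.0, 0.0), scl_effect=0.0, hr_effect=0.0)

    def reduced_rate(self, fs: float = 128.0) -> "GeneratorConfig":
        """Copy at a reduced sampling rate with the EMG band pulled under
        Nyquist (fs must stay above twice the power-line frequency)."""
        if fs <= 2 * self.powerline_freq and self.powerline_amp > 0:
            raise ValueError("reduced rate must keep the power-line tone below Nyquist")
        return replace(self, fs=fs, emg_band=(20.0, min(self.emg_band[1], 0.45 * fs)))


# base power-line amplitude per channel, scaled by GeneratorConfig.powerline_amp
_LINE_AMP = {"zEMG": 0.08, "cEMG": 0.08, "tEMG": 0.08, "SCL": 0.01, "ECG": 0.04}


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject random effects emulating per-subject stimulus calibration."""

    subject_id: str
    gains: dict[str, float]         # multiplicative response gain per channel
    hr_baseline: float              # beats/min
    scl_tonic_baseline: float       # µS
    rng_seed: int

    def __post_init__(self):
        if any(g <= 0 for g in self.gains.values()):
            raise ValueError("response gains must be positive")
        if not (50.0 <= self.hr_baseline <= 100.0):
            raise ValueError("hr_baseline outside [50, 100] bpm")


@dataclass
class TrialRecording:
    """One trial: five synchronized channel signals plus metadata."""

    subject_id: str
    trial_id: str
    pain_level: PainLevel
    channels: dict[str, np.ndarray]
    sampling_rate: float
    duration: float
    stimulus_onset: float = 0.0
    ground_truth: dict = field(default_factory=dict)  # generator-injected parameters

    def __post_init__(self):
        n = round(self.duration * self.sampling_rate)
        for name in CHANNELS:
            if name not in self.channels:
                raise ValueError(f"missing channel {name}")
            if len(self.channels[name]) != n:
                raise ValueError(f"channel {name} length != round(duration*fs)")


@dataclass
class DatasetRoster:
    """Enumerates every (subject, level, trial) slot of a dataset."""

    subjects: list[SubjectProfile]
    trials_per_level: int
    levels: tuple[PainLevel, ...]
    master_seed: int

    @property
    def n_trials(self) -> int:
        return len(self.subjects) * len(self.levels) * self.trials_per_level

    def slots(self) -> Iterator[tuple[SubjectProfile, PainLevel, int, int]]:
        """Yield (profile, level, trial_index, trial_seed), one per trial."""
        for si, prof in enumerate(self.subjects):
            for level in self.levels:
                for ti in range(self.trials_per_level):
                    yield prof, level, ti, _slot_seed(self.master_seed, si, level.ordinal, ti)

    def baseline_seed(self, subject_index: int) -> int:
        # dedicated pain-free reference recording, outside the counted trials
        return _slot_seed(self.master_seed, subject_index, 99, 0)


def _slot_seed(master: int, si: int, lvl: int, ti: int) -> int:
    ss = np.random.SeedSequence([int(master), si, lvl, ti])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def make_roster(
    n_subjects: int,
    trials_per_level: int,
    master_seed: int,
    levels: tuple[PainLevel, ...] = ALL_LEVELS,
) -> DatasetRoster:
    """Build a roster of n_subjects × |levels| × trials_per_level trial slots."""
    if n_subjects < 1 or trials_per_level < 1:
        raise ValueError("n_subjects and trials_per_level must be >= 1")
    subj_seeds = np.random.SeedSequence(master_seed).generate_state(n_subjects)
    subjects = [
        synth_subject_profile(f"S{i:03d}", int(s % (2**31 - 1)))
        for i, s in enumerate(subj_seeds)
    ]
    return DatasetRoster(subjects, trials_per_level, tuple(levels), master_seed)


def synth_subject_profile(
    subject_id: str, seed: int, gain_sigma: float = 0.25
) -> SubjectProfile:
    """Draw a subject's random effects.

    Gains are log-normal with median 1 (so half the population responds more
    strongly than the prototype, half less); resting heart rate is uniform in
    [55, 95] bpm; tonic skin conductance uniform in [2, 10] µS.
    """
    rng = np.random.default_rng(seed)
    gains = {ch: float(np.exp(rng.normal(0.0, gain_sigma))) for ch in CHANNELS}
    hr = float(rng.uniform(55.0, 95.0))
    scl = float(rng.uniform(2.0, 10.0))
    return SubjectProfile(subject_id, gains, hr, scl, seed)


def _bandlimited_noise(rng, n, fs, band):
    x = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    s = y.std()
    return y / s if s > 0 else y


def synth_trial(
    profile: SubjectProfile,
    level: PainLevel,
    trial_id: str,
    seed: int,
    config: GeneratorConfig | None = None,
) -> TrialRecording:
    """Synthesize one trial's five channels.

    EMG channels are band-limited Gaussian noise whose envelope amplitude grows
    with level ordinal × subject gain; SCL is a tonic baseline plus a
    pain-triggered bi-exponential (Bateman) phasic response; ECG is a train of
    Gaussian-bump QRS complexes whose rate decreases slightly with level.
    """
    cfg = config or GeneratorConfig()
    if cfg.fs <= 2 * cfg.emg_band[1]:
        raise ValueError(
            f"fs={cfg.fs} violates Nyquist for EMG band edge {cfg.emg_band[1]} Hz"
        )
    if cfg.duration < 5.5:
        raise ValueError("duration must cover the 5.5 s response window")
    rng = np.random.default_rng(seed)
    n = round(cfg.duration * cfg.fs)
    t = np.arange(n) / cfg.fs
    o = level.ordinal / 4.0  # 0 at B, 1 at T4
    gt: dict = {"level_ordinal": level.ordinal}
    channels: dict[str, np.ndarray] = {}

    # --- EMG: scaled band-limited noise -------------------------------------
    for ch, d_eff in zip(EMG_CHANNELS, cfg.emg_effects):
        amp = (
            cfg.emg_base_amp
            * profile.gains[ch]
            * (1.0 + d_eff * cfg.trial_cv * o + cfg.trial_cv * rng.standard_normal())
        )
        amp = max(amp, 0.05 * cfg.emg_base_amp)
        channels[ch] = amp * _bandlimited_noise(rng, n, cfg.fs, cfg.emg_band)
        gt[f"{ch}_amp"] = amp

    # --- SCL: tonic + drift + Bateman phasic response ------------------------
    scr_amp = (
        cfg.scr_base_amp
        * profile.gains["SCL"]
        * (1.0 + cfg.scl_effect * cfg.trial_cv * o + cfg.trial_cv * rng.standard_normal())
    )
    scr_amp = max(scr_amp, 0.0)
    tt = t - cfg.stimulus_onset - cfg.scr_latency_s
    kernel = np.where(
        tt > 0, np.exp(-np.maximum(tt, 0) / cfg.scr_decay_s) - np.exp(-np.maximum(tt, 0) / cfg.scr_rise_s), 0.0
    )
    peak = kernel.max()
    if peak > 0:
        kernel = kernel / peak
    drift = 0.02 * profile.gains["SCL"] * rng.standard_normal() * t / cfg.duration
    meas_noise = 0.005 * rng.standard_normal(n)
    channels["SCL"] = profile.scl_tonic_baseline + scr_amp * kernel + drift + meas_noise
    gt["scr_amp"] = scr_amp

    # --- ECG: Gaussian QRS template train ------------------------------------
    hr = (
        profile.hr_baseline
        + cfg.hr_effect * cfg.hr_trial_sd * o
        + cfg.hr_trial_sd * rng.standard_normal()
    )
    hr = float(np.clip(hr, 40.0, 140.0))
    rr0 = 60.0 / hr
    peak_times = []
    tp = float(rng.uniform(0.0, rr0))
    while tp < cfg.duration:
        peak_times.append(tp)
        tp += rr0 * (1.0 + cfg.rr_jitter * rng.standard_normal())
    ecg = 0.02 * rng.standard_normal(n)
    width = 0.02  # QRS bump SD, s
    for pt in peak_times:
        ecg += 1.0 * np.exp(-0.5 * ((t - pt) / width) ** 2)
    channels["ECG"] = ecg
    gt["hr"] = hr
    gt["r_peak_times"] = np.asarray(peak_times)

    # --- power-line contamination --------------------------------------------
    if cfg.powerline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        line = np.sin(2 * np.pi * cfg.powerline_freq * t + phase)
        for ch in CHANNELS:
            channels[ch] = channels[ch] + cfg.powerline_amp * _LINE_AMP[ch] * line

    return TrialRecording(
        subject_id=profile.subject_id,
        trial_id=trial_id,
        pain_level=level,
        channels=channels,
        sampling_rate=cfg.fs,
        duration=cfg.duration,
        stimulus_onset=0.0,
        ground_truth=gt,
    )


def synth_baseline(
    roster: DatasetRoster, subject_index: int, config: GeneratorConfig | None = None
) -> TrialRecording:
    """Dedicated pain-free (level B) reference recording for one subject."""
    prof = roster.subjects[subject_index]
    return synth_trial(
        prof, PainLevel.B, "baseline", roster.baseline_seed(subject_index), config
    )


def generate_dataset(
    roster: DatasetRoster, config: GeneratorConfig | None = None
) -> Iterator[TrialRecording]:
    """Yield every trial of the roster, in roster order."""
    for prof, level, ti, seed in roster.slots():
        yield synth_trial(prof, level, f"{prof.subject_id}_{level.name}_{ti:02d}", seed, config)


# ---------------------------------------------------------------------------
# Feature-level generator: registry-shaped matrices with designated
# informative columns.  Used to exercise the selection machinery with a known
# ground truth without paying for signal synthesis + extraction.
# ---------------------------------------------------------------------------

def synth_feature_matrix(
    feature_names: list[str],
    n_subjects: int,
    trials_per_level: int,
    levels: tuple[PainLevel, ...],
    informative: dict[str, float],
    seed: int,
    subject_sd: float = 0.5,
):
    """Build (values, meta) arrays of a synthetic feature matrix.

    Every column is unit-variance noise plus a per-subject random intercept
    (SD ``subject_sd``); columns named in ``informative`` additionally carry a
    linear-in-ordinal class effect whose B→T4 standardized size is the mapped
    Cohen's d.  Returns a :class:`painmap.featurebank.FeatureMatrix`.
    """
    import pandas as pd

    from .featurebank import FeatureMatrix

    rng = np.random.default_rng(seed)
    rows = []
    meta = []
    for si in range(n_subjects):
        offs = rng.normal(0.0, subject_sd, size=len(feature_names))
        for level in levels:
            o = level.ordinal / 4.0
            for ti in range(trials_per_level):
                x = offs + rng.standard_normal(len(feature_names))
                for j, name in enumerate(feature_names):
                    d = informative.get(name)
                    if d:
                        x[j] += d * o
                rows.append(x)
                meta.append((f"S{si:03d}", f"S{si:03d}_{level.name}_{ti:02d}", level.name))
    values = pd.DataFrame(np.asarray(rows), columns=feature_names)
    meta_df = pd.DataFrame(meta, columns=["subject", "trial", "level"])
    return FeatureMatrix(values=values, meta=meta_df, normalization="raw")


# ---------------------------------------------------------------------------
# Dataset writer
# ---------------------------------------------------------------------------

def write_dataset(
    roster: DatasetRoster,
    out_dir: str | Path,
    config: GeneratorConfig | None = None,
    write_trials: bool = True,
) -> Path:
    """Write a dataset directory: per-trial CSVs plus a roster manifest JSON."""
    cfg = config or GeneratorConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "master_seed": roster.master_seed,
        "fs": cfg.fs,
        "duration": cfg.duration,
        "trials_per_level": roster.trials_per_level,
        "levels": [lv.name for lv in roster.levels],
        "subjects": [p.subject_id for p in roster.subjects],
        "trials": [],
    }
    for trial in generate_dataset(roster, cfg):
        rel = f"{trial.trial_id}.csv"
        if write_trials:
            _write_trial_csv(trial, out / rel)
        manifest["trials"].append(
            {
                "subject": trial.subject_id,
                "trial": trial.trial_id,
                "level": trial.pain_level.name,
                "file": rel,
            }
        )
    (out / "roster.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _write_trial_csv(trial: TrialRecording, path: Path) -> None:
    n = len(trial.channels["ECG"])
    t = np.arange(n) / trial.sampling_rate
    cols = [t] + [trial.channels[ch] for ch in CHANNELS]
    header = "time_s," + ",".join(CHANNELS)
    np.savetxt(path, np.column_stack(cols), delimiter=",", header=header, comments="")
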