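"""Synthetic occipital EEG, EOG and behavioral data.

The generator emulates the signal structure the analysis pipeline
assumes: a single Oz channel sampled at 2,048 Hz containing

* 1/f-shaped background noise (white noise shaped in the frequency
  domain, slope configurable),
* a 10 Hz alpha rhythm with a slowly diffusing (random-walk) phase so
  stimulus onsets are not phase-locked to alpha,
* gamma activity whose amplitude is modulated by the instantaneous
  alpha phase with coupling depth ``kappa`` and preferred phase
  ``pac_phase`` (amplitude-modulation construction:
  ``gamma_amp * (1 + kappa*cos(phi_alpha - phi0)) / (1 + kappa)``),
* white measurement noise,

plus a horizontal EOG channel (baseline drift, optional step-like
saccades at Poisson times) and 4-AFC behavioral responses whose
accuracy follows a guessing-floored logistic model in optotype size,
target speed and a per-(condition, session) effect.

Condition/session effects enter in two places, mirroring the assumed
neuromodulation: ``alpha_boost`` multiplies the alpha amplitude and
``behavior_effect`` shifts the log-odds of a correct response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import fft as sp_fft

from .task import GAP_DIRS, SIZES, TrialSchedule, response_table

EEG_FS = 2048.0


def _default_intercepts() -> dict:
    # size-graded baseline accuracies (~0.45 / 0.65 / 0.8 at mid speed)
    return {3: 0.8, 4: 1.7, 5: 2.5}


@dataclass
class SyntheticSubjectSpec:
    """Generative parameters for one synthetic subject."""

    alpha_amp: float = 10.0  # uV
    gamma_amp: float = 2.0  # uV
    pac_depth: float = 0.6  # kappa in [0, 1]
    pac_phase: float = 3 * math.pi / 2  # preferred alpha phase of gamma, rad
    noise_1f_scale: float = 8.0  # uV RMS of the shaped background
    noise_1f_slope: float = 1.0  # spectral slope of the background
    white_sigma: float = 2.0  # uV
    phase_diffusion: float = 5.0  # rad^2/s of the alpha phase random walk
    alpha_boost: dict = field(default_factory=dict)  # (condition, session) -> factor
    behavior_intercepts: dict = field(default_factory=_default_intercepts)
    behavior_speed_slope: float = 0.35  # log-odds per 100 deg/s above 200
    behavior_effect: dict = field(default_factory=dict)  # (condition, session) -> delta
    subject_shift: float = 0.0  # per-subject log-odds offset
    artifact_frac: float = 0.0  # fraction of trials with injected artifacts
    artifact_amp: float = 150.0  # uV
    saccade_rate: float = 0.0  # events / min
    fs: float = EEG_FS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pac_depth <= 1:
            raise ValueError("pac_depth must lie in [0, 1]")
        if not 0 <= self.artifact_frac < 1:
            raise ValueError("artifact_frac must lie in [0, 1)")


@dataclass
class Recording:
    """EEG + EOG traces with stimulus events."""

    eeg: np.ndarray  # uV
    eog: np.ndarray  # uV
    events: pd.DataFrame  # per-trial: sample, onset_s + trial factors
    fs: float

    def __post_init__(self) -> None:
        if len(self.events) and self.events["sample"].max() >= len(self.eeg):
            raise ValueError("event index beyond trace end")


def _pink_noise(n: int, slope: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f^slope noise via frequency-domain shaping."""
    nfft = sp_fft.next_fast_len(n)  # arbitrary n can have slow FFT factors
    white = rng.standard_normal(nfft)
    spec = sp_fft.rfft(white)
    f = sp_fft.rfftfreq(nfft, d=1.0)
    f[0] = f[1]  # keep DC finite; high-pass removes it downstream anyway
    spec *= f ** (-slope / 2)
    x = sp_fft.irfft(spec, nfft)[:n]
    return x / x.std()


def _alpha_phase(n: int, fs: float, freq: float, diffusion: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Alpha instantaneous phase with a Wiener-process perturbation."""
    dt = 1.0 / fs
    walk = np.cumsum(rng.standard_normal(n) * math.sqrt(diffusion * dt))
    return 2 * math.pi * freq * np.arange(n) * dt + rng.uniform(0, 2 * math.pi) + walk


def gen_eeg(
    spec: SyntheticSubjectSpec,
    schedule: TrialSchedule,
    condition: str = "sham",
    session: str = "pre",
    alpha_freq: float = 10.0,
    gamma_freq: float = 80.0,
    pad_s: float = 2.0,
) -> Recording:
    """Synthesize the EEG channel for one task session.

    Events are placed at the schedule's stimulus onsets; because the
    alpha phase random-walks between trials, onsets are not locked to
    any alpha phase.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    duration = float(schedule.trials["onset_s"].iloc[-1]) + pad_s
    n = int(round(duration * fs))
    if duration <= schedule.trials["onset_s"].iloc[-1]:
        raise ValueError("trace shorter than the schedule span")

    phi = _alpha_phase(n, fs, alpha_freq, spec.phase_diffusion, rng)
    boost = spec.alpha_boost.get((condition, session), 1.0)
    alpha = spec.alpha_amp * boost * np.sin(phi)

    k = spec.pac_depth
    envelope = spec.gamma_amp * (1 + k * np.cos(phi - spec.pac_phase)) / (1 + k)
    t = np.arange(n) / fs
    gamma = envelope * np.sin(2 * math.pi * gamma_freq * t + rng.uniform(0, 2 * math.pi))

    eeg = (
        spec.noise_1f_scale * _pink_noise(n, spec.noise_1f_slope, rng)
        + alpha
        + gamma
        + spec.white_sigma * rng.standard_normal(n)
    )

    events = schedule.trials.copy()
    events.insert(0, "sample", (events["onset_s"] * fs).round().astype(int))
    eog = np.zeros(n)  # filled by gen_eog when requested
    return Recording(eeg=eeg, eog=eog, events=events, fs=fs)


def inject_artifacts(
    recording: Recording, spec: SyntheticSubjectSpec
) -> tuple[Recording, list[int]]:
    """Add >100 uV transients inside the pre-stimulus window of a seeded
    random subset of trials; returns the ground-truth trial indices."""
    rng = np.random.default_rng(spec.seed + 1)
    n_trials = len(recording.events)
    n_bad = int(round(spec.artifact_frac * n_trials))
    bad = sorted(rng.choice(n_trials, size=n_bad, replace=False).tolist())
    fs = recording.fs
    eeg = recording.eeg.copy()
    width = int(0.05 * fs)  # 50 ms Gaussian bump: passes a 1 Hz high-pass
    bump = spec.artifact_amp * np.exp(
        -0.5 * ((np.arange(4 * width) - 2 * width) / (width / 2)) ** 2
    )
    for i in bad:
        onset = int(recording.events["sample"].iloc[i])
        centre = onset - int(0.5 * fs) + int(rng.integers(-int(0.3 * fs), int(0.3 * fs)))
        start = max(0, centre - 2 * width)
        seg = eeg[start : start + len(bump)]
        seg += bump[: len(seg)]
    out = Recording(eeg=eeg, eog=recording.eog, events=recording.events, fs=fs)
    return out, bad


def gen_eog(
    spec: SyntheticSubjectSpec, schedule: TrialSchedule, pad_s: float = 2.0
) -> tuple[np.ndarray, list[float]]:
    """Horizontal EOG trace: slow drift plus optional saccade steps.

    Saccades are step-like deflections with a 10-50 ms sigmoid rise at
    Poisson event times (``saccade_rate`` per minute); returns the trace
    and the ground-truth saccade times in seconds.
    """
    rng = np.random.default_rng(spec.seed + 2)
    fs = spec.fs
    duration = float(schedule.trials["onset_s"].iloc[-1]) + pad_s
    n = int(round(duration * fs))
    drift = 30.0 * _pink_noise(n, 2.0, rng)  # slow baseline wander, uV
    eog = drift + 3.0 * rng.standard_normal(n)

    times: list[float] = []
    if spec.saccade_rate > 0:
        t = rng.exponential(60.0 / spec.saccade_rate)
        while t < duration - 0.5:
            times.append(t)
            t += rng.exponential(60.0 / spec.saccade_rate)
        sign = 1.0
        for t0 in times:
            rise = rng.uniform(0.010, 0.050)
            amp = rng.uniform(80.0, 200.0)
            i0 = int(t0 * fs)
            tt = (np.arange(n - i0) / fs) / rise
            eog[i0:] += sign * amp / (1 + np.exp(-8 * (tt - 0.5)))
            sign = -sign  # alternate so the trace stays bounded
    return eog, times


def gen_behavior(
    spec: SyntheticSubjectSpec,
    schedule: TrialSchedule,
    condition: str = "sham",
    session: str = "pre",
) -> pd.DataFrame:
    """Sample 4-AFC responses for one session.

    P(correct) = 0.25 + 0.75 * logistic(intercept_size
    - slope * (speed-200)/100 + delta_{condition,session} + subject
    shift); wrong answers are uniform over the remaining three gap
    directions.
    """
    rng = np.random.default_rng(spec.seed + 3)
    delta = spec.behavior_effect.get((condition, session), 0.0)
    trials = schedule.trials
    eta = (
        trials["size"].map(spec.behavior_intercepts).to_numpy(dtype=float)
        - spec.behavior_speed_slope * (trials["speed"].to_numpy() - 200) / 100.0
        + delta
        + spec.subject_shift
    )
    p_correct = 0.25 + 0.75 / (1 + np.exp(-eta))
    correct = rng.uniform(size=len(trials)) < p_correct
    responses = []
    for ok, gap in zip(correct, trials["gap_dir"]):
        if ok:
            responses.append(gap)
        else:
            others = [g for g in GAP_DIRS if g != gap]
            responses.append(others[rng.integers(3)])
    return response_table(schedule, responses)


# ---------------------------------------------------------------------------
# cohort presets

#: per-(condition, session) effects; pre-sessions always null so baselines match
PRESETS = {
    "null": {"delta": 0.0, "boost": 1.0},
    "moderate": {"delta": 0.8, "boost": 1.3},
    "strong": {"delta": 1.5, "boost": 1.6},
}


def subject_spec(
    preset: str, subject: int, seed: int, **overrides
) -> SyntheticSubjectSpec:
    """Build one subject's spec under a named preset.

    Non-null presets apply the accuracy and alpha-power effects to the
    trough condition's post0/post10 sessions only, matching the assumed
    trough-specific neuromodulation; peak and sham stay at baseline.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset: {preset!r}")
    cfg = PRESETS[preset]
    effect = {
        ("trough", "post0"): cfg["delta"],
        ("trough", "post10"): cfg["delta"],
    }
    boost = {
        ("trough", "post0"): cfg["boost"],
        ("trough", "post10"): cfg["boost"],
    }
    rng = np.random.default_rng(np.random.SeedSequence([seed, subject]))
    kw = dict(
        behavior_effect=effect,
        alpha_boost=boost,
        subject_shift=float(rng.normal(0.0, 0.4)),
        seed=int(rng.integers(2**31 - 1)),
    )
    kw.update(overrides)
    return SyntheticSubjectSpec(**kw)
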