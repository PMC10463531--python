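"""Occipital-EEG feature pipeline.

All features are computed on the 1 s pre-stimulus window (-1000 ms to
0 ms relative to stimulus onset) of preprocessed, artifact-screened
epochs:

* **ITPC** — inter-trial phase coherence from a complex Morlet wavelet
  transform, 1-100 Hz in 1 Hz steps; at each time-frequency point the
  magnitude of the across-trial mean unit phasor.
* **Power spectrum** — per-trial periodogram of the 1 s window (1 Hz
  resolution) averaged over trials, with scalars at 10 and 80 Hz.
* **PAC comodulogram** — Tort's modulation index over phase frequencies
  4-20 Hz (step 1) x amplitude frequencies 30-100 Hz (step 5), with 18
  phase bins; Canolty's mean-vector-length available as an alternative.
* **Saccade detection** on the EOG channel by velocity thresholding.

Filters are zero-phase (forward-backward) throughout; the phase
convention is the analytic-signal angle shifted to a sine reference,
matching the waveform module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, iirnotch, filtfilt, oaconvolve, periodogram, sosfiltfilt

from .synth import Recording

PHASE_FREQS = np.arange(4, 21, 1)  # Hz, 17 bins
AMP_FREQS = np.arange(30, 101, 5)  # Hz, 15 bins
ITPC_FREQS = np.arange(1, 101, 1)  # Hz
N_PHASE_BINS = 18
REJECT_UV = 100.0
EPOCH_WINDOW_S = (-1.0, 0.0)
PAD_S = 0.5

#: ITPC windows of interest: (f_lo, f_hi) Hz x (t_lo, t_hi) s pre-onset
ITPC_WINDOWS = {
    f"{int(flo)}-{int(fhi)}Hz_{int(tlo*1000)}to{int(thi*1000)}ms": ((flo, fhi), (tlo, thi))
    for flo, fhi in [(7.0, 13.0), (70.0, 90.0)]
    for tlo, thi in [(-0.6, -0.4), (-0.4, -0.2), (-0.2, 0.0)]
}
PAC_WINDOW = ((7.0, 13.0), (70.0, 90.0))  # phase Hz x amplitude Hz


# ---------------------------------------------------------------------------
# preprocessing & epoching

def preprocess(recording: Recording, hp_hz: float = 1.0, notch_hz: float = 60.0,
               notch_q: float = 30.0) -> Recording:
    """Zero-phase 1 Hz high-pass (4th-order Butterworth) and 60 Hz notch."""
    fs = recording.fs
    if fs < 200:
        raise ValueError("sampling rate too low for the notch filter")
    sos = butter(4, hp_hz, btype="highpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, recording.eeg)
    b, a = iirnotch(notch_hz, notch_q, fs=fs)
    x = filtfilt(b, a, x)
    return Recording(eeg=x, eog=recording.eog, events=recording.events, fs=fs)


@dataclass
class EpochSet:
    """Pre-stimulus epochs after amplitude-based artifact rejection.

    ``epochs`` holds only the kept trials; ``padded`` carries the same
    trials with ``pad`` extra samples of trace context on each side for
    edge-safe time-frequency transforms.
    """

    epochs: np.ndarray  # kept trials x (fs * 1 s) samples, uV
    padded: np.ndarray  # kept trials x (fs * 1 s + 2*pad)
    pad: int
    fs: float
    kept_trial_ids: list[int]
    rejected_trial_ids: list[int]
    invalid_trial_ids: list[int] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return len(self.kept_trial_ids)

    @classmethod
    def from_array(cls, epochs: np.ndarray, fs: float, pad_s: float = PAD_S) -> "EpochSet":
        """Wrap a trials x samples array directly (reflection padding),
        bypassing epoching — convenient for synthetic trial matrices."""
        epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
        pad = int(round(pad_s * fs))
        padded = np.pad(epochs, ((0, 0), (pad, pad)), mode="reflect")
        return cls(epochs=epochs, padded=padded, pad=pad, fs=fs,
                   kept_trial_ids=list(range(len(epochs))), rejected_trial_ids=[])


def epoch_and_reject(
    recording: Recording,
    reject_uv: float = REJECT_UV,
    pad_s: float = PAD_S,
) -> EpochSet:
    """Cut [-1000, 0) ms epochs and reject any whose absolute amplitude
    exceeds *reject_uv*; trials too close to the trace edges are marked
    invalid rather than silently dropped."""
    fs = recording.fs
    win = int(round(fs))  # window length = fs x 1 s
    pad = int(round(pad_s * fs))
    kept, rejected, invalid = [], [], []
    plain, padded = [], []
    x = recording.eeg
    for i, onset in enumerate(recording.events["sample"].to_numpy()):
        if onset - win - pad < 0 or onset + pad > len(x):
            invalid.append(i)
            continue
        ep = x[onset - win : onset]
        if np.max(np.abs(ep)) > reject_uv:
            rejected.append(i)
            continue
        kept.append(i)
        plain.append(ep)
        padded.append(x[onset - win - pad : onset + pad])
    return EpochSet(
        epochs=np.array(plain) if kept else np.empty((0, win)),
        padded=np.array(padded) if kept else np.empty((0, win + 2 * pad)),
        pad=pad,
        fs=fs,
        kept_trial_ids=kept,
        rejected_trial_ids=rejected,
        invalid_trial_ids=invalid,
    )


# ---------------------------------------------------------------------------
# ITPC

def morlet_wavelet(freq: float, fs: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet wavelet ``exp(i*2*pi*f*t) * gauss(t)`` with
    sigma_t = n_cycles / (2*pi*f), truncated at +/-3 sigma, odd length."""
    sigma_t = n_cycles / (2 * math.pi * freq)
    half = int(math.ceil(3 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    return np.exp(2j * math.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))


def default_cycles(freq: np.ndarray | float) -> np.ndarray | float:
    """Cycle count rising linearly from 3 at 1 Hz to 8 at 100 Hz."""
    return 3.0 + 5.0 * (np.asarray(freq, dtype=float) - 1.0) / 99.0


@dataclass
class TimeFreqMap:
    """ITPC values on a frequency x time grid, all in [0, 1]."""

    values: np.ndarray  # freqs x times
    freqs: np.ndarray  # Hz
    times: np.ndarray  # s, relative to stimulus onset (negative = pre)
    n_trials: int


def itpc(epochs: EpochSet, freqs: np.ndarray = ITPC_FREQS) -> TimeFreqMap:
    """Inter-trial phase coherence map of the pre-stimulus window.

    ITPC(f,t) = | mean_n exp(i * phi_n(f,t)) | with phi_n the phase of
    the complex Morlet transform of trial n.  Epochs enter with +/-500 ms
    of trace context which is discarded after the transform.
    """
    if epochs.n_kept < 2:
        raise ValueError("ITPC requires at least 2 kept trials")
    fs, pad = epochs.fs, epochs.pad
    win = epochs.epochs.shape[1]
    out = np.empty((len(freqs), win))
    for fi, f in enumerate(freqs):
        w = morlet_wavelet(f, fs, float(default_cycles(f)))
        tf = oaconvolve(epochs.padded, w[None, :], mode="same", axes=1)
        tf = tf[:, pad : pad + win]
        phasors = tf / np.abs(tf)
        out[fi] = np.abs(phasors.mean(axis=0))
    times = np.arange(win) / fs + EPOCH_WINDOW_S[0]
    return TimeFreqMap(values=out, freqs=np.asarray(freqs, float), times=times,
                       n_trials=epochs.n_kept)


def window_mean(tfmap: TimeFreqMap, windows: dict = ITPC_WINDOWS) -> dict:
    """Mean map value over each (frequency-band x time-window) of
    interest; raises if a window falls outside the grid."""
    out = {}
    for name, ((flo, fhi), (tlo, thi)) in windows.items():
        if flo < tfmap.freqs[0] or fhi > tfmap.freqs[-1]:
            raise ValueError(f"window {name} outside frequency grid")
        dt = tfmap.times[1] - tfmap.times[0]
        if tlo < tfmap.times[0] - 1e-9 or thi > tfmap.times[-1] + dt + 1e-9:
            raise ValueError(f"window {name} outside time grid")
        fm = (tfmap.freqs >= flo) & (tfmap.freqs <= fhi)
        tm = (tfmap.times >= tlo) & (tfmap.times < thi)
        out[name] = float(tfmap.values[np.ix_(fm, tm)].mean())
    return out


# ---------------------------------------------------------------------------
# power spectrum

@dataclass
class Spectrum:
    power: np.ndarray  # uV^2 per frequency bin
    freqs: np.ndarray  # Hz, 1 Hz resolution
    n_trials: int

    def at(self, freq: float) -> float:
        return float(self.power[int(np.argmin(np.abs(self.freqs - freq)))])


def power_spectrum(epochs: EpochSet) -> Spectrum:
    """Trial-averaged periodogram of the 1 s pre-stimulus window.

    The 1 s window gives 1 Hz bin spacing; a pure sinusoid of amplitude
    A at an integer frequency lands in a single bin with power A^2/2.
    """
    if epochs.n_kept < 1:
        raise ValueError("no kept trials")
    freqs, pxx = periodogram(epochs.epochs, fs=epochs.fs, scaling="spectrum", axis=1)
    return Spectrum(power=pxx.mean(axis=0), freqs=freqs, n_trials=epochs.n_kept)


# ---------------------------------------------------------------------------
# phase-amplitude coupling

def modulation_index(phase: np.ndarray, amp: np.ndarray,
                     n_bins: int = N_PHASE_BINS) -> float:
    """Tort's normalized-entropy modulation index.

    Bin phases into *n_bins* bins, P_k = mean amplitude in bin k
    normalized to sum 1; MI = (log K - H(P)) / log K, with the
    0*log0 == 0 convention for empty bins.
    """
    edges = np.linspace(-math.pi, math.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=amp, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    total = means.sum()
    if total <= 0:
        return 0.0
    p = means / total
    nz = p > 0
    h = -np.sum(p[nz] * np.log(p[nz]))
    return float((math.log(n_bins) - h) / math.log(n_bins))


def mean_vector_length(phase: np.ndarray, amp: np.ndarray) -> float:
    """Canolty's mean-vector-length coupling measure |mean(A*e^{i*phi})|."""
    return float(np.abs(np.mean(amp * np.exp(1j * phase))))


def _bandpassed_analytic(padded: np.ndarray, fs: float, band: tuple[float, float],
                         pad: int, win: int) -> np.ndarray:
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = hilbert(sosfiltfilt(sos, padded, axis=1), axis=1)
    return y[:, pad : pad + win]


@dataclass
class Comodulogram:
    values: np.ndarray  # phase freqs x amp freqs
    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    n_phase_bins: int
    method: str


def pac_comodulogram(
    epochs: EpochSet,
    phase_freqs: np.ndarray = PHASE_FREQS,
    amp_freqs: np.ndarray = AMP_FREQS,
    n_bins: int = N_PHASE_BINS,
    method: str = "tort",
) -> Comodulogram:
    """Phase-amplitude comodulogram over the pre-stimulus epochs.

    Epochs are filtered with their +/-500 ms context, cropped, and then
    concatenated before binning.  Phase bands are f +/- 1 Hz; amplitude
    bands are f_amp +/- (f_phase + 2) Hz so both modulation sidebands of
    the phase frequency fall inside the band.
    """
    if epochs.n_kept < 1:
        raise ValueError("no kept trials")
    fs, pad = epochs.fs, epochs.pad
    win = epochs.epochs.shape[1]
    measure = modulation_index if method == "tort" else mean_vector_length
    out = np.empty((len(phase_freqs), len(amp_freqs)))
    for pi, fp in enumerate(phase_freqs):
        ph = np.angle(
            _bandpassed_analytic(epochs.padded, fs, (fp - 1.0, fp + 1.0), pad, win)
        ).ravel()
        half_bw = fp + 2.0
        for ai, fa in enumerate(amp_freqs):
            lo = max(fa - half_bw, fp + 2.0)
            hi = min(fa + half_bw, fs / 2 * 0.95)
            am = np.abs(
                _bandpassed_analytic(epochs.padded, fs, (lo, hi), pad, win)
            ).ravel()
            out[pi, ai] = measure(ph, am)
    return Comodulogram(values=out, phase_freqs=np.asarray(phase_freqs, float),
                        amp_freqs=np.asarray(amp_freqs, float),
                        n_phase_bins=n_bins, method=method)


def pac_window_mean(com: Comodulogram, window=PAC_WINDOW) -> float:
    """Mean MI over the (7-13 Hz phase) x (70-90 Hz amplitude) cells."""
    (plo, phi_), (alo, ahi) = window
    pm = (com.phase_freqs >= plo) & (com.phase_freqs <= phi_)
    am = (com.amp_freqs >= alo) & (com.amp_freqs <= ahi)
    return float(com.values[np.ix_(pm, am)].mean())


# ---------------------------------------------------------------------------
# EOG saccade detection

def detect_saccades(
    eog: np.ndarray,
    fs: float,
    threshold_uv_per_10ms: float = 25.0,
    refractory_s: float = 0.1,
) -> list[float]:
    """Velocity-threshold saccade detector.

    Low-passes the trace at 30 Hz, computes first-difference velocity in
    uV per 10 ms, and reports threshold crossings merged within a 100 ms
    refractory window.  Returns event times in seconds.
    """
    sos = butter(4, 30.0, btype="lowpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, eog)
    vel = np.abs(np.diff(x)) * fs * 0.01  # uV per 10 ms
    above = np.flatnonzero(vel > threshold_uv_per_10ms)
    events: list[float] = []
    last = -math.inf
    for i in above:
        t = i / fs
        if t - last >= refractory_s:
            events.append(t)
        last = t
    return events
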