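"""Tailored tACS current-waveform synthesis.

The stimulation current superposes short gamma bursts (three cycles of
80 Hz by default) on a 10 Hz alpha carrier, with the burst centred either
on the alpha peak or on the alpha trough.  Phases follow the *sine*
convention throughout: the alpha carrier is ``sin(2*pi*f_alpha*t)``, so
its peak sits at phase pi/2 and its trough at 3*pi/2.

Two published interval sets exist for the burst placement; the default
(`"discussion"`) set — peak [pi/16, 15*pi/16], trough [17*pi/16,
31*pi/16] — is the one that is centred on the carrier extrema and wide
enough (7*pi/8 of a cycle, i.e. 43.75 ms at 10 Hz) to hold a 37.5 ms
burst.  The narrower `"methods"` set is retained for sensitivity checks
but cannot contain the default burst.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

Condition = Literal["peak", "trough", "sham"]

#: burst-placement intervals (radians, sine convention), per interval source
_INTERVALS = {
    "discussion": {
        "peak": (math.pi / 16, 15 * math.pi / 16),
        "trough": (17 * math.pi / 16, 31 * math.pi / 16),
    },
    "methods": {
        "peak": (math.pi / 8, 3 * math.pi / 8),
        "trough": (5 * math.pi / 8, 7 * math.pi / 8),
    },
}


def canonical_interval(
    condition: str,
    convention: str = "sine",
    source: str = "discussion",
) -> tuple[float, float]:
    """Return the burst entrainment interval for *condition* in radians.

    Under the sine convention the interval is centred on the alpha peak
    (pi/2) for the peak condition and on the trough (3*pi/2) for the
    trough condition.  ``source="methods"`` selects the narrow
    alternative interval set.
    """
    if convention != "sine":
        raise ValueError(f"unsupported phase convention: {convention!r}")
    if condition == "sham":
        raise ValueError("sham stimulation has no entrainment interval")
    try:
        return _INTERVALS[source][condition]
    except KeyError:
        raise ValueError(
            f"unknown condition/source: {condition!r}/{source!r}"
        ) from None


@dataclass(frozen=True)
class StimParams:
    """Stimulation design parameters.

    Amplitudes are component peak-to-peak currents in mA; the composite
    session plateau is rescaled to ``composite_pkpk`` peak-to-peak,
    preserving the alpha:gamma component ratio.
    """

    condition: str = "trough"
    alpha_freq: float = 10.0
    gamma_freq: float = 80.0
    alpha_pkpk: float = 1.8
    gamma_pkpk: float = 1.2
    composite_pkpk: float = 3.0
    n_gamma_cycles: int = 3
    entrain_interval: tuple[float, float] | None = None
    interval_source: str = "discussion"
    ramp_s: float = 30.0
    plateau_s: float = 1200.0
    fs: float = 2048.0
    allow_overfull_interval: bool = False

    def __post_init__(self) -> None:
        if self.condition not in ("peak", "trough", "sham"):
            raise ValueError(f"unknown condition: {self.condition!r}")
        if self.composite_pkpk <= 0:
            raise ValueError("composite_pkpk must be positive")
        if self.ramp_s < 0 or self.plateau_s < 0:
            raise ValueError("durations must be non-negative")
        if self.condition == "sham":
            return  # gamma fields ignored for sham
        if self.fs <= 2 * self.gamma_freq:
            raise ValueError(
                f"fs={self.fs} cannot resolve gamma at {self.gamma_freq} Hz"
            )
        if self.n_gamma_cycles < 1:
            raise ValueError("n_gamma_cycles must be >= 1")
        if self.burst_s > 1.0 / self.alpha_freq:
            raise ValueError("gamma burst longer than one alpha period")
        lo, hi = self.interval
        width_s = (hi - lo) / (2 * math.pi * self.alpha_freq)
        if self.burst_s > width_s and not self.allow_overfull_interval:
            raise ValueError(
                f"{self.burst_s * 1e3:.1f} ms burst does not fit the "
                f"{width_s * 1e3:.1f} ms entrainment interval"
            )

    @property
    def interval(self) -> tuple[float, float]:
        if self.entrain_interval is not None:
            return self.entrain_interval
        return canonical_interval(self.condition, source=self.interval_source)

    @property
    def burst_s(self) -> float:
        """Burst duration in seconds (n cycles of the gamma carrier)."""
        return self.n_gamma_cycles / self.gamma_freq


@dataclass
class Waveform:
    """A sampled injection-current waveform with labelled segments."""

    samples: np.ndarray  # current, mA
    fs: float
    segments: dict[str, tuple[int, int]]  # label -> [start, stop) sample
    params: StimParams

    def __post_init__(self) -> None:
        spans = sorted(self.segments.values())
        if spans[0][0] != 0 or spans[-1][1] != len(self.samples):
            raise ValueError("segments do not cover the sample range")
        for (_, a_stop), (b_start, _) in zip(spans, spans[1:]):
            if a_stop != b_start:
                raise ValueError("segments overlap or leave gaps")

    @property
    def duration_s(self) -> float:
        return (len(self.samples) - 1) / self.fs

    def segment(self, label: str) -> np.ndarray:
        start, stop = self.segments[label]
        return self.samples[start:stop]


def synth_burst(params: StimParams) -> np.ndarray:
    """One Hann-tapered gamma burst, sampled at ``params.fs`` (mA).

    The untapered carrier has peak-to-peak ``gamma_pkpk``; the taper
    brings both endpoints to exactly 0.
    """
    if params.n_gamma_cycles < 1:
        raise ValueError("n_gamma_cycles must be >= 1")
    if params.burst_s > 1.0 / params.alpha_freq:
        raise ValueError("gamma burst longer than one alpha period")
    n = int(round(params.burst_s * params.fs)) + 1
    t = np.arange(n) / params.fs
    env = 0.5 * (1 - np.cos(2 * math.pi * t / params.burst_s))
    env[0] = env[-1] = 0.0  # exact endpoints against rounding
    return env * (params.gamma_pkpk / 2) * np.sin(
        2 * math.pi * params.gamma_freq * t
    )


def _verum_current(t: np.ndarray, params: StimParams) -> np.ndarray:
    """Unscaled composite current at continuous times *t* (seconds).

    Closed-form in t: alpha carrier plus one Hann-tapered gamma burst per
    alpha cycle, centred at the midpoint of the entrainment interval.
    Evaluating in continuous time avoids tiling drift when the alpha
    period is a non-integer number of samples.
    """
    fa = params.alpha_freq
    phase = 2 * math.pi * fa * t % (2 * math.pi)
    out = (params.alpha_pkpk / 2) * np.sin(phase)

    lo, hi = params.interval
    centre = 0.5 * (lo + hi)
    tb = params.burst_s
    # signed time offset from the burst centre, within one alpha cycle
    trel = ((phase - centre + math.pi) % (2 * math.pi) - math.pi) / (
        2 * math.pi * fa
    )
    inside = np.abs(trel) <= tb / 2
    tr = trel[inside]
    env = 0.5 * (1 + np.cos(2 * math.pi * tr / tb))
    carrier = np.sin(2 * math.pi * params.gamma_freq * (tr + tb / 2))
    out[inside] += env * (params.gamma_pkpk / 2) * carrier
    return out


def compose_cycle(params: StimParams) -> np.ndarray:
    """One alpha-period tile of the composite waveform, rescaled so the
    periodic extension has peak-to-peak ``composite_pkpk`` (mA)."""
    if params.condition == "sham":
        raise ValueError("sham has no composite cycle")
    n = int(round(params.fs / params.alpha_freq))
    t = np.arange(n) / params.fs
    tile = _verum_current(t, params)
    # continuous-limit peak-to-peak from a heavily oversampled period
    t_fine = np.arange(n * 16) / (params.fs * 16)
    fine = _verum_current(t_fine, params)
    return tile * (params.composite_pkpk / np.ptp(fine))


def build_session(params: StimParams) -> Waveform:
    """Full stimulation-session current trace.

    Peak/trough: linear ramp-up (``ramp_s``), plateau (``plateau_s``),
    linear ramp-down, of the composite waveform; the plateau is rescaled
    to exactly ``composite_pkpk`` peak-to-peak on its own sample grid.
    Sham: pure alpha under a triangular envelope that reaches
    ``composite_pkpk`` peak-to-peak at its apex (up ``ramp_s``, down
    ``ramp_s``), then zero current for the rest of the session.
    """
    r, p, fs = params.ramp_s, params.plateau_s, params.fs
    total = 2 * r + p
    n = int(round(total * fs)) + 1
    t = np.arange(n) / fs
    i_r = int(round(r * fs))
    i_rp = int(round((r + p) * fs))

    if params.condition == "sham":
        env = np.zeros(n)
        up = t <= r
        env[up] = t[up] / r
        down = (t > r) & (t <= 2 * r)
        env[down] = (2 * r - t[down]) / r
        # carrier phased so the envelope apex lands on a current peak
        carrier = np.cos(2 * math.pi * params.alpha_freq * (t - r))
        samples = env * (params.composite_pkpk / 2) * carrier
        segments = {
            "ramp_up": (0, i_r),
            "ramp_down": (i_r, 2 * i_r),
            "rest": (2 * i_r, n),
        }
    else:
        raw = _verum_current(t, params)
        env = np.minimum(1.0, np.minimum(t / r, (total - t) / r))
        env[0] = env[-1] = 0.0
        scale = params.composite_pkpk / np.ptp(raw[i_r:i_rp])
        samples = env * raw * scale
        segments = {
            "ramp_up": (0, i_r),
            "plateau": (i_r, i_rp),
            "ramp_down": (i_rp, n),
        }
    return Waveform(samples=samples, fs=fs, segments=segments, params=params)


def entrainment_profile(
    x: np.ndarray,
    fs: float,
    alpha_band: tuple[float, float] = (7.0, 13.0),
    gamma_band: tuple[float, float] = (70.0, 90.0),
    edge_s: float = 1.0,
) -> tuple[float, float]:
    """Gamma-envelope-weighted alpha phase statistics of a raw trace.

    Band-passes *x* in the alpha band for instantaneous phase (sine
    convention) and in the gamma band for the analytic-signal envelope,
    then returns ``(preferred_phase, concentration)`` — the circular mean
    of alpha phase weighted by gamma envelope, and the weighted mean
    resultant length.
    """
    sos_a = butter(4, alpha_band, btype="bandpass", fs=fs, output="sos")
    sos_g = butter(4, gamma_band, btype="bandpass", fs=fs, output="sos")
    phase = np.angle(hilbert(sosfiltfilt(sos_a, x))) + math.pi / 2
    envel = np.abs(hilbert(sosfiltfilt(sos_g, x)))
    k = int(edge_s * fs)
    if k and len(x) > 2 * k:
        phase, envel = phase[k:-k], envel[k:-k]
    z = np.sum(envel * np.exp(1j * phase))
    pref = float(np.angle(z) % (2 * math.pi))
    conc = float(np.abs(z) / np.sum(envel))
    return pref, conc


def verify_entrainment(w: Waveform, segment: str = "plateau") -> tuple[float, float]:
    """Check where in the alpha cycle the gamma envelope concentrates.

    Returns ``(preferred_phase, concentration)`` computed on the named
    segment (the plateau by default).  A trough-condition session should
    yield a preferred phase near 3*pi/2, a peak session near pi/2.
    """
    x = w.segment(segment)
    if len(x) < 10 * w.fs / w.params.alpha_freq:
        raise ValueError("segment shorter than 10 alpha periods")
    return entrainment_profile(x, w.fs)


def export_waveform(w: Waveform, path: str | Path) -> None:
    """Write a two-column CSV (time_s, current_mA) plus a JSON sidecar
    holding the stimulation parameters and segment boundaries."""
    path = Path(path)
    t = np.arange(len(w.samples)) / w.fs
    np.savetxt(
        path,
        np.column_stack([t, w.samples]),
        delimiter=",",
        header="time_s,current_mA",
        comments="",
        fmt="%.9f",
    )
    meta = {
        "fs": w.fs,
        "segments": {k: list(v) for k, v in w.segments.items()},
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(w.params).items()
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def import_waveform(path: str | Path) -> Waveform:
    """Read back a waveform written by :func:`export_waveform`."""
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    pkw = dict(meta["params"])
    if pkw.get("entrain_interval") is not None:
        pkw["entrain_interval"] = tuple(pkw["entrain_interval"])
    params = StimParams(**pkw)
    return Waveform(
        samples=data[:, 1],
        fs=float(meta["fs"]),
        segments={k: tuple(v) for k, v in meta["segments"].items()},
        params=params,
    )
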