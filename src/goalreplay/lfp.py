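"""LFP analysis: ripple detection and theta quantification.

Ripples: 150-250 Hz band, Hilbert envelope smoothed with a 12.5 ms
Gaussian, averaged across channels; events are local peaks > mean + 3 SD
during immobility (< 5 cm/s), with boundaries at the surrounding
mean-crossings.  Theta: 6-12 Hz band, 300 ms-smoothed Hilbert envelope
z-scored over the session, consumed only during active movement
(> 10 cm/s).  Theta cycles are delimited at 60 deg with the filtered-signal
trough at 0 deg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, hilbert, sosfiltfilt


@dataclass(frozen=True)
class RippleEvent:
    start: float
    peak: float
    end: float
    peak_amplitude: float    # SD units of the session envelope
    duration: float


@dataclass
class ThetaCycle:
    start: float
    end: float
    trial: int = -1
    mean_speed: float = np.nan

    @property
    def duration(self) -> float:
        return self.end - self.start


def bandpass(signal: np.ndarray, fs: float, low: float, high: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward), same length.

    Zero-phase filtering preserves event timing, which matters for
    boundary detection.
    """
    if not 0 < low < high < fs / 2:
        raise ValueError("band must satisfy 0 < low < high < fs/2")
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=0)


def ripple_envelope(filtered: np.ndarray, fs: float,
                    smooth_sd: float = 0.0125) -> np.ndarray:
    """|Hilbert| of the ripple-band signal, Gaussian-smoothed (SD 12.5 ms)."""
    env = np.abs(hilbert(np.asarray(filtered, dtype=float), axis=0))
    return gaussian_filter1d(env, smooth_sd * fs, axis=0)


def detect_ripples(envelopes: np.ndarray, t: np.ndarray,
                   speed: np.ndarray, speed_t: np.ndarray,
                   threshold_sd: float = 3.0, speed_max: float = 5.0,
                   stats_on: str = "all") -> list[RippleEvent]:
    """Detect ripples on the channel-averaged smoothed envelope.

    envelopes: (n_samples,) or (n_samples, n_channels) smoothed envelope
    t:         envelope sample times [s]
    speed:     speed series [cm/s] with its own times ``speed_t``
    stats_on:  "all" (default) computes the threshold mean/SD over the
               whole session; "immobile" restricts the statistics to
               immobility samples.  Detection itself is always restricted
               to immobility.

    Events are local peaks above mean + threshold_sd * SD; boundaries at
    the nearest mean-crossings around the peak; overlapping boundary
    intervals are merged keeping the larger peak.
    """
    env = np.asarray(envelopes, dtype=float)
    if env.ndim == 2:
        env = env.mean(axis=1)
    sp = np.interp(t, speed_t, speed)
    immobile = sp < speed_max
    if not immobile.any():
        warnings.warn("no immobility epochs; no ripples can be detected")
        return []
    stat_sel = immobile if stats_on == "immobile" else slice(None)
    mu = env[stat_sel].mean()
    sd = env[stat_sel].std()
    thresh = mu + threshold_sd * sd

    above = env > thresh
    # local peaks above threshold during immobility
    peaks = np.nonzero(
        above[1:-1] & (env[1:-1] >= env[:-2]) & (env[1:-1] > env[2:])
        & immobile[1:-1])[0] + 1
    if len(peaks) == 0:
        return []

    below = env <= mu
    events: list[tuple[int, int, int]] = []
    for p in peaks:
        left = np.nonzero(below[:p])[0]
        i0 = left[-1] + 1 if len(left) else 0
        right = np.nonzero(below[p:])[0]
        i1 = p + right[0] - 1 if len(right) else len(env) - 1
        events.append((i0, p, i1))

    # merge events sharing boundary intervals, keep the larger peak
    events.sort()
    merged: list[tuple[int, int, int]] = []
    for i0, p, i1 in events:
        if merged and i0 <= merged[-1][2]:
            j0, q, j1 = merged[-1]
            best = p if env[p] > env[q] else q
            merged[-1] = (j0, best, max(i1, j1))
        else:
            merged.append((i0, p, i1))

    out = []
    for i0, p, i1 in merged:
        out.append(RippleEvent(
            start=float(t[i0]), peak=float(t[p]), end=float(t[i1]),
            peak_amplitude=float((env[p] - mu) / sd),
            duration=float(t[i1] - t[i0])))
    return out


def theta_power(signal: np.ndarray, fs: float,
                smooth_sd: float = 0.3) -> np.ndarray:
    """z-scored 6-12 Hz envelope (Gaussian smoothing SD 300 ms).

    The z-score is over the entire session; consumers mask the result to
    active movement (> 10 cm/s) themselves.
    """
    filt = bandpass(signal, fs, 6.0, 12.0)
    env = gaussian_filter1d(np.abs(hilbert(filt, axis=0)), smooth_sd * fs,
                            axis=0)
    return (env - env.mean()) / env.std()


def instantaneous_phase_deg(filtered_theta: np.ndarray) -> np.ndarray:
    """Unwrapped theta phase in degrees with troughs of the filtered signal
    at 0 (mod 360).

    The analytic-signal phase of a band-limited oscillation is 0 at signal
    maxima and +-180 at minima; shifting by 180 deg maps minima (troughs)
    to 0.  The signal is reflect-padded before the Hilbert transform to
    suppress edge distortion of the phase at the record boundaries.
    """
    x = np.asarray(filtered_theta, dtype=float)
    pad = min(len(x) - 1, 4096)
    xp = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]])
    ph = np.unwrap(np.angle(hilbert(xp)))[pad:pad + len(x)]
    return np.degrees(ph) + 180.0


def segment_theta_cycles(filtered_theta: np.ndarray, t: np.ndarray,
                         speed: np.ndarray, speed_t: np.ndarray,
                         speed_min: float = 10.0) -> list[ThetaCycle]:
    """Delimit theta cycles at successive 60 deg phase crossings.

    Only cycles whose mean running speed exceeds ``speed_min`` are
    returned (theta analyses are restricted to active movement).
    """
    phase = instantaneous_phase_deg(filtered_theta)
    # crossing times of 60 + k*360 in the unwrapped phase
    k0 = np.ceil((phase[0] - 60.0) / 360.0)
    k1 = np.floor((phase[-1] - 60.0) / 360.0)
    targets = 60.0 + 360.0 * np.arange(k0, k1 + 1)
    cross = np.interp(targets, phase, t)
    sp = np.interp(t, speed_t, speed)
    cycles = []
    for a, b in zip(cross[:-1], cross[1:]):
        m = (t >= a) & (t < b)
        ms = float(sp[m].mean()) if m.any() else np.nan
        if np.isfinite(ms) and ms > speed_min:
            cycles.append(ThetaCycle(start=float(a), end=float(b),
                                     mean_speed=ms))
    return cycles


def phase_interpolator(filtered_theta: np.ndarray, t: np.ndarray):
    """Callable mapping times -> unwrapped phase [deg] (troughs = 0 mod 360)."""
    phase = instantaneous_phase_deg(filtered_theta)

    def f(times):
        return np.interp(times, t, phase)

    return f


def event_participation(windows: list[tuple[float, float]],
                        spikes: list[np.ndarray]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-event (fraction of units active, mean spikes per participant).

    The fraction is over all recorded units; the per-participant count is
    the mean spike count among units with >= 1 spike in the window (NaN
    when no unit participates).
    """
    n_units = len(spikes)
    frac = np.zeros(len(windows))
    per = np.full(len(windows), np.nan)
    for i, (a, b) in enumerate(windows):
        counts = np.array([np.searchsorted(s, b) - np.searchsorted(s, a)
                           for s in spikes])
        active = counts > 0
        frac[i] = active.sum() / n_units if n_units else 0.0
        if active.any():
            per[i] = counts[active].mean()
    return frac, per
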