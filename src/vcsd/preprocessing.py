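"""Front-end signal processing for multichannel extracellular recordings.

The raw extracellular potential mixes two signals: local field potentials
(LFP, synaptic population activity, < 500 Hz) and unit activity (spikes of
nearby neurons, > 500 Hz).  This module separates the bands, averages
stimulus-locked epochs into event-related potentials (ERPs), detects spikes
by negative-threshold crossing, and computes spike-triggered average
potentials (STAPs).

Filters are Butterworth band-passes applied forward-backward (zero phase),
so ERP and STAP latencies are not skewed by the filter's group delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import DegenerateInputError

__all__ = [
    "Recording",
    "SpikeTrain",
    "BANDS",
    "bandpass",
    "epoch_average",
    "detect_spikes",
    "spike_triggered_average",
]

# band-pass corner frequencies, Hz
BANDS = {"lfp": (1.0, 500.0), "unit": (500.0, 8000.0)}

SNIPPET_PRE = 8    # samples kept before the spike trough
SNIPPET_POST = 12  # samples kept after the trough (20-sample snippets)


@dataclass(frozen=True)
class Recording:
    """Channels x time potentials (volts) with sampling and event metadata."""

    samples: np.ndarray
    sampling_rate: float  # Hz
    event_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    channel_labels: tuple = ()
    band: str = "raw"

    def __post_init__(self):
        x = np.atleast_2d(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", x)
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be positive")
        ev = np.asarray(self.event_times, dtype=float).ravel()
        if np.any((ev < 0) | (ev > self.duration)):
            raise ValueError("event times fall outside the recording")
        object.__setattr__(self, "event_times", ev)
        if not self.channel_labels:
            object.__setattr__(
                self, "channel_labels",
                tuple(f"ch{i:03d}" for i in range(x.shape[0])))

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class SpikeTrain:
    """Spike trough times (seconds) and waveform snippets for one channel."""

    channel: int
    times: np.ndarray
    waveforms: np.ndarray  # (n_spikes, SNIPPET_PRE + SNIPPET_POST)
    labels: np.ndarray = None  # optional per-spike cluster labels

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float).ravel()
        w = np.asarray(self.waveforms, dtype=float)
        if w.ndim != 2 or w.shape[0] != len(t):
            raise ValueError("one waveform snippet per spike is required")
        if w.shape[1] != SNIPPET_PRE + SNIPPET_POST:
            raise ValueError(
                f"snippets must span {SNIPPET_PRE}+{SNIPPET_POST} samples")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "waveforms", w)

    @property
    def n_spikes(self) -> int:
        return len(self.times)


def bandpass(recording: Recording, band, order=4) -> Recording:
    """Zero-phase Butterworth band-pass at the named or explicit corners.

    ``band`` is ``'lfp'`` (1-500 Hz), ``'unit'`` (500 Hz-8 kHz) or an
    explicit ``(low, high)`` pair.  The upper corner must stay below the
    Nyquist frequency.
    """
    corners = BANDS[band] if isinstance(band, str) else tuple(band)
    lo, hi = (float(c) for c in corners)
    nyq = recording.sampling_rate / 2.0
    if not (0 < lo < hi):
        raise ValueError("need 0 < low < high")
    if hi >= nyq:
        raise ValueError(
            f"upper corner {hi} Hz is not below Nyquist ({nyq} Hz)")
    sos = sps.butter(order, [lo, hi], btype="bandpass",
                     fs=recording.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.samples, axis=1)
    return replace(recording, samples=filtered,
                   band=band if isinstance(band, str) else f"{lo:g}-{hi:g}Hz")


def epoch_average(recording: Recording, window=(-0.050, 0.100),
                  event_times=None) -> np.ndarray:
    """Average stimulus-locked epochs: channels x window samples.

    ``window`` is (pre, post) in seconds relative to each event; every
    epoch must lie inside the recording, otherwise the offending events are
    reported.
    """
    events = recording.event_times if event_times is None else np.asarray(event_times)
    if len(events) == 0:
        raise ValueError("no events to average")
    pre, post = window
    if post <= pre:
        raise ValueError("window end must exceed its start")
    fs = recording.sampling_rate
    i0 = np.round(events * fs).astype(int) + int(np.round(pre * fs))
    n_win = int(np.round((post - pre) * fs))
    bad = np.flatnonzero((i0 < 0) | (i0 + n_win > recording.n_samples))
    if len(bad):
        raise ValueError(
            f"epoch window exceeds the recording for events {bad.tolist()}")
    acc = np.zeros((recording.n_channels, n_win))
    for start in i0:
        acc += recording.samples[:, start:start + n_win]
    return acc / len(i0)


def _channel_sd(x, robust):
    if robust:
        return np.median(np.abs(x)) / 0.6745
    return float(np.std(x))


def detect_spikes(recording: Recording, threshold_sd=4.0, dead_time=1.5e-3,
                  robust_sd=False):
    """Negative-edge spike detection on a unit-band recording.

    Per channel, the threshold is ``-threshold_sd`` times the channel's
    standard deviation (or a median-absolute-deviation estimate with
    ``robust_sd``).  Each downward crossing registers a spike; further
    crossings within ``dead_time`` are suppressed; the spike time is the
    trough (minimum) within the dead-time window; a 20-sample snippet
    (8 before, 12 after the trough) is extracted.

    Returns a list of :class:`SpikeTrain`, one per channel.
    """
    fs = recording.sampling_rate
    dead = max(1, int(round(dead_time * fs)))
    n_snip = SNIPPET_PRE + SNIPPET_POST
    trains = []
    for ch in range(recording.n_channels):
        x = recording.samples[ch]
        if len(x) < n_snip:
            warnings.warn(f"channel {ch} shorter than one snippet; skipped")
            trains.append(SpikeTrain(ch, np.empty(0), np.empty((0, n_snip))))
            continue
        thr = -threshold_sd * _channel_sd(x, robust_sd)
        below = x < thr
        crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
        troughs = []
        last_end = -1
        for c in crossings:
            if c <= last_end:
                continue
            end = min(c + dead, len(x))
            troughs.append(c + int(np.argmin(x[c:end])))
            last_end = c + dead - 1
        times, waves = [], []
        for t in troughs:
            a, b = t - SNIPPET_PRE, t + SNIPPET_POST
            if a < 0 or b > len(x):
                continue  # trough too close to the record edge
            times.append(t / fs)
            waves.append(x[a:b])
        waves = np.asarray(waves) if waves else np.empty((0, n_snip))
        trains.append(SpikeTrain(ch, np.asarray(times), waves))
    return trains


def spike_triggered_average(recording: Recording, spikes: SpikeTrain,
                            window=(-0.002, 0.003)) -> np.ndarray:
    """Mean potential epoch across spike times: channels x window samples.

    Computed on whatever band ``recording`` carries (wide-band or LFP as the
    caller configures).  Spikes whose window leaves the recording are
    dropped; with none left an error is raised.
    """
    pre, post = window
    if post <= pre:
        raise ValueError("window end must exceed its start")
    fs = recording.sampling_rate
    n_win = int(np.round((post - pre) * fs))
    i0 = np.round(spikes.times * fs).astype(int) + int(np.round(pre * fs))
    ok = (i0 >= 0) & (i0 + n_win <= recording.n_samples)
    if not np.any(ok):
        raise DegenerateInputError("no spike with full window coverage")
    acc = np.zeros((recording.n_channels, n_win))
    for start in i0[ok]:
        acc += recording.samples[:, start:start + n_win]
    return acc / int(np.sum(ok))
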