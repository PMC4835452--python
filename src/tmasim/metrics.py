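"""Firing-pattern statistics extracted from a membrane-potential trace.

Three quantities characterise the response to a stimulus:

AMP : mean peak voltage of the detected action potentials (mV, shifted
      frame), after discarding an onset transient;
ISI : interspike interval -- time between adjacent spikes *within a burst*
      (ms); for a pulsed stimulus the silent inter-burst gaps are excluded;
FR  : firing rate -- spikes per repetition cycle of a pulsed stimulus.

Spike detection is deliberately simple: a spike is a local maximum of V
exceeding a threshold (default 50 mV, roughly half a healthy ~100 mV spike
and far above subthreshold ripple), with a minimum peak separation playing
the role of a refractory period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "SpikeTrain",
    "SpikeTrainSummary",
    "detect_spikes",
    "amplitude_stat",
    "isi_stat",
    "firing_rate_per_cycle",
    "summarize",
    "DETECTION_THRESHOLD_MV",
    "MIN_SEPARATION_MS",
    "TRANSIENT_MS",
]

#: Default spike-detection threshold, mV (shifted frame).
DETECTION_THRESHOLD_MV = 50.0

#: Default minimum separation between detected peaks, ms.
MIN_SEPARATION_MS = 2.0

#: Default onset transient excluded from AMP/ISI statistics, ms.
TRANSIENT_MS = 100.0


@dataclass(frozen=True)
class SpikeTrain:
    """Detected spike peak times (ms, strictly increasing) and voltages (mV)."""

    times: np.ndarray
    peaks: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.peaks):
            raise ValueError("times and peaks must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class SpikeTrainSummary:
    """AMP/ISI/FR summary of one simulation.

    Undefined statistics (no post-transient spikes, or fewer than two spikes
    in a burst) are NaN / empty, never zero.  ``fr_per_cycle`` is None for
    continuous-wave stimulation, where no repetition cycle exists.
    """

    amp_mean: float
    isi_mean: float
    isi_values: np.ndarray
    fr_per_cycle: float | None
    n_spikes: int


def detect_spikes(
    result,
    threshold: float = DETECTION_THRESHOLD_MV,
    min_separation: float = MIN_SEPARATION_MS,
) -> SpikeTrain:
    """Find action-potential peaks in ``result`` (anything with .t and .v).

    A spike is a local maximum of v exceeding ``threshold`` mV; successive
    peaks must be at least ``min_separation`` ms apart.
    """
    t = np.asarray(result.t, dtype=float)
    v = np.asarray(result.v, dtype=float)
    if t.size == 0:
        raise ValueError("empty trace")
    if not threshold > 0 or not min_separation > 0:
        raise ValueError("threshold and min_separation must be > 0")
    if t.size < 3:
        return SpikeTrain(np.empty(0), np.empty(0))
    dt_rec = t[1] - t[0]
    distance = max(1, int(round(min_separation / dt_rec)))
    idx, _ = find_peaks(v, height=threshold, distance=distance)
    return SpikeTrain(t[idx], v[idx])


def amplitude_stat(train: SpikeTrain, transient: float = TRANSIENT_MS) -> float:
    """Mean spike peak voltage (mV) over spikes after ``transient`` ms.

    NaN when no spike survives the transient cutoff (undefined, not zero).
    """
    peaks = train.peaks[train.times > transient]
    return float(np.mean(peaks)) if peaks.size else math.nan


def isi_stat(
    train: SpikeTrain,
    burst_split: float = math.inf,
    transient: float = 0.0,
) -> tuple[np.ndarray, float]:
    """(isi_values, isi_mean): consecutive spike-time differences in ms.

    Gaps larger than ``burst_split`` are treated as inter-burst silences and
    excluded, so the statistic measures the interval of adjacent spikes
    *within* a burst.  For continuous stimulation leave ``burst_split`` at
    +inf (every gap counts).  Spikes at or before ``transient`` ms are
    ignored.  With fewer than two retained spikes the values are empty and
    the mean is NaN.
    """
    times = train.times[train.times > transient]
    if times.size < 2:
        return np.empty(0), math.nan
    gaps = np.diff(times)
    kept = gaps[gaps <= burst_split]
    if kept.size == 0:
        return np.empty(0), math.nan
    return kept, float(np.mean(kept))


def firing_rate_per_cycle(
    train: SpikeTrain,
    rep_freq: float,
    duration: float,
    transient_cycles: int = 1,
) -> float:
    """Mean spike count per complete repetition cycle of a pulsed stimulus.

    The first ``transient_cycles`` cycles are skipped; spikes are counted
    over the remaining *complete* cycles (a trailing partial cycle is
    ignored) and averaged.  ``duration`` in ms, ``rep_freq`` in Hz.
    """
    if not rep_freq > 0:
        raise ValueError("rep_freq must be > 0 (Hz)")
    period_ms = 1e3 / rep_freq
    n_complete = int(math.floor(duration / period_ms + 1e-9))
    n_counted = n_complete - transient_cycles
    if n_counted < 1:
        raise ValueError(
            f"duration={duration:g} ms holds only {n_complete} complete "
            f"cycle(s) at RF={rep_freq:g} Hz; need > {transient_cycles}"
        )
    start = transient_cycles * period_ms
    end = n_complete * period_ms
    count = int(np.count_nonzero((train.times > start) & (train.times <= end)))
    return count / n_counted


def default_burst_split(duty_cycle: float, rep_freq: float) -> float:
    """Burst-splitting gap for pulsed ISI: the off-period (1-DC)/RF in ms.

    Any gap longer than the silent phase of the cycle must span a silence;
    a full duty cycle degenerates to continuous stimulation (+inf).
    """
    off_ms = 1e3 * (1.0 - duty_cycle) / rep_freq
    return off_ms if off_ms > 0 else math.inf


def summarize(
    result,
    drive=None,
    threshold: float = DETECTION_THRESHOLD_MV,
    min_separation: float = MIN_SEPARATION_MS,
) -> SpikeTrainSummary:
    """Full AMP/ISI/FR summary of a simulation result.

    ``drive`` (a DriveSpec, or None/number for constant input) selects the
    conventions: continuous/constant input uses a 100 ms onset transient and
    no burst splitting; pulsed input skips the first repetition cycle and
    splits bursts at the off-period.
    """
    train = detect_spikes(result, threshold, min_separation)
    pulsed = getattr(drive, "mode", None) == "pulsed"
    duration = float(result.t[-1])
    if pulsed:
        transient = 1e3 / drive.rep_freq
        burst_split = default_burst_split(drive.duty_cycle, drive.rep_freq)
        fr = firing_rate_per_cycle(train, drive.rep_freq, duration)
    else:
        transient = min(TRANSIENT_MS, 0.2 * duration)
        burst_split = math.inf
        fr = None
    amp = amplitude_stat(train, transient)
    isi_values, isi_mean = isi_stat(train, burst_split, transient)
    return SpikeTrainSummary(
        amp_mean=amp,
        isi_mean=isi_mean,
        isi_values=isi_values,
        fr_per_cycle=fr,
        n_spikes=len(train),
    )
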