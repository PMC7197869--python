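"""Spike-train containers, segmentation and the analysis filters.

A recording session (or one simulated cell's full train) is a
:class:`SpikeTrain`; analysis operates on fixed 200-s windows of it,
:class:`SpikeTrainSegment`.  Experimental-style sessions are either tiled into
non-overlapping windows (for descriptive statistics) or sampled with random
potentially-overlapping windows, 10*T/200 of them, to enlarge fitting
datasets.  Model simulations are used whole (duration 200 s by convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpikeTrain",
    "SpikeTrainSegment",
    "split_session",
    "library_split_halves",
    "filter_trains",
    "filter_segments",
]

MIN_SPIKES = 11          # a usable segment has >= 11 spikes (>= 10 ISIs)
MAX_SKEW = 60.0          # experimental cells above this ISI skew are dropped
MAX_RATE_HZ = 10.0       # experimental cells above this session rate are dropped
SEGMENT_LEN = 200.0


def _check_times(t: np.ndarray, duration: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.size:
        if np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if t[0] < 0 or t[-1] > duration:
            raise ValueError("spike times outside [0, duration]")
    return t


@dataclass
class SpikeTrain:
    """One cell's spikes over a whole session/simulation, with metadata."""

    spike_times: np.ndarray
    duration: float
    cell_id: int = 0
    group: str = ""
    age: float = np.nan
    source: str = ""

    def __post_init__(self):
        self.spike_times = _check_times(self.spike_times, self.duration)

    @property
    def rate(self) -> float:
        return self.spike_times.size / self.duration


@dataclass
class SpikeTrainSegment:
    """Spike times within one observation window, re-referenced to t = 0."""

    spike_times: np.ndarray
    t_seg: float = SEGMENT_LEN
    group: str = ""
    age: float = np.nan
    source: str = ""

    def __post_init__(self):
        self.spike_times = _check_times(self.spike_times, self.t_seg)

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


def _window(train: SpikeTrain, start: float, length: float) -> SpikeTrainSegment:
    t = train.spike_times
    sel = t[(t >= start) & (t < start + length)] - start
    return SpikeTrainSegment(
        spike_times=sel, t_seg=length,
        group=train.group, age=train.age,
        source=f"{train.source}/c{train.cell_id}",
    )


def split_session(
    train: SpikeTrain,
    mode: str = "nonoverlapping",
    seed: int | np.random.Generator | None = None,
    segment_len: float = SEGMENT_LEN,
) -> list[SpikeTrainSegment]:
    """Cut one session into 200-s analysis windows.

    ``nonoverlapping`` tiles [0, T] into floor(T/200) windows;
    ``random_overlapping`` draws exactly round(10*T/200) windows with
    uniformly random starts in [0, T-200] (the convention used to build
    fitting datasets).  Sparse windows are dropped later by
    :func:`filter_segments`, not here.
    """
    T = train.duration
    if T < segment_len:
        raise ValueError(f"session of {T} s is shorter than one {segment_len} s segment")
    if mode == "nonoverlapping":
        starts = np.arange(int(T // segment_len)) * segment_len
    elif mode == "random_overlapping":
        rng = np.random.default_rng(seed)
        n = int(round(10 * T / segment_len))
        starts = rng.uniform(0.0, T - segment_len, size=n)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [_window(train, s, segment_len) for s in starts]


def library_split_halves(
    trains: list[SpikeTrain], half: float | None = None
) -> tuple[list[SpikeTrainSegment], list[SpikeTrainSegment]]:
    """Split every train into two non-overlapping halves.

    The first halves play the role of an experimental dataset and the second
    halves the model library in parameter-recovery validation.
    """
    first, second = [], []
    for tr in trains:
        h = tr.duration / 2 if half is None else half
        first.append(_window(tr, 0.0, h))
        second.append(_window(tr, h, h))
    return first, second


def _session_skew(train: SpikeTrain) -> float:
    isis = np.diff(train.spike_times)
    if isis.size < 3:
        return 0.0
    mu = isis.mean()
    var = np.mean(isis**2) - mu**2
    if var <= 0:
        return 0.0
    return float((np.mean(isis**3) - 3 * mu * var - mu**3) / var**1.5)


def filter_trains(trains: list[SpikeTrain], mode: str = "experimental"):
    """Whole-cell exclusion rules.

    Experimental mode drops cells with anomalously high session ISI skew
    (> 60, indicating record errors) or session-wide mean rate > 10 Hz.
    Model mode drops only cells with fewer than 11 spikes in the simulation.
    Returns (retained, rejection log).
    """
    kept, log = [], []
    for tr in trains:
        if mode == "experimental":
            if _session_skew(tr) > MAX_SKEW:
                log.append((tr.cell_id, "session ISI skew > 60"))
                continue
            if tr.rate > MAX_RATE_HZ:
                log.append((tr.cell_id, "session mean rate > 10 Hz"))
                continue
        elif mode == "model":
            if tr.spike_times.size < MIN_SPIKES:
                log.append((tr.cell_id, "fewer than 11 spikes"))
                continue
        else:
            raise ValueError(f"unknown mode {mode!r}")
        kept.append(tr)
    return kept, log


def filter_segments(segments: list[SpikeTrainSegment]):
    """Drop segments with fewer than 11 spikes.  Returns (retained, log)."""
    kept, log = [], []
    for k, seg in enumerate(segments):
        if seg.n_spikes < MIN_SPIKES:
            log.append((k, f"{seg.n_spikes} spikes < {MIN_SPIKES}"))
        else:
            kept.append(seg)
    return kept, log
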