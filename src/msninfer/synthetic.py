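"""Surrogate "experimental" spike-train datasets.

Real MSN recordings behind this kind of analysis are archival single-unit
sessions of 20-30 minutes; none are bundled here.  Two surrogate routes make
every downstream stage runnable and testable without them:

* model-simulation surrogates — spike trains from the network simulator
  itself (faithful to the analysis assumptions but slow); see
  :mod:`msninfer.network` and :func:`msninfer.segments.library_split_halves`.
* MMPP surrogates — each cell an independent two-state Markov-modulated
  Poisson process (a high-rate burst state and a low-rate quiescent state
  with exponential dwell times).  These are fast caricatures of the bursty
  (WT-like, ISI CV well above 1, positive serial correlations) and
  near-Poisson (HD-like, CV near 1) phenotypes, suitable for exercising the
  feature/fit stack; they are not a substitute for model validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .segments import SpikeTrain, SpikeTrainSegment

__all__ = [
    "MMPPSpec",
    "PRESETS",
    "generate_mmpp_train",
    "generate_mmpp_trains",
    "AgeDataset",
    "build_age_datasets",
]


@dataclass
class MMPPSpec:
    """Two-state MMPP session generator settings.

    Rates in Hz, dwell times (mean burst / inter-burst durations) in seconds.
    ``ages`` assigns a nominal age in weeks to each cell (scalar or per-cell
    array) so age-trend analyses can be exercised with planted structure.
    """

    burst_rate: float = 8.0
    quiet_rate: float = 0.1
    burst_duration: float = 2.0
    quiet_duration: float = 20.0
    duration: float = 1800.0
    n_cells: int = 50
    group: str = ""
    ages: float | np.ndarray = np.nan
    seed: int = 0

    def __post_init__(self):
        if self.burst_rate < 0 or self.quiet_rate < 0:
            raise ValueError("rates must be non-negative")
        if min(self.burst_duration, self.quiet_duration, self.duration) <= 0:
            raise ValueError("durations must be positive")

    @property
    def mean_rate(self) -> float:
        """Stationary mean rate of the modulated process (Hz)."""
        tb, tq = self.burst_duration, self.quiet_duration
        return (self.burst_rate * tb + self.quiet_rate * tq) / (tb + tq)


#: Session-generator presets: bursty WT-like, weakly modulated HD-like, and a
#: homogeneous Poisson control.
PRESETS: dict[str, dict] = {
    "wt": dict(burst_rate=8.0, quiet_rate=0.1,
               burst_duration=2.0, quiet_duration=20.0),
    "hd": dict(burst_rate=3.0, quiet_rate=1.0,
               burst_duration=2.0, quiet_duration=5.0),
    "poisson": dict(burst_rate=2.0, quiet_rate=2.0,
                    burst_duration=5.0, quiet_duration=5.0),
}


def generate_mmpp_train(spec: MMPPSpec, rng: np.random.Generator) -> np.ndarray:
    """Spike times of one two-state MMPP cell over [0, duration)."""
    T = spec.duration
    tb, tq = spec.burst_duration, spec.quiet_duration
    in_burst = rng.random() < tb / (tb + tq)   # stationary initial state
    t = 0.0
    times = []
    while t < T:
        dwell = rng.exponential(tb if in_burst else tq)
        end = min(t + dwell, T)
        rate = spec.burst_rate if in_burst else spec.quiet_rate
        if rate > 0:
            n = rng.poisson(rate * (end - t))
            if n:
                times.append(np.sort(rng.uniform(t, end, n)))
        t = end
        in_burst = not in_burst
    if not times:
        return np.empty(0)
    out = np.concatenate(times)
    # coincident draws are measure-zero but would violate strict ordering
    return np.unique(out)


def generate_mmpp_trains(spec: MMPPSpec) -> list[SpikeTrain]:
    """A session dataset of independent MMPP cells; reproducible from seed."""
    rng = np.random.default_rng(spec.seed)
    ages = np.broadcast_to(np.asarray(spec.ages, float), (spec.n_cells,))
    return [
        SpikeTrain(
            spike_times=generate_mmpp_train(spec, rng),
            duration=spec.duration,
            cell_id=i, group=spec.group, age=float(ages[i]),
            source=f"mmpp-{spec.group or 'anon'}-s{spec.seed}",
        )
        for i in range(spec.n_cells)
    ]


@dataclass
class AgeDataset:
    """Segments falling in one age interval [alpha*i, alpha*(i+1)) weeks."""

    interval_index: int
    age_lo: float
    age_hi: float
    segments: list[SpikeTrainSegment]
    mean_age: float
    usable: bool


def build_age_datasets(
    segments: list[SpikeTrainSegment],
    interval_weeks: float,
    mode: str = "nonoverlapping",
) -> list[AgeDataset]:
    """Group segments into age-interval datasets.

    A segment of age x joins the interval i with alpha*i <= x < alpha*(i+1).
    Datasets too small to fit (< 10 segments in non-overlapping mode, < 100
    in overlapping-sampling mode) are kept but flagged unusable.
    """
    if mode not in ("nonoverlapping", "overlapping"):
        raise ValueError(f"unknown mode {mode!r}")
    min_n = 10 if mode == "nonoverlapping" else 100
    ages = np.array([s.age for s in segments], dtype=float)
    if np.isnan(ages).any():
        raise ValueError("every segment needs an age for age-interval grouping")
    idx = np.floor(ages / interval_weeks).astype(int)
    out = []
    for i in np.unique(idx):
        sel = [s for s, j in zip(segments, idx) if j == i]
        out.append(AgeDataset(
            interval_index=int(i),
            age_lo=i * interval_weeks,
            age_hi=(i + 1) * interval_weeks,
            segments=sel,
            mean_age=float(np.mean([s.age for s in sel])),
            usable=len(sel) >= min_n,
        ))
    return out
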