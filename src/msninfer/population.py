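"""Multi-unit diagnostics of simulated networks.

Binned-rate correlation structure (dimensionality via the explained-variance
entropy of the correlation matrix eigenvalues), K-means raster ordering,
active-cell accounting, and the mean-field rate rescaling r * g_I / g_E.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "rate_matrix",
    "DimensionalitySummary",
    "rate_correlation_entropy",
    "raster_order",
    "active_cell_counts",
    "dmft_rescaled_rate",
    "segmentwise_network_stats",
]

RATE_BIN_S = 0.1
MIN_SPIKES_RATE = 10    # cells with fewer spikes are excluded from rate analyses


def rate_matrix(
    spikes: list[np.ndarray], duration: float, bin_s: float = RATE_BIN_S,
    min_spikes: int = MIN_SPIKES_RATE,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike counts per non-overlapping bin for qualifying cells.

    Returns (counts matrix of shape (n_qualifying, n_bins), qualifying cell
    indices).
    """
    nbins = int(duration / bin_s)
    keep = np.array([i for i, t in enumerate(spikes) if len(t) >= min_spikes], int)
    mat = np.zeros((keep.size, nbins), dtype=np.int64)
    for row, i in enumerate(keep):
        idx = np.minimum((np.asarray(spikes[i]) / bin_s).astype(int), nbins - 1)
        mat[row] = np.bincount(idx, minlength=nbins)
    return mat, keep


@dataclass
class DimensionalitySummary:
    """Eigen-decomposition of the rate correlation matrix.

    ``entropy`` is -sum p_i ln p_i over the explained-variance shares
    p_i = lambda_i / sum lambda_j; it is 0 for rank-one (fully coherent)
    rate fluctuations and ln(n_cells) for uncorrelated white rates.
    """

    eigenvalues: np.ndarray
    shares: np.ndarray
    entropy: float
    n_cells: int
    dropped: list[int]


def rate_correlation_entropy(
    spikes: list[np.ndarray], duration: float, bin_s: float = RATE_BIN_S
) -> DimensionalitySummary:
    """Eigenvalues / explained-variance entropy of the binned-rate correlations.

    Zero-variance cells cannot be correlated and are dropped (logged in
    ``dropped``).  Eigenvalues of a correlation matrix sum to the number of
    retained cells.
    """
    mat, keep = rate_matrix(spikes, duration, bin_s)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 qualifying cells")
    var = mat.var(axis=1)
    ok = var > 0
    dropped = [int(i) for i in keep[~ok]]
    mat = mat[ok]
    corr = np.corrcoef(mat)
    lam = np.linalg.eigvalsh(corr)[::-1]
    lam = np.clip(lam, 0.0, None)
    p = lam / lam.sum()
    nz = p > 0
    entropy = float(-(p[nz] * np.log(p[nz])).sum())
    return DimensionalitySummary(
        eigenvalues=lam, shares=p, entropy=entropy,
        n_cells=int(mat.shape[0]), dropped=dropped,
    )


def raster_order(
    corr: np.ndarray, k: int = 30, seed: int | None = 0
) -> np.ndarray:
    """Cell permutation grouping correlated cells for raster display.

    K-means (k-means++ init, seeded) clusters the rows of the correlation
    matrix; cells are ordered by cluster, and within a cluster by their
    correlation with the cluster's mean row.  If fewer cells than clusters
    are available, k is reduced.
    """
    corr = np.asarray(corr, float)
    n = corr.shape[0]
    k = min(k, n)
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(corr)
    order = []
    for lab in np.unique(labels):
        members = np.nonzero(labels == lab)[0]
        centroid = corr[members].mean(axis=0)
        strength = corr[members] @ centroid
        order.extend(members[np.argsort(-strength)])
    return np.asarray(order, int)


def active_cell_counts(spikes: list[np.ndarray]) -> tuple[int, int]:
    """(cells with >= 1 spike, cells with >= 11 spikes).

    The first count tracks the frozen/active transition; the second is the
    population entering single-unit statistics.
    """
    n_any = sum(1 for t in spikes if len(t) >= 1)
    n_stats = sum(1 for t in spikes if len(t) >= 11)
    return n_any, n_stats


def dmft_rescaled_rate(mean_rate: float, g_e: float, g_i: float) -> float:
    """Mean-field balanced-rate rescaling r * (g_I / g_E).

    Under excitation-inhibition balance the population rate is proportional
    to g_E / g_I, so this product is approximately constant across the
    active regime.
    """
    if g_e <= 0:
        raise ValueError("g_e must be positive")
    return float(mean_rate) * g_i / g_e


def segmentwise_network_stats(
    spikes: list[np.ndarray], duration: float, segment_len: float = 40.0
) -> pd.DataFrame:
    """Per-segment network-average single-unit statistics with across-segment SEM.

    The run is tiled into non-overlapping segments (200 s / 40 s -> 5); in
    each, every cell with >= 11 spikes contributes its rate, ISI CV and
    lognormal shape, which are averaged across cells.  The last row ("sem")
    is the standard error across segments.
    """
    from .features import isi_moments, ml_lognormal, DegenerateTrainError

    n_seg = int(round(duration / segment_len))
    if abs(n_seg * segment_len - duration) > 1e-9 or n_seg < 1:
        raise ValueError("duration must divide into whole segments")
    rows = []
    for s in range(n_seg):
        lo, hi = s * segment_len, (s + 1) * segment_len
        rates, cvs, slns = [], [], []
        for t in spikes:
            t = np.asarray(t)
            seg = t[(t >= lo) & (t < hi)]
            if seg.size < 11:
                continue
            isis = np.diff(seg)
            try:
                _, cv, _, rate = isi_moments(isis, t_seg=segment_len)
            except DegenerateTrainError:
                cv, rate = 0.0, seg.size / segment_len
            rates.append(rate)
            cvs.append(cv)
            slns.append(ml_lognormal(isis)[1])
        rows.append({
            "segment": s, "n_cells": len(rates),
            "rate": np.mean(rates) if rates else np.nan,
            "cv": np.mean(cvs) if cvs else np.nan,
            "sigma_ln": np.mean(slns) if slns else np.nan,
        })
    df = pd.DataFrame(rows)
    sem = df[["rate", "cv", "sigma_ln"]].sem()
    df.attrs["sem"] = sem.to_dict()
    return df
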