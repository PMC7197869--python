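"""Single-unit inter-spike-interval (ISI) statistics.

Every statistic operates on one ISI sequence, i.e. the ordered positive
intervals between consecutive spikes of one cell within a fixed observation
window (200 s by convention).  Fifteen of these statistics form the canonical
feature vector used for network-parameter inference: the first two serial ISI
autocorrelations, the first three scaled ISI moments plus the firing rate,
four of the five local-CV quintiles, and the maximum-likelihood shape/scale
parameters of the lognormal, gamma and inverse-Gaussian families.

The window censors long intervals (an ISI longer than the time remaining in
the window is never observed), so the empirical survival function is
reweighted by T/(T - I) before Kolmogorov-Smirnov distances to the fitted
families are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special
from sklearn.base import BaseEstimator, TransformerMixin

from .segments import SpikeTrainSegment

__all__ = [
    "FEATURE_NAMES",
    "DegenerateTrainError",
    "isi_moments",
    "serial_autocorrelation",
    "local_cv_quintiles",
    "ml_lognormal",
    "ml_gamma",
    "ml_invgauss",
    "censored_cumulative",
    "ks_distance",
    "ks_distances",
    "feature_vector",
    "ISIFeatureExtractor",
    "CumulativeISI",
]

#: Canonical order of the 15 inference features.  The third local-CV quintile
#: is excluded by construction.
FEATURE_NAMES: tuple[str, ...] = (
    "rho1", "rho2", "mu", "cv", "skew_cv", "rate",
    "lcv1", "lcv2", "lcv4", "lcv5",
    "ln_mu_gamma", "sigma_gamma", "mu_ln", "sigma_ln", "sigma_ig",
)

#: Minimum spike count for a segment to enter any analysis (>= 10 ISIs).
MIN_SPIKES = 11

# Relative ISI spread below which a train is treated as degenerate
# (periodic); higher moments and ML shapes are undefined there.
_DEGENERATE_REL_SIGMA = 1e-9


class DegenerateTrainError(ValueError):
    """Raised when a statistic is undefined for a (near-)periodic train."""


def _as_isis(x) -> np.ndarray:
    isis = np.asarray(x, dtype=float)
    if isis.ndim != 1:
        raise ValueError("ISI sequence must be one-dimensional")
    if isis.size and isis.min() <= 0:
        raise ValueError("ISIs must be strictly positive")
    return isis


def isis_from_times(spike_times: np.ndarray) -> np.ndarray:
    """Ordered inter-spike intervals of a strictly increasing spike-time array."""
    t = np.asarray(spike_times, dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("spike times must be strictly increasing")
    return np.diff(t)


def isi_moments(isis, t_seg: float = 200.0):
    """Mean ISI, CV, rescaled skew S/CV, and firing rate.

    The rate is (spike count)/T = (N + 1)/T for N ISIs; the skew is reported
    rescaled by the CV.  Raises :class:`DegenerateTrainError` for periodic
    trains, whose CV is zero and skew undefined.
    """
    isis = _as_isis(isis)
    if isis.size < 10:
        raise ValueError("need at least 10 ISIs")
    mu = isis.mean()
    var = np.mean(isis**2) - mu**2
    rate = (isis.size + 1) / float(t_seg)
    if var <= (_DEGENERATE_REL_SIGMA * mu) ** 2:
        raise DegenerateTrainError("zero ISI variance: CV = 0, skew undefined")
    sigma = np.sqrt(var)
    skew = (np.mean(isis**3) - 3 * mu * var - mu**3) / sigma**3
    cv = sigma / mu
    return mu, cv, skew / cv, rate


def serial_autocorrelation(isis, lag: int) -> float:
    """Serial ISI autocorrelation rho(n) = (<I_{i+n} I_i> - mu^2) / sigma^2."""
    isis = _as_isis(isis)
    n = int(lag)
    if n < 1 or isis.size <= n + 1:
        raise ValueError("need more than lag+1 ISIs")
    mu = isis.mean()
    var = np.mean(isis**2) - mu**2
    if var <= (_DEGENERATE_REL_SIGMA * mu) ** 2:
        raise DegenerateTrainError("zero ISI variance: autocorrelation undefined")
    return float((np.mean(isis[n:] * isis[:-n]) - mu**2) / var)


def local_cv_quintiles(isis) -> np.ndarray:
    """Quintile masses of the local-CV distribution.

    X_i = |I_{i+1} - I_i| / (I_{i+1} + I_i) lies in [0, 1]; the five bins are
    the half-open intervals [j/5, (j+1)/5) with the last bin closed at 1, so
    the quintiles partition every pair and sum to one.
    """
    isis = _as_isis(isis)
    if isis.size < 2:
        raise ValueError("need at least 2 ISIs")
    x = np.abs(np.diff(isis)) / (isis[1:] + isis[:-1])
    idx = np.minimum((x * 5).astype(int), 4)
    return np.bincount(idx, minlength=5) / x.size


def ml_lognormal(isis) -> tuple[float, float]:
    """Maximum-likelihood lognormal scale mu_LN = <ln I> and shape sigma_LN."""
    isis = _as_isis(isis)
    logs = np.log(isis)
    mu_ln = logs.mean()
    sigma_ln = np.sqrt(np.mean((logs - mu_ln) ** 2))
    return float(mu_ln), float(sigma_ln)


def ml_gamma(isis) -> tuple[float, float]:
    """ML gamma shape sigma_gamma and scale mu_gamma (closed-form approximation).

    Uses z = ln(mu) - <ln I> >= 0 (Jensen), with
    shape = (3 - z + sqrt((3 - z)^2 + 24 z)) / (12 z) and scale = mu / shape.
    """
    isis = _as_isis(isis)
    mu = isis.mean()
    z = np.log(mu) - np.mean(np.log(isis))
    if z <= 0:
        raise DegenerateTrainError("constant ISIs: gamma shape diverges")
    shape = (3.0 - z + np.sqrt((3.0 - z) ** 2 + 24.0 * z)) / (12.0 * z)
    return float(shape), float(mu / shape)


def ml_invgauss(isis) -> float:
    """ML inverse-Gaussian shape sigma_IG = (<1/I> - 1/mu)^-1 (scale is mu)."""
    isis = _as_isis(isis)
    mu = isis.mean()
    d = np.mean(1.0 / isis) - 1.0 / mu
    if d <= 0:
        raise DegenerateTrainError("constant ISIs: inverse-Gaussian shape diverges")
    return float(1.0 / d)


@dataclass
class CumulativeISI:
    """Censorship-corrected cumulative (survival) ISI distribution.

    ``q[n]`` is the corrected probability of an ISI >= n*dtau; q[0] = 1 and q
    is non-increasing.  ``m`` is the largest index with q[m] > 1e-8, the upper
    limit used for KS distances.
    """

    q: np.ndarray
    dtau: float
    t_seg: float
    #: first bin index of each constant-q run (bins containing an observed ISI)
    support: np.ndarray = field(repr=False)

    @property
    def m(self) -> int:
        above = np.nonzero(self.q > 1e-8)[0]
        return int(above[-1]) if above.size else 0


def censored_cumulative(isis, dtau: float = 0.01, t_seg: float = 200.0) -> CumulativeISI:
    """Censorship-corrected cumulative ISI distribution on bins of width dtau.

    Each interval I contributes weight T/(T - I), compensating the window's
    censorship of long intervals; the weighted bin mass is then summed from
    above and normalized so q[0] = 1.
    """
    isis = _as_isis(isis)
    if isis.size == 0:
        raise ValueError("empty ISI sequence")
    if isis.max() >= t_seg:
        raise ValueError("ISI >= segment length is impossible within a segment")
    w = t_seg / (t_seg - isis)
    idx = np.floor(isis / dtau).astype(np.int64)
    nbins = int(idx.max()) + 2
    p = np.bincount(idx, weights=w, minlength=nbins)
    q = p[::-1].cumsum()[::-1]
    q /= q[0]
    return CumulativeISI(q=q, dtau=dtau, t_seg=t_seg, support=np.unique(idx))


_KS_FAMILIES = ("exponential", "gamma", "lognormal", "invgauss")


def _family_cdf(family: str, x: np.ndarray, params: tuple) -> np.ndarray:
    if family == "exponential":
        (mu,) = params
        return 1.0 - np.exp(-x / mu)
    if family == "gamma":
        shape, scale = params
        return special.gammainc(shape, x / scale)
    if family == "lognormal":
        mu_ln, sigma_ln = params
        return 0.5 * (1.0 + special.erf((np.log(x) - mu_ln) / (np.sqrt(2.0) * sigma_ln)))
    if family == "invgauss":
        lam, mu = params
        a = np.sqrt(lam / x)
        # exp(2*lam/mu) * Phi(-a*x/mu - a) computed in log space: the two
        # factors overflow/underflow in opposite directions for small x.
        second = np.exp(2.0 * lam / mu + special.log_ndtr(-a * x / mu - a))
        return special.ndtr(a * x / mu - a) + second
    raise ValueError(f"unknown family {family!r}")


def ks_distance(cum: CumulativeISI, family: str, params: tuple) -> float:
    """KS distance max_n |1 - D(n) - Q(n)| between the corrected survival and a
    fitted family CDF, over n = 1..M with Q(M) > 1e-8.

    Q is piecewise constant between occupied bins while D is monotone
    increasing, so the maximand is monotone on every constant-Q run and the
    maximum is attained at a run endpoint; only those bins are evaluated.
    """
    if family not in _KS_FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    m = cum.m
    if m < 1:
        return 1.0
    starts = cum.support + 1          # first bin after each jump
    cand = np.unique(np.concatenate([[1], starts, starts - 1, [m]]))
    cand = cand[(cand >= 1) & (cand <= m)]
    x = cand * cum.dtau
    d = _family_cdf(family, x, params)
    return float(np.max(np.abs(1.0 - d - cum.q[cand])))


def ks_distances(isis, t_seg: float = 200.0, dtau: float = 1e-4) -> dict[str, float]:
    """KS distances of one train from its four ML-fitted families.

    Returns a dict with keys ``ks_e``, ``ks_gamma``, ``ks_ln``, ``ks_ig``.
    Families whose ML fit is degenerate are reported at distance 1.
    """
    isis = _as_isis(isis)
    cum = censored_cumulative(isis, dtau=dtau, t_seg=t_seg)
    mu = isis.mean()
    out = {"ks_e": ks_distance(cum, "exponential", (mu,))}
    try:
        shape, scale = ml_gamma(isis)
        out["ks_gamma"] = ks_distance(cum, "gamma", (shape, scale))
    except DegenerateTrainError:
        out["ks_gamma"] = 1.0
    mu_ln, sigma_ln = ml_lognormal(isis)
    if sigma_ln > 0:
        out["ks_ln"] = ks_distance(cum, "lognormal", (mu_ln, sigma_ln))
    else:
        out["ks_ln"] = 1.0
    try:
        lam = ml_invgauss(isis)
        out["ks_ig"] = ks_distance(cum, "invgauss", (lam, mu))
    except DegenerateTrainError:
        out["ks_ig"] = 1.0
    return out


def feature_vector(segment: SpikeTrainSegment) -> np.ndarray:
    """The 15 inference features of one segment, in canonical order.

    Raises :class:`DegenerateTrainError` (periodic train) or ``ValueError``
    (too few spikes) when the vector is undefined; callers batching many
    segments should catch these and log the rejection.
    """
    isis = isis_from_times(segment.spike_times)
    if isis.size < MIN_SPIKES - 1:
        raise ValueError(f"segment has {isis.size + 1} spikes; need >= {MIN_SPIKES}")
    mu, cv, skew_cv, rate = isi_moments(isis, t_seg=segment.t_seg)
    rho1 = serial_autocorrelation(isis, 1)
    rho2 = serial_autocorrelation(isis, 2)
    lcv = local_cv_quintiles(isis)
    mu_ln, sigma_ln = ml_lognormal(isis)
    shape_g, scale_g = ml_gamma(isis)
    sigma_ig = ml_invgauss(isis)
    return np.array([
        rho1, rho2, mu, cv, skew_cv, rate,
        lcv[0], lcv[1], lcv[3], lcv[4],
        np.log(scale_g), shape_g, mu_ln, sigma_ln, sigma_ig,
    ])


class ISIFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping spike-train segments to the 15-feature table.

    Stateless (``fit`` only validates); ``transform`` accepts a sequence of
    :class:`~msninfer.segments.SpikeTrainSegment` and returns a DataFrame with
    one row per retained segment, the 15 canonical feature columns and the
    segment metadata.  Segments that are degenerate or too sparse are dropped;
    the rejection log of the last transform is kept in ``rejections_``.
    """

    def __init__(self, t_seg: float = 200.0):
        self.t_seg = t_seg

    def fit(self, X: Sequence[SpikeTrainSegment], y=None):
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X: Sequence[SpikeTrainSegment]) -> pd.DataFrame:
        rows, meta, rejections = [], [], []
        for k, seg in enumerate(X):
            try:
                rows.append(feature_vector(seg))
            except (DegenerateTrainError, ValueError) as err:
                rejections.append((k, str(err)))
                continue
            meta.append({"group": seg.group, "age": seg.age, "source": seg.source})
        self.rejections_ = rejections
        df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
        return pd.concat([df, pd.DataFrame(meta, index=df.index)], axis=1)
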