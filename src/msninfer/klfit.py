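"""Network-parameter inference by KL matching of feature distributions.

The estimator compares an observed dataset D (one 15-feature row per spike
train segment) with a library of model datasets M, one per simulated
(g_E, g_I) grid point.  For a random subset R of n features, every
observation is reduced to the binary pattern "above / below the experimental
median" of each feature in R; D and each M then define probability vectors
over the 2^n joint bins (the model is always binned against D's medians), and

    K_{M,D,R} = sum_bins P_D ln(P_D / (P_M + eps))

measures the model-data mismatch.  A soft minimum over the grid,
alpha_m = K_m^-beta / sum K^-beta, turns each subset into a weighted point
estimate of (g_E, g_I) with a weighted spread; repeating over many random
subsets and weighting subsets by inverse spread gives the final estimate and
its standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .features import FEATURE_NAMES

__all__ = [
    "ModelLibrary",
    "ParamEstimate",
    "RegressionFit",
    "median_split_joint",
    "kl_distance",
    "subset_estimate",
    "KLParameterEstimator",
    "fit_dataset",
    "recovery_experiment",
    "recovery_slopes",
    "eiv_regression",
]

EPS = 1e-7          # added to model bin probabilities (empty-bin guard)
K_FLOOR = 1e-6      # K values are clipped here before the K^-beta weighting
MIN_FIT_SEGMENTS = 10   # a dataset of fewer non-overlapping segments is unusable


def _feature_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X[list(FEATURE_NAMES)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected (n, {len(FEATURE_NAMES)}) feature matrix")
    return X


@dataclass
class ModelLibrary:
    """Feature sets of a grid of model simulations.

    ``params`` has one (g_E, g_I) row per entry of ``features``; each entry is
    the (n_cells_active, 15) feature matrix of that simulation.
    """

    params: np.ndarray
    features: list[np.ndarray]

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        if self.params.shape != (len(self.features), 2):
            raise ValueError("params must be (n_models, 2) matching features")
        self.features = [_feature_matrix(f) for f in self.features]

    @classmethod
    def from_dict(cls, d: dict[tuple[float, float], np.ndarray]) -> "ModelLibrary":
        keys = sorted(d)
        return cls(np.array(keys, float), [d[k] for k in keys])

    @property
    def g_e_levels(self) -> np.ndarray:
        return np.unique(self.params[:, 0])

    @property
    def g_i_levels(self) -> np.ndarray:
        return np.unique(self.params[:, 1])


def median_split_joint(
    X, reference_medians: np.ndarray, subset: np.ndarray
) -> np.ndarray:
    """Joint probabilities over the 2^|R| binary above-median bins.

    Bin index is the bit pattern of the indicators F_j > median_j over the
    features in ``subset`` (bit k for the k-th subset feature); ties count as
    "below".  The reference medians always come from the experimental-side
    dataset.
    """
    F = _feature_matrix(X)
    if F.shape[0] == 0:
        raise ValueError("empty dataset")
    subset = np.asarray(subset, dtype=int)
    above = F[:, subset] > np.asarray(reference_medians, float)[subset]
    idx = above @ (1 << np.arange(subset.size))
    return np.bincount(idx, minlength=1 << subset.size) / F.shape[0]


def kl_distance(p_d: np.ndarray, p_m: np.ndarray, eps: float = EPS) -> float:
    """K = sum P_D ln(P_D / (P_M + eps)), with 0 ln(0/x) := 0."""
    p_d = np.asarray(p_d, float)
    p_m = np.asarray(p_m, float)
    if p_d.shape != p_m.shape:
        raise ValueError("distributions must share the same bins")
    nz = p_d > 0
    return float(np.sum(p_d[nz] * np.log(p_d[nz] / (p_m[nz] + eps))))


def subset_estimate(
    k_values: np.ndarray,
    param_values: np.ndarray,
    beta: float = 3.0,
    k_floor: float = K_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Soft-minimum weighted estimate over the model grid for one subset.

    alpha_m = K_m^-beta / sum_m K_m^-beta (K clipped at ``k_floor``; the
    eps-regularized KL can be marginally negative for a near-perfect match).
    Returns (estimates, spreads) for each column of ``param_values``; the
    weights are shared across columns.
    """
    k = np.maximum(np.asarray(k_values, float), k_floor)
    x = np.atleast_2d(np.asarray(param_values, float).T).T  # (n_models, n_params)
    if k.shape[0] != x.shape[0]:
        raise ValueError("one K per model required")
    logw = -beta * np.log(k)
    w = np.exp(logw - logw.max())
    alpha = w / w.sum()
    est = alpha @ x
    spread = np.sqrt(np.maximum(((x - est) ** 2 * alpha[:, None]).sum(axis=0), 0.0))
    return est, spread


@dataclass
class ParamEstimate:
    """Weighted best-fit parameters with weighted standard errors."""

    g_e: float
    g_i: float
    g_e_se: float
    g_i_se: float
    #: per-subset point estimates x_{D,R}, shape (n_subsets, 2)
    subset_estimates: np.ndarray = field(repr=False)
    #: per-subset spreads sigma(x_{D,R}), shape (n_subsets, 2)
    subset_spreads: np.ndarray = field(repr=False)
    #: subset weights phi_{D,R} per parameter, shape (n_subsets, 2)
    subset_weights: np.ndarray = field(repr=False)


class KLParameterEstimator(BaseEstimator):
    """Estimate (g_E, g_I) for a feature dataset against a model library.

    Parameters
    ----------
    library : ModelLibrary
        Feature sets of the simulated (g_E, g_I) grid.
    n_feat : int
        Number of features per random subset (joint bins are 2^n_feat).
    n_subsets : int
        Number of independently drawn subsets.
    beta : float
        Soft-minimum exponent of the K^-beta model weighting.
    eps, k_floor : float
        Empty-bin regularizer and positivity floor for K.
    min_segments : int
        Refuse datasets smaller than this.
    random_state : int or None
        Seed of the subset draws.

    Attributes (after ``fit``)
    --------------------------
    g_e_, g_i_ : float         weighted best-fit excitation / inhibition
    g_e_se_, g_i_se_ : float   weighted standard errors
    log_kl_grid_ : ndarray     mean over subsets of ln K per grid model
    kl_subsets_ : ndarray      (n_subsets, n_models) raw K values
    subsets_ : ndarray         (n_subsets, n_feat) drawn feature indices
    medians_ : ndarray         the 15 experimental reference medians
    estimate_ : ParamEstimate  full record including per-subset intermediates
    """

    def __init__(
        self,
        library: ModelLibrary,
        n_feat: int = 7,
        n_subsets: int = 30,
        beta: float = 3.0,
        eps: float = EPS,
        k_floor: float = K_FLOOR,
        min_segments: int = MIN_FIT_SEGMENTS,
        random_state: int | None = None,
    ):
        self.library = library
        self.n_feat = n_feat
        self.n_subsets = n_subsets
        self.beta = beta
        self.eps = eps
        self.k_floor = k_floor
        self.min_segments = min_segments
        self.random_state = random_state

    def fit(self, X, y=None):
        F = _feature_matrix(X)
        if F.shape[0] < self.min_segments:
            raise ValueError(
                f"dataset has {F.shape[0]} segments; "
                f"need >= {self.min_segments} for fitting"
            )
        lib = self.library
        rng = np.random.default_rng(self.random_state)
        self.medians_ = np.median(F, axis=0)
        self.subsets_ = np.stack(
            [rng.choice(len(FEATURE_NAMES), self.n_feat, replace=False)
             for _ in range(self.n_subsets)]
        )
        n_models = len(lib.features)
        K = np.empty((self.n_subsets, n_models))
        for r, subset in enumerate(self.subsets_):
            p_d = median_split_joint(F, self.medians_, subset)
            for m, Fm in enumerate(lib.features):
                p_m = median_split_joint(Fm, self.medians_, subset)
                K[r, m] = kl_distance(p_d, p_m, self.eps)
        self.kl_subsets_ = K
        self.log_kl_grid_ = np.log(np.maximum(K, self.k_floor)).mean(axis=0)

        est = np.empty((self.n_subsets, 2))
        spread = np.empty((self.n_subsets, 2))
        for r in range(self.n_subsets):
            est[r], spread[r] = subset_estimate(
                K[r], lib.params, beta=self.beta, k_floor=self.k_floor
            )
        inv = 1.0 / np.maximum(spread, 1e-12)
        phi = inv / inv.sum(axis=0)              # per-parameter subset weights
        x_d = (est * phi).sum(axis=0)
        se = np.sqrt(((x_d - est) ** 2 * phi).sum(axis=0))
        self.estimate_ = ParamEstimate(
            g_e=x_d[0], g_i=x_d[1], g_e_se=se[0], g_i_se=se[1],
            subset_estimates=est, subset_spreads=spread, subset_weights=phi,
        )
        self.g_e_, self.g_i_ = float(x_d[0]), float(x_d[1])
        self.g_e_se_, self.g_i_se_ = float(se[0]), float(se[1])
        return self

    def kl_grid_frame(self) -> pd.DataFrame:
        """Heat-map table: one row per grid model with its mean ln K."""
        return pd.DataFrame({
            "g_e": self.library.params[:, 0],
            "g_i": self.library.params[:, 1],
            "log_kl": self.log_kl_grid_,
        })


def fit_dataset(
    X,
    library: ModelLibrary,
    n_feat: int = 7,
    n_subsets: int = 30,
    beta: float = 3.0,
    seed: int | None = None,
) -> tuple[ParamEstimate, pd.DataFrame]:
    """Functional wrapper: returns (ParamEstimate, log-KL grid table)."""
    est = KLParameterEstimator(
        library, n_feat=n_feat, n_subsets=n_subsets, beta=beta, random_state=seed
    ).fit(X)
    return est.estimate_, est.kl_grid_frame()


def recovery_experiment(
    half_datasets: dict[tuple[float, float], tuple[np.ndarray, np.ndarray]],
    n_feat: int = 7,
    n_subsets: int = 30,
    beta: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Self-recovery validation on model-generated data.

    ``half_datasets`` maps each true (g_E, g_I) to a pair of feature matrices
    built from the two non-overlapping halves of the same simulation.  The
    first halves play the role of experimental datasets; the second halves
    form the model library.  Returns one row per grid point with the true and
    estimated parameters, their errors, and the bias.
    """
    keys = sorted(half_datasets)
    library = ModelLibrary(
        np.array(keys, float), [half_datasets[k][1] for k in keys]
    )
    rows = []
    for i, key in enumerate(keys):
        est, _ = fit_dataset(
            half_datasets[key][0], library,
            n_feat=n_feat, n_subsets=n_subsets, beta=beta, seed=seed + i,
        )
        rows.append({
            "g_e": key[0], "g_i": key[1],
            "g_e_est": est.g_e, "g_i_est": est.g_i,
            "g_e_se": est.g_e_se, "g_i_se": est.g_i_se,
            "g_e_bias": est.g_e - key[0], "g_i_bias": est.g_i - key[1],
        })
    return pd.DataFrame(rows)


def recovery_slopes(table: pd.DataFrame) -> pd.DataFrame:
    """Per-g_E regression of estimated g_E on estimated g_I (errors in both).

    In an unbiased recovery the two estimates are independent and every slope
    is statistically indistinguishable from zero.
    """
    rows = []
    for g_e, grp in table.groupby("g_e"):
        fit = eiv_regression(
            grp["g_i_est"].to_numpy(), grp["g_e_est"].to_numpy(),
            grp["g_i_se"].to_numpy(), grp["g_e_se"].to_numpy(),
        )
        rows.append({"g_e": g_e, "slope": fit.slope,
                     "slope_se": fit.slope_se, "p_value": fit.p_value})
    return pd.DataFrame(rows)


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    slope_se: float
    p_value: float
    n: int


def eiv_regression(x, y, sx=None, sy=None, max_iter: int = 200, tol: float = 1e-12):
    """Straight-line fit with errors in both coordinates (effective variance).

    Minimizes chi^2 = sum (y - a - b x)^2 / (sy^2 + b^2 sx^2), iterating the
    weights to convergence; with sx -> 0 this reduces to weighted ordinary
    least squares.  The slope standard error comes from the curvature of
    chi^2 at the optimum and the p-value from a two-tailed t-test on
    slope/SE with n - 2 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("all x identical: slope is singular")
    sx = np.zeros(n) if sx is None else np.asarray(sx, float)
    sy = np.zeros(n) if sy is None else np.asarray(sy, float)

    b = np.polyfit(x, y, 1)[0]
    for _ in range(max_iter):
        w = 1.0 / np.maximum(sy**2 + b**2 * sx**2, 1e-30)
        W = w.sum()
        xb, yb = (w * x).sum() / W, (w * y).sum() / W
        b_new = (w * (x - xb) * (y - yb)).sum() / (w * (x - xb) ** 2).sum()
        if abs(b_new - b) <= tol * max(1.0, abs(b)):
            b = b_new
            break
        b = b_new
    w = 1.0 / np.maximum(sy**2 + b**2 * sx**2, 1e-30)
    W = w.sum()
    xb, yb = (w * x).sum() / W, (w * y).sum() / W
    a = yb - b * xb
    slope_se = float(np.sqrt(1.0 / (w * (x - xb) ** 2).sum()))
    t = b / slope_se
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return RegressionFit(slope=float(b), intercept=float(a),
                         slope_se=slope_se, p_value=p, n=n)
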