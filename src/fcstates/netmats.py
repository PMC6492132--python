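"""Network-matrix (netmat) estimation: per-scan dependency features.

Four measures over node-by-time series:

* ``amplitude``   — per-node variance (unbiased, T-1 denominator);
* ``covariance``  — sample covariance;
* ``correlation`` — Pearson correlation, optionally Fisher z-transformed;
* ``partial_correlation`` — ridge (Tikhonov) regularized partial correlation.

The ridge partial correlation scales the sample covariance to unit mean
diagonal before adding lambda*I, so one lambda grid is comparable across node
sets and overall signal scales:

    S~ = S / mean(diag S),   P = (S~ + lambda I)^-1,
    rho_ij = -P_ij / sqrt(P_ii P_jj)   (i != j), diagonal 0.

Partial correlation estimates the dependence between two nodes after removing
the linear influence of all other nodes — the direct, rather than the
marginal, connectivity.  At lambda = 0 on a well-conditioned sample it equals
the classic residual-regression partial correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .spectral import FilterSpec

_R_CLIP = 1.0 - 1e-7

MEASURES = ("amplitude", "covariance", "correlation", "partial_correlation")


@dataclass
class NetMat:
    """One dependency estimate for one scan, with provenance labels."""

    measure: str
    values: np.ndarray  # node x node symmetric, or node vector for amplitude
    lam: float | None = None
    fisher_z_applied: bool = False
    subject: int | None = None
    state: int | None = None
    filter_spec: FilterSpec | None = None

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def node_amplitude(ts: np.ndarray) -> np.ndarray:
    """Per-node variance (T-1 denominator) of the demeaned series."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[-1] < 2:
        raise ValueError("need at least 2 timepoints for a variance")
    return ts.var(axis=-1, ddof=1)


def covariance_matrix(ts: np.ndarray) -> np.ndarray:
    """Sample covariance (T-1 denominator); diagonal equals node_amplitude."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[-1] < 2:
        raise ValueError("need at least 2 timepoints for a covariance")
    return np.cov(ts, ddof=1)


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def correlation_matrix(ts: np.ndarray, apply_fisher_z: bool = True) -> NetMat:
    """Pearson correlation; off-diagonals optionally Fisher z = atanh(r).

    |r| is clipped at 1 - 1e-7 before atanh so features stay finite; the
    diagonal is set to 0 (self-correlations carry no information).
    """
    ts = np.asarray(ts, dtype=float)
    var = node_amplitude(ts)
    zero = np.flatnonzero(var == 0)
    if zero.size:
        raise ValueError(f"zero-variance node(s): {zero.tolist()}")
    r = np.corrcoef(ts)
    if apply_fisher_z:
        r = _fisher_z(r)
    np.fill_diagonal(r, 0.0)
    return NetMat("correlation", r, fisher_z_applied=apply_fisher_z)


def ridge_partial_correlation(
    ts: np.ndarray,
    lam: float,
    apply_fisher_z: bool = True,
) -> NetMat:
    """L2/Tikhonov-regularized partial correlation.

    lambda is scale-free: the covariance is normalized to unit mean diagonal
    before lambda*I is added.  lambda = 0 requires an invertible covariance
    (T > n_nodes); large lambda shrinks all partial correlations toward 0.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    s = covariance_matrix(ts)
    return _partial_corr_from_cov(s, lam, apply_fisher_z)


def partial_correlation_from_covariance(
    cov: np.ndarray, lam: float = 0.0, apply_fisher_z: bool = False
) -> NetMat:
    """Partial correlation from a given (population or sample) covariance."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return _partial_corr_from_cov(np.asarray(cov, dtype=float), lam, apply_fisher_z)


def _partial_corr_from_cov(s: np.ndarray, lam: float, apply_fisher_z: bool) -> NetMat:
    s_scaled = s / np.mean(np.diag(s))
    a = s_scaled + lam * np.eye(s.shape[0])
    try:
        p = np.linalg.inv(a)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "covariance is singular at lambda = 0; use lambda > 0"
        ) from err
    if lam == 0.0 and np.linalg.cond(a) > 1e12:
        raise np.linalg.LinAlgError(
            "covariance is numerically singular at lambda = 0; use lambda > 0"
        )
    d = np.sqrt(np.diag(p))
    rho = -p / np.outer(d, d)
    rho = np.clip(rho, -1.0, 1.0)
    if apply_fisher_z:
        rho = _fisher_z(rho)
    np.fill_diagonal(rho, 0.0)
    rho = (rho + rho.T) / 2.0  # symmetrize away rounding noise
    return NetMat("partial_correlation", rho, lam=lam, fisher_z_applied=apply_fisher_z)


def lambda_grid(max_value: float = 5.0, step: float = 0.1, extend_to: float | None = None) -> np.ndarray:
    """Regularization grid {0, step, ..., max_value}, optionally extended.

    Defaults give 51 values from 0 to 5.  ``extend_to`` continues the grid at
    the same step beyond ``max_value``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    stop = extend_to if extend_to is not None else max_value
    n = int(round(stop / step))
    grid = np.round(np.arange(n + 1) * step, 10)
    return grid[grid <= stop + 1e-12]


def compute_netmat(
    ts: np.ndarray,
    measure: str,
    lam: float = 0.1,
    apply_fisher_z: bool = True,
) -> NetMat:
    """Compute a single netmat of the requested measure."""
    if measure == "amplitude":
        return NetMat("amplitude", node_amplitude(ts))
    if measure == "covariance":
        return NetMat("covariance", covariance_matrix(ts))
    if measure == "correlation":
        return correlation_matrix(ts, apply_fisher_z)
    if measure == "partial_correlation":
        return ridge_partial_correlation(ts, lam, apply_fisher_z)
    raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")


def vectorize_features(netmat: NetMat) -> np.ndarray:
    """Strict upper triangle in row-major pair order; amplitude passes through.

    A symmetric n x n matrix yields n(n-1)/2 features ordered
    (0,1), (0,2), ..., (0,n-1), (1,2), ...; the ordering is identical for
    every sample, so features are comparable across scans.
    """
    v = netmat.values
    if v.ndim == 1:
        return v.copy()
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]


def pair_labels(n_nodes: int) -> list[str]:
    """Feature names matching :func:`vectorize_features` ordering."""
    iu = np.triu_indices(n_nodes, k=1)
    return [f"edge_{i}_{j}" for i, j in zip(*iu)]


class ConnectivityFeatures(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: time-series samples -> feature matrix.

    ``transform`` accepts a (n_samples, n_nodes, n_time) array or a list of
    node-by-time matrices and returns (n_samples, n_features) with the
    vectorization contract of :func:`vectorize_features`.  Stateless.
    """

    def __init__(
        self,
        measure: str = "correlation",
        lam: float = 0.1,
        fisher_z: bool = True,
    ):
        self.measure = measure
        self.lam = lam
        self.fisher_z = fisher_z

    def fit(self, X, y=None):
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        return self

    def transform(self, X) -> np.ndarray:
        self.fit(X)
        rows = [
            vectorize_features(compute_netmat(np.asarray(ts, float), self.measure,
                                              self.lam, self.fisher_z))
            for ts in X
        ]
        return np.asarray(rows)
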