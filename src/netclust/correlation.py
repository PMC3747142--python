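"""Per-edge partial correlations under permutations of the behavioral measure.

For every edge k and permutation vector i we need the partial (Spearman or
Pearson) correlation r_k^(i) between the edge weight across subjects and the
behavioral measure reordered by permutation i, controlling for covariates.
Only the measure is reordered; covariates and weights keep the original
subject order, so their (rank-)residualization can be computed once and the
whole N x m field reduces to one matrix product.

Conventions:

* Spearman partial correlation = Pearson correlation of average-tie ranks
  after residualizing both rank vectors on the covariate ranks plus an
  intercept.
* The last permutation (index N-1 here, PV_N in 1-based terms) is always the
  identity, i.e. the observed ordering, so observed quantities are the last
  column of every per-permutation array and the permutation p-value floor is
  1/N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

Side = Literal["negative", "positive", "two-sided"]
Method = Literal["spearman", "pearson"]

#: residual-norm floor (relative to n) below which an edge is "constant":
#: zero variance after residualization, correlation undefined.
_CONSTANT_TOL = 1e-12


def rank_transform(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Average-tie ranks 1..n (ties get the mean of their positions)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("rank_transform needs a 1-d vector of length >= 2")
    return stats.rankdata(values)


@dataclass(frozen=True)
class PermutationSet:
    """N orderings of subject indices; the last is the identity (observed)."""

    orders: np.ndarray  # (N, n) int array; each row a permutation of 0..n-1
    seed: int | None = None

    @property
    def N(self) -> int:
        return self.orders.shape[0]

    @property
    def n(self) -> int:
        return self.orders.shape[1]


def make_permutations(n: int, N: int, seed: int | None = None) -> PermutationSet:
    """Draw N-1 uniformly random orderings plus the identity, identity last.

    Duplicates are permitted (sampling with replacement from S_n), as in any
    plain permutation test; results are deterministic for a fixed seed.
    """
    if n < 2:
        raise ValueError(f"need at least 2 subjects, got {n}")
    if N < 1:
        raise ValueError(f"need at least 1 permutation, got {N}")
    rng = np.random.default_rng(seed)
    orders = np.empty((N, n), dtype=np.int64)
    for i in range(N - 1):
        orders[i] = rng.permutation(n)
    orders[N - 1] = np.arange(n)
    return PermutationSet(orders=orders, seed=seed)


def _residual_basis(covariates: np.ndarray, n: int) -> np.ndarray:
    """Orthonormal basis of the span of [intercept, covariates]."""
    design = np.column_stack([np.ones(n), covariates])
    q, r = np.linalg.qr(design)
    # drop numerically null directions (e.g. a constant covariate)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def _residualize(x: np.ndarray, q: np.ndarray) -> np.ndarray:
    return x - q @ (q.T @ x)


def partial_correlation(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    covariates: Sequence[Sequence[float]] | np.ndarray = (),
    method: Method = "spearman",
) -> float:
    """Partial correlation of x and y given covariates.

    Spearman: rank-transform x, y and each covariate, then compute the partial
    Pearson correlation of the ranks (residualize both on the covariate ranks
    plus intercept, correlate the residuals).  With no covariates this is the
    plain (rank) correlation.  Returns 0.0 when either residual has zero
    variance (the "constant" case).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariates, dtype=float)
    if cov.size == 0:
        cov = np.empty((x.size, 0))
    elif cov.ndim == 1:
        cov = cov[:, None]
    elif cov.shape[0] != x.size and cov.shape[1] == x.size:
        cov = cov.T  # accept covariates given as rows
    if y.size != x.size or cov.shape[0] != x.size:
        raise ValueError("x, y and covariates must share one length")
    n_cov = cov.shape[1]
    if x.size < n_cov + 3:
        raise ValueError(
            f"need at least {n_cov + 3} observations for {n_cov} covariate(s)"
        )
    if method == "spearman":
        x = rank_transform(x)
        y = rank_transform(y)
        cov = np.column_stack([rank_transform(c) for c in cov.T]) if n_cov else cov
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    q = _residual_basis(cov, x.size)
    rx = _residualize(x, q)
    ry = _residualize(y, q)
    nx = np.linalg.norm(rx)
    ny = np.linalg.norm(ry)
    if nx <= _CONSTANT_TOL * x.size or ny <= _CONSTANT_TOL * x.size:
        return 0.0
    return float(np.clip(rx @ ry / (nx * ny), -1.0, 1.0))


@dataclass
class CorrelationFields:
    """Per-edge correlation coefficients for all N orderings.

    ``r`` has shape (m, N); column i is the edge-correlation field of
    permutation vector i and the last column is the observed field.
    ``constant_edges`` marks edges with zero weight variance after
    residualization; their r is recorded as 0 and they are excluded from
    testing (p = 1).
    """

    r: np.ndarray
    method: Method
    covariate_names: list[str] = field(default_factory=list)
    constant_edges: np.ndarray | None = None  # bool mask, length m

    def __post_init__(self) -> None:
        if self.constant_edges is None:
            self.constant_edges = np.zeros(self.r.shape[0], dtype=bool)

    @property
    def m(self) -> int:
        return self.r.shape[0]

    @property
    def N(self) -> int:
        return self.r.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """The edge-correlation field of the original (identity) ordering."""
        return self.r[:, -1]

    def field(self, i: int) -> np.ndarray:
        """Field of permutation vector i (0-based; i = N-1 is observed)."""
        return self.r[:, i]

    @property
    def m_effective(self) -> int:
        """Number of testable (non-constant) edges."""
        return int((~self.constant_edges).sum())


def correlation_fields(
    weights: np.ndarray,
    measure: np.ndarray,
    perms: PermutationSet,
    covariates: np.ndarray | None = None,
    method: Method = "spearman",
    covariate_names: Sequence[str] = (),
) -> CorrelationFields:
    """Compute r_k^(i) for every edge k and permutation vector i.

    ``weights`` is the (n_subjects, m) edge-weight table; ``measure`` the
    behavioral score in original subject order.  Field i uses the measure
    reordered by permutation i while covariates and weights keep their
    original order.  Permuting the raw measure and re-ranking equals permuting
    its ranks, so ranks are computed once.
    """
    weights = np.asarray(weights, dtype=float)
    measure = np.asarray(measure, dtype=float)
    n, m = weights.shape
    if measure.size != n or perms.n != n:
        raise ValueError("weights, measure and permutations must agree on n")
    cov = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if method == "spearman":
        x = stats.rankdata(weights, axis=0)
        y = stats.rankdata(measure)
        cov = (np.column_stack([stats.rankdata(c) for c in cov.T])
               if cov.shape[1] else cov)
    else:
        x = weights
        y = measure
    q = _residual_basis(cov, n)
    xr = _residualize(x, q)
    # reorder the (rank-transformed) measure per permutation, then residualize
    yp = y[perms.orders.T]  # (n, N)
    yr = _residualize(yp, q)
    xn = np.linalg.norm(xr, axis=0)
    yn = np.linalg.norm(yr, axis=0)
    constant = xn <= _CONSTANT_TOL * n
    if (yn <= _CONSTANT_TOL * n).any():
        raise ValueError("behavioral measure is constant after residualization")
    xn_safe = np.where(constant, 1.0, xn)
    r = (xr.T @ yr) / xn_safe[:, None] / yn[None, :]
    r[constant, :] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    return CorrelationFields(
        r=r,
        method=method,
        covariate_names=list(covariate_names),
        constant_edges=constant,
    )


@dataclass(frozen=True)
class EdgePValues:
    """Per-edge permutation significance levels."""

    p: np.ndarray
    side: Side
    N: int


def edge_permutation_p(fields: CorrelationFields, side: Side) -> EdgePValues:
    """Per-edge permutation p: proportion of orderings at least as extreme.

    negative:  p_k = #{i : r_k^(i) <= r_k^(obs)} / N
    positive:  p_k = #{i : r_k^(i) >= r_k^(obs)} / N
    two-sided: p_k = #{i : |r_k^(i)| >= |r_k^(obs)|} / N

    Counts include the observed ordering itself, so p_k >= 1/N.  Constant
    edges carry p = 1.
    """
    r = fields.r
    obs = fields.observed[:, None]
    if side == "negative":
        counts = (r <= obs).sum(axis=1)
    elif side == "positive":
        counts = (r >= obs).sum(axis=1)
    elif side == "two-sided":
        counts = (np.abs(r) >= np.abs(obs)).sum(axis=1)
    else:
        raise ValueError(f"unknown side {side!r}")
    p = counts / fields.N
    p[fields.constant_edges] = 1.0
    return EdgePValues(p=p, side=side, N=fields.N)


def r_to_t(r: float | np.ndarray, df: int) -> float | np.ndarray:
    """Map a correlation coefficient to its t statistic.

    t = r * sqrt(df / (1 - r^2)) with df = n - 2 - (#covariates).  The map is
    monotone and super-linear in r on (0, 1), which is why a cluster-forming
    threshold on r needs finer control at larger magnitudes.
    """
    r = np.asarray(r, dtype=float)
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if (np.abs(r) >= 1).any():
        raise ValueError("|r| must be < 1 for the t transform")
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(t) if t.ndim == 0 else t


def t_approximation_p(
    r: np.ndarray, n: int, n_covariates: int = 0, side: Side = "two-sided"
) -> np.ndarray:
    """Analytic p-value for correlation r via the t transform.

    The classical approximation: t = r*sqrt(df/(1-r^2)) ~ t_df under the null,
    df = n - 2 - n_covariates.  Used as the comparison route for the
    permutation p-values, not as the primary significance measure.
    """
    df = n - 2 - n_covariates
    t = r_to_t(np.clip(np.asarray(r, float), -0.999999, 0.999999), df)
    if side == "two-sided":
        return 2.0 * stats.t.sf(np.abs(t), df)
    if side == "negative":
        return stats.t.cdf(t, df)
    if side == "positive":
        return stats.t.sf(t, df)
    raise ValueError(f"unknown side {side!r}")
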