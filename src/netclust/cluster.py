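"""Supra-threshold clustering and the max-cluster-extent permutation null.

Given the per-edge correlation field of each permutation, edges beyond the
signed cluster-forming threshold tau_init are grouped into clusters (connected
sub-networks: edges joined through shared endpoint nodes).  The edge count of
the largest cluster under each reordering, M_i, forms the permutation null;
each observed cluster of size s_j gets the family-wise corrected p-value

    p_j = #{i : M_i >= s_j} / N

with the observed ordering included in the count, so p_j >= 1/N.  The
significance level is valid for any choice of tau_init, though the identified
sub-network depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .correlation import (
    CorrelationFields,
    EdgePValues,
    Method,
    PermutationSet,
    Side,
    correlation_fields,
    edge_permutation_p,
    make_permutations,
)
from .io import BehaviorTable, Cohort, EdgeIndexMap, edge_index_map, vectorize

ClusterSide = Literal["negative", "positive"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis settings; defaults follow the full-scale study design."""

    tau_init: float = -0.39
    side: ClusterSide | None = None  # inferred from sign(tau_init) if None
    n_permutations: int = 10000
    seed: int | None = 0
    method: Method = "spearman"
    covariate_names: tuple[str, ...] = ()
    min_count: float | None = 3.0
    alpha: float = 0.05

    def resolved_side(self) -> ClusterSide:
        if self.side is not None:
            return self.side
        if self.tau_init < 0:
            return "negative"
        if self.tau_init > 0:
            return "positive"
        raise ValueError(
            "tau_init = 0 is degenerate; pass side='negative' or 'positive' "
            "explicitly to force a one-sided analysis at zero"
        )


def supra_threshold_edges(
    r: np.ndarray, tau: float, side: ClusterSide
) -> np.ndarray:
    """Edge indices beyond the signed threshold (strict inequality).

    negative side: {k : r_k < tau};  positive side: {k : r_k > tau}.
    """
    r = np.asarray(r, dtype=float)
    if side == "negative":
        if tau > 0:
            raise ValueError("negative side needs tau <= 0")
        return np.flatnonzero(r < tau)
    if side == "positive":
        if tau < 0:
            raise ValueError("positive side needs tau >= 0")
        return np.flatnonzero(r > tau)
    raise ValueError(f"unknown side {side!r}")


@dataclass
class Cluster:
    """One connected sub-network of supra-threshold edges."""

    edges: np.ndarray  # sorted flat edge indices
    nodes: np.ndarray  # sorted incident node indices

    @property
    def size(self) -> int:
        return len(self.edges)


@dataclass
class ClusterSet:
    """Disjoint supra-threshold clusters for one ordering."""

    clusters: list[Cluster]
    threshold: float
    side: ClusterSide

    @property
    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.clusters], dtype=int)

    @property
    def count(self) -> int:
        return len(self.clusters)


class _UnionFind:
    """Union-find over arbitrary hashable node ids, path-halving."""

    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def find(self, a: int) -> int:
        parent = self.parent
        if a not in parent:
            parent[a] = a
            return a
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _component_labels(pairs: np.ndarray) -> np.ndarray:
    """Component label per edge for an (k, 2) array of node pairs."""
    uf = _UnionFind()
    for i, j in pairs:
        uf.union(int(i), int(j))
    return np.array([uf.find(int(i)) for i in pairs[:, 0]], dtype=np.int64)


def extract_clusters(
    edges: Iterable[int] | np.ndarray,
    emap: EdgeIndexMap,
    threshold: float = 0.0,
    side: ClusterSide = "negative",
) -> ClusterSet:
    """Group supra-threshold edges into connected sub-networks.

    The graph has exactly the given edges, over the nodes they touch; clusters
    are its connected components.  Output order is deterministic: decreasing
    size, ties broken by smallest member edge index.
    """
    edges = np.asarray(list(edges) if not isinstance(edges, np.ndarray) else edges,
                       dtype=np.int64)
    if edges.size == 0:
        return ClusterSet(clusters=[], threshold=threshold, side=side)
    pairs = emap.pairs[edges]
    labels = _component_labels(pairs)
    clusters = []
    for lab in np.unique(labels):
        sel = labels == lab
        member_edges = np.sort(edges[sel])
        nodes = np.unique(pairs[sel])
        clusters.append(Cluster(edges=member_edges, nodes=nodes))
    clusters.sort(key=lambda c: (-c.size, int(c.edges[0])))
    return ClusterSet(clusters=clusters, threshold=threshold, side=side)


def max_cluster_extent(cs: ClusterSet) -> int:
    """Edge count of the largest cluster; 0 when there is none."""
    return int(cs.sizes.max()) if cs.count else 0


def _max_extent_from_pairs(pairs: np.ndarray) -> int:
    """Largest component's edge count for an (k, 2) node-pair array."""
    if pairs.shape[0] == 0:
        return 0
    if pairs.shape[0] == 1:
        return 1
    labels = _component_labels(pairs)
    _, counts = np.unique(labels, return_counts=True)
    return int(counts.max())


@dataclass
class NullDistribution:
    """Maximum cluster extents M_i over all N orderings (observed last)."""

    M: np.ndarray
    threshold: float
    side: ClusterSide

    @property
    def N(self) -> int:
        return len(self.M)


def null_distribution(
    fields: CorrelationFields,
    tau: float,
    side: ClusterSide,
    emap: EdgeIndexMap,
) -> NullDistribution:
    """M_i = max cluster extent of each permutation's supra-threshold graph."""
    r = fields.r
    mask = r < tau if side == "negative" else r > tau
    if side == "negative" and tau > 0:
        raise ValueError("negative side needs tau <= 0")
    if side == "positive" and tau < 0:
        raise ValueError("positive side needs tau >= 0")
    M = np.zeros(fields.N, dtype=np.int64)
    pairs = emap.pairs
    counts = mask.sum(axis=0)
    for i in np.flatnonzero(counts):
        M[i] = _max_extent_from_pairs(pairs[mask[:, i]])
    return NullDistribution(M=M, threshold=tau, side=side)


@dataclass
class ClusterResult:
    """Observed clusters with FWER-corrected p-values and the null they used."""

    observed: ClusterSet
    p: np.ndarray  # corrected p per observed cluster, same order
    null: NullDistribution
    r_observed: np.ndarray | None = None  # per-edge observed correlations
    edge_p: EdgePValues | None = None  # per-edge uncorrected permutation p
    config: AnalysisConfig | None = None
    constant_edge_count: int = 0
    m_effective: int = 0
    # per-permutation extreme representative statistics, for the
    # extreme-statistics comparator (min over edges, max over edges)
    rep_min: np.ndarray | None = None
    rep_max: np.ndarray | None = None
    node_labels: list[str] = field(default_factory=list)
    emap: EdgeIndexMap | None = None

    @property
    def min_p(self) -> float:
        return float(self.p.min()) if self.p.size else 1.0

    def significant_clusters(self, alpha: float | None = None) -> list[int]:
        """Indices of clusters with corrected p <= alpha."""
        if alpha is None:
            alpha = self.config.alpha if self.config else 0.05
        return [j for j in range(len(self.p)) if self.p[j] <= alpha]

    def significant_edges(self, alpha: float | None = None) -> np.ndarray:
        """Union of member edges of all significant clusters."""
        js = self.significant_clusters(alpha)
        if not js:
            return np.array([], dtype=np.int64)
        return np.unique(np.concatenate(
            [self.observed.clusters[j].edges for j in js]
        ))


def cluster_pvalues(
    observed: ClusterSet, null: NullDistribution
) -> ClusterResult:
    """Corrected p_j = #{i : M_i >= s_j} / N for each observed cluster.

    Non-strict and including the observed ordering's own entry, so the test is
    exact and p_j >= 1/N; p is non-increasing in cluster size.
    """
    if null.N == 0:
        raise ValueError("empty null distribution")
    sizes = observed.sizes
    p = np.array([(null.M >= s).sum() / null.N for s in sizes])
    return ClusterResult(observed=observed, p=p, null=null)


def run_cluster_analysis(
    cohort: Cohort,
    behavior: BehaviorTable,
    config: AnalysisConfig,
    perms: PermutationSet | None = None,
    fields: CorrelationFields | None = None,
) -> ClusterResult:
    """End-to-end cluster-based analysis on aligned inputs.

    Composes edge vectorization, per-permutation partial correlations,
    supra-threshold clustering and the max-extent null.  Fully reproducible
    from (inputs, config); a prebuilt PermutationSet or CorrelationFields can
    be injected (used by the threshold sweep to share one permutation draw).
    """
    side = config.resolved_side()
    if cohort.subjects != behavior.subjects:
        raise ValueError("cohort and behavior are not aligned; call align()")
    emap = edge_index_map(cohort.n_nodes)
    if fields is None:
        weights = vectorize(cohort, emap)
        if perms is None:
            perms = make_permutations(
                cohort.n_subjects, config.n_permutations, config.seed
            )
        cov = behavior.covariate_array()
        names = behavior.covariate_names
        if config.covariate_names:
            missing = set(config.covariate_names) - set(names)
            if missing:
                raise ValueError(f"covariates not in behavior table: {missing}")
            idx = [names.index(c) for c in config.covariate_names]
            cov = cov[:, idx]
            names = list(config.covariate_names)
        fields = correlation_fields(
            weights, behavior.measure, perms,
            covariates=cov if cov.shape[1] else None,
            method=config.method, covariate_names=names,
        )
    null = null_distribution(fields, config.tau_init, side, emap)
    supra = supra_threshold_edges(fields.observed, config.tau_init, side)
    observed = extract_clusters(supra, emap, config.tau_init, side)
    result = cluster_pvalues(observed, null)
    result.r_observed = fields.observed.copy()
    result.edge_p = edge_permutation_p(fields, side)
    result.config = config
    result.constant_edge_count = int(fields.constant_edges.sum())
    result.m_effective = fields.m_effective
    testable = ~fields.constant_edges
    result.rep_min = fields.r[testable].min(axis=0) if testable.any() else None
    result.rep_max = fields.r[testable].max(axis=0) if testable.any() else None
    result.node_labels = list(cohort.node_labels)
    result.emap = emap
    return result


def default_tau_grid(
    lo: float = -0.5, hi: float = 0.5, step: float = 0.01
) -> np.ndarray:
    """The systematic threshold grid, excluding the degenerate tau = 0."""
    k = int(round((hi - lo) / step))
    grid = np.round(lo + step * np.arange(k + 1), 10)
    return grid[np.abs(grid) > step / 2]


def threshold_sweep(
    cohort: Cohort,
    behavior: BehaviorTable,
    config: AnalysisConfig,
    tau_grid: Sequence[float] | np.ndarray | None = None,
):
    """Rerun the cluster analysis over a grid of initial thresholds.

    One PermutationSet (hence one correlation field matrix) is shared across
    the whole grid, so rows differ only in the cluster-forming threshold.
    Returns a pandas DataFrame with columns tau, side, n_clusters, max_size,
    min_p, significant; ``df.attrs['stable_ranges']`` lists the contiguous
    tau intervals where min_p <= alpha.
    """
    import pandas as pd

    if tau_grid is None:
        tau_grid = default_tau_grid()
    tau_grid = np.asarray(tau_grid, dtype=float)
    if tau_grid.size == 0:
        raise ValueError("empty threshold grid")
    if (tau_grid == 0).any():
        raise ValueError("tau = 0 is degenerate; exclude it from the grid")
    emap = edge_index_map(cohort.n_nodes)
    weights = vectorize(cohort, emap)
    perms = make_permutations(cohort.n_subjects, config.n_permutations,
                              config.seed)
    cov = behavior.covariate_array()
    fields = correlation_fields(
        weights, behavior.measure, perms,
        covariates=cov if cov.shape[1] else None,
        method=config.method, covariate_names=behavior.covariate_names,
    )
    rows = []
    for tau in tau_grid:
        side: ClusterSide = "negative" if tau < 0 else "positive"
        null = null_distribution(fields, tau, side, emap)
        supra = supra_threshold_edges(fields.observed, tau, side)
        observed = extract_clusters(supra, emap, tau, side)
        res = cluster_pvalues(observed, null)
        rows.append({
            "tau": tau,
            "side": side,
            "n_clusters": observed.count,
            "max_size": max_cluster_extent(observed),
            "min_p": res.min_p if observed.count else np.nan,
            "significant": bool(observed.count and res.min_p <= config.alpha),
        })
    df = pd.DataFrame(rows)
    df.attrs["stable_ranges"] = _contiguous_ranges(
        df["tau"].to_numpy(), df["significant"].to_numpy()
    )
    df.attrs["alpha"] = config.alpha
    return df


def _contiguous_ranges(tau: np.ndarray, flag: np.ndarray) -> list[tuple[float, float]]:
    """Contiguous grid intervals where the significance flag holds."""
    ranges: list[tuple[float, float]] = []
    start = None
    for t, f in zip(tau, flag):
        if f and start is None:
            start = t
        elif not f and start is not None:
            ranges.append((start, prev))
            start = None
        prev = t
    if start is not None:
        ranges.append((start, tau[-1]))
    return ranges


def subsample_stability(
    cohort: Cohort,
    behavior: BehaviorTable,
    config: AnalysisConfig,
    drop_fraction: float = 0.10,
    B: int = 20,
    seed: int | None = None,
):
    """Rerun the analysis on B random subject subsets.

    Each run removes ``floor(drop_fraction * n)`` subjects uniformly at random
    (no demographic matching of subsets).  Reports per-run significance
    (min corrected p <= alpha) and the fraction of the full-data significant
    cluster's edges that the subset run recovers.  Returns a DataFrame with
    ``df.attrs['n_significant']`` and ``df.attrs['full_min_p']``.
    """
    import pandas as pd

    if not (0 <= drop_fraction < 0.5):
        raise ValueError("drop_fraction must be in [0, 0.5)")
    if B < 1:
        raise ValueError("B must be >= 1")
    n = cohort.n_subjects
    n_drop = int(np.floor(drop_fraction * n))
    n_keep = n - n_drop
    if n_keep < len(behavior.covariate_names) + 3:
        raise ValueError("subset too small for covariate-adjusted correlation")
    full = run_cluster_analysis(cohort, behavior, config)
    ref_edges = set(full.significant_edges().tolist())
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for b in range(B):
        keep = np.sort(rng.choice(n, size=n_keep, replace=False))
        sub_cohort = Cohort(
            subjects=[cohort.subjects[i] for i in keep],
            matrices=cohort.matrices[keep],
            node_labels=list(cohort.node_labels),
        )
        covs = None
        if behavior.covariates is not None:
            covs = behavior.covariates.iloc[keep].reset_index(drop=True)
        sub_behavior = BehaviorTable(
            subjects=[behavior.subjects[i] for i in keep],
            measure=behavior.measure[keep],
            measure_name=behavior.measure_name,
            covariates=covs,
        )
        res = run_cluster_analysis(sub_cohort, sub_behavior, config)
        sig_edges = set(res.significant_edges().tolist())
        recovered = (len(ref_edges & sig_edges) / len(ref_edges)
                     if ref_edges else np.nan)
        rows.append({
            "run": b,
            "n_subjects": n_keep,
            "min_p": res.min_p if res.observed.count else np.nan,
            "significant": bool(res.observed.count
                                and res.min_p <= config.alpha),
            "recovered_fraction": recovered,
        })
    df = pd.DataFrame(rows)
    df.attrs["n_significant"] = int(df["significant"].sum())
    df.attrs["full_min_p"] = full.min_p
    return df
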