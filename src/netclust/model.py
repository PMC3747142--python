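"""Model/Results front end for the cluster-based network-behavior analysis.

Usage::

    model = NetworkCorrelation(cohort, behavior, covariates=["age", "gender"])
    res = model.fit(tau_init=-0.39, n_permutations=10000, seed=7)
    print(res.summary())
    res.bonferroni(alpha=0.05)
    sweep = model.threshold_sweep()

``NetworkCorrelation`` holds the aligned, filtered data and the analysis
settings that do not change between fits; :meth:`fit` runs the permutation
engine at one cluster-forming threshold and returns a
:class:`NetworkCorrelationResults` carrying the observed clusters, their
FWER-corrected p-values, the null distribution of maximum cluster extents and
everything the comparator corrections need.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import cluster as _cluster
from .cluster import AnalysisConfig, ClusterResult
from .corrections import (
    CorrectionOutcome,
    bonferroni as _bonferroni,
    extreme_statistics_from_reps,
    fdr_bh as _fdr_bh,
    sign_families,
)
from .correlation import Method
from .io import BehaviorTable, Cohort, align, apply_min_weight_filter


class NetworkCorrelation:
    """Edge-wise partial correlation of a brain network with a behavior.

    Parameters
    ----------
    cohort : Cohort
        Per-subject symmetric connectivity matrices.
    behavior : BehaviorTable
        Behavioral measure of interest plus covariates.  Subjects are aligned
        with the cohort (intersection, cohort order).
    covariates : sequence of str, optional
        Covariate columns to control for; defaults to every covariate in the
        behavior table.
    method : {"spearman", "pearson"}
        Correlation flavor; Spearman (rank) by default since connectivity
        weights are rarely normal.
    min_count : float or None
        Per-subject streamline-count floor applied before analysis
        (entries strictly below are zeroed); None disables the filter.
    """

    def __init__(
        self,
        cohort: Cohort,
        behavior: BehaviorTable,
        covariates: Sequence[str] | None = None,
        method: Method = "spearman",
        min_count: float | None = 3.0,
    ) -> None:
        cohort, behavior = align(cohort, behavior)
        if min_count is not None:
            cohort = apply_min_weight_filter(cohort, min_count)
        if covariates is None:
            covariates = behavior.covariate_names
        self.cohort = cohort
        self.behavior = behavior
        self.covariates = tuple(covariates)
        self.method: Method = method
        self.min_count = min_count

    @classmethod
    def from_files(
        cls,
        matrix_paths: Sequence[str],
        behavior_path: str,
        measure: str,
        covariates: Sequence[str] = (),
        label_path: str | None = None,
        subject_col: str = "subject",
        **kwargs,
    ) -> "NetworkCorrelation":
        """Build the model straight from delimited text files."""
        from .io import read_behavior, read_cohort

        cohort = read_cohort(matrix_paths, label_path=label_path)
        behavior = read_behavior(behavior_path, measure, covariates,
                                 subject_col=subject_col)
        return cls(cohort, behavior, covariates=list(covariates), **kwargs)

    def _config(self, tau_init, side, n_permutations, seed, alpha) -> AnalysisConfig:
        return AnalysisConfig(
            tau_init=tau_init, side=side, n_permutations=n_permutations,
            seed=seed, method=self.method, covariate_names=self.covariates,
            min_count=self.min_count, alpha=alpha,
        )

    def fit(
        self,
        tau_init: float = -0.39,
        side: str | None = None,
        n_permutations: int = 10000,
        seed: int | None = 0,
        alpha: float = 0.05,
    ) -> "NetworkCorrelationResults":
        """Run the cluster-based permutation analysis at one threshold."""
        config = self._config(tau_init, side, n_permutations, seed, alpha)
        result = _cluster.run_cluster_analysis(self.cohort, self.behavior, config)
        return NetworkCorrelationResults(self, result)

    def threshold_sweep(self, tau_grid=None, n_permutations: int = 10000,
                        seed: int | None = 0, alpha: float = 0.05):
        """Cluster analysis over a grid of initial thresholds.

        Default grid: -0.5 .. 0.5 in 0.01 steps, excluding 0.  One permutation
        draw is shared across the grid.
        """
        config = self._config(-0.01, None, n_permutations, seed, alpha)
        return _cluster.threshold_sweep(self.cohort, self.behavior, config,
                                        tau_grid)

    def subsample_stability(self, tau_init: float = -0.39,
                            drop_fraction: float = 0.10, B: int = 20,
                            n_permutations: int = 10000,
                            seed: int | None = 0, alpha: float = 0.05):
        """Stability of the result under random removal of subjects."""
        config = self._config(tau_init, None, n_permutations, seed, alpha)
        return _cluster.subsample_stability(self.cohort, self.behavior, config,
                                            drop_fraction=drop_fraction, B=B)


class NetworkCorrelationResults:
    """Results of one cluster-based permutation fit."""

    def __init__(self, model: NetworkCorrelation, result: ClusterResult) -> None:
        self.model = model
        self._result = result

    # -- pass-through accessors -------------------------------------------
    @property
    def clusters(self):
        return self._result.observed.clusters

    @property
    def cluster_p(self) -> np.ndarray:
        return self._result.p

    @property
    def null_M(self) -> np.ndarray:
        return self._result.null.M

    @property
    def r_observed(self) -> np.ndarray:
        return self._result.r_observed

    @property
    def edge_p(self) -> np.ndarray:
        return self._result.edge_p.p

    @property
    def config(self) -> AnalysisConfig:
        return self._result.config

    @property
    def min_p(self) -> float:
        return self._result.min_p

    def significant_clusters(self, alpha: float | None = None):
        return self._result.significant_clusters(alpha)

    def significant_edges(self, alpha: float | None = None) -> np.ndarray:
        return self._result.significant_edges(alpha)

    # -- comparator corrections -------------------------------------------
    def _family(self, side: str | None) -> tuple[str, np.ndarray]:
        side = side or self.config.resolved_side()
        fams = sign_families(self.r_observed,
                             constant=None)
        return side, fams[side]

    def bonferroni(self, alpha: float = 0.05,
                   side: str | None = None) -> CorrectionOutcome:
        """Bonferroni within the sign family of the analysis side."""
        side, fam = self._family(side)
        out = _bonferroni(self.edge_p[fam], alpha, m_effective=len(fam))
        return CorrectionOutcome(
            method=out.method, level=out.level, m_effective=out.m_effective,
            significant=fam[out.significant], threshold=out.threshold,
        )

    def fdr(self, q: float = 0.05, side: str | None = None) -> CorrectionOutcome:
        """Benjamini–Hochberg FDR within the sign family."""
        side, fam = self._family(side)
        out = _fdr_bh(self.edge_p[fam], q, m=len(fam))
        return CorrectionOutcome(
            method=out.method, level=out.level, m_effective=out.m_effective,
            significant=fam[out.significant], threshold=out.threshold,
        )

    def extreme(self, alpha: float = 0.05,
                side: str | None = None) -> CorrectionOutcome:
        """Extreme-statistics correction from the stored per-permutation
        extreme correlations."""
        side, fam = self._family(side)
        rep = (self._result.rep_min if side == "negative"
               else self._result.rep_max)
        return extreme_statistics_from_reps(
            rep, self.r_observed, self.config.alpha if alpha is None else alpha,
            side=side, candidates=fam,
        )

    # -- presentation ------------------------------------------------------
    def summary(self, alpha: float | None = None) -> str:
        """Plain-text summary table of the fit."""
        res = self._result
        cfg = res.config
        alpha = cfg.alpha if alpha is None else alpha
        lines = [
            "Cluster-based network-behavior correlation",
            "=" * 58,
            f"subjects: {self.model.cohort.n_subjects}    "
            f"nodes: {self.model.cohort.n_nodes}    "
            f"edges tested: {res.m_effective} "
            f"(+{res.constant_edge_count} constant)",
            f"method: {cfg.method} partial correlation | "
            f"covariates: {', '.join(cfg.covariate_names) or 'none'}",
            f"permutations: {cfg.n_permutations}    seed: {cfg.seed}",
            f"initial threshold tau = {cfg.tau_init:+.3f} "
            f"({cfg.resolved_side()} side)    alpha = {alpha:g}",
            "-" * 58,
        ]
        if not res.observed.count:
            lines.append("no supra-threshold clusters")
        else:
            lines.append(f"{'cluster':>8} {'edges':>6} {'nodes':>6} "
                         f"{'corrected p':>12}")
            for j, c in enumerate(res.observed.clusters):
                mark = " *" if res.p[j] <= alpha else ""
                lines.append(f"{j:>8} {c.size:>6} {len(c.nodes):>6} "
                             f"{res.p[j]:>12.4f}{mark}")
            lines.append("-" * 58)
            lines.append(f"null max extent: median {np.median(res.null.M):g}, "
                         f"95th pct {np.percentile(res.null.M, 95):g}, "
                         f"max {res.null.M.max()}")
        return "\n".join(lines)

    def report(self, alpha: float | None = None) -> str:
        """Edge-level report of significant clusters (label, r, p)."""
        from .reporting import make_cluster_report

        return make_cluster_report(self._result,
                                   self._result.node_labels, alpha=alpha)

    def to_dict(self) -> dict:
        """JSON-ready structured dump (config echo, clusters, null histogram)."""
        from .reporting import result_to_dict

        return result_to_dict(self._result)

    def plot_null(self, ax=None):
        """Histogram of the permutation null of maximum cluster extents."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        M = self.null_M
        ax.hist(M, bins=np.arange(M.max() + 2) - 0.5, color="0.6")
        for j, c in enumerate(self._result.observed.clusters):
            ax.axvline(c.size, color="C3", lw=1)
        ax.set_xlabel("maximum cluster extent (edges)")
        ax.set_ylabel("permutations")
        ax.set_title(f"tau = {self.config.tau_init:+.2f}")
        return ax
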