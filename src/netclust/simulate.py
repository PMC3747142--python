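"""Synthetic connectome cohorts with known ground truth.

The generator emulates the data shape of a DTI streamline-count study: a
symmetric 90x90 integer weight matrix per subject, a skewed non-negative
severity score (CDR-SOB-like: half-normal, rounded to 0.5 steps, capped at
18), and age/gender covariates — at cohort sizes around 40 subjects.

Planted effects use a Gaussian copula: one latent standard normal per subject
drives the behavioral score, and each planted edge's latent is correlated
with it at the Pearson level rho_P = 2*sin(pi*rho_S/6) so that the population
Spearman correlation of the continuous weights with the score equals the
requested rho_target (the classical Pearson-to-Spearman conversion for
bivariate normals).  Rounding weights to integer counts and the score to 0.5
steps attenuates the realized rank correlation slightly; that residual
discretization bias is measured by the test suite, not assumed away.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import BehaviorTable, Cohort, edge_index_map
from .labels import default_labels


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; defaults mirror the emulated study's shape."""

    n_subjects: int = 40
    n_nodes: int = 90
    #: probability that a non-planted edge exists for a given subject
    density: float = 0.3
    #: log-normal parameters of positive streamline counts (log scale)
    weight_log_mean: float = 3.0
    weight_log_sd: float = 1.0
    #: number of edges in the planted connected sub-network (0 = null cohort)
    planted_k: int = 0
    #: target per-edge population Spearman correlation with the score
    rho_target: float = 0.0
    #: half-normal scale of the severity score
    score_scale: float = 3.0
    #: round the score to multiples of this (None = continuous score)
    score_rounding: float | None = 0.5
    score_max: float = 18.0
    age_mean: float = 72.5
    age_sd: float = 6.7
    p_female: float = 0.4
    #: optional score-independent age effect on the planted edges' latents
    confound_coef: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must be in (0, 1]")
        if abs(self.rho_target) >= 1.0:
            raise ValueError("|rho_target| must be < 1")
        max_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if self.planted_k > max_edges:
            raise ValueError(
                f"planted_k={self.planted_k} exceeds {max_edges} possible edges"
            )


def spearman_to_pearson(rho_s: float) -> float:
    """Invert rho_S = (6/pi) * arcsin(rho_P / 2) for bivariate normals."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def plant_connected_subnetwork(
    n_nodes: int, k: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """A connected set of exactly k edges grown by a seeded random walk.

    The walk starts at a random node and keeps stepping to uniformly random
    other nodes, adding each previously unseen edge it traverses; the
    resulting edge set is connected by construction.  Returns a (k, 2) array
    of node pairs with i < j.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not (1 <= k <= max_edges):
        raise ValueError(f"k must be in [1, {max_edges}], got {k}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    current = int(rng.integers(n_nodes))
    edges: set[tuple[int, int]] = set()
    while len(edges) < k:
        nxt = int(rng.integers(n_nodes))
        if nxt == current:
            continue
        edges.add((min(current, nxt), max(current, nxt)))
        current = nxt
    out = np.array(sorted(edges), dtype=np.int64)
    return out


def _score_from_latent(z: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Map the copula latent to the skewed, tie-prone severity score."""
    u = stats.norm.cdf(z)
    s = stats.halfnorm.ppf(u, scale=spec.score_scale)
    if spec.score_rounding:
        s = np.round(s / spec.score_rounding) * spec.score_rounding
    return np.minimum(s, spec.score_max)


def _weights_from_latent(z: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Map edge latents to integer streamline-like counts (monotone)."""
    u = stats.norm.cdf(z)
    w = stats.lognorm.ppf(u, s=spec.weight_log_sd,
                          scale=np.exp(spec.weight_log_mean))
    return np.maximum(np.round(w), 0.0)


def generate_cohort(
    spec: SyntheticSpec,
) -> tuple[Cohort, BehaviorTable, np.ndarray]:
    """Generate (Cohort, BehaviorTable, planted node-pair array).

    Non-planted edge weights are independent of the score (present with
    probability ``density``, log-normal counts when present).  Planted edge
    weights share the score's copula latent at the calibrated Pearson level,
    so their population Spearman correlation with the score is ``rho_target``.
    Fixed seed gives byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n, nodes = spec.n_subjects, spec.n_nodes
    emap = edge_index_map(nodes)

    z0 = rng.standard_normal(n)  # copula latent shared by score and planted edges
    score = _score_from_latent(z0, spec)
    age = spec.age_mean + spec.age_sd * rng.standard_normal(n)
    gender = (rng.random(n) < spec.p_female).astype(float)

    planted = (plant_connected_subnetwork(nodes, spec.planted_k, rng)
               if spec.planted_k else np.empty((0, 2), dtype=np.int64))
    planted_set = {tuple(p) for p in map(tuple, planted)}
    planted_mask = np.array(
        [tuple(p) in planted_set for p in map(tuple, emap.pairs)], dtype=bool
    )

    weights = np.zeros((n, emap.m))
    # background edges: presence Bernoulli(density), independent of the score
    bg = ~planted_mask
    n_bg = int(bg.sum())
    present = rng.random((n, n_bg)) < spec.density
    w_bg = _weights_from_latent(rng.standard_normal((n, n_bg)), spec)
    weights[:, bg] = w_bg * present

    if planted_mask.any():
        rho_p = spearman_to_pearson(spec.rho_target)
        beta = spec.confound_coef
        resid_var = 1.0 - rho_p ** 2 - beta ** 2
        if resid_var <= 0:
            raise ValueError("rho_target and confound_coef are jointly infeasible")
        k = int(planted_mask.sum())
        eps = rng.standard_normal((n, k))
        z_age = (age - spec.age_mean) / spec.age_sd
        z_edge = (rho_p * z0[:, None] + beta * z_age[:, None]
                  + np.sqrt(resid_var) * eps)
        weights[:, planted_mask] = _weights_from_latent(z_edge, spec)

    mats = np.zeros((n, nodes, nodes))
    mats[:, emap.pairs[:, 0], emap.pairs[:, 1]] = weights
    mats[:, emap.pairs[:, 1], emap.pairs[:, 0]] = weights

    subjects = [f"S{i + 1:03d}" for i in range(n)]
    cohort = Cohort(subjects=subjects, matrices=mats,
                    node_labels=default_labels(nodes))
    behavior = BehaviorTable(
        subjects=subjects,
        measure=score,
        measure_name="severity",
        covariates=pd.DataFrame({"age": age, "gender": gender}),
    )
    return cohort, behavior, planted


def generate_null_cohort(spec: SyntheticSpec) -> tuple[Cohort, BehaviorTable]:
    """A cohort with no planted coupling (score independent of all edges)."""
    if spec.planted_k or spec.rho_target:
        spec = SyntheticSpec(**{**asdict(spec), "planted_k": 0,
                                "rho_target": 0.0})
    cohort, behavior, _ = generate_cohort(spec)
    return cohort, behavior


def write_simulation(
    out_dir: str | Path,
    spec: SyntheticSpec,
) -> tuple[Cohort, BehaviorTable, np.ndarray]:
    """Write per-subject matrix CSVs, behavior.csv and ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, behavior, planted = generate_cohort(spec)
    for s, mat in zip(cohort.subjects, cohort.matrices):
        np.savetxt(out / f"{s}.csv", mat, fmt="%.1f", delimiter=",")
    df = pd.DataFrame({"subject": behavior.subjects,
                       behavior.measure_name: behavior.measure})
    if behavior.covariates is not None:
        for c in behavior.covariates.columns:
            df[c] = behavior.covariates[c].to_numpy()
    df.to_csv(out / "behavior.csv", index=False)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({"spec": asdict(spec),
                   "planted_edges": [list(map(int, p)) for p in planted]},
                  fh, indent=2)
    return cohort, behavior, planted
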