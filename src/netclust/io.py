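"""Connectivity-matrix and behavior-table input, alignment and preprocessing.

A study is represented by two containers:

* :class:`Cohort` — an ordered stack of per-subject symmetric node-by-node
  weight matrices (e.g. streamline counts between atlas regions) plus node
  labels.
* :class:`BehaviorTable` — one behavioral measure of interest per subject
  (e.g. a dementia severity score) and zero or more numeric covariates
  (e.g. age, gender coded 0/1), aligned to the cohort's subject order.

Edges are indexed by the row-major strict upper triangle of the matrix,
``(0,1), (0,2), ..., (n-2, n-1)``; :class:`EdgeIndexMap` is the bijection
between that flat edge index and the node pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .labels import default_labels

logger = logging.getLogger(__name__)

#: relative tolerance for declaring a matrix symmetric: max|A - A.T| must not
#: exceed SYMMETRY_RTOL * max|A|.  Tractography outputs are nominally
#: symmetric but can carry float noise; anything beyond this is a data error.
SYMMETRY_RTOL = 1e-8

#: streamline-count floor below which edges are treated as tracking artifact
DEFAULT_MIN_COUNT = 3.0


class CohortError(ValueError):
    """Raised for invalid connectivity or behavior inputs."""


@dataclass
class Cohort:
    """Subject-aligned stack of symmetric non-negative connectivity matrices.

    Parameters
    ----------
    subjects : list of str
        Unique subject identifiers, in stack order.
    matrices : ndarray, shape (n_subjects, n_nodes, n_nodes)
        Symmetric weight matrices with zero diagonal.
    node_labels : list of str
        Region names, one per node.
    """

    subjects: list[str]
    matrices: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise CohortError(
                f"matrices must be a (subjects, nodes, nodes) stack, "
                f"got shape {self.matrices.shape}"
            )
        if self.matrices.shape[1] < 2:
            raise CohortError("a cohort needs at least 2 nodes")
        if len(self.subjects) != self.matrices.shape[0]:
            raise CohortError("subject list does not match matrix stack size")
        if len(set(self.subjects)) != len(self.subjects):
            raise CohortError("duplicate subject IDs in cohort")
        if not self.node_labels:
            self.node_labels = default_labels(self.n_nodes)
        if len(self.node_labels) != self.n_nodes:
            raise CohortError(
                f"{len(self.node_labels)} labels for {self.n_nodes} nodes"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]


@dataclass
class BehaviorTable:
    """Per-subject behavioral measure of interest plus numeric covariates."""

    subjects: list[str]
    measure: np.ndarray
    measure_name: str = "measure"
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.measure = np.asarray(self.measure, dtype=float)
        if self.measure.ndim != 1 or len(self.measure) != len(self.subjects):
            raise CohortError("measure must be one value per subject")
        if len(set(self.subjects)) != len(self.subjects):
            raise CohortError("duplicate subject IDs in behavior table")
        if np.isnan(self.measure).any():
            raise CohortError("missing values in the behavioral measure")
        if self.covariates is not None:
            self.covariates = pd.DataFrame(self.covariates)
            if len(self.covariates) != len(self.subjects):
                raise CohortError("covariate rows must match subjects")
            if self.covariates.isna().any().any():
                raise CohortError("missing values in covariates")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def covariate_names(self) -> list[str]:
        if self.covariates is None:
            return []
        return list(self.covariates.columns)

    def covariate_array(self) -> np.ndarray:
        """Covariates as an (n_subjects, n_covariates) float array."""
        if self.covariates is None or self.covariates.shape[1] == 0:
            return np.empty((self.n_subjects, 0))
        return self.covariates.to_numpy(dtype=float)


@dataclass(frozen=True)
class EdgeIndexMap:
    """Bijection between flat edge indices and strict upper-triangle pairs."""

    node_count: int
    pairs: np.ndarray  # (m, 2) int array, i < j, row-major order

    @property
    def m(self) -> int:
        return self.pairs.shape[0]


def edge_index_map(node_count: int) -> EdgeIndexMap:
    """Enumerate the ``node_count*(node_count-1)/2`` undirected edges.

    A 90-node network yields 4005 edges.
    """
    if node_count < 2:
        raise CohortError(f"need at least 2 nodes, got {node_count}")
    iu = np.triu_indices(node_count, k=1)
    pairs = np.column_stack(iu).astype(np.int64)
    return EdgeIndexMap(node_count=node_count, pairs=pairs)


def _load_matrix(path: Path) -> np.ndarray:
    """Load a dense numeric matrix from delimited text (comma or whitespace)."""
    try:
        return np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError:
        return np.loadtxt(path, ndmin=2)


def _validate_matrix(a: np.ndarray, name: str) -> np.ndarray:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise CohortError(f"{name}: matrix is not square (shape {a.shape})")
    if (a < 0).any():
        raise CohortError(f"{name}: negative weights are not allowed")
    scale = np.abs(a).max()
    asym = np.abs(a - a.T).max()
    if scale > 0 and asym > SYMMETRY_RTOL * scale:
        raise CohortError(
            f"{name}: asymmetric beyond tolerance "
            f"(max|A-A.T| = {asym:g} > {SYMMETRY_RTOL:g} * max|A| = "
            f"{SYMMETRY_RTOL * scale:g})"
        )
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


def read_cohort(
    matrix_paths: Sequence[str | Path],
    label_path: str | Path | None = None,
    subject_ids: Sequence[str] | None = None,
) -> Cohort:
    """Read one dense delimited matrix file per subject.

    Subject IDs default to the file stems.  All matrices must share one shape;
    each is checked for symmetry (within :data:`SYMMETRY_RTOL`), symmetrized as
    ``(A + A.T)/2`` and its diagonal zeroed.
    """
    paths = [Path(p) for p in matrix_paths]
    if not paths:
        raise CohortError("no matrix files given")
    if subject_ids is None:
        subject_ids = [p.stem for p in paths]
    mats = []
    shape = None
    for p in paths:
        a = _validate_matrix(_load_matrix(p), str(p))
        if shape is None:
            shape = a.shape
        elif a.shape != shape:
            raise CohortError(
                f"{p}: shape {a.shape} does not match first subject's {shape}"
            )
        mats.append(a)
    labels = read_node_labels(label_path, shape[0]) if label_path else []
    return Cohort(subjects=list(subject_ids), matrices=np.stack(mats),
                  node_labels=labels)


def read_cohort_stacked(
    path: str | Path,
    subject_col: str = "subject",
    label_path: str | Path | None = None,
) -> Cohort:
    """Read all subjects from one long-format file.

    Expected columns: ``subject, node_i, node_j, weight`` with 0-based node
    indices; each undirected edge may appear once (it is mirrored).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {subject_col, "node_i", "node_j", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise CohortError(f"{path}: missing columns {sorted(missing)}")
    n_nodes = int(max(df["node_i"].max(), df["node_j"].max())) + 1
    subjects = list(dict.fromkeys(df[subject_col].astype(str)))
    mats = np.zeros((len(subjects), n_nodes, n_nodes))
    index = {s: k for k, s in enumerate(subjects)}
    for s, i, j, w in zip(df[subject_col].astype(str), df["node_i"],
                          df["node_j"], df["weight"]):
        mats[index[s], int(i), int(j)] = w
        mats[index[s], int(j), int(i)] = w
    for k, s in enumerate(subjects):
        mats[k] = _validate_matrix(mats[k], f"{path}[{s}]")
    labels = read_node_labels(label_path, n_nodes) if label_path else []
    return Cohort(subjects=subjects, matrices=mats, node_labels=labels)


def read_node_labels(path: str | Path | None, node_count: int) -> list[str]:
    """Read a two-column (index, label) text file; default labels if absent."""
    if path is None:
        return default_labels(node_count)
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     names=["index", "label"])
    if len(df) != node_count:
        raise CohortError(
            f"{path}: {len(df)} labels for {node_count} nodes"
        )
    order = np.argsort(df["index"].to_numpy())
    return [str(x) for x in df["label"].to_numpy()[order]]


def read_behavior(
    path: str | Path,
    measure_name: str,
    covariate_names: Iterable[str] = (),
    subject_col: str = "subject",
) -> BehaviorTable:
    """Read a delimited behavior table restricted to the named columns."""
    covariate_names = list(covariate_names)
    df = pd.read_csv(path, sep=None, engine="python")
    needed = [subject_col, measure_name, *covariate_names]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing column(s) {missing}")
    subjects = df[subject_col].astype(str).tolist()
    if len(set(subjects)) != len(subjects):
        raise CohortError(f"{path}: duplicate subject IDs")
    numeric = df[[measure_name, *covariate_names]].apply(
        pd.to_numeric, errors="coerce"
    )
    if numeric.isna().any().any():
        bad = numeric.columns[numeric.isna().any()].tolist()
        raise CohortError(f"{path}: non-numeric or missing cells in {bad}")
    covs = numeric[covariate_names] if covariate_names else None
    return BehaviorTable(
        subjects=subjects,
        measure=numeric[measure_name].to_numpy(),
        measure_name=measure_name,
        covariates=covs,
    )


def align(cohort: Cohort, behavior: BehaviorTable) -> tuple[Cohort, BehaviorTable]:
    """Restrict both inputs to the shared subjects, in cohort order."""
    common = [s for s in cohort.subjects if s in set(behavior.subjects)]
    if not common:
        raise CohortError("cohort and behavior table share no subjects")
    dropped_c = [s for s in cohort.subjects if s not in set(common)]
    dropped_b = [s for s in behavior.subjects if s not in set(common)]
    for s in dropped_c:
        logger.info("align: dropping cohort subject %s (no behavior row)", s)
    for s in dropped_b:
        logger.info("align: dropping behavior subject %s (no matrix)", s)
    ci = [cohort.subjects.index(s) for s in common]
    bi = [behavior.subjects.index(s) for s in common]
    new_cohort = Cohort(
        subjects=common,
        matrices=cohort.matrices[ci],
        node_labels=list(cohort.node_labels),
    )
    covs = None
    if behavior.covariates is not None:
        covs = behavior.covariates.iloc[bi].reset_index(drop=True)
    new_behavior = BehaviorTable(
        subjects=common,
        measure=behavior.measure[bi],
        measure_name=behavior.measure_name,
        covariates=covs,
    )
    return new_cohort, new_behavior


def apply_min_weight_filter(cohort: Cohort, min_count: float = DEFAULT_MIN_COUNT) -> Cohort:
    """Zero out edges with weight strictly below ``min_count``, per subject.

    The default of 3 discards too-weak streamline counts that are likely
    tracking artifact; entries exactly at the floor are kept.
    """
    if min_count < 0:
        raise CohortError(f"min_count must be non-negative, got {min_count}")
    mats = cohort.matrices.copy()
    mats[mats < min_count] = 0.0
    if mats.max() == 0 and cohort.matrices.max() > 0:
        logger.warning(
            "min-weight filter at %g zeroed every edge in every subject",
            min_count,
        )
    return Cohort(subjects=list(cohort.subjects), matrices=mats,
                  node_labels=list(cohort.node_labels))


def vectorize(cohort: Cohort, emap: EdgeIndexMap | None = None) -> np.ndarray:
    """Flatten each subject's matrix into its upper-triangle edge vector.

    Returns an (n_subjects, m) array whose column k is the weight of edge
    ``emap.pairs[k]`` across subjects.
    """
    if emap is None:
        emap = edge_index_map(cohort.n_nodes)
    if emap.node_count != cohort.n_nodes:
        raise CohortError(
            f"edge map is for {emap.node_count} nodes, cohort has "
            f"{cohort.n_nodes}"
        )
    return cohort.matrices[:, emap.pairs[:, 0], emap.pairs[:, 1]]


def rebuild(
    weights: np.ndarray,
    emap: EdgeIndexMap,
    subjects: Sequence[str] | None = None,
    node_labels: Sequence[str] | None = None,
) -> Cohort:
    """Inverse of :func:`vectorize`: edge vectors back to symmetric matrices."""
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[1] != emap.m:
        raise CohortError(
            f"weights shape {weights.shape} does not match m={emap.m}"
        )
    n_sub = weights.shape[0]
    if subjects is None:
        subjects = [f"S{k + 1:03d}" for k in range(n_sub)]
    mats = np.zeros((n_sub, emap.node_count, emap.node_count))
    mats[:, emap.pairs[:, 0], emap.pairs[:, 1]] = weights
    mats[:, emap.pairs[:, 1], emap.pairs[:, 0]] = weights
    return Cohort(subjects=list(subjects), matrices=mats,
                  node_labels=list(node_labels or []))
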