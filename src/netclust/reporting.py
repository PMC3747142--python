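"""Human-readable and machine-readable reports of cluster results.

The edge-level report follows the conventional clinical-table layout: one row
per member edge, "LABEL1 - LABEL2, r, uncorrected p", sorted by |r|
descending, with the cluster-level corrected p, the initial threshold and the
permutation count in the header.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import ClusterResult


def _edge_label(pair, labels) -> str:
    return f"{labels[pair[0]]} - {labels[pair[1]]}"


def make_cluster_report(
    result: ClusterResult,
    labels: list[str] | None = None,
    alpha: float | None = None,
) -> str:
    """Delimited-text report of the significant clusters.

    Header comment lines (prefixed ``#``) carry the analysis settings and one
    line per reported cluster; the body is CSV with columns
    ``cluster,connection,r,p_uncorrected``.  An empty result yields a
    header-only report saying so.
    """
    cfg = result.config
    labels = labels or result.node_labels
    if alpha is None:
        alpha = cfg.alpha if cfg else 0.05
    lines = []
    if cfg is not None:
        lines.append(f"# tau_init={cfg.tau_init:g} side={cfg.resolved_side()} "
                     f"N={cfg.n_permutations} seed={cfg.seed} alpha={alpha:g}")
    sig = result.significant_clusters(alpha)
    if not sig:
        lines.append("# no significant clusters")
        lines.append("cluster,connection,r,p_uncorrected")
        return "\n".join(lines) + "\n"
    for j in sig:
        c = result.observed.clusters[j]
        lines.append(f"# cluster {j}: {c.size} connections, "
                     f"corrected p={result.p[j]:g}")
    lines.append("cluster,connection,r,p_uncorrected")
    for j in sig:
        c = result.observed.clusters[j]
        r = result.r_observed[c.edges]
        p = result.edge_p.p[c.edges]
        order = np.argsort(-np.abs(r), kind="stable")
        for k in order:
            e = c.edges[k]
            if result.emap is None:
                raise ValueError("result carries no edge index map")
            pair = result.emap.pairs[e]
            if pair[0] >= len(labels) or pair[1] >= len(labels):
                raise ValueError(f"missing label for node pair {tuple(pair)}")
            lines.append(f"{j},{_edge_label(pair, labels)},"
                         f"{r[k]:.4f},{p[k]:.4f}")
    return "\n".join(lines) + "\n"


def parse_cluster_report(text: str) -> pd.DataFrame:
    """Parse a report back into a DataFrame (round-trip of the CSV body)."""
    body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
    return pd.read_csv(_io.StringIO(body))


def result_to_dict(result: ClusterResult) -> dict:
    """JSON-ready dump: config echo, null histogram, clusters, p-values."""
    cfg = result.config
    M = result.null.M
    values, counts = np.unique(M, return_counts=True)
    return {
        "config": None if cfg is None else {
            "tau_init": cfg.tau_init,
            "side": cfg.resolved_side(),
            "n_permutations": cfg.n_permutations,
            "seed": cfg.seed,
            "method": cfg.method,
            "covariates": list(cfg.covariate_names),
            "min_count": cfg.min_count,
            "alpha": cfg.alpha,
        },
        "m_effective": result.m_effective,
        "constant_edges": result.constant_edge_count,
        "null_histogram": {int(v): int(c) for v, c in zip(values, counts)},
        "clusters": [
            {
                "size": int(c.size),
                "corrected_p": float(result.p[j]),
                "edges": [list(map(int, result.emap.pairs[e]))
                          for e in c.edges] if result.emap is not None else [],
                "nodes": [int(v) for v in c.nodes],
            }
            for j, c in enumerate(result.observed.clusters)
        ],
    }


def write_result(result: ClusterResult, out_dir: str | Path) -> None:
    """Write result.json, report.csv and report.txt into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "result.json", "w") as fh:
        json.dump(result_to_dict(result), fh, indent=2)
    report = make_cluster_report(result)
    (out / "report.csv").write_text(report)
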