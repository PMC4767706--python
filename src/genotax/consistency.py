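"""Clustering-consistency diagnostics for threshold-based species delimitation.

A pairwise distance threshold T implicitly promises a transitive link
relation: if A is "the same species" as B and B as C, then A should be as
well.  Real genome distances are not ultrametric, so the promise breaks.
Two diagnostics quantify how badly, for a given matrix and threshold:

* **cluster consistency** — given a partition, a genome pair is
  inconsistent when it sits in one cluster despite d > T, or in two
  clusters despite d <= T; per-cluster and global consistent fractions
  are reported.
* **triplet consistency** — over all C(n,3) genome triplets, the fraction
  whose link relation is transitive (0, 1 or 3 links; exactly 2 links
  would assign one genome to two species at once).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .clustering import ClusteringParams, optsil_cluster
from .io import Partition, RelatednessMatrix, ValidationError

__all__ = [
    "ConsistencyReport",
    "cluster_consistency",
    "triplet_consistency",
    "consistency_sweep",
]


@dataclass
class ConsistencyReport:
    """Consistency of one partition/matrix at one threshold."""

    T: float
    F: float | None
    per_cluster: dict[str, float]   # cluster label -> consistent pair fraction
    mean_consistency: float         # unweighted mean over clusters (headline)
    global_consistency: float       # consistent fraction over all pairs
    triplet_consistency: float | None = None

    def __post_init__(self) -> None:
        vals = list(self.per_cluster.values()) + [self.mean_consistency,
                                                  self.global_consistency]
        if any(not 0.0 <= v <= 1.0 + 1e-12 for v in vals):
            raise ValidationError("consistency values must lie in [0, 1]")


def _links(d: RelatednessMatrix, T: float) -> np.ndarray:
    if d.scale != "distance":
        raise ValidationError("consistency requires a distance matrix")
    if d.has_missing():
        raise ValidationError("distance matrix has missing entries")
    links = d.values <= T
    np.fill_diagonal(links, False)
    return links


def cluster_consistency(p: Partition, d: RelatednessMatrix, T: float,
                        F: float | None = None) -> ConsistencyReport:
    """Pairwise consistency of a partition with the link relation at T.

    A cluster's consistency is the consistent fraction among all pairs
    with at least one member in that cluster; the headline number is the
    unweighted mean across clusters, with the global pairwise fraction
    reported alongside.
    """
    missing = set(d.ids) - set(p.ids)
    if missing:
        raise ValidationError(f"partition misses genomes: {sorted(missing)[:3]}...")
    links = _links(d, T)
    n = len(d)
    if n < 2:
        raise ValidationError("need at least two genomes")
    labels = np.array([p.assignment[g] for g in d.ids])
    same = labels[:, None] == labels[None, :]
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    inconsistent = (same ^ links) & upper   # same & no-link, or split & link

    total_pairs = upper.sum()
    global_cons = 1.0 - inconsistent.sum() / total_pairs

    per_cluster: dict[str, float] = {}
    for label in dict.fromkeys(labels.tolist()):
        touch = (labels[:, None] == label) | (labels[None, :] == label)
        pairs = (touch & upper).sum()
        bad = (inconsistent & touch).sum()
        per_cluster[str(label)] = 1.0 - bad / pairs if pairs else 1.0
    mean_cons = float(np.mean(list(per_cluster.values())))
    return ConsistencyReport(T=T, F=F, per_cluster=per_cluster,
                             mean_consistency=mean_cons,
                             global_consistency=float(global_cons))


def triplet_consistency(d: RelatednessMatrix, T: float) -> float:
    """Fraction of genome triplets whose link relation at T is transitive.

    Counted in closed form from the link graph: a triplet is inconsistent
    iff it carries exactly two links (a path that is not a triangle), so
    inconsistent = sum_j C(deg_j, 2) - 3 * triangles.
    """
    links = _links(d, T)
    n = len(d)
    if n < 3:
        raise ValidationError("need at least three genomes for triplets")
    a = links.astype(np.int64)
    deg = a.sum(axis=1)
    triangles = int(np.trace(a @ a @ a)) // 6
    open_paths = int((deg * (deg - 1) // 2).sum()) - 3 * triangles
    return 1.0 - open_paths / comb(n, 3)


def consistency_sweep(d: RelatednessMatrix,
                      T_grid: np.ndarray,
                      F_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
                      ) -> pd.DataFrame:
    """Cluster + triplet consistency over a (T, F) grid.

    The partition is recomputed by F-linkage clustering for every cell;
    triplet consistency depends on T only and is repeated across F rows
    for convenience.
    """
    rows = []
    for T in np.asarray(T_grid, dtype=float):
        trip = triplet_consistency(d, T) if len(d) >= 3 else np.nan
        for F in F_grid:
            part = optsil_cluster(d, ClusteringParams(T=float(T), F=float(F)))
            rep = cluster_consistency(part, d, float(T), F=float(F))
            rows.append({
                "T": float(T), "F": float(F),
                "n_clusters": part.n_clusters,
                "mean_consistency": rep.mean_consistency,
                "global_consistency": rep.global_consistency,
                "triplet_consistency": trip,
            })
    return pd.DataFrame(rows)
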