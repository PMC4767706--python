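"""Collector's (rarefaction) curves for cluster counts and genome fractions.

Each replicate draws a random permutation of the genomes and evaluates the
statistic on every prefix ("sequentially added strains"), so the curve is
an accumulation curve; independent per-size subsampling is available by
flag.  Replicates default to 200 and curves report the mean with the
empirical first and third quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ClusteringParams, optsil_cluster
from .io import RelatednessMatrix, ValidationError
from .pangenome import OrthoGroups

__all__ = ["RarefactionCurve", "rarefy_clusters", "rarefy_fractions"]

DEFAULT_REPLICATES = 200


@dataclass
class RarefactionCurve:
    """Replicate values of a statistic as a function of sample size."""

    statistic: str
    sizes: np.ndarray            # (k,) sample sizes
    values: np.ndarray           # (R, k) one row per replicate

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != self.sizes.size:
            raise ValidationError("replicate array shape does not match sizes")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def q1(self) -> np.ndarray:
        return np.quantile(self.values, 0.25, axis=0)  # type-7 interpolation

    @property
    def q3(self) -> np.ndarray:
        return np.quantile(self.values, 0.75, axis=0)

    def saturation_size(self, target: float) -> int | None:
        """Smallest n at which *every* replicate has reached ``target``."""
        hit = (self.values >= target).all(axis=0)
        idx = np.flatnonzero(hit)
        return int(self.sizes[idx[0]]) if idx.size else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.sizes, "mean": self.mean,
                             "q1": self.q1, "q3": self.q3})


def rarefy_clusters(d: RelatednessMatrix, params: ClusteringParams,
                    R: int = DEFAULT_REPLICATES, seed: int = 0,
                    sizes: np.ndarray | None = None,
                    nested: bool = True) -> RarefactionCurve:
    """Cluster count versus number of sampled genomes.

    For each replicate and sample size, the submatrix of the sampled
    genomes is clustered with the given (T, F) and the number of clusters
    recorded.  Deterministic for a fixed seed.
    """
    if R < 1:
        raise ValidationError("need at least one replicate")
    if d.has_missing():
        raise ValidationError("matrix has missing entries")
    n = len(d)
    sizes = np.arange(1, n + 1) if sizes is None else np.asarray(sizes, dtype=int)
    if sizes.min() < 1 or sizes.max() > n:
        raise ValidationError("sample sizes out of range")
    rng = np.random.default_rng(seed)
    values = np.zeros((R, sizes.size))
    for r in range(R):
        order = rng.permutation(n)
        for k, size in enumerate(sizes):
            chosen = order[:size] if nested else rng.choice(n, size=size, replace=False)
            if size == 1:
                values[r, k] = 1
                continue
            sub = d.submatrix([d.ids[i] for i in sorted(chosen)])
            values[r, k] = optsil_cluster(sub, params).n_clusters
    return RarefactionCurve("n_clusters", sizes, values)


def rarefy_fractions(og: OrthoGroups, R: int = DEFAULT_REPLICATES, seed: int = 0,
                     sizes: np.ndarray | None = None, nested: bool = True
                     ) -> dict[str, RarefactionCurve]:
    """Core, strain-specific and pan sizes versus number of sampled genomes.

    On a subsample S: core = groups present in every genome of S; pan =
    groups present in at least one; strain-specific = CDS count in groups
    confined to exactly one sampled genome.  Returns the three curves
    keyed ``core``, ``strain_specific`` and ``pan``.
    """
    if R < 1:
        raise ValidationError("need at least one replicate")
    n = len(og.genomes)
    sizes = np.arange(1, n + 1) if sizes is None else np.asarray(sizes, dtype=int)
    if sizes.min() < 1 or sizes.max() > n:
        raise ValidationError("sample sizes out of range")
    rng = np.random.default_rng(seed)
    presence, counts = og.occupancy_matrix()
    out = {name: np.zeros((R, sizes.size))
           for name in ("core", "strain_specific", "pan")}
    for r in range(R):
        order = rng.permutation(n)
        for k, size in enumerate(sizes):
            chosen = order[:size] if nested else rng.choice(n, size=size, replace=False)
            sub = presence[:, chosen]
            out["core"][r, k] = sub.all(axis=1).sum()
            out["pan"][r, k] = sub.any(axis=1).sum()
            solo = sub.sum(axis=1) == 1
            out["strain_specific"][r, k] = counts[np.ix_(solo, chosen)].sum()
    return {name: RarefactionCurve(name, sizes, vals)
            for name, vals in out.items()}
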