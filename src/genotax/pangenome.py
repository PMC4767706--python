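"""Orthologous gene grouping and genome-fraction arithmetic.

Proteomes are compared all-against-all with local alignment (BLOSUM62
Smith-Waterman through Biopython), hits are filtered by alignment
coverage and a decoy-calibrated score floor, and ortho-groups are formed
as connected components over bidirectional-best-hit (BBH) edges between
genomes plus within-genome paralog edges that score at least as well as
a gene's best inter-genome match.  Every input protein belongs to
exactly one group; proteins with no edges become size-1 groups
(singletons).

From the groups and a genome partition the four classic fractions are
computed by set arithmetic:

* **core** — groups present in every genome;
* **group core** — groups present in every member of one group label;
* **group-specific** — groups in one label's core and in no other
  label's core;
* **strain-specific** — CDSs confined to a single genome (singletons
  plus within-strain paralog families);
* **pan** — all groups.

Percentages are reported relative to the mean per-genome CDS count.

A pass-through mode accepts an externally produced tabular hit file
(standard 12-column blast tabular) or externally computed groups, for
reproduction attempts with the original search engines.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io import GenomeRecord, Partition, ValidationError

__all__ = [
    "OrthoGroups",
    "GenomeFractions",
    "all_vs_all_hits",
    "calibrate_score_floor",
    "build_orthogroups",
    "genome_fractions",
    "trait_prevalence",
    "read_hit_table",
    "write_hit_table",
]

GeneId = tuple[str, str]  # (genome id, protein id)

HIT_COLUMNS = ["qgenome", "qseqid", "sgenome", "sseqid", "pident",
               "length", "qcov", "scov", "score"]


@dataclass
class OrthoGroups:
    """Clusters of gene identifiers spanning genomes."""

    groups: list[frozenset[GeneId]]
    genomes: list[str]
    gene_counts: dict[str, int] = field(default_factory=dict)  # CDS per genome

    def __post_init__(self) -> None:
        seen: set[GeneId] = set()
        for grp in self.groups:
            if not grp:
                raise ValidationError("empty ortho-group")
            if seen & grp:
                raise ValidationError("a protein appears in more than one group")
            seen |= grp
        genomes = set(self.genomes)
        for g, _ in seen:
            if g not in genomes:
                raise ValidationError(f"group references unknown genome {g!r}")
        if not self.gene_counts:
            self.gene_counts = {g: 0 for g in self.genomes}
            for grp in self.groups:
                for g, _ in grp:
                    self.gene_counts[g] += 1

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def occupancy(self, index: int) -> frozenset[str]:
        return frozenset(g for g, _ in self.groups[index])

    def occupancy_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(groups x genomes) presence matrix and per-cell CDS counts."""
        gi = {g: k for k, g in enumerate(self.genomes)}
        counts = np.zeros((len(self.groups), len(self.genomes)), dtype=np.int64)
        for r, grp in enumerate(self.groups):
            for g, _ in grp:
                counts[r, gi[g]] += 1
        return counts > 0, counts


@dataclass
class GenomeFractions:
    """The four genome fractions plus percentages of the mean CDS count."""

    core: set[int]                       # group indices present in all genomes
    group_core: dict[str, set[int]]      # label -> indices in all its members
    group_specific: dict[str, set[int]]  # label -> core indices unique to it
    strain_specific: dict[str, int]      # genome -> CDS count confined to it
    pan: int
    mean_cds: float
    percent: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, gc in self.group_core.items():
            if not self.core <= gc:
                raise ValidationError(f"core not contained in group core of {label!r}")
        labels = list(self.group_specific)
        for a, b in itertools.combinations(labels, 2):
            if self.group_specific[a] & self.group_specific[b]:
                raise ValidationError("group-specific sets overlap")
        if self.pan < len(self.core):
            raise ValidationError("pan-genome smaller than core")
        if not self.percent:
            m = self.mean_cds
            self.percent = {"core": 100.0 * len(self.core) / m}
            for label, gc in self.group_core.items():
                self.percent[f"group_core:{label}"] = 100.0 * len(gc) / m
            for label, gs in self.group_specific.items():
                self.percent[f"group_specific:{label}"] = 100.0 * len(gs) / m
            for g, c in self.strain_specific.items():
                self.percent[f"strain_specific:{g}"] = 100.0 * c / m


# ---------------------------------------------------------------------------
# All-vs-all protein search
# ---------------------------------------------------------------------------

def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _shares_kmer(a: str, b_kmers: set[str], k: int = 4) -> bool:
    return any(a[i:i + k] in b_kmers for i in range(len(a) - k + 1))


def calibrate_score_floor(proteomes: list[GenomeRecord], seed: int = 0,
                          n_decoys: int = 30) -> float:
    """Score floor separating real homology from chance local alignments.

    Aligns shuffled versions of sampled proteins against unrelated real
    proteins and returns the maximum chance score plus a margin.  Serves
    the same role as a BLAST e-value cutoff but is deterministic for a
    given seed and independent of any specific search engine's statistics.
    """
    rng = np.random.default_rng(seed)
    pool = [(g.id, name, seq) for g in proteomes for name, seq in g.sequences]
    if not pool:
        raise ValidationError("no proteins to calibrate on")
    aligner = _protein_aligner()
    best = 0.0
    for _ in range(n_decoys):
        gi, ti = rng.integers(0, len(pool), size=2)
        decoy = "".join(rng.permutation(list(pool[gi][2])))
        target = pool[ti][2]
        score = aligner.align(target, decoy).score
        best = max(best, float(score))
    return best * 1.1 + 5.0


def all_vs_all_hits(proteomes: list[GenomeRecord],
                    coverage_min: float = 0.5,
                    score_floor: float | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """All-against-all local protein search with coverage and score filters.

    Returns the tabular hit format (one row per ordered protein pair that
    passes).  Coverage is applied on both query and subject.  Self hits
    (a protein against itself) are excluded.
    """
    for p in proteomes:
        if p.alphabet != "protein":
            raise ValidationError(f"{p.id} is not a proteome")
        if not p.sequences:
            raise ValidationError(f"empty proteome {p.id}")
    if score_floor is None:
        score_floor = calibrate_score_floor(proteomes, seed=seed)
    aligner = _protein_aligner()
    genes = [(g.id, name, seq) for g in proteomes for name, seq in g.sequences]
    kmer_sets = [{seq[i:i + 4] for i in range(len(seq) - 3)} for _, _, seq in genes]
    rows = []
    for i, (qg, qid, qseq) in enumerate(genes):
        for j, (sg, sid, sseq) in enumerate(genes):
            if i == j:
                continue
            if not _shares_kmer(qseq, kmer_sets[j]):
                continue
            alignments = aligner.align(sseq, qseq)
            score = float(alignments.score)
            if score < score_floor:
                continue
            aln = alignments[0]
            counts = aln.counts()
            cols = counts.identities + counts.mismatches + counts.gaps
            qcov = sum(e - s for s, e in aln.aligned[1]) / len(qseq)
            scov = sum(e - s for s, e in aln.aligned[0]) / len(sseq)
            if qcov < coverage_min or scov < coverage_min:
                continue
            rows.append((qg, qid, sg, sid,
                         100.0 * counts.identities / cols if cols else 0.0,
                         cols, qcov, scov, score))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def read_hit_table(path, coverage_min: float = 0.5,
                   score_floor: float = 0.0) -> pd.DataFrame:
    """Pass-through mode: load an externally produced tabular hit file.

    Accepts either the native 9-column format or 12-column blast tabular
    with gene ids of the form ``genome|protein``; rows failing the
    coverage or score filters are dropped.
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != HIT_COLUMNS:
        raw = pd.read_csv(path, sep="\t", header=None)
        if raw.shape[1] != 12:
            raise ValidationError("unrecognized hit-table format")
        qg, qid = zip(*(str(x).split("|", 1) for x in raw[0]))
        sg, sid = zip(*(str(x).split("|", 1) for x in raw[1]))
        df = pd.DataFrame({
            "qgenome": qg, "qseqid": qid, "sgenome": sg, "sseqid": sid,
            "pident": raw[2], "length": raw[3],
            "qcov": np.nan, "scov": np.nan, "score": raw[11],
        })
    mask = df["score"] >= score_floor
    for col in ("qcov", "scov"):
        mask &= df[col].fillna(1.0) >= coverage_min
    return df[mask].reset_index(drop=True)


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ortho-group construction
# ---------------------------------------------------------------------------

def build_orthogroups(hits: pd.DataFrame,
                      proteomes: list[GenomeRecord]) -> OrthoGroups:
    """BBH graph + within-genome paralog edges, grouped by connected components.

    An inter-genome edge joins two genes that are each other's best hit
    between their two genomes (ties broken by smaller subject id).  A
    within-genome edge joins two genes scoring at least as high as the
    weaker gene's best inter-genome hit (in-paralogs); genes without any
    inter-genome hit accept any within-genome hit.
    """
    all_genes: list[GeneId] = [(g.id, name) for g in proteomes for name, _ in g.sequences]
    genomes = [g.id for g in proteomes]
    known = set(all_genes)
    if not hits.empty:
        for _, row in hits.iterrows():
            for gid in ((row.qgenome, row.qseqid), (row.sgenome, row.sseqid)):
                if gid not in known:
                    raise ValidationError(f"hit references unknown gene {gid}")

    graph = nx.Graph()
    graph.add_nodes_from(all_genes)
    if not hits.empty:
        inter = hits[hits.qgenome != hits.sgenome]
        best_inter_score: dict[GeneId, float] = {}
        best_partner: dict[tuple[GeneId, str], GeneId] = {}
        if not inter.empty:
            ranked = inter.sort_values(["score", "sseqid"],
                                       ascending=[False, True], kind="stable")
            for row in ranked.itertuples():
                q = (row.qgenome, row.qseqid)
                key = (q, row.sgenome)
                if key not in best_partner:
                    best_partner[key] = (row.sgenome, row.sseqid)
                best_inter_score[q] = max(best_inter_score.get(q, 0.0), row.score)
            for (q, sg), s in best_partner.items():
                if best_partner.get((s, q[0])) == q:
                    graph.add_edge(q, s)
        intra = hits[hits.qgenome == hits.sgenome]
        for row in intra.itertuples():
            q = (row.qgenome, row.qseqid)
            s = (row.sgenome, row.sseqid)
            floor = min(best_inter_score.get(q, -np.inf),
                        best_inter_score.get(s, -np.inf))
            if row.score >= floor:
                graph.add_edge(q, s)

    components = [frozenset(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: sorted(c))
    counts = {g.id: len(g.sequences) for g in proteomes}
    return OrthoGroups(groups=components, genomes=genomes, gene_counts=counts)


# ---------------------------------------------------------------------------
# Genome fractions
# ---------------------------------------------------------------------------

def genome_fractions(og: OrthoGroups, groups: Partition,
                     strain_specific_as: str = "cds") -> GenomeFractions:
    """Compute core / group-core / group-specific / strain-specific / pan.

    ``strain_specific_as`` is ``"cds"`` (count CDSs, the published
    convention) or ``"groups"`` (count paralog families once).
    """
    missing = set(og.genomes) - set(groups.ids)
    if missing:
        raise ValidationError(f"partition misses genomes: {sorted(missing)[:3]}")
    if any(c == 0 for c in og.gene_counts.values()):
        empty = [g for g, c in og.gene_counts.items() if c == 0]
        raise ValidationError(f"genome(s) with zero CDSs: {empty}")

    all_genomes = set(og.genomes)
    occ = [og.occupancy(i) for i in range(og.n_groups)]
    core = {i for i, o in enumerate(occ) if o == all_genomes}

    blocks = {label: set(members)
              for label, members in groups.restrict(og.genomes).blocks().items()}
    group_core = {label: {i for i, o in enumerate(occ) if members <= o}
                  for label, members in blocks.items()}
    group_specific: dict[str, set[int]] = {}
    for label, gc in group_core.items():
        others: set[int] = set()
        for other, ogc in group_core.items():
            if other != label:
                others |= ogc
        group_specific[label] = gc - others

    strain_specific: dict[str, int] = {g: 0 for g in og.genomes}
    for i, o in enumerate(occ):
        if len(o) == 1:
            (g,) = o
            strain_specific[g] += len(og.groups[i]) if strain_specific_as == "cds" else 1

    mean_cds = float(np.mean([og.gene_counts[g] for g in og.genomes]))
    return GenomeFractions(core=core, group_core=group_core,
                           group_specific=group_specific,
                           strain_specific=strain_specific,
                           pan=og.n_groups, mean_cds=mean_cds)


def trait_prevalence(og: OrthoGroups, groups: Partition,
                     trait: set[int], mode: str = "complete",
                     core_markers: set[int] | None = None) -> dict[str, float]:
    """Percent of strains per group label carrying a marker gene set.

    ``trait`` is a set of ortho-group indices marking a gene cluster;
    with ``mode="complete"`` a strain counts when it carries every
    marker, with ``mode="core_subset"`` when it carries at least the
    ``core_markers`` subset (the functionally essential CDSs).
    """
    if not trait:
        raise ValidationError("empty trait marker set")
    for i in trait | (core_markers or set()):
        if not 0 <= i < og.n_groups:
            raise ValidationError(f"unknown marker group id {i}")
    required = trait if mode == "complete" else (core_markers or trait)
    if mode not in ("complete", "core_subset"):
        raise ValidationError(f"unknown mode {mode!r}")
    present: dict[str, set[int]] = {g: set() for g in og.genomes}
    for i in required:
        for g in og.occupancy(i):
            present[g].add(i)
    out: dict[str, float] = {}
    for label, members in groups.restrict(og.genomes).blocks().items():
        have = sum(1 for g in members if required <= present[g])
        out[label] = 100.0 * have / len(members)
    return out
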