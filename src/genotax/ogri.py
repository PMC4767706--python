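"""Overall genome relatedness indices computed from sequence.

Two alignment-based and one alignment-free index:

* **ANIb** — the query genome is cut into consecutive fragments
  (1,020 nt by default), each fragment is locally aligned against the
  subject genome on both strands, and the mean percent identity over
  hits with >= 30% identity and >= 70% alignable fraction is reported.
* **TETRA** — tetranucleotide usage z-scores against a maximal-order
  Markov null, compared between genomes by Pearson correlation.

Local alignments run through Biopython's ``PairwiseAligner`` (exact
Smith-Waterman with affine gaps) restricted to a window around shared
k-mer seeds, which keeps the search close to BLASTN behaviour at a
fraction of the cost.  dDDH values are ingested from files, never
computed here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .io import GenomeRecord, RelatednessMatrix, ValidationError

__all__ = [
    "FragmentHit",
    "TetraProfile",
    "fragment_genome",
    "best_hit",
    "anib_oneway",
    "anib_matrix",
    "tetra_profile",
    "tetra_correlation",
    "tetra_matrix",
    "similarity_to_distance",
    "distance_to_similarity",
]

DEFAULT_FRAGMENT_LENGTH = 1020
MIN_IDENTITY = 30.0          # percent, ANIb hit filter
MIN_ALIGNABLE_FRACTION = 0.70
SEED_K = 15                  # shared-word prefilter for fragment search
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FragmentHit:
    """Best local alignment of one query fragment against a subject genome."""

    fragment_index: int
    identity: float            # percent identical columns over aligned columns
    alignable_fraction: float  # aligned fragment positions / fragment length
    score: float

    def passes(self, min_identity: float = MIN_IDENTITY,
               min_alignable: float = MIN_ALIGNABLE_FRACTION) -> bool:
        return self.identity >= min_identity and self.alignable_fraction >= min_alignable


@dataclass(frozen=True)
class TetraProfile:
    """256-vector of tetranucleotide z-scores, lexicographic AAAA..TTTT."""

    genome_id: str
    z: np.ndarray

    def __post_init__(self) -> None:
        if self.z.shape != (256,) or not np.all(np.isfinite(self.z)):
            raise ValidationError("tetranucleotide profile must be 256 finite values")


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------

def fragment_genome(genome: GenomeRecord,
                    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
                    max_n_fraction: float = 0.5) -> list[str]:
    """Cut each contig into consecutive non-overlapping windows.

    The terminal remainder shorter than ``fragment_length`` is discarded,
    as are fragments that are mostly ambiguous (> ``max_n_fraction`` N).
    """
    if genome.alphabet != "nucleotide":
        raise ValidationError("ANIb fragmentation requires nucleotide records")
    if fragment_length < 1:
        raise ValidationError("fragment_length must be positive")
    fragments: list[str] = []
    for _, contig in genome.sequences:
        for start in range(0, len(contig) - fragment_length + 1, fragment_length):
            frag = contig[start:start + fragment_length]
            if frag.count("N") / len(frag) <= max_n_fraction:
                fragments.append(frag)
    return fragments


# ---------------------------------------------------------------------------
# Seeded local alignment
# ---------------------------------------------------------------------------

def _dna_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    table: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        word = seq[i:i + k]
        if "N" not in word:
            table.setdefault(word, []).append(i)
    return table


class SubjectIndex:
    """Pre-indexed subject genome: concatenated contigs + k-mer positions.

    Contigs are joined with runs of N longer than any seed word so that
    seeds and alignments can never bridge two contigs.
    """

    def __init__(self, genome: GenomeRecord, k: int = SEED_K) -> None:
        spacer = "N" * (k + 1)
        self.sequence = spacer.join(s for _, s in genome.sequences)
        self.k = k
        self.kmers = _kmer_positions(self.sequence, k)


def _seed_windows(fragment: str, index: SubjectIndex,
                  margin: int = 200, max_windows: int = 4) -> list[tuple[int, int]]:
    """Candidate subject windows from the most seed-supported diagonals."""
    k = index.k
    diag_votes: dict[int, int] = {}
    for i in range(0, len(fragment) - k + 1, 4):  # stride 4: cheap, still dense
        for j in index.kmers.get(fragment[i:i + k], ()):
            d = j - i
            diag_votes[d] = diag_votes.get(d, 0) + 1
    if not diag_votes:
        return []
    # bucket nearby diagonals together (indel tolerance)
    buckets: dict[int, int] = {}
    for d, v in diag_votes.items():
        buckets[d // margin] = buckets.get(d // margin, 0) + v
    best = sorted(buckets, key=lambda b: (-buckets[b], b))[:max_windows]
    n = len(index.sequence)
    windows = []
    for b in best:
        d0 = b * margin
        start = max(0, d0 - margin)
        end = min(n, d0 + margin + len(fragment) + margin)
        windows.append((start, end))
    return windows


def best_hit(fragment: str, index: SubjectIndex,
             fragment_index: int = 0,
             aligner: Align.PairwiseAligner | None = None,
             score_floor: float = 2.0 * SEED_K) -> FragmentHit | None:
    """Highest-scoring local alignment of a fragment vs an indexed subject.

    Both strands are searched.  Returns ``None`` when no shared seed word
    exists or no alignment reaches ``score_floor``.
    """
    aligner = aligner or _dna_aligner()
    best: FragmentHit | None = None
    for strand_seq in (fragment, reverse_complement(fragment)):
        for start, end in _seed_windows(strand_seq, index):
            window = index.sequence[start:end]
            alignments = aligner.align(window, strand_seq)
            if not alignments or alignments.score < score_floor:
                continue
            aln = alignments[0]
            counts = aln.counts()
            cols = counts.identities + counts.mismatches + counts.gaps
            if cols == 0:
                continue
            qsegs = aln.aligned[1]
            covered = int(sum(e - s for s, e in qsegs))
            hit = FragmentHit(
                fragment_index=fragment_index,
                identity=100.0 * counts.identities / cols,
                alignable_fraction=covered / len(fragment),
                score=float(alignments.score),
            )
            if best is None or hit.score > best.score:
                best = hit
    return best


# ---------------------------------------------------------------------------
# ANIb
# ---------------------------------------------------------------------------

def anib_oneway(query: GenomeRecord, subject: GenomeRecord,
                fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
                min_identity: float = MIN_IDENTITY,
                min_alignable: float = MIN_ALIGNABLE_FRACTION) -> float:
    """One-directional ANIb: mean identity of accepted fragment hits.

    Returns NaN when no fragment hit passes the identity / alignable-fraction
    filters (reported as a missing cell in the matrix).
    """
    fragments = fragment_genome(query, fragment_length)
    if not fragments:
        raise ValidationError(f"no usable fragments in query {query.id}")
    index = SubjectIndex(subject)
    aligner = _dna_aligner()
    identities = []
    for i, frag in enumerate(fragments):
        hit = best_hit(frag, index, fragment_index=i, aligner=aligner)
        if hit is not None and hit.passes(min_identity, min_alignable):
            identities.append(hit.identity)
    return float(np.mean(identities)) if identities else float("nan")


def anib_matrix(genomes: list[GenomeRecord],
                fragment_length: int = DEFAULT_FRAGMENT_LENGTH) -> RelatednessMatrix:
    """Reciprocal ANIb matrix: both directions computed, diagonal 100."""
    if len(genomes) < 2:
        raise ValidationError("need at least two genomes")
    ids = [g.id for g in genomes]
    n = len(ids)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    for i, j in itertools.permutations(range(n), 2):
        values[i, j] = anib_oneway(genomes[i], genomes[j], fragment_length)
    return RelatednessMatrix(ids, values, scale="similarity_percent", kind="ANIb")


# ---------------------------------------------------------------------------
# TETRA
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_TETRAS = ["".join(w) for w in itertools.product(_BASES, repeat=4)]
_TETRA_INDEX = {w: i for i, w in enumerate(_TETRAS)}


def _count_words(seqs: list[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if "N" not in w:
                counts[w] = counts.get(w, 0) + 1
    return counts


def tetra_profile(genome: GenomeRecord) -> TetraProfile:
    """Tetranucleotide z-scores over pooled contigs plus reverse complements.

    The null model is the maximal-order Markov expectation
    ``E(abcd) = N(abc) * N(bcd) / N(bc)`` with variance
    ``E * (N(bc) - N(abc)) * (N(bc) - N(bcd)) / N(bc)^2``; components with
    zero variance or an undefined expectation get z = 0.
    """
    if genome.alphabet != "nucleotide":
        raise ValidationError("TETRA requires nucleotide records")
    if genome.total_length < 4:
        raise ValidationError("sequence too short for tetranucleotide analysis")
    strands = [s for _, s in genome.sequences]
    strands += [reverse_complement(s) for s in strands]
    n4 = _count_words(strands, 4)
    n3 = _count_words(strands, 3)
    n2 = _count_words(strands, 2)
    z = np.zeros(256)
    for idx, word in enumerate(_TETRAS):
        abc, bcd, bc = word[:3], word[1:], word[1:3]
        denom = n2.get(bc, 0)
        if denom == 0:
            continue
        e = n3.get(abc, 0) * n3.get(bcd, 0) / denom
        var = e * (denom - n3.get(abc, 0)) * (denom - n3.get(bcd, 0)) / denom ** 2
        if var <= 0:
            continue
        z[idx] = (n4.get(word, 0) - e) / np.sqrt(var)
    return TetraProfile(genome.id, z)


def tetra_correlation(a: TetraProfile, b: TetraProfile) -> float:
    """Pearson correlation between two tetranucleotide z-score vectors."""
    if np.std(a.z) == 0 or np.std(b.z) == 0:
        raise ValidationError("zero-variance tetranucleotide profile")
    return float(np.corrcoef(a.z, b.z)[0, 1])


def tetra_matrix(genomes: list[GenomeRecord]) -> RelatednessMatrix:
    profiles = [tetra_profile(g) for g in genomes]
    n = len(profiles)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = tetra_correlation(profiles[i], profiles[j])
    return RelatednessMatrix([g.id for g in genomes], values,
                             scale="similarity_percent", kind="TETRA")


# ---------------------------------------------------------------------------
# Scale conversion
# ---------------------------------------------------------------------------

def similarity_to_distance(m: RelatednessMatrix) -> RelatednessMatrix:
    """Convert percent similarity to distance: d = 100 - s, diagonal 0.

    Applies to ANIb and dDDH percentage matrices; clustering thresholds
    stated on the similarity scale map to T = 100 - threshold.
    """
    if m.scale != "similarity_percent" or m.kind == "TETRA":
        raise ValidationError("expected a percent-similarity matrix")
    values = 100.0 - m.values
    np.fill_diagonal(values, 0.0)
    return RelatednessMatrix(m.ids, values, scale="distance", kind=m.kind)


def distance_to_similarity(m: RelatednessMatrix) -> RelatednessMatrix:
    if m.scale != "distance":
        raise ValidationError("expected a distance matrix")
    values = 100.0 - m.values
    np.fill_diagonal(values, 100.0)
    return RelatednessMatrix(m.ids, values, scale="similarity_percent", kind=m.kind)
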