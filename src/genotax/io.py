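"""Readers and writers for genome FASTA, square relatedness matrices,
partitions and Newick trees.

All readers validate strictly and raise :class:`ValidationError` on
malformed input instead of silently coercing.  Matrices are kept on the
scale they were produced on (`similarity_percent` or `distance`) and carry
the index kind (ANIb, TETRA, dDDH, GBDP) so downstream code can check it
is being fed the right thing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ValidationError",
    "GenomeRecord",
    "RelatednessMatrix",
    "Partition",
    "read_fasta",
    "write_fasta",
    "read_matrix",
    "write_matrix",
    "symmetrize",
    "read_partition",
    "write_partition",
    "write_newick",
    "xlsx_sheet_to_tsv",
    "normalize_id",
]

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

_SCALES = ("similarity_percent", "distance")
_KINDS = ("ANIb", "TETRA", "dDDH", "GBDP", "generic")


class ValidationError(ValueError):
    """Raised when an input file or matrix violates its contract."""


def normalize_id(raw: str) -> str:
    """Normalize a strain identifier: strip, collapse whitespace to '_'.

    Case is preserved because strain names are case-sensitive labels
    (e.g. ``Pf-5`` vs ``pf-5`` would be different strains).
    """
    token = re.sub(r"\s+", "_", raw.strip())
    if not token:
        raise ValidationError("empty identifier")
    return token


@dataclass
class GenomeRecord:
    """A genome or proteome: an identifier plus an ordered set of sequences.

    Parameters
    ----------
    id :
        Unique token identifying the strain.
    sequences :
        Ordered ``(name, residues)`` pairs; residues are upper-case and must
        come from a single alphabet (nucleotide ``ACGTN`` or amino acid).
    alphabet :
        ``"nucleotide"`` or ``"protein"``.
    group :
        Optional higher-level affiliation label (e.g. a phylogenomic group).
    """

    id: str
    sequences: list[tuple[str, str]]
    alphabet: str = "nucleotide"
    group: str | None = None

    def __post_init__(self) -> None:
        self.id = normalize_id(self.id)
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValidationError(f"unknown alphabet {self.alphabet!r}")
        allowed = NUCLEOTIDE_ALPHABET if self.alphabet == "nucleotide" else PROTEIN_ALPHABET
        seen: set[str] = set()
        cleaned: list[tuple[str, str]] = []
        for name, seq in self.sequences:
            if name in seen:
                raise ValidationError(f"duplicate sequence name {name!r} in {self.id}")
            seen.add(name)
            if not seq:
                raise ValidationError(f"empty sequence {name!r} in {self.id}")
            seq = seq.upper()
            bad = set(seq) - allowed
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise ValidationError(
                    f"illegal residue {seq[pos]!r} at position {pos} of {name!r} ({self.id})"
                )
            cleaned.append((name, seq))
        if not cleaned:
            raise ValidationError(f"genome {self.id} has no sequences")
        self.sequences = cleaned

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.sequences)

    def concatenated(self) -> str:
        return "".join(s for _, s in self.sequences)


class RelatednessMatrix:
    """Square matrix of pairwise genome relatedness values.

    Stores reciprocal (possibly asymmetric) values exactly as read; use
    :func:`symmetrize` before clustering or tree building.

    Attributes
    ----------
    ids : list of str
        Ordered genome identifiers labelling rows and columns.
    values : (n, n) ndarray
        Pairwise entries; NaN marks a missing cell.
    scale : {"similarity_percent", "distance"}
    kind : {"ANIb", "TETRA", "dDDH", "GBDP", "generic"}
    """

    def __init__(self, ids: Sequence[str], values: np.ndarray,
                 scale: str = "similarity_percent", kind: str = "generic") -> None:
        ids = [normalize_id(i) for i in ids]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate identifiers in matrix")
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValidationError(f"matrix must be square, got shape {values.shape}")
        if values.shape[0] != len(ids):
            raise ValidationError("id count does not match matrix dimension")
        if scale not in _SCALES:
            raise ValidationError(f"unknown scale {scale!r}")
        if kind not in _KINDS:
            raise ValidationError(f"unknown kind {kind!r}")
        finite = values[np.isfinite(values)]
        if scale == "similarity_percent" and kind != "TETRA":
            if finite.size and (finite.min() < 0 or finite.max() > 100):
                raise ValidationError("similarity values must lie in [0, 100]")
        if kind == "TETRA":
            if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
                raise ValidationError("TETRA correlations must lie in [-1, 1]")
        self.ids = list(ids)
        self.values = values
        self.scale = scale
        self.kind = kind
        self._index = {g: i for i, g in enumerate(self.ids)}

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    @property
    def diagonal_identity(self) -> float:
        if self.kind == "TETRA":
            return 1.0
        return 100.0 if self.scale == "similarity_percent" else 0.0

    def max_asymmetry(self) -> float:
        """Largest |v_ij - v_ji| over all pairs (NaN-aware)."""
        diff = np.abs(self.values - self.values.T)
        diff = diff[np.isfinite(diff)]
        return float(diff.max()) if diff.size else 0.0

    def is_symmetric(self, tol: float = 0.0) -> bool:
        return self.max_asymmetry() <= tol

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def submatrix(self, ids: Sequence[str]) -> "RelatednessMatrix":
        idx = [self._index[g] for g in ids]
        return RelatednessMatrix([self.ids[i] for i in idx],
                                 self.values[np.ix_(idx, idx)],
                                 scale=self.scale, kind=self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def copy(self) -> "RelatednessMatrix":
        return RelatednessMatrix(self.ids, self.values.copy(), self.scale, self.kind)

    def drop_missing(self) -> "RelatednessMatrix":
        """Drop genomes involved in missing cells (greedy, most-missing first)."""
        vals = self.values.copy()
        keep = list(range(len(self.ids)))
        while True:
            sub = vals[np.ix_(keep, keep)]
            miss = np.isnan(sub).sum(axis=0) + np.isnan(sub).sum(axis=1)
            if miss.max(initial=0) == 0:
                break
            keep.pop(int(np.argmax(miss)))
        return self.submatrix([self.ids[i] for i in keep])


class Partition:
    """Assignment of genome identifiers to cluster labels.

    Labels are kept as given; :meth:`canonical` renumbers clusters 1..k by
    first appearance so that partitions can be compared structurally.
    """

    def __init__(self, assignment: Mapping[str, str]) -> None:
        if not assignment:
            raise ValidationError("empty partition")
        self.assignment = {normalize_id(g): str(l) for g, l in assignment.items()}
        for g, l in self.assignment.items():
            if not l:
                raise ValidationError(f"empty cluster label for {g!r}")

    @property
    def ids(self) -> list[str]:
        return list(self.assignment)

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for l in self.assignment.values():
            seen.setdefault(l)
        return list(seen)

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def blocks(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, l in self.assignment.items():
            out.setdefault(l, []).append(g)
        return out

    def canonical(self) -> "Partition":
        remap: dict[str, str] = {}
        new: dict[str, str] = {}
        for g, l in self.assignment.items():
            if l not in remap:
                remap[l] = str(len(remap) + 1)
            new[g] = remap[l]
        return Partition(new)

    def restrict(self, ids: Iterable[str]) -> "Partition":
        return Partition({g: self.assignment[g] for g in ids})

    def __eq__(self, other: object) -> bool:  # structural equality
        if not isinstance(other, Partition):
            return NotImplemented
        a, b = self.canonical().assignment, other.canonical().assignment
        return a == b

    def __len__(self) -> int:
        return len(self.assignment)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "nucleotide",
               record_id: str | None = None, group: str | None = None) -> GenomeRecord:
    """Read one FASTA file into a single :class:`GenomeRecord`.

    All sequences in the file become contigs (nucleotide) or proteins
    (protein) of one record; the record id defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    seqs: list[tuple[str, str]] = []
    names: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in names:
            raise ValidationError(f"duplicate sequence name {rec.id!r} in {path.name}")
        names.add(rec.id)
        seqs.append((rec.id, str(rec.seq)))
    if not seqs:
        raise ValidationError(f"empty or non-FASTA file: {path}")
    return GenomeRecord(record_id or path.stem, seqs, alphabet=alphabet, group=group)


def read_fasta_dir(directory: str | Path, alphabet: str = "nucleotide",
                   pattern: str = "*.fasta") -> list[GenomeRecord]:
    """Read every matching FASTA in a directory, one genome per file."""
    directory = Path(directory)
    paths = sorted(directory.glob(pattern)) or sorted(directory.glob("*.fa")) \
        or sorted(directory.glob("*.fna")) or sorted(directory.glob("*.faa"))
    if not paths:
        raise ValidationError(f"no FASTA files in {directory}")
    return [read_fasta(p, alphabet=alphabet) for p in paths]


def write_fasta(record: GenomeRecord, path: str | Path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in record.sequences]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_matrix(path: str | Path, scale: str = "similarity_percent",
                kind: str = "generic", on_missing: str = "keep") -> RelatednessMatrix:
    """Read a square labelled matrix from delimited text (TSV or CSV).

    First row and first column carry identifiers and must agree in content
    and order.  Empty cells or the token ``NA`` become NaN; ``on_missing``
    is ``keep`` (default), ``drop`` (remove offending genomes) or ``error``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    sep = _sniff_delimiter(first)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", "na", ""])
    rows = [normalize_id(str(i)) for i in df.index]
    cols = [normalize_id(str(c)) for c in df.columns]
    if len(rows) != len(cols):
        raise ValidationError(f"matrix not square: {len(rows)} rows vs {len(cols)} columns")
    if rows != cols:
        raise ValidationError("row labels do not match column labels")
    values = df.to_numpy(dtype=float)
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("non-numeric cell in matrix")
    m = RelatednessMatrix(rows, values, scale=scale, kind=kind)
    if m.has_missing():
        if on_missing == "error":
            raise ValidationError(f"missing cells in {path.name}")
        if on_missing == "drop":
            m = m.drop_missing()
    return m


def write_matrix(m: RelatednessMatrix, path: str | Path, sep: str = "\t") -> None:
    m.to_frame().to_csv(path, sep=sep, na_rep="NA")


def symmetrize(m: RelatednessMatrix, method: str = "mean") -> RelatednessMatrix:
    """Collapse reciprocal values: v_ij = v_ji = method(v_ij, v_ji).

    The diagonal is forced to the scale identity (100 for similarity, 0 for
    distance, 1 for TETRA).  NaN on one side adopts the other side's value.
    """
    v = m.values
    if method == "mean":
        with np.errstate(invalid="ignore"):
            out = np.where(np.isnan(v), v.T, np.where(np.isnan(v.T), v, (v + v.T) / 2.0))
    elif method == "min":
        out = np.fmin(v, v.T)
    elif method == "max":
        out = np.fmax(v, v.T)
    else:
        raise ValidationError(f"unknown symmetrization method {method!r}")
    out = out.copy()
    np.fill_diagonal(out, m.diagonal_identity)
    return RelatednessMatrix(m.ids, out, scale=m.scale, kind=m.kind)


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------

def read_partition(path: str | Path) -> Partition:
    """Read a two-column delimited id → cluster-label file."""
    path = Path(path)
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(",") if "," in line else line.split()
            if len(parts) < 2 or not parts[1].strip():
                raise ValidationError(f"{path.name}:{lineno}: expected 'id<sep>label'")
            gid, label = normalize_id(parts[0]), parts[1].strip()
            if gid in assignment and assignment[gid] != label:
                raise ValidationError(
                    f"{path.name}:{lineno}: {gid!r} assigned to both "
                    f"{assignment[gid]!r} and {label!r}")
            assignment[gid] = label
    if not assignment:
        raise ValidationError(f"no assignments in {path}")
    return Partition(assignment)


def write_partition(p: Partition, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g, l in p.assignment.items():
            fh.write(f"{g}\t{l}\n")


def write_newick(newick: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip() + "\n")


# ---------------------------------------------------------------------------
# Supplementary-workbook conversion
# ---------------------------------------------------------------------------

def xlsx_sheet_to_tsv(xlsx_path: str | Path, tsv_path: str | Path,
                      sheet: str | int = 0) -> None:
    """Export one sheet of an XLSX workbook to TSV.

    Convenience for converting supplementary similarity workbooks into the
    delimited-text dialect the runtime readers use; XLSX itself is never a
    runtime format.
    """
    df = pd.read_excel(xlsx_path, sheet_name=sheet, index_col=0)
    df.to_csv(tsv_path, sep="\t")
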