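"""Alignment and sample-metadata handling for mtDNA cohort analyses.

This module owns the input side of the pipeline: reading a pre-aligned FASTA
together with a tab-separated metadata table (``id  group  time_gen  year``),
classifying alignment columns (segregating / singleton / parsimony-informative),
collapsing sequences into haplotypes, and flagging haplotypes that are so
divergent from the rest of a comparison set that they likely belong to a
different population and should be excluded from diversity statistics and
demographic inference.

Sequences are stored as a rectangular ``uint8`` matrix of ASCII codes.  Only
``A``, ``C``, ``G``, ``T`` are treated as called bases; gaps (``-``) and any
IUPAC ambiguity code count as missing.  The default "complete deletion" rule
(DnaSP-style) drops every column containing a missing state in any retained
sequence before any statistic or haplotype definition is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Alignment",
    "SiteClassification",
    "HaplotypeTable",
    "read_alignment",
    "read_metadata",
    "read_fasta",
    "classify_sites",
    "collapse_haplotypes",
    "flag_divergent_haplotypes",
    "pairwise_differences",
    "write_fasta",
    "write_metadata",
]

_BASES = b"ACGT"
_BASE_CODES = np.frombuffer(_BASES, dtype=np.uint8)

METADATA_COLUMNS = ("id", "group", "time_gen")


class AlignmentError(ValueError):
    """Raised when an alignment or its metadata fails validation."""


@dataclass
class Alignment:
    """A rectangular multiple-sequence alignment.

    Parameters
    ----------
    ids
        Unique sequence identifiers, one per row.
    matrix
        ``(n, L)`` uint8 array of uppercase ASCII codes (``U`` mapped to ``T``).
    """

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-dimensional")
        if len(self.ids) != self.matrix.shape[0]:
            raise AlignmentError(
                f"{len(self.ids)} ids but {self.matrix.shape[0]} sequence rows"
            )
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        if self.n < 1:
            raise AlignmentError("alignment must contain at least one sequence")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    def called_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` mask of unambiguously called bases (A/C/G/T)."""
        return np.isin(self.matrix, _BASE_CODES)

    def usable_columns(self) -> np.ndarray:
        """Columns free of gaps/ambiguity in every row (complete deletion)."""
        return self.called_mask().all(axis=0)

    def index_of(self, seq_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.ids)}
        try:
            return np.array([lookup[s] for s in seq_ids], dtype=int)
        except KeyError as exc:
            raise AlignmentError(f"unknown sequence id {exc.args[0]!r}") from exc

    def subset(self, seq_ids) -> "Alignment":
        idx = self.index_of(seq_ids)
        return Alignment(list(seq_ids), self.matrix[idx])

    def take(self, rows: np.ndarray) -> "Alignment":
        rows = np.asarray(rows, dtype=int)
        return Alignment([self.ids[i] for i in rows], self.matrix[rows])

    def sequences(self) -> list[str]:
        return [row.tobytes().decode("ascii") for row in self.matrix]


@dataclass
class SiteClassification:
    """Per-column categories of an alignment under a deletion rule.

    ``category`` holds one code per alignment column: ``"excluded"``,
    ``"monomorphic"``, ``"singleton"`` or ``"informative"``.  Counts refer to
    usable columns; every segregating column is either a singleton column
    (all minor alleles carried by exactly one sequence each) or
    parsimony-informative (at least two alleles present in >= 2 sequences),
    so ``S == singletons + parsimony_informative``.
    """

    usable: np.ndarray
    category: np.ndarray
    S: int
    singletons: int
    parsimony_informative: int
    monomorphic: int
    deletion_rule: str

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())

    def segregating_positions(self) -> np.ndarray:
        """1-based alignment positions of segregating columns."""
        return np.flatnonzero(np.isin(self.category, ("singleton", "informative"))) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": np.arange(1, len(self.category) + 1), "category": self.category}
        )


@dataclass
class HaplotypeTable:
    """Sequences collapsed to haplotypes over usable columns.

    ``assignments`` maps each sequence id to its haplotype label; haplotypes
    are numbered ``Hap_1, Hap_2, ...`` by first occurrence in the alignment.
    """

    labels: list[str]
    representatives: Alignment
    counts: pd.Series
    members: dict[str, list[str]]
    assignments: pd.Series
    usable: np.ndarray

    @property
    def n_haplotypes(self) -> int:
        return len(self.labels)

    def group_counts(self, groups: pd.Series) -> pd.DataFrame:
        """Haplotype x group count table from a per-sequence group Series."""
        df = pd.DataFrame(
            {"hap": self.assignments, "group": groups.reindex(self.assignments.index)}
        )
        table = df.groupby(["hap", "group"], observed=True).size().unstack(fill_value=0)
        return table.reindex(self.labels, fill_value=0)


def _clean_matrix(mat: np.ndarray) -> np.ndarray:
    """Uppercase and map U->T in place-safe fashion."""
    mat = mat.copy()
    lower = (mat >= ord("a")) & (mat <= ord("z"))
    mat[lower] -= 32
    mat[mat == ord("U")] = ord("T")
    return mat


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file; raise naming the offending id if ragged."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        rows.append(np.frombuffer(str(record.seq).encode("ascii"), dtype=np.uint8))
    if not ids:
        raise AlignmentError(f"no sequences found in {path}")
    L = len(rows[0])
    for sid, row in zip(ids, rows):
        if len(row) != L:
            raise AlignmentError(
                f"sequence {sid!r} has length {len(row)}, expected {L}: "
                "input must be a rectangular alignment"
            )
    return Alignment(ids, _clean_matrix(np.vstack(rows)))


def read_metadata(path) -> pd.DataFrame:
    """Read the tab-separated sample table (``id  group  time_gen  [year]``)."""
    meta = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str, "group": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise AlignmentError(f"metadata is missing required columns: {missing}")
    if meta["id"].duplicated().any():
        dupes = meta.loc[meta["id"].duplicated(), "id"].tolist()
        raise AlignmentError(f"duplicate metadata ids: {dupes}")
    meta = meta.set_index("id")
    times = meta["time_gen"].astype(float)
    if not np.isfinite(times).all() or (times < 0).any():
        raise AlignmentError("sampling times must be finite and >= 0")
    meta["time_gen"] = times
    return meta


def read_alignment(fasta_path, metadata_path) -> tuple[Alignment, pd.DataFrame]:
    """Read and cross-validate an alignment and its cohort table.

    Every sequence id in the FASTA must have exactly one metadata row; the
    returned cohort table is reindexed to alignment order.
    """
    aln = read_fasta(fasta_path)
    meta = read_metadata(metadata_path)
    absent = [s for s in aln.ids if s not in meta.index]
    if absent:
        raise AlignmentError(f"alignment ids missing from metadata: {absent}")
    return aln, meta.loc[aln.ids]


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.sequences()):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.reset_index().rename(columns={"index": "id"}).to_csv(path, sep="\t", index=False)


def _allele_counts(matrix: np.ndarray, row_mask=None) -> np.ndarray:
    """``(L, 4)`` counts of A/C/G/T per column over the selected rows."""
    rows = matrix if row_mask is None else matrix[row_mask]
    return np.stack([(rows == code).sum(axis=0) for code in _BASE_CODES], axis=1)


def classify_sites(aln: Alignment, deletion_rule: str = "complete") -> SiteClassification:
    """Classify every alignment column.

    Under ``"complete"`` deletion a column is usable only when all rows carry
    a called base; under ``"pairwise"`` any column with >= 2 called bases is
    usable and alleles are counted among called rows only.
    """
    if aln.n < 2:
        raise AlignmentError("site classification requires at least 2 sequences")
    called = aln.called_mask()
    if deletion_rule == "complete":
        usable = called.all(axis=0)
        counts = _allele_counts(aln.matrix)
        counts[~usable] = 0
    elif deletion_rule == "pairwise":
        usable = called.sum(axis=0) >= 2
        masked = np.where(called, aln.matrix, 0)
        counts = np.stack([(masked == code).sum(axis=0) for code in _BASE_CODES], axis=1)
        counts[~usable] = 0
    else:
        raise ValueError(f"unknown deletion rule {deletion_rule!r}")

    n_alleles = (counts > 0).sum(axis=1)
    segregating = usable & (n_alleles >= 2)
    informative = usable & ((counts >= 2).sum(axis=1) >= 2) & segregating
    singleton = segregating & ~informative

    category = np.full(aln.L, "excluded", dtype=object)
    category[usable] = "monomorphic"
    category[singleton] = "singleton"
    category[informative] = "informative"

    return SiteClassification(
        usable=usable,
        category=category,
        S=int(segregating.sum()),
        singletons=int(singleton.sum()),
        parsimony_informative=int(informative.sum()),
        monomorphic=int((usable & (n_alleles <= 1)).sum()),
        deletion_rule=deletion_rule,
    )


def collapse_haplotypes(aln: Alignment, deletion_rule: str = "complete") -> HaplotypeTable:
    """Collapse sequences into haplotypes (identity over usable columns).

    Haplotypes are numbered deterministically by first occurrence.
    """
    if deletion_rule != "complete":
        raise ValueError("haplotype collapsing is defined under complete deletion only")
    usable = aln.usable_columns()
    sub = np.ascontiguousarray(aln.matrix[:, usable])
    # first-occurrence grouping of identical rows
    seen: dict[bytes, int] = {}
    hap_of_row = np.empty(aln.n, dtype=int)
    first_rows: list[int] = []
    for i in range(aln.n):
        key = sub[i].tobytes()
        if key not in seen:
            seen[key] = len(first_rows)
            first_rows.append(i)
        hap_of_row[i] = seen[key]

    labels = [f"Hap_{h + 1}" for h in range(len(first_rows))]
    reps = Alignment([labels[k] for k in range(len(first_rows))], aln.matrix[first_rows])
    assignments = pd.Series([labels[h] for h in hap_of_row], index=aln.ids, name="hap")
    counts = pd.Series(np.bincount(hap_of_row), index=labels, name="count")
    members = {
        lab: [aln.ids[i] for i in np.flatnonzero(hap_of_row == h)]
        for h, lab in enumerate(labels)
    }
    return HaplotypeTable(labels, reps, counts, members, assignments, usable)


def pairwise_differences(matrix: np.ndarray, columns=None) -> np.ndarray:
    """Symmetric ``(n, n)`` matrix of nucleotide differences over ``columns``.

    ``columns`` defaults to all columns of ``matrix``; pass a usable-column
    mask (or index array) to honour a deletion rule.
    """
    sub = matrix if columns is None else matrix[:, columns]
    n = sub.shape[0]
    # restrict to variable columns; constant columns contribute nothing
    variable = (sub != sub[0]).any(axis=0)
    sub = np.ascontiguousarray(sub[:, variable])
    diff = np.zeros((n, n), dtype=np.int64)
    if sub.shape[1]:
        neq = sub[:, None, :] != sub[None, :, :]
        diff = neq.sum(axis=2, dtype=np.int64)
    return diff


def flag_divergent_haplotypes(
    haplotypes: HaplotypeTable,
    min_steps: int = 10,
    comparison_labels=None,
) -> list[str]:
    """Flag haplotypes >= ``min_steps`` differences from *every* other haplotype.

    ``comparison_labels`` restricts the comparison set (e.g. the haplotypes of
    one regional lineage); by default all haplotypes in the table are used.
    Such outliers likely belong to an unsampled population and are excluded
    from diversity statistics and demographic inference downstream.
    """
    labels = list(haplotypes.labels if comparison_labels is None else comparison_labels)
    if len(labels) < 2:
        raise AlignmentError("divergence flagging needs >= 2 haplotypes to compare")
    reps = haplotypes.representatives.subset(labels)
    dist = pairwise_differences(reps.matrix, haplotypes.usable)
    np.fill_diagonal(dist, np.iinfo(np.int64).max)
    flagged = [labels[i] for i in range(len(labels)) if dist[i].min() >= min_steps]
    return flagged
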