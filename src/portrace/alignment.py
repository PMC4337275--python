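"""Alignment column analytics: core trimming, logo preparation, sequence
logos, and residue-class similarity.

The similarity measure follows the chemical residue classes used when
comparing POR paralogs across lineages: polar (GSTYC), neutral amide (QN),
positively charged (KRH), negatively charged (DE), and hydrophobic
(AVLIPWFM).  Two aligned residues are "similar" when they fall in the same
class; percentages are computed over columns where both sequences carry a
residue, so signal peptides, transit peptides and lineage-specific
extensions contribute nothing once trimmed or gapped out.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .records import AMINO_ACIDS, InputError

logger = logging.getLogger(__name__)

GAP = "-"

#: Chemical residue classes used for class-based similarity.
RESIDUE_CLASSES: dict[str, str] = {
    "polar": "GSTYC",
    "neutral": "QN",
    "positive": "KRH",
    "negative": "DE",
    "hydrophobic": "AVLIPWFM",
}

#: The identity partition: every residue in its own class.  Similarity under
#: this partition equals percent identity.
IDENTITY_CLASSES: dict[str, str] = {aa: aa for aa in AMINO_ACIDS}

_ALLOWED = frozenset(AMINO_ACIDS + "X" + GAP)


def _class_lookup(classes: Mapping[str, str]) -> dict[str, int]:
    lookup: dict[str, int] = {}
    for idx, members in enumerate(classes.values()):
        for aa in members:
            if aa in lookup:
                raise InputError(f"residue {aa!r} appears in more than one class")
            lookup[aa] = idx
    missing = set(AMINO_ACIDS) - set(lookup)
    if missing:
        raise InputError(f"residue classes do not cover {sorted(missing)}")
    return lookup


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment over residues, ``X`` and gaps."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise InputError("alignment requires at least one row")
        if len(self.ids) != len(self.rows):
            raise InputError("ids and rows differ in length")
        ncol = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != ncol:
                raise InputError(
                    f"row {sid!r} has length {len(row)}, expected {ncol}"
                )
            bad = set(row) - _ALLOWED
            if bad:
                raise InputError(
                    f"row {sid!r} contains invalid characters: {sorted(bad)}"
                )
        if len(set(self.ids)) != len(self.ids):
            raise InputError("alignment row ids must be unique")

    @property
    def ncol(self) -> int:
        return len(self.rows[0])

    @property
    def nrow(self) -> int:
        return len(self.rows)

    def row(self, sid: str) -> str:
        try:
            return self.rows[self.ids.index(sid)]
        except ValueError:
            raise KeyError(f"no alignment row with id {sid!r}") from None

    def to_array(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows], dtype="U1")

    @classmethod
    def from_records(cls, ids: Sequence[str], rows: Sequence[str]) -> "Alignment":
        return cls(tuple(ids), tuple(str(r).upper() for r in rows))

    @classmethod
    def from_fasta(cls, source: str | Path | TextIO) -> "Alignment":
        records = list(SeqIO.parse(source, "fasta"))
        if not records:
            raise InputError("empty alignment FASTA")
        return cls.from_records(
            [r.id for r in records], [str(r.seq) for r in records]
        )

    def to_fasta(self, dest: str | Path | TextIO) -> None:
        recs = [
            _BioSeqRecord(Seq(row), id=sid, description="")
            for sid, row in zip(self.ids, self.rows)
        ]
        if isinstance(dest, (str, Path)):
            with open(dest, "w") as fh:
                SeqIO.write(recs, fh, "fasta")
        else:
            SeqIO.write(recs, dest, "fasta")


@dataclass(frozen=True)
class LogoMatrix:
    """Per-column residue frequencies and information content (bits).

    ``frequencies`` is an ``ncol x 20`` table (columns ordered as
    :data:`AMINO_ACIDS`); gaps and ``X`` are excluded from the denominator.
    ``information_content`` is ``log2(20)`` minus the Shannon entropy of the
    column's frequency vector; empty columns carry zero information.
    """

    frequencies: pd.DataFrame
    information_content: np.ndarray
    n_effective: np.ndarray

    def to_tsv(self, dest: str | Path | TextIO) -> None:
        long = self.frequencies.stack().rename("frequency").reset_index()
        long.columns = ["column", "residue", "frequency"]
        long["information_content"] = long["column"].map(
            dict(zip(self.frequencies.index, self.information_content))
        )
        long.to_csv(dest, sep="\t", index=False)


@dataclass(frozen=True)
class SimilarityResult:
    """Pairwise percent similarity between (or within) two id groups."""

    group_a_ids: tuple[str, ...]
    group_b_ids: tuple[str, ...]
    pairwise: pd.DataFrame  # percent in [0, 100]; NaN where undefined
    mean_percent: float


def trim_core(
    aln: Alignment,
    max_gap_fraction: float = 0.0,
    max_x_fraction: float = 0.0,
) -> tuple[Alignment, list[int]]:
    """Keep only columns whose gap and ``X`` fractions are within bounds.

    With the strict defaults this removes every column containing a gap or
    an undetermined residue, i.e. it reduces the alignment to its fully
    determined conserved core.  Returns the trimmed alignment and the kept
    1-based column indices (strictly increasing).
    """
    for name, value in (("max_gap_fraction", max_gap_fraction),
                        ("max_x_fraction", max_x_fraction)):
        if not (0.0 <= value <= 1.0):
            raise InputError(f"{name} must lie in [0, 1]")
    arr = aln.to_array()
    n = arr.shape[0]
    gap_frac = (arr == GAP).sum(axis=0) / n
    x_frac = (arr == "X").sum(axis=0) / n
    keep = (gap_frac <= max_gap_fraction) & (x_frac <= max_x_fraction)
    kept_columns = [i + 1 for i in range(aln.ncol) if keep[i]]
    rows = ["".join(arr[r, keep]) for r in range(n)]
    if not kept_columns:
        rows = ["" for _ in rows]
    trimmed = Alignment(aln.ids, tuple(rows)) if kept_columns else _empty_like(aln)
    return trimmed, kept_columns


def _empty_like(aln: Alignment) -> Alignment:
    # an Alignment must have ncol >= 0; zero columns is representable
    object_rows = tuple("" for _ in aln.rows)
    return Alignment(aln.ids, object_rows)


def logo_prune(aln: Alignment, max_gap_rows: int = 2) -> Alignment:
    """Drop insertion columns carried by at most ``max_gap_rows`` sequences.

    A column is removed when the number of rows bearing a residue (anything
    other than a gap) is ``<= max_gap_rows``; this is the usual preparation
    step before drawing a sequence logo, removing rare insertions while
    never touching a column in which more sequences carry residues.
    """
    if max_gap_rows < 0:
        raise InputError("max_gap_rows must be >= 0")
    arr = aln.to_array()
    occupancy = (arr != GAP).sum(axis=0)
    # only insertion columns (some row gapped) are candidates for removal
    keep = (occupancy > max_gap_rows) | (occupancy == aln.nrow)
    rows = tuple("".join(arr[r, keep]) for r in range(aln.nrow))
    if not keep.any():
        return _empty_like(aln)
    return Alignment(aln.ids, rows)


def compute_logo(aln: Alignment) -> LogoMatrix:
    """Column residue frequencies and information content in bits."""
    arr = aln.to_array()
    ncol = aln.ncol
    counts = np.zeros((ncol, len(AMINO_ACIDS)), dtype=float)
    for j, aa in enumerate(AMINO_ACIDS):
        counts[:, j] = (arr == aa).sum(axis=0)
    n_eff = counts.sum(axis=1)
    freqs = np.zeros_like(counts)
    nz = n_eff > 0
    freqs[nz] = counts[nz] / n_eff[nz, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = np.where(nz, math.log2(len(AMINO_ACIDS)) - entropy, 0.0)
    frame = pd.DataFrame(
        freqs, index=pd.RangeIndex(1, ncol + 1, name="column"),
        columns=list(AMINO_ACIDS),
    )
    return LogoMatrix(frame, ic, n_eff.astype(int))


def group_similarity(
    aln: Alignment,
    group_a: Sequence[str],
    group_b: Sequence[str] | None = None,
    classes: Mapping[str, str] | None = None,
) -> SimilarityResult:
    """Class-based percent similarity between two groups of aligned rows.

    The pairwise similarity of two rows is ``100 x (columns where both
    residues fall in the same class) / (columns where both rows carry a
    residue)``.  ``X`` is treated like a gap (excluded from both counts).
    When ``group_b`` is omitted the comparison is within ``group_a`` and the
    mean is taken over off-diagonal pairs; otherwise over all pairs.  Pairs
    with no mutually occupied column are undefined (NaN) and excluded from
    the mean with a warning.
    """
    within = group_b is None
    group_b = list(group_a) if within else list(group_b)
    group_a = list(group_a)
    lookup = _class_lookup(classes if classes is not None else RESIDUE_CLASSES)

    def encode(sid: str) -> np.ndarray:
        return np.array([lookup.get(ch, -1) for ch in aln.row(sid)], dtype=int)

    enc_a = {sid: encode(sid) for sid in group_a}
    enc_b = {sid: encode(sid) for sid in group_b}

    mat = np.full((len(group_a), len(group_b)), np.nan)
    undefined = 0
    for i, sa in enumerate(group_a):
        for j, sb in enumerate(group_b):
            ea, eb = enc_a[sa], enc_b[sb]
            both = (ea >= 0) & (eb >= 0)
            denom = int(both.sum())
            if denom == 0:
                undefined += 1
                continue
            same = int(((ea == eb) & both).sum())
            mat[i, j] = 100.0 * same / denom
    if undefined:
        logger.warning(
            "group_similarity: %d pair(s) share no mutually occupied column "
            "and were excluded from the mean", undefined,
        )
    frame = pd.DataFrame(mat, index=group_a, columns=group_b)
    if within:
        mask = ~np.eye(len(group_a), dtype=bool)
        vals = mat[mask]
    else:
        vals = mat.ravel()
    vals = vals[~np.isnan(vals)]
    mean = float(vals.mean()) if vals.size else float("nan")
    return SimilarityResult(tuple(group_a), tuple(group_b), frame, mean)


def pairwise_distance_matrix(
    aln: Alignment, ids: Sequence[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """p-distance matrix (1 - identity over mutually occupied columns).

    Suitable as input to the neighbor-joining stand-in builder.  Pairs with
    no shared columns get the maximal distance 1.0.
    """
    labels = list(ids) if ids is not None else list(aln.ids)
    enc = {}
    for sid in labels:
        row = aln.row(sid)
        enc[sid] = np.array(
            [AMINO_ACIDS.index(c) if c in AMINO_ACIDS else -1 for c in row],
            dtype=int,
        )
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ea, eb = enc[labels[i]], enc[labels[j]]
            both = (ea >= 0) & (eb >= 0)
            denom = int(both.sum())
            if denom == 0:
                d = 1.0
            else:
                d = 1.0 - ((ea == eb) & both).sum() / denom
            dist[i, j] = dist[j, i] = d
    return labels, dist
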