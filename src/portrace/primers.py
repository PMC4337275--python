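"""Degenerate PCR primer design from conserved protein alignment blocks.

To amplify *por* genes across widely diverged algal taxa, primers are
reverse-translated from conserved amino-acid windows of a protein
alignment.  Each codon position carries the IUPAC code covering the union
of nucleotides used by every codon of every residue observed at that
alignment column, so any observed residue can be encoded by some expansion
of the primer.  Cores are flanked 5' with a fixed non-degenerate tail
(conventionally 23 bp) that provides a clean annealing site for sequencing
primers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .alignment import Alignment, GAP
from .records import ConfigurationError, InputError

#: IUPAC code -> set of plain nucleotides it covers.
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(expansion) for code, expansion in ambiguous_dna_values.items()
}
_SET_TO_CODE: dict[frozenset[str], str] = {
    v: k for k, v in IUPAC_SETS.items() if k != "X"
}

#: residue -> tuple of codons (standard genetic code)
CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    CODONS.setdefault(_aa, ())
    CODONS[_aa] += (_codon,)


class PrimerDesignError(ValueError):
    """Raised when a requested primer cannot be built."""


@dataclass(frozen=True)
class DegeneratePrimer:
    """A degenerate primer: IUPAC core, degeneracy, window, and 5' tail.

    ``iupac`` is already oriented (reverse primers are reverse-complemented);
    ``sequence`` is the full synthesizable oligo, tail first.
    """

    iupac: str
    degeneracy: int
    aa_window: tuple[int, int]  # (1-based alignment start column, length)
    orientation: str
    tail: str = ""

    @property
    def sequence(self) -> str:
        return self.tail + self.iupac

    def __len__(self) -> int:
        return len(self.sequence)


def codes_for_nucleotides(nucleotides: Iterable[str]) -> str:
    """The single IUPAC code covering a set of plain nucleotides."""
    s = frozenset(nucleotides)
    if not s <= frozenset("ACGT"):
        raise InputError(f"not plain nucleotides: {sorted(s)}")
    try:
        return _SET_TO_CODE[s]
    except KeyError:
        raise InputError(f"no IUPAC code for empty set") from None


def expand_degenerate(iupac: str) -> Iterator[str]:
    """All plain nucleotide strings covered by a degenerate string."""
    pools = []
    for code in iupac:
        if code not in IUPAC_SETS:
            raise InputError(f"unknown IUPAC code {code!r}")
        pools.append(sorted(IUPAC_SETS[code]))
    for combo in itertools.product(*pools):
        yield "".join(combo)


def degeneracy_of(iupac: str) -> int:
    d = 1
    for code in iupac:
        d *= len(IUPAC_SETS[code])
    return d


def reverse_complement(iupac: str) -> str:
    """IUPAC-aware reverse complement (an involution)."""
    return str(Seq(iupac).reverse_complement())


def _codon_union(residues: Iterable[str]) -> tuple[str, int]:
    """IUPAC codon covering all codons of all given residues."""
    position_sets: list[set[str]] = [set(), set(), set()]
    for aa in residues:
        if aa not in CODONS:
            raise PrimerDesignError(
                f"residue {aa!r} has no codons in the standard genetic code"
            )
        for codon in CODONS[aa]:
            for k in range(3):
                position_sets[k].add(codon[k])
    iupac = "".join(codes_for_nucleotides(s) for s in position_sets)
    degeneracy = 1
    for s in position_sets:
        degeneracy *= len(s)
    return iupac, degeneracy


def reverse_translate(aa_window: str) -> tuple[str, int]:
    """Reverse-translate a residue string into a degenerate IUPAC string.

    Per codon position the IUPAC code covers the union of nucleotides used
    by the residue's codons; the covering may exceed the exact codon set
    (e.g. Leu's six codons yield ``YTN``, which also expands to non-Leu
    codons).  Degeneracy is the product of per-position cardinalities.
    """
    if any(ch in (GAP, "X") for ch in aa_window):
        raise PrimerDesignError("window contains gaps or undetermined residues")
    iupac = ""
    degeneracy = 1
    for aa in aa_window:
        codon, d = _codon_union([aa])
        iupac += codon
        degeneracy *= d
    return iupac, degeneracy


#: columns with a gap fraction above this are never part of a primer window
MAX_WINDOW_GAP_FRACTION = 0.10


def find_conserved_blocks(
    aln: Alignment,
    window_aa: int = 7,
    top_k: int = 5,
    max_gap_fraction: float = MAX_WINDOW_GAP_FRACTION,
) -> list[tuple[int, float]]:
    """Rank alignment windows by mean per-column conservation.

    Conservation of a column is the frequency of its modal residue among
    non-gap, non-X entries.  Windows containing a column whose gap fraction
    exceeds ``max_gap_fraction`` (or with no residues at all) are
    disqualified.  Returns up to ``top_k`` tuples of (1-based start column,
    mean conservation), ties broken toward the smaller start.
    """
    if window_aa < 3:
        raise ConfigurationError("window_aa must be >= 3")
    if window_aa > aln.ncol:
        raise InputError(
            f"window of {window_aa} columns exceeds alignment width {aln.ncol}"
        )
    arr = aln.to_array()
    n = arr.shape[0]
    conservation = []
    qualified = []
    for j in range(aln.ncol):
        col = arr[:, j]
        residues = col[(col != GAP) & (col != "X")]
        gap_frac = (col == GAP).sum() / n
        if residues.size == 0 or gap_frac > max_gap_fraction:
            conservation.append(0.0)
            qualified.append(False)
            continue
        _, counts = _mode_counts(residues)
        conservation.append(counts / residues.size)
        qualified.append(True)
    windows = []
    for start in range(aln.ncol - window_aa + 1):
        span = slice(start, start + window_aa)
        if all(qualified[span]):
            score = sum(conservation[span]) / window_aa
            windows.append((start + 1, score))
    windows.sort(key=lambda w: (-w[1], w[0]))
    return windows[:top_k]


def _mode_counts(residues) -> tuple[str, int]:
    best_aa, best_n = "", 0
    for aa in sorted(set(residues.tolist())):
        c = int((residues == aa).sum())
        if c > best_n:
            best_aa, best_n = aa, c
    return best_aa, best_n


def build_primer(
    aln: Alignment,
    start_column: int,
    window_aa: int,
    orientation: str = "forward",
    tail: str = "",
    max_degeneracy: int = 512,
) -> DegeneratePrimer:
    """Build a degenerate primer over an alignment window.

    The degenerate core covers, per column, every residue observed in the
    alignment at that column (union of codon sets), so the primer can
    anneal to any sampled variant.  Reverse primers are IUPAC
    reverse-complemented; the tail is prepended 5' after orientation.
    """
    if orientation not in ("forward", "reverse"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    tail = tail.upper()
    if set(tail) - set("ACGT"):
        raise InputError("tail must be non-degenerate (A/C/G/T only)")
    if not (1 <= start_column and start_column + window_aa - 1 <= aln.ncol):
        raise InputError(
            f"window [{start_column}, {start_column + window_aa - 1}] outside "
            f"alignment of {aln.ncol} columns"
        )
    arr = aln.to_array()
    core = ""
    degeneracy = 1
    per_column: list[tuple[int, int]] = []
    for j in range(start_column - 1, start_column - 1 + window_aa):
        col = arr[:, j]
        residues = sorted(set(col[(col != GAP) & (col != "X")].tolist()))
        if not residues:
            raise PrimerDesignError(f"column {j + 1} has no determined residues")
        codon, d = _codon_union(residues)
        core += codon
        degeneracy *= d
        per_column.append((j + 1, d))
    if degeneracy > max_degeneracy:
        worst = sorted(per_column, key=lambda cd: -cd[1])
        detail = ", ".join(f"column {c} (x{d})" for c, d in worst if d > 4)
        raise PrimerDesignError(
            f"window degeneracy {degeneracy} exceeds cap {max_degeneracy}; "
            f"most degenerate columns: {detail or 'none above 4-fold'}"
        )
    if orientation == "reverse":
        core = reverse_complement(core)
    return DegeneratePrimer(
        iupac=core,
        degeneracy=degeneracy,
        aa_window=(start_column, window_aa),
        orientation=orientation,
        tail=tail,
    )
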