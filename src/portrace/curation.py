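"""Diagnostic-motif curation of candidate POR homologs.

POR belongs to the large short-chain dehydrogenase-reductase (SDR) family,
so sequence-search scores alone cannot separate genuine PORs from close SDR
relatives.  Curation therefore anchors three diagnostic features of the
enzyme onto each candidate by pairwise alignment to a cyanobacterial
reference POR:

* the N-terminal Rossman fold pattern ``G-x-x-x-G-x-G`` required for NADPH
  binding;
* the ``Y-x-x-x-K`` pair that coordinates the enzyme-cofactor-substrate
  complex, with the Tyr acting as the catalytic proton donor;
* the catalytic cysteine.

Candidates missing any diagnostic motif are rejected, with one tolerance:
sequences whose N-terminus is missing (typical of transcriptome-derived
fragments) are kept as fragments when the Y-x-x-x-K pair and the cysteine
are intact, because the absence of the Rossman region is then an artifact
of truncation rather than evidence of a non-POR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .records import (
    AMINO_ACIDS,
    ConfigurationError,
    InputError,
    SEQUENCE_ALPHABET,
    SequenceRecord,
)

#: Default gap scores (negative = penalty); a gap of length L costs
#: ``gap_open + (L - 1) * gap_extend``.
DEFAULT_GAP_OPEN = -11.0
DEFAULT_GAP_EXTEND = -1.0

#: Default alignment search window (residues) around each anchored motif
#: position; absorbs small indels between query and reference.
DEFAULT_WINDOW = 10

VERDICT_ACCEPT = "accept"
VERDICT_FRAGMENT = "accept_fragment"
VERDICT_REJECT = "reject"

REJECT_REASONS = ("too_short", "too_many_X", "duplicate", "motif_fail")


def default_substitution_matrix():
    """The log-odds substitution table used for reference anchoring (BLOSUM62)."""
    return substitution_matrices.load("BLOSUM62")


def simple_substitution_matrix(
    match: float = 1.0,
    mismatch: float = -1.0,
    alphabet: str = AMINO_ACIDS + "X",
):
    """A match/mismatch table, mainly useful for identity-style scoring."""
    arr = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            arr[a, b] = match if a == b else mismatch
    return arr


@dataclass(frozen=True)
class ReferenceAnchor:
    """A cyanobacterial reference POR with 1-based diagnostic coordinates.

    ``rossman_start`` points at the first Gly of the ``G-x-x-x-G-x-G``
    pattern; ``tyr_pos``/``lys_pos`` at the catalytic Tyr/Lys (exactly three
    residues apart); ``cys_pos`` at the catalytic Cys.
    """

    reference: SequenceRecord
    rossman_start: int
    tyr_pos: int
    lys_pos: int
    cys_pos: int

    def __post_init__(self) -> None:
        seq = self.reference.residues
        n = len(seq)
        for name in ("rossman_start", "tyr_pos", "lys_pos", "cys_pos"):
            pos = getattr(self, name)
            if not (1 <= pos <= n):
                raise ConfigurationError(
                    f"anchor position {name}={pos} exceeds reference length {n}"
                )
        if self.rossman_start + 6 > n:
            raise ConfigurationError(
                "Rossman pattern extends past the end of the reference"
            )
        if not self.rossman_start < self.tyr_pos:
            raise ConfigurationError("rossman_start must precede tyr_pos")
        if self.tyr_pos + 4 != self.lys_pos:
            raise ConfigurationError(
                "tyr_pos and lys_pos must bracket exactly three residues "
                f"(got tyr_pos={self.tyr_pos}, lys_pos={self.lys_pos})"
            )
        if not self.lys_pos < self.cys_pos:
            raise ConfigurationError("lys_pos must precede cys_pos")
        expect = {
            self.tyr_pos: "Y",
            self.lys_pos: "K",
            self.cys_pos: "C",
            self.rossman_start: "G",
            self.rossman_start + 4: "G",
            self.rossman_start + 6: "G",
        }
        for pos, aa in expect.items():
            if seq[pos - 1] != aa:
                raise ConfigurationError(
                    f"reference residue at position {pos} is {seq[pos - 1]!r}, "
                    f"expected {aa!r}"
                )


@dataclass(frozen=True)
class AlignedPair:
    """A global pairwise alignment of a query against the reference.

    ``column_map`` maps 1-based reference residue indices to 1-based query
    residue indices for every reference position matched to a query residue
    (gapped positions are absent).
    """

    query_aligned: str
    reference_aligned: str
    score: float
    column_map: Mapping[int, int]


@dataclass(frozen=True)
class MotifHit:
    found: bool
    position: int | None = None


@dataclass(frozen=True)
class YKHit:
    found: bool
    tyr_position: int | None = None
    lys_position: int | None = None


@dataclass(frozen=True)
class MotifReport:
    """Per-sequence outcome of the three diagnostic-motif checks."""

    seq_id: str
    rossman: MotifHit
    yk: YKHit
    cys: MotifHit
    n_truncated: bool
    verdict: str


@dataclass(frozen=True)
class RejectedReport:
    report: MotifReport
    reason: str


def _as_residues(query: SequenceRecord | str) -> tuple[str, str]:
    if isinstance(query, SequenceRecord):
        return query.id, query.residues
    residues = str(query)
    bad = set(residues) - SEQUENCE_ALPHABET
    if bad:
        raise InputError(
            f"sequence contains characters outside the accepted alphabet: "
            f"{sorted(bad)}"
        )
    return "query", residues


def align_to_reference(
    query: SequenceRecord | str,
    anchor: ReferenceAnchor | SequenceRecord | str,
    substitution_table=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignedPair:
    """Globally align ``query`` to the anchor's reference sequence.

    Returns the optimal global (Needleman-Wunsch / Gotoh) score together
    with the reference-to-query column map of the first optimal alignment
    in the aligner's deterministic enumeration order.
    """
    _, q = _as_residues(query)
    if isinstance(anchor, ReferenceAnchor):
        r = anchor.reference.residues
    else:
        _, r = _as_residues(anchor)
    if not q or not r:
        raise InputError("query and reference must be non-empty")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = (
        substitution_table if substitution_table is not None
        else default_substitution_matrix()
    )
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    try:
        result = aligner.align(q, r)
    except ValueError as exc:  # residue missing from the substitution table
        raise InputError(str(exc)) from exc
    best = result[0]
    q_blocks, r_blocks = best.aligned
    column_map: dict[int, int] = {}
    for (qs, qe), (rs, re_) in zip(q_blocks, r_blocks):
        for off in range(qe - qs):
            column_map[int(rs) + off + 1] = int(qs) + off + 1
    return AlignedPair(
        query_aligned=str(best[0]),
        reference_aligned=str(best[1]),
        score=float(best.score),
        column_map=column_map,
    )


def _expected_query_position(column_map: Mapping[int, int], ref_pos: int, qlen: int) -> int:
    """Project a reference coordinate onto the query.

    Uses the mapped column when available, otherwise offsets from the
    nearest mapped reference column (ties resolved leftward).  The result
    is clamped to the query coordinate range.
    """
    if ref_pos in column_map:
        return column_map[ref_pos]
    nearest = min(column_map, key=lambda r: (abs(r - ref_pos), r))
    pos = column_map[nearest] + (ref_pos - nearest)
    return max(1, min(qlen, pos))


def _search_near(center: int, window: int, max_start: int):
    """Yield candidate 1-based start positions by increasing distance from
    ``center`` (ties leftward)."""
    for dist in range(window + 1):
        for s in ((center - dist, center + dist) if dist else (center,)):
            if 1 <= s <= max_start:
                yield s


def screen_motifs(
    query: SequenceRecord | str,
    anchor: ReferenceAnchor,
    window: int = DEFAULT_WINDOW,
    substitution_table=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    aligned: AlignedPair | None = None,
) -> MotifReport:
    """Screen one candidate for the three diagnostic POR motifs.

    Motif positions are transferred from the reference by global alignment
    and each pattern is searched for within ``±window`` residues of its
    projected position.  ``X`` never satisfies a motif position.  A query
    whose alignment starts after the Rossman region is flagged
    ``n_truncated`` and may still be accepted as a fragment.
    """
    seq_id, q = _as_residues(query)
    if window < 0:
        raise ConfigurationError("window must be non-negative")
    pair = aligned if aligned is not None else align_to_reference(
        query, anchor, substitution_table, gap_open, gap_extend
    )
    cmap = pair.column_map
    qlen = len(q)

    if not cmap:
        return MotifReport(
            seq_id, MotifHit(False), YKHit(False), MotifHit(False), False,
            VERDICT_REJECT,
        )

    # The query is N-truncated when the alignment leaves the reference's
    # N-terminal region (through the end of the Rossman pattern) mostly
    # unmapped.  A fraction rather than the first mapped column is used
    # because a global alignment of a truncated query often matches a
    # stray leading residue before opening the long gap.
    region = range(1, anchor.rossman_start + 7)
    mapped_in_region = sum(1 for c in region if c in cmap)
    n_truncated = mapped_in_region < 0.5 * len(region)

    rossman = MotifHit(False)
    if not n_truncated:
        center = _expected_query_position(cmap, anchor.rossman_start, qlen)
        for s in _search_near(center, window, qlen - 6):
            if q[s - 1] == "G" and q[s + 3] == "G" and q[s + 5] == "G":
                rossman = MotifHit(True, s)
                break

    yk = YKHit(False)
    center = _expected_query_position(cmap, anchor.tyr_pos, qlen)
    for s in _search_near(center, window, qlen - 4):
        if q[s - 1] == "Y" and q[s + 3] == "K":
            yk = YKHit(True, s, s + 4)
            break

    cys = MotifHit(False)
    center = _expected_query_position(cmap, anchor.cys_pos, qlen)
    for s in _search_near(center, window, qlen):
        if q[s - 1] == "C":
            cys = MotifHit(True, s)
            break

    if rossman.found and yk.found and cys.found:
        verdict = VERDICT_ACCEPT
    elif n_truncated and yk.found and cys.found:
        verdict = VERDICT_FRAGMENT
    else:
        verdict = VERDICT_REJECT
    return MotifReport(seq_id, rossman, yk, cys, n_truncated, verdict)


def pairwise_identity(
    a: str,
    b: str,
    substitution_table=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Global-alignment identity as matches over the shorter sequence length."""
    pair = align_to_reference(a, b, substitution_table, gap_open, gap_extend)
    matches = sum(
        1
        for x, y in zip(pair.query_aligned, pair.reference_aligned)
        if x == y and x != "-"
    )
    return matches / min(len(a), len(b))


def apply_curation(
    records: Sequence[SequenceRecord],
    anchor: ReferenceAnchor,
    min_length: int = 150,
    max_unknown_fraction: float = 0.05,
    dedup_identity: float = 0.99,
    window: int = DEFAULT_WINDOW,
    substitution_table=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[list[MotifReport], list[RejectedReport]]:
    """Run the full curation filter over a candidate set.

    Filters, in order: minimum length, fraction of undetermined residues,
    diagnostic-motif screen, and same-taxon deduplication (pairwise identity
    over the shorter sequence at or above ``dedup_identity``; the longest
    representative is kept).  Every input record lands in exactly one of the
    two returned lists.
    """
    if not (0.0 <= max_unknown_fraction <= 1.0):
        raise ConfigurationError("max_unknown_fraction must lie in [0, 1]")
    if not (0.0 <= dedup_identity <= 1.0):
        raise ConfigurationError("dedup_identity must lie in [0, 1]")

    accepted: list[MotifReport] = []
    rejected: list[RejectedReport] = []
    survivors: list[tuple[SequenceRecord, MotifReport]] = []

    for rec in records:
        report = screen_motifs(
            rec, anchor, window, substitution_table, gap_open, gap_extend
        )
        if len(rec) < min_length:
            rejected.append(RejectedReport(report, "too_short"))
        elif rec.unknown_fraction > max_unknown_fraction:
            rejected.append(RejectedReport(report, "too_many_X"))
        elif report.verdict == VERDICT_REJECT:
            rejected.append(RejectedReport(report, "motif_fail"))
        else:
            survivors.append((rec, report))

    # same-taxon dedup: longest first; a later sequence matching a kept one
    # at >= dedup_identity over the shorter is discarded as a duplicate.
    by_taxon: dict[str, list[tuple[SequenceRecord, MotifReport]]] = {}
    for rec, report in survivors:
        by_taxon.setdefault(rec.taxon_name, []).append((rec, report))

    kept_ids: set[str] = set()
    dropped: dict[str, MotifReport] = {}
    for taxon, members in by_taxon.items():
        ordered = sorted(members, key=lambda rr: (-len(rr[0]), rr[0].id))
        kept: list[SequenceRecord] = []
        for rec, report in ordered:
            is_dup = any(
                pairwise_identity(
                    rec.residues, other.residues,
                    substitution_table, gap_open, gap_extend,
                ) >= dedup_identity
                for other in kept
            )
            if is_dup:
                dropped[rec.id] = report
            else:
                kept.append(rec)
                kept_ids.add(rec.id)

    for rec, report in survivors:  # preserve input order in the outputs
        if rec.id in kept_ids:
            accepted.append(report)
        else:
            rejected.append(RejectedReport(dropped[rec.id], "duplicate"))
    return accepted, rejected
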