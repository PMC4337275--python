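"""LIPOR gene-complement classification and its association with por copies.

The light-independent protochlorophyllide oxidoreductase (LIPOR) is encoded
by three chloroplast genes, chlL, chlN and chlB.  Typically a chloroplast
genome carries all three or none; partial complements and pseudogenes mark
loss in progress.  Because the light-dependent enzyme (POR, nuclear *por*
genes) is isofunctional, a natural question is whether lineages that keep
duplicated *por* genes are the ones that let LIPOR go.  This module
classifies per-species complements, summarizes them by taxonomic group,
and tests the por-copy-number x LIPOR-loss association with a two-sided
exact (hypergeometric) test — an explicit statistical extension of a
qualitatively reported pattern.

Status symbols follow the tabular convention: ``+`` present, ``+,2``
present in two copies, ``-`` absent from a fully sequenced chloroplast
genome, ``ψ`` pseudogene, ``?`` unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import stats

from .records import ConfigurationError, InputError

logger = logging.getLogger(__name__)

GENE_STATUSES = ("present", "present_multi", "pseudogene", "absent", "unknown")
_PRESENT = {"present", "present_multi"}

CLASS_COMPLETE = "complete"
CLASS_PARTIAL = "partial"
CLASS_PSEUDOGENIZED = "pseudogenized"
CLASS_ABSENT = "absent"
CLASS_INDETERMINATE = "indeterminate"
COMPLEMENT_CLASSES = (
    CLASS_COMPLETE, CLASS_PARTIAL, CLASS_PSEUDOGENIZED, CLASS_ABSENT,
    CLASS_INDETERMINATE,
)

_SYMBOLS = {
    "+": "present",
    "+,2": "present_multi",
    "+2": "present_multi",
    "-": "absent",
    "−": "absent",   # minus sign
    "ψ": "pseudogene",  # ψ
    "psi": "pseudogene",
    "?": "unknown",
}


@dataclass(frozen=True)
class LiporRecord:
    """Per-species chlL/chlN/chlB status plus *por* gene copy count.

    ``por_count`` stores the minimum of a reported range (e.g. "1-2" is
    stored as 1 with ``por_count_max`` 2); ``None`` means unknown.
    """

    species: str
    group: str
    chlL: str
    chlN: str
    chlB: str
    por_count: int | None = None
    por_count_max: int | None = None
    genome_accession: str | None = None
    subgroup: str | None = None

    def __post_init__(self) -> None:
        for gene in ("chlL", "chlN", "chlB"):
            value = getattr(self, gene)
            if value not in GENE_STATUSES:
                raise InputError(
                    f"{self.species}: invalid {gene} status {value!r}"
                )
        if self.por_count is not None and self.por_count < 0:
            raise InputError(f"{self.species}: por_count must be >= 0")

    @property
    def statuses(self) -> tuple[str, str, str]:
        return (self.chlL, self.chlN, self.chlB)


def classify_complement(rec: LiporRecord) -> str:
    """Classify a LIPOR gene complement.

    Rule order: complete (all three present), absent (all three absent),
    pseudogenized (at least one pseudogene and nothing intact), partial
    (a mix of present and absent, fully determined), and indeterminate
    whenever an unknown status blocks the earlier rules.
    """
    s = rec.statuses
    if all(x in _PRESENT for x in s):
        return CLASS_COMPLETE
    if all(x == "absent" for x in s):
        return CLASS_ABSENT
    if any(x == "pseudogene" for x in s) and not any(x in _PRESENT for x in s):
        return CLASS_PSEUDOGENIZED
    if set(s) <= (_PRESENT | {"absent"}) and "unknown" not in s:
        return CLASS_PARTIAL
    return CLASS_INDETERMINATE


def summarize_by_group(records: Sequence[LiporRecord]) -> pd.DataFrame:
    """Count complement classes per group, groups in input order."""
    if not records:
        raise InputError("summarize_by_group requires at least one record")
    order: list[str] = []
    buckets: dict[str, list[str]] = {}
    for rec in records:
        if rec.group not in buckets:
            order.append(rec.group)
            buckets[rec.group] = []
        buckets[rec.group].append(classify_complement(rec))
    rows = []
    for group in order:
        classes = buckets[group]
        rows.append(
            {
                "group": group,
                "n_species": len(classes),
                "n_complete": classes.count(CLASS_COMPLETE),
                "n_partial": classes.count(CLASS_PARTIAL),
                "n_pseudogenized": classes.count(CLASS_PSEUDOGENIZED),
                "n_absent": classes.count(CLASS_ABSENT),
                "n_indeterminate": classes.count(CLASS_INDETERMINATE),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AssociationResult:
    """2x2 association of multiple por copies with a reduced LIPOR complement.

    Rows: por_count >= 2 vs <= 1.  Columns: complement reduced (absent,
    pseudogenized or partial) vs complete.  Record rows are the unit of
    analysis as printed in the source tables; note that por counts are
    genus-level while LIPOR status is species-level.
    """

    table: np.ndarray
    p_value: float
    n_included: int
    n_excluded: int


def por_lipor_association(records: Sequence[LiporRecord]) -> AssociationResult:
    """Two-sided exact test of por duplication vs LIPOR reduction.

    Records with an unknown por count or an indeterminate complement are
    excluded (with a logged count).  A range-valued por count contributes
    its minimum, which is conservative toward the duplication-with-loss
    hypothesis.
    """
    table = np.zeros((2, 2), dtype=int)
    excluded = 0
    for rec in records:
        cls = classify_complement(rec)
        if rec.por_count is None or cls == CLASS_INDETERMINATE:
            excluded += 1
            continue
        row = 0 if rec.por_count >= 2 else 1
        col = 0 if cls in (CLASS_ABSENT, CLASS_PSEUDOGENIZED, CLASS_PARTIAL) else 1
        table[row, col] += 1
    included = int(table.sum())
    if included < 1:
        raise InputError("no records usable for the por/LIPOR association")
    if excluded:
        logger.info(
            "por_lipor_association: excluded %d record(s) with unknown por "
            "count or indeterminate complement", excluded,
        )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return AssociationResult(table, float(p), included, excluded)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("species", "group", "chlL", "chlN", "chlB")


def _parse_status(raw: str, row_number: int) -> str:
    token = str(raw).strip().replace(" ", "")
    key = token.lower() if token.lower() == "psi" else token
    if key not in _SYMBOLS:
        raise InputError(
            f"row {row_number}: unknown gene status symbol {raw!r}"
        )
    return _SYMBOLS[key]


def _parse_por_count(raw, row_number: int) -> tuple[int | None, int | None]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None, None
    token = str(raw).strip()
    if token in ("", "?", "nan"):
        return None, None
    for dash in ("–", "—"):  # en/em dash ranges
        token = token.replace(dash, "-")
    if "-" in token:
        lo, _, hi = token.partition("-")
        try:
            return int(lo), int(hi)
        except ValueError:
            raise InputError(f"row {row_number}: bad por count {raw!r}") from None
    try:
        return int(token), None
    except ValueError:
        raise InputError(f"row {row_number}: bad por count {raw!r}") from None


def parse_complement_table(source: str | Path | TextIO) -> list[LiporRecord]:
    """Read a gene-complement TSV into records.

    Required columns: species, group, chlL, chlN, chlB.  Optional:
    subgroup, por_count, accession.  An empty file (header only, or no
    content) yields an empty list.
    """
    try:
        frame = pd.read_csv(source, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if frame.empty and not set(_REQUIRED_COLUMNS) <= set(frame.columns):
        return []
    missing = set(_REQUIRED_COLUMNS) - set(frame.columns)
    if missing:
        raise InputError(f"complement table missing columns: {sorted(missing)}")
    records: list[LiporRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        por_min, por_max = _parse_por_count(getattr(row, "por_count", None), i)
        accession = getattr(row, "accession", None)
        if isinstance(accession, float):
            accession = None
        subgroup = getattr(row, "subgroup", None)
        if isinstance(subgroup, float):
            subgroup = None
        records.append(
            LiporRecord(
                species=str(row.species),
                group=str(row.group),
                chlL=_parse_status(row.chlL, i),
                chlN=_parse_status(row.chlN, i),
                chlB=_parse_status(row.chlB, i),
                por_count=por_min,
                por_count_max=por_max,
                genome_accession=accession,
                subgroup=subgroup,
            )
        )
    return records


def complement_table(records: Sequence[LiporRecord]) -> pd.DataFrame:
    """Records with their complement class, as a writable table."""
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "group": r.group,
                "subgroup": r.subgroup,
                "chlL": r.chlL,
                "chlN": r.chlN,
                "chlB": r.chlB,
                "por_count": r.por_count,
                "por_count_max": r.por_count_max,
                "complement_class": classify_complement(r),
            }
            for r in records
        ]
    )


def load_reference_complements() -> list[LiporRecord]:
    """The bundled survey of chloroplast LIPOR complements and por counts.

    Two tables: one covering chlorophytic algae, chlorarachniophytes and
    euglenids, the other covering rhodophytes and CASH algae.
    """
    records: list[LiporRecord] = []
    for name in ("lipor_chlorophyte_table.tsv", "lipor_cash_table.tsv"):
        with resources.files("portrace.data").joinpath(name).open() as fh:
            records.extend(parse_complement_table(fh))
    return records
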