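"""Protein sequence records with taxon and lineage metadata.

Candidate POR (light-dependent protochlorophyllide oxidoreductase) homologs
arrive as ungapped amino-acid sequences tagged with the taxon they were
sampled from and the algal lineage that taxon belongs to.  The lineage tag
drives every downstream interpretation step (expected plastid donor,
grouping in similarity analyses), so it is restricted to a fixed vocabulary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: The twenty standard amino acids, in the conventional alphabetical order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Residue alphabet accepted in sequence records (standard residues plus the
#: "undetermined" placeholder X).  Gap characters are never allowed here.
SEQUENCE_ALPHABET: frozenset[str] = frozenset(AMINO_ACIDS + "X")

#: Controlled vocabulary of algal lineages.
LINEAGES: tuple[str, ...] = (
    "cyanobacteria",
    "glaucophyte",
    "rhodophyte",
    "prasinophyte",
    "utc_chlorophyte",
    "streptophyte",
    "cryptophyte",
    "haptophyte",
    "stramenopile",
    "dinoflagellate",
    "chlorarachniophyte",
    "euglenid",
    "other",
)

SOURCES: tuple[str, ...] = ("genome", "transcriptome", "amplicon")


class InputError(ValueError):
    """Raised for malformed user-supplied data (sequences, tables, trees)."""


class ConfigurationError(ValueError):
    """Raised when a configuration value is internally inconsistent."""


@dataclass(frozen=True)
class SequenceRecord:
    """One ungapped protein sequence with its taxon/lineage metadata.

    Parameters
    ----------
    id:
        Unique identifier within a dataset.
    residues:
        Amino-acid string over the twenty standard letters plus ``X``.
    taxon_name:
        Name of the organism the sequence was sampled from.  Several
        records (paralogs, strains) may share one taxon name.
    lineage:
        One of :data:`LINEAGES`.
    source:
        ``genome``, ``transcriptome`` or ``amplicon``.
    """

    id: str
    residues: str
    taxon_name: str = ""
    lineage: str = "other"
    source: str = "genome"

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence record requires a non-empty id")
        if not self.residues:
            raise InputError(f"sequence {self.id!r}: residues must be non-empty")
        bad = set(self.residues) - SEQUENCE_ALPHABET
        if bad:
            raise InputError(
                f"sequence {self.id!r} contains characters outside the accepted "
                f"alphabet: {sorted(bad)}"
            )
        if self.lineage not in LINEAGES:
            raise InputError(
                f"sequence {self.id!r}: unknown lineage {self.lineage!r} "
                f"(expected one of {', '.join(LINEAGES)})"
            )
        if self.source not in SOURCES:
            raise InputError(
                f"sequence {self.id!r}: unknown source {self.source!r}"
            )
        if not self.taxon_name:
            object.__setattr__(self, "taxon_name", self.id)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def unknown_fraction(self) -> float:
        """Fraction of residues that are undetermined (``X``)."""
        return self.residues.count("X") / len(self.residues)


def _parse_header(description: str) -> dict[str, str]:
    # header grammar: "id key=value key=value ..."
    fields: dict[str, str] = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            fields[key] = value
    return fields


def read_fasta(source: str | Path | TextIO) -> list[SequenceRecord]:
    """Read sequence records from FASTA.

    Headers are parsed as ``>id key=value ...`` with recognised keys
    ``taxon``, ``lineage`` and ``source``.  Unrecognised keys are ignored;
    missing keys fall back to the record defaults.
    """
    handle: TextIO
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle = source
        close = False
    try:
        records = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise InputError(f"duplicate sequence id in FASTA: {rec.id!r}")
            seen.add(rec.id)
            meta = _parse_header(rec.description)
            records.append(
                SequenceRecord(
                    id=rec.id,
                    residues=str(rec.seq).upper().replace("-", ""),
                    taxon_name=meta.get("taxon", rec.id),
                    lineage=meta.get("lineage", "other"),
                    source=meta.get("source", "genome"),
                )
            )
        return records
    finally:
        if close:
            handle.close()


def write_fasta(records: Iterable[SequenceRecord], dest: str | Path | TextIO) -> None:
    """Write records as FASTA with ``taxon=... lineage=... source=...`` headers."""
    bio = [
        _BioSeqRecord(
            Seq(r.residues),
            id=r.id,
            description=f"taxon={r.taxon_name} lineage={r.lineage} source={r.source}",
        )
        for r in records
    ]
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            SeqIO.write(bio, fh, "fasta")
    else:
        SeqIO.write(bio, dest, "fasta")


def fasta_string(records: Iterable[SequenceRecord]) -> str:
    buf = io.StringIO()
    write_fasta(records, buf)
    return buf.getvalue()
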