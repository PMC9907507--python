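"""Core sequence containers shared by every stage of the pipeline.

A :class:`SequenceRecord` is one named protein (or nucleotide) sequence with
optional species/paralog metadata; an :class:`Alignment` is an ordered,
rectangular set of gapped records.  Both validate their invariants on
construction so downstream code never re-checks alphabets or row lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_AMBIGUOUS = frozenset("X")
NUCLEOTIDE_ALPHABET = frozenset("ACGTU")
NUCLEOTIDE_AMBIGUOUS = frozenset("N")
GAP = "-"


class SequenceError(ValueError):
    """Raised when a sequence or alignment violates a structural invariant."""


@dataclass
class SequenceRecord:
    """One named sequence.

    Parameters
    ----------
    id:
        Unique identifier within a dataset; must contain no whitespace.
    residues:
        Uppercase residue string over the declared alphabet plus the
        ambiguity code (X for protein, N for nucleotide).
    species, description:
        Optional metadata carried through reports.
    moltype:
        ``"protein"`` (default) or ``"nucleotide"``.
    """

    id: str
    residues: str
    species: str = ""
    description: str = ""
    moltype: str = "protein"

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceError(f"record id {self.id!r} is empty or contains whitespace")
        if self.moltype not in ("protein", "nucleotide"):
            raise SequenceError(f"unknown moltype {self.moltype!r}")
        if not self.residues:
            raise SequenceError(f"record {self.id!r} has an empty sequence")
        if self.moltype == "protein":
            allowed = PROTEIN_ALPHABET | PROTEIN_AMBIGUOUS
        else:
            allowed = NUCLEOTIDE_ALPHABET | NUCLEOTIDE_AMBIGUOUS
        for pos, ch in enumerate(self.residues):
            if ch not in allowed:
                raise SequenceError(
                    f"record {self.id!r}: illegal character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def with_residues(self, residues: str) -> "SequenceRecord":
        return replace(self, residues=residues)


@dataclass
class GappedRecord:
    """A single alignment row: a record whose residues may contain ``-``."""

    id: str
    residues: str
    species: str = ""
    description: str = ""
    moltype: str = "protein"

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A rectangular multiple sequence alignment.

    Rows are :class:`GappedRecord` entries whose ``residues`` may contain
    ``-``; all rows must have equal length and degap to a valid record.
    """

    records: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise SequenceError("alignment has no rows")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            offender = next(
                r for r in self.records if len(r.residues) != len(self.records[0].residues)
            )
            raise SequenceError(
                f"ragged alignment: row {offender.id!r} has length "
                f"{len(offender.residues)}, expected {len(self.records[0].residues)}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise SequenceError(f"duplicate row id {dup!r} in alignment")
        for r in self.records:
            degapped = r.residues.replace(GAP, "")
            # validates alphabet of the ungapped row
            SequenceRecord(id=r.id, residues=degapped, moltype=r.moltype)

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    @property
    def n_rows(self) -> int:
        return len(self.records)

    def column(self, j: int) -> list:
        """Residues (including gaps) of column ``j``."""
        return [r.residues[j] for r in self.records]

    def degapped(self) -> list:
        """Rows with gaps removed, as plain :class:`SequenceRecord` objects."""
        return [
            SequenceRecord(
                id=r.id,
                residues=r.residues.replace(GAP, ""),
                species=r.species,
                description=r.description,
                moltype=r.moltype,
            )
            for r in self.records
        ]
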