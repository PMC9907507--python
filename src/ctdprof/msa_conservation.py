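"""Alignment-column conservation classes and conserved-block extraction.

Columns are annotated with the comparative coloring scheme used for CtBP
alignments: a residue present in more than half of the (non-gap) rows is
"conserved"; failing that, a chemical group pooled above half is
"chemical"; a distinct second residue carried by 25-50% of rows is recorded
as secondary.  Columns occupied in fewer than half of the rows are classed
"none".  Runs of conserved/chemical columns become named blocks (the
central AHSTT / PELNGA-type motifs of CtBP CTDs are recovered this way).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import List, Optional

from .records import Alignment, GAP, SequenceError

#: Chemical conservation groups (disjoint by construction).
CHEMICAL_GROUPS = {
    "aliphatic": frozenset("MVIL"),
    "aromatic": frozenset("WYF"),
    "acidic": frozenset("DE"),
    "basic": frozenset("KR"),
    "hydroxyl": frozenset("ST"),
}


@dataclass
class ColumnAnnotation:
    column: int
    primary_class: str  # conserved | chemical | secondary | none
    primary_residue: str  # residue, or chemical-group name, or ""
    secondary_residue: Optional[str]
    occupancy: float


@dataclass
class ConservedBlock:
    start: int  # column interval, half-open
    end: int
    consensus: str
    mean_occupancy: float


def annotate_columns(msa: Alignment) -> List[ColumnAnnotation]:
    """Annotate every column with its conservation class.

    Frequencies are computed among non-gap rows only; X is treated as an
    ordinary (never-matching) symbol.  Requires at least 2 rows.
    """
    if msa.n_rows < 2:
        raise SequenceError("conservation annotation needs at least 2 alignment rows")
    annotations: List[ColumnAnnotation] = []
    for j in range(msa.n_columns):
        column = [c for c in msa.column(j) if c != GAP]
        occupancy = len(column) / msa.n_rows
        if occupancy < 0.5 or not column:
            annotations.append(
                ColumnAnnotation(
                    column=j, primary_class="none", primary_residue="",
                    secondary_residue=None, occupancy=occupancy,
                )
            )
            continue
        counts = Counter(c for c in column if c != "X")
        n = len(column)
        primary_class, primary_residue = "none", ""
        top_residue = None
        if counts:
            top_residue, top_count = counts.most_common(1)[0]
            if top_count / n > 0.5:
                primary_class, primary_residue = "conserved", top_residue
        if primary_class == "none":
            for group, members in CHEMICAL_GROUPS.items():
                pooled = sum(counts[aa] for aa in members)
                if pooled / n > 0.5:
                    primary_class, primary_residue = "chemical", group
                    break
        secondary = None
        for residue, count in counts.most_common():
            if primary_class == "conserved" and residue == primary_residue:
                continue
            if 0.25 <= count / n <= 0.5:
                secondary = residue
                break
        annotations.append(
            ColumnAnnotation(
                column=j,
                primary_class=primary_class,
                primary_residue=primary_residue,
                secondary_residue=secondary,
                occupancy=occupancy,
            )
        )
    return annotations


def find_conserved_blocks(
    annotations: List[ColumnAnnotation],
    msa: Optional[Alignment] = None,
    min_len: int = 5,
    max_break: int = 1,
) -> List[ConservedBlock]:
    """Extract maximal runs of conserved/chemical columns.

    A run may absorb up to ``max_break`` interrupting (non-conserved)
    columns in total and must span at least ``min_len`` columns.  The
    consensus is the per-column majority residue (lowercase ``x`` where the
    column is only chemically conserved); ``msa`` supplies residue counts
    for consensus letters of chemical columns when given.
    """
    good = [a.primary_class in ("conserved", "chemical") for a in annotations]
    blocks: List[ConservedBlock] = []
    i = 0
    n = len(annotations)
    while i < n:
        if not good[i]:
            i += 1
            continue
        j = i
        breaks = 0
        end = i + 1  # last good column + 1
        while j + 1 < n:
            if good[j + 1]:
                j += 1
                end = j + 1
            elif breaks < max_break:
                breaks += 1
                j += 1
            else:
                break
        if end - i >= min_len:
            cols = annotations[i:end]
            consensus = []
            for a in cols:
                if a.primary_class == "conserved":
                    consensus.append(a.primary_residue)
                elif a.primary_class == "chemical" and msa is not None:
                    column = [c for c in msa.column(a.column) if c != GAP and c != "X"]
                    consensus.append(Counter(column).most_common(1)[0][0].lower())
                else:
                    consensus.append("x")
            blocks.append(
                ConservedBlock(
                    start=i,
                    end=end,
                    consensus="".join(consensus),
                    mean_occupancy=sum(a.occupancy for a in cols) / len(cols),
                )
            )
        i = end
    return blocks


def drop_gappy_columns(msa: Alignment, max_gap_fraction: float = 0.8) -> Alignment:
    """Remove columns whose gap fraction exceeds ``max_gap_fraction``.

    Row order is preserved; removing every column is an error.
    """
    keep = []
    for j in range(msa.n_columns):
        column = msa.column(j)
        gap_fraction = column.count(GAP) / len(column)
        if gap_fraction <= max_gap_fraction:
            keep.append(j)
    if not keep:
        raise SequenceError("all columns exceed the gap-fraction threshold")
    from .records import GappedRecord

    rows = [
        GappedRecord(
            id=r.id,
            residues="".join(r.residues[j] for j in keep),
            species=r.species,
            description=r.description,
            moltype=r.moltype,
        )
        for r in msa.records
    ]
    return Alignment(records=rows)
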