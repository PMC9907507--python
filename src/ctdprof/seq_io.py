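"""FASTA / alignment input-output and tabular report writing.

Parsing is delegated to Biopython (``SeqIO``/``AlignIO``); this module layers
the pipeline's validation on top: unique ids, legal alphabets, uppercase
residues, terminal stop characters (``*``) stripped with a logged note, and
bit-stable TSV/JSON report output (fixed column order, floats to 4 decimals).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO

from .records import Alignment, GappedRecord, SequenceRecord, SequenceError

log = logging.getLogger(__name__)

_MSA_DIALECTS = {"aligned_fasta": "fasta", "clustalw": "clustal"}


def _clean_residues(raw: str, record_id: str) -> str:
    residues = str(raw).upper()
    if residues.endswith("*"):
        residues = residues.rstrip("*")
        log.info("stripped terminal stop '*' from record %s", record_id)
    return residues


def read_fasta(path, moltype: str = "protein") -> list[SequenceRecord]:
    """Read a multi-record FASTA file into validated :class:`SequenceRecord` s.

    Line wraps are joined, residues uppercased, terminal ``*`` stripped, and
    input order preserved.  Raises :class:`SequenceError` for an empty file,
    duplicate ids, or illegal characters (with position).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = _clean_residues(rec.seq, rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        species = _species_from_description(desc)
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=residues,
                species=species,
                description=desc,
                moltype=moltype,
            )
        )
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def _species_from_description(desc: str) -> str:
    # convention: a "species=..." key in the description carries the species
    for token in desc.split():
        if token.startswith("species="):
            return token[len("species="):]
    return ""


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write records as wrapped FASTA; round-trips ids and residues exactly."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id
            if rec.description:
                header = f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_msa(path, dialect: str = "aligned_fasta", moltype: str = "protein") -> Alignment:
    """Read a multiple sequence alignment in aligned-FASTA or ClustalW dialect.

    ClustalW block structure is reassembled into full-length rows.  Ragged
    rows raise :class:`SequenceError` naming the offending row.
    """
    if dialect not in _MSA_DIALECTS:
        raise SequenceError(
            f"unknown MSA dialect {dialect!r}; expected one of {sorted(_MSA_DIALECTS)}"
        )
    path = Path(path)
    if dialect == "aligned_fasta":
        # parse leniently so unequal row lengths surface as our ragged error
        rows = []
        for rec in SeqIO.parse(str(path), "fasta"):
            residues = _clean_residues(rec.seq, rec.id)
            desc = rec.description[len(rec.id):].strip() if rec.description else ""
            rows.append(
                GappedRecord(
                    id=rec.id,
                    residues=residues,
                    species=_species_from_description(desc),
                    description=desc,
                    moltype=moltype,
                )
            )
        if not rows:
            raise SequenceError(f"no alignment rows found in {path}")
        return Alignment(records=rows)
    msa = AlignIO.read(str(path), _MSA_DIALECTS[dialect])
    rows = [
        GappedRecord(
            id=rec.id,
            residues=_clean_residues(rec.seq, rec.id),
            moltype=moltype,
        )
        for rec in msa
    ]
    return Alignment(records=rows)


def write_msa(alignment: Alignment, path, dialect: str = "aligned_fasta") -> None:
    """Write an alignment in aligned-FASTA or ClustalW dialect."""
    if dialect not in _MSA_DIALECTS:
        raise SequenceError(f"unknown MSA dialect {dialect!r}")
    path = Path(path)
    if dialect == "aligned_fasta":
        with path.open("w") as fh:
            for row in alignment.records:
                fh.write(f">{row.id}\n{row.residues}\n")
        return
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord as BioSeqRecord

    msa = MultipleSeqAlignment(
        [BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in alignment.records]
    )
    AlignIO.write(msa, str(path), "clustal")


def _format_value(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return f"{value:.4f}"
    return str(value)


def write_report(rows: Sequence[dict], path, format: str = "tsv", columns=None) -> None:
    """Write keyed rows as TSV or JSON with bit-stable formatting.

    All rows must share one key set; column order is the first row's key
    order (or ``columns`` if given); floats are fixed to 4 decimals.  Empty
    ``rows`` with explicit ``columns`` yields a header-only file.
    """
    path = Path(path)
    if rows:
        keys = list(rows[0].keys())
        for i, row in enumerate(rows):
            if list(row.keys()) != keys and set(row.keys()) != set(keys):
                raise SequenceError(
                    f"report row {i} keys {sorted(row.keys())} differ from {sorted(keys)}"
                )
        if columns is None:
            columns = keys
    elif columns is None:
        columns = []
    if format == "tsv":
        with path.open("w") as fh:
            fh.write("\t".join(columns) + "\n")
            for row in rows:
                fh.write("\t".join(_format_value(row[c]) for c in columns) + "\n")
    elif format == "json":
        serialisable = [
            {c: (round(v, 4) if isinstance(v, float) else v) for c, v in ((c, row[c]) for c in columns)}
            for row in rows
        ]
        with path.open("w") as fh:
            json.dump(serialisable, fh, indent=2, sort_keys=False)
            fh.write("\n")
    else:
        raise SequenceError(f"unknown report format {format!r}")
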