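"""Vertebrate paralog calling, terminal-ending catalogue, SUMO scanning,
and reference-site audits.

Paralog calls combine two signals: percent identity of the dehydrogenase
core (the RPLVALL...NCVN window) to designated CtBP1 and CtBP2 reference
proteins, and the characteristic CTD start/end motifs of each duplicate
family (KEYL...PADQ for the CtBP1 side, KEFF...LTEQ for the CtBP2 side;
matched within one substitution since lineages vary them).  Concordant
signals yield a family call; conflicting signals yield ``unresolved`` with
both rule firings recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence as Seq

from .idr_composition import HYDROPHOBIC
from .pairwise import global_align, window_identity
from .records import SequenceRecord
from .segmentation import (
    DEFAULT_ENDING_CATALOG,
    segment_domains,
)

#: Family CTD boundary motifs: (start 4-mer, end 4-mer) per side.
FAMILY1_MOTIFS = ("KEYL", "PADQ")
FAMILY2_MOTIFS = ("KEFF", "LTEQ")

#: Reference PTM / structural sites, editable by callers.  Positions are
#: 1-based in the numbering of the designated reference protein.
DEFAULT_SITES_CTBP1 = {
    "S422_phospho_HIPK2": (422, "S"),
    "K428_sumo": (428, "K"),
}
DEFAULT_SITES_CTBP2 = {
    "S128_tetramer": (128, "S"),
    "A129_tetramer": (129, "A"),
    "R190_tetramer": (190, "R"),
    "G216_tetramer": (216, "G"),
    "L221_tetramer": (221, "L"),
    "S365_phospho": (365, "S"),
    "T414_phospho": (414, "T"),
    "S428_phospho": (428, "S"),
}


@dataclass
class ParalogCall:
    query_id: str
    family: str  # CtBP1 | CtBP1_like | CtBP1a | CtBP2 | CtBP2_like | CtBP | unresolved
    identity_to_ref1: float
    identity_to_ref2: float
    ctd_start_motif: Optional[str]
    ctd_end_motif: Optional[str]
    evidence: List[str] = field(default_factory=list)


@dataclass
class SumoSite:
    k_position: int  # 0-based index of the lysine
    context: str  # the psi-K-x-alpha 4-mer
    psi_residue: str
    alpha_residue: str


@dataclass
class SiteAudit:
    site: str
    reference_position: int  # 1-based
    expected_residue: str
    query_residue: str  # residue or "-" when the column is gapped
    conserved: bool


def _hamming_le(a: str, b: str, budget: int) -> bool:
    return len(a) == len(b) and sum(x != y for x, y in zip(a, b)) <= budget


def _ctd_motif_family(ctd: str, motif_mismatch: int = 1) -> tuple:
    """Return (family_side, start_motif, end_motif) from CTD boundary motifs.

    ``family_side`` is "1", "2", or None; a side is called only when the
    start and end motifs do not disagree with each other.
    """
    start = ctd[:4] if len(ctd) >= 4 else ""
    end = ctd[-4:] if len(ctd) >= 4 else ""
    start_side = None
    if start and _hamming_le(start, FAMILY1_MOTIFS[0], motif_mismatch):
        start_side = "1"
    elif start and _hamming_le(start, FAMILY2_MOTIFS[0], motif_mismatch):
        start_side = "2"
    end_side = None
    if end and _hamming_le(end, FAMILY1_MOTIFS[1], motif_mismatch):
        end_side = "1"
    elif end and _hamming_le(end, FAMILY2_MOTIFS[1], motif_mismatch):
        end_side = "2"
    if start_side and end_side and start_side != end_side:
        return None, start, end
    side = start_side or end_side
    return side, start if start_side else None, end if end_side else None


def classify_paralog(
    query: SequenceRecord,
    ref1: SequenceRecord,
    ref2: SequenceRecord,
    canonical_threshold: float = 98.0,
    motif_mismatch: int = 1,
    max_anchor_mismatch: int = 1,
) -> ParalogCall:
    """Call the paralog family of one vertebrate CtBP query.

    Core identity to each reference is measured over the anchored
    RPLVALL...NCVN window of that reference; the provisional family is the
    nearer reference's side.  CTD start/end motifs refine the call; when
    motif and identity signals disagree the call is ``unresolved`` with both
    rule firings in ``evidence``.  Queries nearly identical to a reference
    (identity >= ``canonical_threshold``) are called the canonical family
    (CtBP1/CtBP2); other concordant queries get the ``_like`` call, which
    :func:`rank_species_calls` may refine to CtBP1a within a species.
    """
    seg = segment_domains(query, max_mismatch=max_anchor_mismatch)
    ctd = query.residues[seg.ctd[0] : seg.ctd[1]]
    id1 = window_identity(ref1, query, max_mismatch=max_anchor_mismatch).identity_pct
    id2 = window_identity(ref2, query, max_mismatch=max_anchor_mismatch).identity_pct
    evidence: List[str] = []
    if id1 == id2:
        identity_side = None
        evidence.append(f"identity_tie:{id1:.2f}")
    else:
        identity_side = "1" if id1 > id2 else "2"
        evidence.append(f"identity_nearer_ref{identity_side}:{max(id1, id2):.2f}")
    motif_side, start_motif, end_motif = _ctd_motif_family(ctd, motif_mismatch)
    if start_motif or end_motif:
        evidence.append(
            f"ctd_motifs_side{motif_side or 'conflict'}:"
            f"{start_motif or '-'}..{end_motif or '-'}"
        )
    if motif_side and identity_side and motif_side != identity_side:
        family = "unresolved"
        evidence.append("conflict:identity_vs_motif")
    else:
        side = motif_side or identity_side
        if side is None:
            family = "unresolved"
            evidence.append("no_signal")
        else:
            nearest = id1 if side == "1" else id2
            if nearest >= canonical_threshold:
                family = f"CtBP{side}"
                evidence.append(f"canonical:identity>={canonical_threshold:.0f}")
            else:
                family = f"CtBP{side}_like"
    return ParalogCall(
        query_id=query.id,
        family=family,
        identity_to_ref1=id1,
        identity_to_ref2=id2,
        ctd_start_motif=start_motif,
        ctd_end_motif=end_motif,
        evidence=evidence,
    )


def rank_species_calls(calls: Iterable[ParalogCall]) -> List[ParalogCall]:
    """Within one species, demote extra CtBP1-side duplicates to CtBP1a.

    Among non-canonical 1-family calls, the highest core identity keeps
    CtBP1_like and the next becomes CtBP1a (duplicates beyond that stay
    CtBP1a with a note).  Calls are returned in the input order.
    """
    calls = list(calls)
    like1 = [c for c in calls if c.family == "CtBP1_like"]
    like1.sort(key=lambda c: (-c.identity_to_ref1, c.query_id))
    for rank, call in enumerate(like1):
        if rank >= 1:
            call.family = "CtBP1a"
            call.evidence.append(f"species_rank:{rank + 1}_of_{len(like1)}")
    return calls


def scan_sumo_sites(seq, psi_set=HYDROPHOBIC) -> List[SumoSite]:
    """Report every psi-K-x-[DE] sumoylation consensus in the sequence.

    psi is any residue of the hydrophobic set; overlapping sites are all
    reported.  Returns an empty list when no site matches.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else str(seq)
    sites: List[SumoSite] = []
    for i in range(1, len(residues) - 2):
        if residues[i] == "K" and residues[i - 1] in psi_set and residues[i + 2] in "DE":
            sites.append(
                SumoSite(
                    k_position=i,
                    context=residues[i - 1 : i + 3],
                    psi_residue=residues[i - 1],
                    alpha_residue=residues[i + 2],
                )
            )
    return sites


def audit_reference_sites(
    query: SequenceRecord,
    reference: SequenceRecord,
    sites: Mapping[str, tuple],
) -> List[SiteAudit]:
    """Audit named reference sites against an aligned query.

    ``sites`` maps site name to ``(1-based reference position, expected
    residue)``.  The query is globally aligned to the reference and the
    query residue in each site's column is reported; ``conserved`` means
    the query residue equals the expected residue.
    """
    for name, (pos, _expected) in sites.items():
        if not 1 <= pos <= len(reference.residues):
            raise ValueError(
                f"site {name!r} position {pos} outside reference length "
                f"{len(reference.residues)}"
            )
    result = global_align(reference, query)
    # column index of each reference position
    ref_cols = {}
    pos = 0
    for col, ch in enumerate(result.aligned_a):
        if ch != "-":
            pos += 1
            ref_cols[pos] = col
    audits = []
    for name in sorted(sites, key=lambda k: sites[k][0]):
        pos, expected = sites[name]
        query_residue = result.aligned_b[ref_cols[pos]]
        audits.append(
            SiteAudit(
                site=name,
                reference_position=pos,
                expected_residue=expected,
                query_residue=query_residue,
                conserved=query_residue == expected,
            )
        )
    return audits


def catalog_endings(
    records: Seq[SequenceRecord],
    k: int = 7,
    known: Seq[str] = DEFAULT_ENDING_CATALOG,
) -> Dict[str, dict]:
    """Label each record's terminal k-mer with the longest known suffix motif.

    Returns ``{record_id: {"species", "terminal_kmer", "ending_label"}}``;
    unknown suffixes are labelled ``"novel"`` with the raw k-mer retained.
    Use :func:`endings_presence_table` for the species-by-ending grid.
    """
    table: Dict[str, dict] = {}
    for rec in records:
        label, best = "novel", -1
        for motif in known:
            if rec.residues.endswith(motif) and len(motif) > best:
                label, best = motif, len(motif)
        table[rec.id] = {
            "species": rec.species,
            "terminal_kmer": rec.residues[-k:],
            "ending_label": label,
        }
    return table


def endings_presence_table(catalog: Mapping[str, dict]):
    """Species-by-ending presence grid (pandas DataFrame of X marks)."""
    import pandas as pd

    rows = [
        {"species": entry["species"] or rec_id, "ending": entry["ending_label"]}
        for rec_id, entry in catalog.items()
    ]
    df = pd.DataFrame(rows)
    grid = df.assign(mark="X").pivot_table(
        index="species", columns="ending", values="mark", aggfunc="first", fill_value=""
    )
    return grid
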