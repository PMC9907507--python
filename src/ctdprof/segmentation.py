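"""Anchor-motif domain segmentation and long/short isoform typing.

CtBP-family proteins decompose into an N-terminal domain (NTD), a conserved
dehydrogenase core, and an intrinsically disordered C-terminal domain (CTD).
The core is operationalized as the window from the start of the RPLVALL
anchor to the end of the NCVN anchor: NCVN is the last motif of the core, so
the CTD begins immediately after it.  All coordinates are 0-based half-open
and the three intervals tile ``[0, L)`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import SequenceRecord

NTD_ANCHOR = "RPLVALL"
CTD_ANCHOR = "NCVN"

#: Known terminal motifs across the family: ancestral long endings and
#: lineage-specific short endings.
DEFAULT_ENDING_CATALOG = (
    "PEPSEVH",
    "SEVH",
    "APECARP",
    "SNQEK",
    "ESTEAP",
    "RLSSRC",
    "DNTAR",
    "AKK",
    "PADQ",
    "LTEQ",
)


class SegmentationError(ValueError):
    """Raised when a sequence cannot be segmented (both anchors missing)."""


@dataclass
class AnchorMatch:
    """Location of a (possibly inexact) anchor motif match."""

    motif: str
    start: int
    end: int
    mismatches: int

    def __post_init__(self) -> None:
        assert self.end - self.start == len(self.motif)


@dataclass
class AnchorNotFound:
    """No window within the mismatch budget; carries the best distance seen."""

    motif: str
    best_distance: int


@dataclass
class DomainSegmentation:
    """NTD / core / CTD intervals tiling ``[0, L)``."""

    ntd: tuple
    core: tuple
    ctd: tuple
    flags: set = field(default_factory=set)

    @property
    def ctd_length(self) -> int:
        return self.ctd[1] - self.ctd[0]

    @property
    def ntd_length(self) -> int:
        return self.ntd[1] - self.ntd[0]


@dataclass
class IsoformCall:
    """Long/short typing plus terminal-motif label and NTD-extension flag."""

    form: str
    ending_label: str
    ctd_length: int
    ntd_extension: str = "none"
    terminal_kmer: str = ""


def find_anchor(seq, motif: str, max_mismatch: int = 0):
    """Find ``motif`` in ``seq`` allowing up to ``max_mismatch`` substitutions.

    An exact match wins and the leftmost exact match is returned; otherwise
    the leftmost window at the minimal Hamming distance ``<= max_mismatch``.
    Returns :class:`AnchorMatch` or :class:`AnchorNotFound`.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else str(seq)
    m = len(motif)
    if m < 3:
        raise ValueError("anchor motif must be at least 3 residues")
    if max_mismatch >= m:
        raise ValueError("max_mismatch must be smaller than the motif length")
    if m > len(residues):
        return AnchorNotFound(motif=motif, best_distance=m)
    best_start, best_dist = -1, m + 1
    for i in range(len(residues) - m + 1):
        dist = sum(1 for a, b in zip(residues[i : i + m], motif) if a != b)
        if dist < best_dist:
            best_start, best_dist = i, dist
            if dist == 0:
                break
    if best_dist <= max_mismatch:
        return AnchorMatch(motif=motif, start=best_start, end=best_start + m, mismatches=best_dist)
    return AnchorNotFound(motif=motif, best_distance=best_dist)


def segment_domains(
    seq: SequenceRecord,
    ntd_anchor: str = NTD_ANCHOR,
    ctd_anchor: str = CTD_ANCHOR,
    max_mismatch: int = 1,
) -> DomainSegmentation:
    """Split a protein into NTD, dehydrogenase core, and CTD.

    ``core_start`` is the start of the RPLVALL match and ``core_end`` the end
    of the NCVN match (NCVN belongs to the core; the CTD starts strictly
    after it).  A missing NTD anchor empties the NTD (flag ``no_ntd_anchor``);
    a missing CTD anchor empties the CTD (flag ``no_ctd_anchor``); an exactly
    core-terminal NCVN yields an empty CTD flagged ``tailless``.  Both
    anchors missing raises :class:`SegmentationError`.
    """
    L = len(seq.residues)
    flags: set = set()
    ntd_hit = find_anchor(seq, ntd_anchor, max_mismatch)
    if isinstance(ntd_hit, AnchorMatch):
        core_start = ntd_hit.start
    else:
        core_start = 0
        flags.add("no_ntd_anchor")
    # search the CTD anchor only downstream of the core start
    tail = seq.residues[core_start:]
    ctd_hit = find_anchor(tail, ctd_anchor, max_mismatch)
    if isinstance(ctd_hit, AnchorMatch):
        core_end = core_start + ctd_hit.end
    else:
        core_end = L
        flags.add("no_ctd_anchor")
    if "no_ntd_anchor" in flags and "no_ctd_anchor" in flags:
        raise SegmentationError(
            f"record {seq.id!r}: neither anchor ({ntd_anchor!r}, {ctd_anchor!r}) found "
            f"within {max_mismatch} mismatches"
        )
    if isinstance(ctd_hit, AnchorMatch) and core_end == L:
        flags.add("tailless")
    return DomainSegmentation(ntd=(0, core_start), core=(core_start, core_end), ctd=(core_end, L), flags=flags)


def classify_isoform(
    segmentation: DomainSegmentation,
    seq: SequenceRecord,
    endings=DEFAULT_ENDING_CATALOG,
    short_threshold: int = 40,
    ribeye_threshold: int = 300,
    terminal_k: int = 7,
) -> IsoformCall:
    """Type an isoform as long or short and label its terminal motif.

    ``short`` iff the CTD is shorter than ``short_threshold`` residues; the
    ending label is the longest catalogued motif that is a suffix of the
    sequence (else ``"novel"``); NTDs of ``ribeye_threshold`` residues or
    more are flagged as RIBEYE-like N-terminal extensions.
    """
    ctd_len = segmentation.ctd_length
    form = "short" if ctd_len < short_threshold else "long"
    label = "novel"
    best = -1
    for motif in endings:
        if seq.residues.endswith(motif) and len(motif) > best:
            label, best = motif, len(motif)
    ntd_ext = "ribeye_like" if segmentation.ntd_length >= ribeye_threshold else "none"
    return IsoformCall(
        form=form,
        ending_label=label,
        ctd_length=ctd_len,
        ntd_extension=ntd_ext,
        terminal_kmer=seq.residues[-terminal_k:],
    )
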