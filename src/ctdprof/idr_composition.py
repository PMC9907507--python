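"""CTD composition panel and IDR charge-phase classification.

For each sequence the panel reports length, the fraction of the
structure-breaking residues P/G/A, the fraction of hydrophobic residues
(M, I, V, L, F, Y, W), and the charge bookkeeping of the Das-Pappu phase
diagram: f+ (K, R), f- (D, E), FCR = f+ + f-, and NCPR = f+ - f- (stored
signed; the magnitude drives thresholds).  Histidine is treated as
uncharged.  The ambiguity code X is excluded from both numerator and
denominator of every fraction.

Two classifications are reported side by side: the full Das-Pappu region
(R1-R5) and a simpler weak-polyampholyte flag (FCR < 0.3 and |NCPR| < 0.25)
as used in comparative surveys of CtBP C-termini.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping

from .records import SequenceRecord
from .segmentation import DomainSegmentation

HYDROPHOBIC = frozenset("MIVLFYW")
PGA = frozenset("PGA")
POSITIVE = frozenset("KR")
NEGATIVE = frozenset("DE")

#: Disorder propensity of the classic structure-breaking residues; proline
#: is maximally disorder-promoting.
DEFAULT_DISORDER_PROPENSITY: Dict[str, float] = {"P": 1.0, "A": 0.45, "G": 0.43}

PHASE_LABELS = (
    "R1_weak",
    "R2_boundary",
    "R3_strong_polyampholyte",
    "R4_negative_polyelectrolyte",
    "R5_positive_polyelectrolyte",
)


class CompositionError(ValueError):
    """Raised for empty or all-ambiguous inputs."""


@dataclass
class CompositionProfile:
    """Composition panel for one sequence (fractions over non-X residues)."""

    length_aa: int
    frac_pga: float
    frac_hydrophobic: float
    f_pos: float
    f_neg: float
    fcr: float
    ncpr_signed: float
    phase_label: str = ""
    weak_polyampholyte_flag: bool = False

    @property
    def ncpr(self) -> float:
        """Net charge per residue as a magnitude."""
        return abs(self.ncpr_signed)

    def as_row(self, **extra) -> dict:
        row = dict(extra)
        row.update(
            length_aa=self.length_aa,
            frac_pga=self.frac_pga,
            frac_hydrophobic=self.frac_hydrophobic,
            f_pos=self.f_pos,
            f_neg=self.f_neg,
            fcr=self.fcr,
            ncpr=self.ncpr,
            ncpr_signed=self.ncpr_signed,
            phase_label=self.phase_label,
            weak_polyampholyte_flag=self.weak_polyampholyte_flag,
        )
        return row


def composition_profile(seq) -> CompositionProfile:
    """Exact counting composition panel with phase classification attached.

    ``length_aa`` counts all residues including X; every fraction uses the
    non-X count as denominator.  Raises :class:`CompositionError` on empty
    or all-X input.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else str(seq)
    if not residues:
        raise CompositionError("cannot profile an empty sequence")
    counts = Counter(residues)
    denom = sum(n for aa, n in counts.items() if aa != "X")
    if denom == 0:
        raise CompositionError("sequence is all ambiguity codes; fractions undefined")
    f_pos = sum(counts[aa] for aa in POSITIVE) / denom
    f_neg = sum(counts[aa] for aa in NEGATIVE) / denom
    profile = CompositionProfile(
        length_aa=len(residues),
        frac_pga=sum(counts[aa] for aa in PGA) / denom,
        frac_hydrophobic=sum(counts[aa] for aa in HYDROPHOBIC) / denom,
        f_pos=f_pos,
        f_neg=f_neg,
        fcr=f_pos + f_neg,
        ncpr_signed=f_pos - f_neg,
    )
    label, flag = phase_classify(profile)
    profile.phase_label = label
    profile.weak_polyampholyte_flag = flag
    return profile


def phase_classify(profile: CompositionProfile) -> tuple:
    """Das-Pappu region plus the simplified weak-polyampholyte flag.

    Regions: R1 (FCR < 0.25), R2 (0.25 <= FCR <= 0.35), R3 (FCR > 0.35 and
    |NCPR| <= 0.35), R4/R5 (FCR > 0.35 and signed NCPR beyond -0.35/+0.35).
    The flag is independent: FCR < 0.3 and |NCPR| < 0.25.
    """
    fcr, ncpr = profile.fcr, profile.ncpr_signed
    if fcr < 0.25:
        label = "R1_weak"
    elif fcr <= 0.35:
        label = "R2_boundary"
    elif ncpr < -0.35:
        label = "R4_negative_polyelectrolyte"
    elif ncpr > 0.35:
        label = "R5_positive_polyelectrolyte"
    else:
        label = "R3_strong_polyampholyte"
    flag = fcr < 0.3 and abs(ncpr) < 0.25
    return label, flag


def mean_disorder_propensity(
    seq, table: Mapping[str, float] = DEFAULT_DISORDER_PROPENSITY, default: float = 0.0
) -> float:
    """Average per-residue disorder propensity under a configurable table."""
    residues = seq.residues if isinstance(seq, SequenceRecord) else str(seq)
    scored = [table.get(aa, default) for aa in residues if aa != "X"]
    if not scored:
        raise CompositionError("no scorable residues")
    return sum(scored) / len(scored)


def select_longest_ctd(
    segmented: Iterable[tuple],
) -> Dict[str, SequenceRecord]:
    """Pick one CTD per species: the longest, ties to the smallest record id.

    ``segmented`` yields ``(record, segmentation)`` pairs; records must carry
    a non-empty ``species``.  Species whose records are all tailless are
    excluded (the caller sees them missing from the result).
    """
    best: Dict[str, SequenceRecord] = {}
    for record, seg in segmented:
        if not record.species:
            raise CompositionError(f"record {record.id!r} has no species metadata")
        if not isinstance(seg, DomainSegmentation):
            raise TypeError("expected (record, DomainSegmentation) pairs")
        lo, hi = seg.ctd
        if hi <= lo:
            continue  # tailless
        ctd = SequenceRecord(
            id=record.id,
            residues=record.residues[lo:hi],
            species=record.species,
            description=record.description,
        )
        incumbent = best.get(record.species)
        if (
            incumbent is None
            or len(ctd) > len(incumbent)
            or (len(ctd) == len(incumbent) and ctd.id < incumbent.id)
        ):
            best[record.species] = ctd
    return best


@dataclass
class GroupSummary:
    """Unweighted per-group mean/min/max of the numeric panel fields."""

    group: str
    n_species: int
    stats: dict  # field -> {"mean": .., "min": .., "max": ..}


_NUMERIC_FIELDS = (
    "length_aa",
    "frac_pga",
    "frac_hydrophobic",
    "f_pos",
    "f_neg",
    "fcr",
    "ncpr",
)


def aggregate_by_group(
    profiles: Mapping[str, CompositionProfile], grouping: Mapping[str, str]
) -> list:
    """Average per-species profiles within groups (clades).

    Every species in ``profiles`` must be mapped by ``grouping``; otherwise
    the unmapped species are listed in the error.  Means are unweighted
    across species.
    """
    missing = sorted(set(profiles) - set(grouping))
    if missing:
        raise CompositionError(f"species missing from grouping table: {missing}")
    by_group: Dict[str, list] = {}
    for species, profile in profiles.items():
        by_group.setdefault(grouping[species], []).append(profile)
    summaries = []
    for group in sorted(by_group):
        members = by_group[group]
        stats = {}
        for fieldname in _NUMERIC_FIELDS:
            values = [getattr(p, fieldname) for p in members]
            stats[fieldname] = {
                "mean": sum(values) / len(values),
                "min": min(values),
                "max": max(values),
            }
        summaries.append(GroupSummary(group=group, n_species=len(members), stats=stats))
    return summaries


def read_grouping_table(path) -> Dict[str, str]:
    """Read a two-column TSV mapping species to group (header optional)."""
    mapping: Dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise CompositionError(f"grouping table line {line_no + 1} has no group column")
            if line_no == 0 and parts[0].lower() in ("species", "taxon"):
                continue
            mapping[parts[0]] = parts[1]
    return mapping
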