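"""Synthetic CtBP-like protein families with known ground truth.

The generator emulates the architecture of real CtBP proteins: an NTD, a
~330-residue dehydrogenase core beginning with RPLVALL and ending with
NCVN, and a ~90-100-residue disordered CTD built from deeply conserved
blocks (a KEY+aromatic prefix, a PELNGAIYRY-type central block, AHSTT, and
a PEPSEVH terminus) separated by P/G/A-rich spacers.  Species descend from
a single ancestor under independent per-site substitution (uniform over the
19 alternative residues); conserved blocks and anchors mutate at a reduced
rate (``block_protection``).  Optional short isoforms truncate after the
core and append a lineage-specific ending; optional paralog duplicates
overwrite the CTD start/end motifs family by family.

Every record's true domain boundaries and labels are recorded, so
segmentation, composition, conservation, and classification can all be
scored against known truth.  Closed-form expectations (spacer composition,
per-site identity) make the generator its own oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .records import Alignment, GappedRecord, SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Spacer residue sampling weights, tuned so spacers look like CtBP CTD
#: linkers: expected P+G+A fraction 0.45, expected charged fraction 0.14,
#: hydrophobics rare.
DEFAULT_SPACER_WEIGHTS: Dict[str, float] = {
    "P": 0.20, "A": 0.15, "G": 0.10,
    "K": 0.04, "R": 0.03, "D": 0.04, "E": 0.03,
    "S": 0.10, "T": 0.08, "Q": 0.06, "N": 0.05, "H": 0.03,
    "V": 0.03, "L": 0.02, "I": 0.01, "M": 0.005, "F": 0.01, "Y": 0.005,
    "C": 0.01, "W": 0.0,
}

#: Folded-core residue weights: hydrophobic-rich (~33%) with ~22% P/G/A,
#: matching the composition contrast between core and CTD.
_CORE_WEIGHTS: Dict[str, float] = {
    "A": 0.09, "G": 0.08, "P": 0.05,
    "M": 0.02, "I": 0.05, "V": 0.08, "L": 0.10, "F": 0.04, "Y": 0.02, "W": 0.02,
    "K": 0.05, "R": 0.05, "D": 0.06, "E": 0.07,
    "S": 0.06, "T": 0.05, "N": 0.04, "Q": 0.03, "H": 0.02, "C": 0.02,
}

DEFAULT_CTD_BLOCKS = ("KEYW", "PELNGAIYRY", "AHSTT", "PEPSEVH")
DEFAULT_SHORT_ENDINGS = ("SNQEK", "APECARP")


class FamilySpecError(ValueError):
    """Raised when a family specification violates its invariants."""


def _weighted_string(rng: np.random.Generator, length: int, weights: Dict[str, float]) -> str:
    letters = sorted(weights)
    p = np.array([weights[aa] for aa in letters], dtype=float)
    p = p / p.sum()
    return "".join(rng.choice(list(letters), size=length, p=p))


def _build_core_template(length: int = 330, seed: int = 77003) -> str:
    """A fixed dehydrogenase-core template: RPLVALL ... NCVN, anchors unique."""
    rng = np.random.default_rng(seed)
    interior_len = length - len("RPLVALL") - len("NCVN")
    while True:
        interior = _weighted_string(rng, interior_len, _CORE_WEIGHTS)
        template = "RPLVALL" + interior + "NCVN"
        if template.count("RPLVALL") == 1 and template.count("NCVN") == 1:
            return template


def _build_ntd_template(length: int = 60, seed: int = 77005) -> str:
    rng = np.random.default_rng(seed)
    while True:
        ntd = _weighted_string(rng, length, _CORE_WEIGHTS)
        if "RPLVALL" not in ntd and "NCVN" not in ntd:
            return ntd


DEFAULT_CORE_TEMPLATE = _build_core_template()
DEFAULT_NTD_TEMPLATE = _build_ntd_template()


@dataclass
class ParalogFamilySpec:
    """One vertebrate-style duplicate family with its CTD boundary motifs."""

    name: str
    ctd_start_motif: str
    ctd_end_motif: str


@dataclass
class FamilySpec:
    """Parameters of one simulated CtBP-like family."""

    n_species: int = 20
    tree: str = "star"  # star | balanced
    p_sub: float = 0.05
    ntd_template: str = DEFAULT_NTD_TEMPLATE
    core_template: str = DEFAULT_CORE_TEMPLATE
    ctd_blocks: tuple = DEFAULT_CTD_BLOCKS
    spacer_lengths: tuple = (22, 22, 22)
    spacer_weights: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPACER_WEIGHTS)
    )
    block_protection: float = 0.1
    short_isoform_prob: float = 0.3
    short_endings: tuple = DEFAULT_SHORT_ENDINGS
    paralog_families: Optional[List[ParalogFamilySpec]] = None
    indel_prob: float = 0.0  # per spacer site deletion probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise FamilySpecError("n_species must be >= 1")
        if not 0.0 <= self.p_sub <= 1.0:
            raise FamilySpecError("p_sub must be in [0, 1]")
        if self.tree not in ("star", "balanced"):
            raise FamilySpecError(f"unknown tree shape {self.tree!r}")
        if self.core_template.count("RPLVALL") != 1 or self.core_template.count("NCVN") != 1:
            raise FamilySpecError("core_template must contain RPLVALL and NCVN exactly once")
        weights = self.spacer_weights
        if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
            raise FamilySpecError("spacer weights must be non-negative and not all zero")
        if len(self.spacer_lengths) != len(self.ctd_blocks) - 1:
            raise FamilySpecError(
                "need exactly one spacer between consecutive CTD blocks "
                f"({len(self.ctd_blocks) - 1} spacers for {len(self.ctd_blocks)} blocks)"
            )
        if not 0.0 <= self.short_isoform_prob <= 1.0:
            raise FamilySpecError("short_isoform_prob must be in [0, 1]")


@dataclass
class SyntheticFamily:
    """Generated family with complete ground truth."""

    records: List[SequenceRecord]
    true_alignment: Alignment
    true_boundaries: Dict[str, dict]  # id -> {"ntd": (a,b), "core": (a,b), "ctd": (a,b)}
    true_labels: Dict[str, dict]  # id -> {"form", "ending", "family", "species"}
    spec: FamilySpec
    ancestor: str
    protected_mask: np.ndarray  # over ancestor coordinates; True = block/anchor site
    spacer_mask: np.ndarray  # over ancestor coordinates; True = CTD spacer site


def _assemble_ancestor(spec: FamilySpec, rng: np.random.Generator):
    """Ancestral sequence plus protection / spacer masks and boundaries."""
    parts: List[str] = [spec.ntd_template, spec.core_template]
    protected: List[np.ndarray] = [
        np.zeros(len(spec.ntd_template), dtype=bool),
        np.zeros(len(spec.core_template), dtype=bool),
    ]
    spacer: List[np.ndarray] = [
        np.zeros(len(spec.ntd_template), dtype=bool),
        np.zeros(len(spec.core_template), dtype=bool),
    ]
    # anchors are protected like blocks
    core_prot = protected[1]
    start = spec.core_template.index("RPLVALL")
    core_prot[start : start + 7] = True
    start = spec.core_template.index("NCVN")
    core_prot[start : start + 4] = True
    for i, block in enumerate(spec.ctd_blocks):
        parts.append(block)
        protected.append(np.ones(len(block), dtype=bool))
        spacer.append(np.zeros(len(block), dtype=bool))
        if i < len(spec.spacer_lengths):
            sp = _weighted_string(rng, spec.spacer_lengths[i], spec.spacer_weights)
            parts.append(sp)
            protected.append(np.zeros(len(sp), dtype=bool))
            spacer.append(np.ones(len(sp), dtype=bool))
    ancestor = "".join(parts)
    protected_mask = np.concatenate(protected)
    spacer_mask = np.concatenate(spacer)
    ntd_end = len(spec.ntd_template)
    core_end = ntd_end + len(spec.core_template)
    boundaries = {
        "ntd": (0, ntd_end),
        "core": (ntd_end, core_end),
        "ctd": (core_end, len(ancestor)),
    }
    return ancestor, protected_mask, spacer_mask, boundaries


def _mutate(
    seq: np.ndarray,
    p_sub: float,
    protected: np.ndarray,
    protection: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One branch of per-site substitution; uniform over the 19 alternatives."""
    rates = np.where(protected, p_sub * protection, p_sub)
    hit = rng.random(len(seq)) < rates
    out = seq.copy()
    if hit.any():
        # draw an offset 1..19 and rotate within the alphabet: uniform over
        # the 19 residues different from the current one
        offsets = rng.integers(1, 20, size=int(hit.sum()))
        out[hit] = (out[hit] + offsets) % 20
    return out


def _encode(s: str) -> np.ndarray:
    return np.array([_AA_INDEX[c] for c in s], dtype=np.int64)


def _decode(arr: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in arr)


def _descend(spec: FamilySpec, ancestor_arr, protected, rng) -> List[np.ndarray]:
    """Leaf sequences for the configured tree shape."""
    if spec.tree == "star":
        return [
            _mutate(ancestor_arr, spec.p_sub, protected, spec.block_protection, rng)
            for _ in range(spec.n_species)
        ]
    # balanced: repeatedly bifurcate until enough leaves exist
    leaves = [ancestor_arr]
    while len(leaves) < spec.n_species:
        nxt = []
        for leaf in leaves:
            nxt.append(_mutate(leaf, spec.p_sub, protected, spec.block_protection, rng))
            nxt.append(_mutate(leaf, spec.p_sub, protected, spec.block_protection, rng))
        leaves = nxt
    return leaves[: spec.n_species]


def generate_family(spec: FamilySpec) -> SyntheticFamily:
    """Generate one family; identical spec + seed gives identical output."""
    rng = np.random.default_rng(spec.seed)
    ancestor, protected_mask, spacer_mask, bounds = _assemble_ancestor(spec, rng)
    ancestor_arr = _encode(ancestor)
    leaf_arrs = _descend(spec, ancestor_arr, protected_mask, rng)

    families = spec.paralog_families or [None]
    ctd_lo, ctd_hi = bounds["ctd"]
    records: List[SequenceRecord] = []
    aligned_rows: List[GappedRecord] = []
    true_boundaries: Dict[str, dict] = {}
    true_labels: Dict[str, dict] = {}

    for s, leaf in enumerate(leaf_arrs):
        species = f"sp{s:03d}"
        # spacer-only deletions, shared by all isoforms/paralogs of the species
        if spec.indel_prob > 0:
            deleted = (rng.random(len(leaf)) < spec.indel_prob) & spacer_mask
        else:
            deleted = np.zeros(len(leaf), dtype=bool)
        keep = ~deleted
        make_short = rng.random() < spec.short_isoform_prob
        short_ending = (
            spec.short_endings[int(rng.integers(len(spec.short_endings)))]
            if spec.short_endings
            else ""
        )
        for fam in families:
            fam_name = fam.name if fam else "CtBP"
            seq_arr = leaf.copy()
            if fam is not None:
                start_arr = _encode(fam.ctd_start_motif)
                end_arr = _encode(fam.ctd_end_motif)
                seq_arr[ctd_lo : ctd_lo + len(start_arr)] = start_arr
                seq_arr[ctd_hi - len(end_arr) : ctd_hi] = end_arr
            full = _decode(seq_arr)
            kept = _decode(seq_arr[keep])
            rec_id = f"{species}|{fam_name}|long"
            records.append(
                SequenceRecord(
                    id=rec_id,
                    residues=kept,
                    species=species,
                    description=f"species={species} family={fam_name} form=long",
                )
            )
            n_del_ntd = int(deleted[: bounds["ntd"][1]].sum())
            n_del_core = int(deleted[: bounds["core"][1]].sum())
            true_boundaries[rec_id] = {
                "ntd": (0, bounds["ntd"][1] - n_del_ntd),
                "core": (bounds["ntd"][1] - n_del_ntd, bounds["core"][1] - n_del_core),
                "ctd": (bounds["core"][1] - n_del_core, len(kept)),
            }
            ending = fam.ctd_end_motif if fam else spec.ctd_blocks[-1]
            true_labels[rec_id] = {
                "species": species,
                "family": fam_name,
                "form": "long",
                "ending": ending,
            }
            gapped = "".join(
                "-" if deleted[i] else full[i] for i in range(len(full))
            )
            aligned_rows.append(
                GappedRecord(id=rec_id, residues=gapped, species=species)
            )
        if make_short:
            base = leaf  # short forms truncate before any family CTD motif
            core_end = bounds["core"][1]
            head_keep = keep[:core_end]
            head = _decode(base[:core_end][head_keep])
            short_seq = head + short_ending
            rec_id = f"{species}|CtBP|short"
            records.append(
                SequenceRecord(
                    id=rec_id,
                    residues=short_seq,
                    species=species,
                    description=f"species={species} family=CtBP form=short",
                )
            )
            n_del_ntd = int(deleted[: bounds["ntd"][1]].sum())
            true_boundaries[rec_id] = {
                "ntd": (0, bounds["ntd"][1] - n_del_ntd),
                "core": (bounds["ntd"][1] - n_del_ntd, len(head)),
                "ctd": (len(head), len(short_seq)),
            }
            true_labels[rec_id] = {
                "species": species,
                "family": "CtBP",
                "form": "short",
                "ending": short_ending,
            }

    return SyntheticFamily(
        records=records,
        true_alignment=Alignment(records=aligned_rows),
        true_boundaries=true_boundaries,
        true_labels=true_labels,
        spec=spec,
        ancestor=ancestor,
        protected_mask=protected_mask,
        spacer_mask=spacer_mask,
    )


def expected_spacer_composition(spec: FamilySpec) -> dict:
    """Closed-form expected spacer composition under the sampling weights.

    Returns expected fractions for the PGA, hydrophobic, and charged residue
    classes; the oracle for composition parameter-recovery tests.
    """
    weights = spec.spacer_weights
    total = sum(weights.values())
    if total <= 0:
        raise FamilySpecError("spacer weights sum to zero")

    def class_fraction(members: str) -> float:
        return sum(weights.get(aa, 0.0) for aa in members) / total

    f_pos = class_fraction("KR")
    f_neg = class_fraction("DE")
    return {
        "frac_pga": class_fraction("PGA"),
        "frac_hydrophobic": class_fraction("MIVLFYW"),
        "f_pos": f_pos,
        "f_neg": f_neg,
        "fcr": f_pos + f_neg,
        "ncpr_signed": f_pos - f_neg,
    }


def expected_pairwise_site_identity(p_sub: float, n_alphabet: int = 20) -> float:
    """Expected per-site identity between two star-tree leaves.

    Both leaves mutate independently from the ancestor with probability
    ``p``; a substitution is uniform over the other ``n-1`` residues, so two
    leaves agree when neither mutated or both mutated to the same residue:
    ``(1-p)^2 + p^2/(n-1)``.
    """
    k = n_alphabet - 1
    return (1.0 - p_sub) ** 2 + p_sub**2 / k


@dataclass
class ParalogBenchmark:
    """Queries with known family labels plus the two reference proteins."""

    queries: List[SequenceRecord]
    ref1: SequenceRecord
    ref2: SequenceRecord
    true_family: Dict[str, str]  # query id -> expected call


def generate_paralog_benchmark(
    n_queries: int = 200,
    seed: int = 0,
    concordant: bool = True,
    ref_branch_p: float = 0.05,
    query_branch_p: float = 0.08,
    spec: Optional[FamilySpec] = None,
) -> ParalogBenchmark:
    """Vertebrate-style paralog queries with controllable signal agreement.

    Two reference lineages (the CtBP1 and CtBP2 sides) diverge from a common
    ancestor by one substitution branch each (``ref_branch_p`` per site, so
    their cores are ~90% identical at the default).  Each query descends
    from one side by a further branch (kept well below the canonical-call
    identity threshold) and carries that side's CTD
    start/end motifs (KEYL...PADQ or KEFF...LTEQ) when ``concordant``; with
    ``concordant=False`` the motifs come from the *opposite* side, so
    identity and motif evidence always disagree and the expected call is
    ``unresolved``.
    """
    from .classification import FAMILY1_MOTIFS, FAMILY2_MOTIFS

    spec = spec or FamilySpec(seed=seed)
    rng = np.random.default_rng(seed)
    ancestor, protected_mask, _spacer_mask, bounds = _assemble_ancestor(spec, rng)
    ancestor_arr = _encode(ancestor)
    ref_arrs = {
        "1": _mutate(ancestor_arr, ref_branch_p, protected_mask, spec.block_protection, rng),
        "2": _mutate(ancestor_arr, ref_branch_p, protected_mask, spec.block_protection, rng),
    }
    ctd_lo, ctd_hi = bounds["ctd"]
    motifs = {"1": FAMILY1_MOTIFS, "2": FAMILY2_MOTIFS}
    for side, arr in ref_arrs.items():
        start, end = motifs[side]
        arr[ctd_lo : ctd_lo + len(start)] = _encode(start)
        arr[ctd_hi - len(end) : ctd_hi] = _encode(end)
    ref1 = SequenceRecord(id="ref_CtBP1", residues=_decode(ref_arrs["1"]))
    ref2 = SequenceRecord(id="ref_CtBP2", residues=_decode(ref_arrs["2"]))
    queries: List[SequenceRecord] = []
    true_family: Dict[str, str] = {}
    for q in range(n_queries):
        side = "1" if rng.random() < 0.5 else "2"
        arr = _mutate(
            ref_arrs[side], query_branch_p, protected_mask, spec.block_protection, rng
        )
        motif_side = side if concordant else ("2" if side == "1" else "1")
        start, end = motifs[motif_side]
        arr[ctd_lo : ctd_lo + len(start)] = _encode(start)
        arr[ctd_hi - len(end) : ctd_hi] = _encode(end)
        qid = f"q{q:04d}"
        queries.append(SequenceRecord(id=qid, residues=_decode(arr)))
        true_family[qid] = f"CtBP{side}_like" if concordant else "unresolved"
    return ParalogBenchmark(queries=queries, ref1=ref1, ref2=ref2, true_family=true_family)


def resolved_spec_dict(spec: FamilySpec) -> dict:
    """JSON-serialisable copy of a spec (for run manifests)."""
    d = dataclasses.asdict(spec)
    d["ctd_blocks"] = list(spec.ctd_blocks)
    d["spacer_lengths"] = list(spec.spacer_lengths)
    d["short_endings"] = list(spec.short_endings)
    if spec.paralog_families:
        d["paralog_families"] = [dataclasses.asdict(f) for f in spec.paralog_families]
    return d
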