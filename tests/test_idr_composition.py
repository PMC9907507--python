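import random

import pytest
from hypothesis import given, settings, strategies as st

from ctdprof.idr_composition import (
    CompositionError,
    CompositionProfile,
    aggregate_by_group,
    composition_profile,
    mean_disorder_propensity,
    phase_classify,
    select_longest_ctd,
)
from ctdprof.records import SequenceRecord
from ctdprof.segmentation import DomainSegmentation

AA = "ACDEFGHIKLMNPQRSTVWY"


def counting_oracle(seq):
    """Independent single-pass counting of the composition panel."""
    n = pga = hyd = pos = neg = 0
    for ch in seq:
        if ch == "X":
            continue
        n += 1
        if ch in "PGA":
            pga += 1
        if ch in "MIVLFYW":
            hyd += 1
        if ch in "KR":
            pos += 1
        if ch in "DE":
            neg += 1
    return pga / n, hyd / n, pos / n, neg / n


class TestCompositionProfile:
    def test_charge_bookkeeping(self):
        p = composition_profile("KKDD")
        assert (p.f_pos, p.f_neg, p.fcr, p.ncpr) == (0.5, 0.5, 1.0, 0.0)

    def test_pga_only(self):
        p = composition_profile("PPGGAA")
        assert (p.frac_pga, p.frac_hydrophobic) == (1.0, 0.0)

    def test_hydrophobic_set(self):
        p = composition_profile("MIVLFYWAAA")
        assert p.frac_hydrophobic == pytest.approx(0.7)
        assert p.frac_pga == pytest.approx(0.3)

    def test_x_excluded_from_denominator(self):
        assert composition_profile("KKXX").f_pos == 1.0
        assert composition_profile("KKXX").length_aa == 4

    def test_errors(self):
        with pytest.raises(CompositionError):
            composition_profile("")
        with pytest.raises(CompositionError):
            composition_profile("XXX")

    def test_matches_counting_oracle_on_random_strings(self):
        """Exact agreement with an independent counter on 1,000 strings."""
        rng = random.Random(1)
        for _ in range(1000):
            seq = "".join(rng.choice(AA + "X") for _ in range(rng.randint(1, 60)))
            if set(seq) == {"X"}:
                continue
            p = composition_profile(seq)
            pga, hyd, pos, neg = counting_oracle(seq)
            assert p.frac_pga == pga
            assert p.frac_hydrophobic == hyd
            assert p.f_pos == pos
            assert p.f_neg == neg
            assert p.fcr == pos + neg
            assert p.ncpr_signed == pos - neg


class TestPhaseClassify:
    @pytest.mark.parametrize(
        "fcr,ncpr_signed,label,flag",
        [
            (0.10, 0.05, "R1_weak", True),
            (1.00, -1.00, "R4_negative_polyelectrolyte", False),
            (1.00, 1.00, "R5_positive_polyelectrolyte", False),
            (0.29, 0.20, "R2_boundary", True),  # flag and region disagree
            (0.50, 0.10, "R3_strong_polyampholyte", False),
            (0.25, 0.0, "R2_boundary", True),
        ],
    )
    def test_regions_and_flag(self, fcr, ncpr_signed, label, flag):
        profile = CompositionProfile(
            length_aa=10, frac_pga=0, frac_hydrophobic=0,
            f_pos=(fcr + ncpr_signed) / 2, f_neg=(fcr - ncpr_signed) / 2,
            fcr=fcr, ncpr_signed=ncpr_signed,
        )
        assert phase_classify(profile) == (label, flag)

    def test_poly_e_classification_end_to_end(self):
        p = composition_profile("EEEEEEEE")
        assert p.phase_label == "R4_negative_polyelectrolyte"
        assert not p.weak_polyampholyte_flag


@settings(derandomize=True, max_examples=200)
@given(st.text(alphabet=AA, min_size=1, max_size=120))
def test_composition_invariants(seq):
    """ncpr <= fcr; class fractions conserve probability mass."""
    p = composition_profile(seq)
    assert p.ncpr <= p.fcr + 1e-12
    rest = sum(1 for c in seq if c not in "PGA") / len(seq)
    assert p.frac_pga + rest == pytest.approx(1.0)
    assert p.fcr == pytest.approx(p.f_pos + p.f_neg)


def test_mean_disorder_propensity_defaults():
    # P scores 1.0, A 0.45, G 0.43, everything else 0
    assert mean_disorder_propensity("PAG") == pytest.approx((1.0 + 0.45 + 0.43) / 3)


def _seg_for(record, ctd_len):
    L = len(record.residues)
    return DomainSegmentation(ntd=(0, 0), core=(0, L - ctd_len), ctd=(L - ctd_len, L))


class TestSelectLongestCtd:
    def test_longest_wins(self):
        long = SequenceRecord(id="a", residues="A" * 100 + "P" * 90, species="sp1")
        short = SequenceRecord(id="b", residues="A" * 100 + "P" * 8, species="sp1")
        chosen = select_longest_ctd(
            [(long, _seg_for(long, 90)), (short, _seg_for(short, 8))]
        )
        assert chosen["sp1"].id == "a"
        assert len(chosen["sp1"]) == 90

    def test_tie_breaks_to_smaller_id(self):
        rec_a = SequenceRecord(id="a", residues="A" * 50 + "P" * 90, species="sp1")
        rec_b = SequenceRecord(id="b", residues="A" * 50 + "G" * 90, species="sp1")
        chosen = select_longest_ctd(
            [(rec_b, _seg_for(rec_b, 90)), (rec_a, _seg_for(rec_a, 90))]
        )
        assert chosen["sp1"].id == "a"

    def test_tailless_only_species_excluded(self):
        rec = SequenceRecord(id="a", residues="A" * 50, species="sp1")
        assert select_longest_ctd([(rec, _seg_for(rec, 0))]) == {}


class TestAggregateByGroup:
    def _profile(self, frac_pga):
        return CompositionProfile(
            length_aa=90, frac_pga=frac_pga, frac_hydrophobic=0.1,
            f_pos=0.05, f_neg=0.08, fcr=0.13, ncpr_signed=-0.03,
        )

    def test_unweighted_mean(self):
        profiles = {"sp1": self._profile(0.40), "sp2": self._profile(0.44)}
        (summary,) = aggregate_by_group(profiles, {"sp1": "insects", "sp2": "insects"})
        assert summary.group == "insects"
        assert summary.n_species == 2
        assert summary.stats["frac_pga"]["mean"] == pytest.approx(0.42)
        assert summary.stats["frac_pga"]["min"] == 0.40
        assert summary.stats["frac_pga"]["max"] == 0.44

    def test_singleton_group_is_identity(self):
        profiles = {"sp1": self._profile(0.37)}
        (summary,) = aggregate_by_group(profiles, {"sp1": "molluscs"})
        assert summary.stats["frac_pga"]["mean"] == 0.37

    def test_unmapped_species_listed(self):
        profiles = {"sp1": self._profile(0.4), "sp2": self._profile(0.4)}
        with pytest.raises(CompositionError, match="sp2"):
            aggregate_by_group(profiles, {"sp1": "insects"})
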