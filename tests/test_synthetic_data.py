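import numpy as np
import pytest

from ctdprof.idr_composition import composition_profile
from ctdprof.segmentation import classify_isoform, segment_domains
from ctdprof.synthetic_data import (
    FamilySpec,
    FamilySpecError,
    ParalogFamilySpec,
    expected_pairwise_site_identity,
    expected_spacer_composition,
    generate_family,
)


class TestFamilySpecValidation:
    def test_bad_rate(self):
        with pytest.raises(FamilySpecError):
            FamilySpec(p_sub=1.5)

    def test_core_template_must_contain_anchors_once(self):
        with pytest.raises(FamilySpecError):
            FamilySpec(core_template="AAAA")
        with pytest.raises(FamilySpecError):
            FamilySpec(core_template="RPLVALLNCVNNCVN")

    def test_zero_weights_rejected(self):
        with pytest.raises(FamilySpecError):
            FamilySpec(spacer_weights={"P": 0.0})

    def test_spacer_block_count_mismatch(self):
        with pytest.raises(FamilySpecError):
            FamilySpec(spacer_lengths=(10,))


class TestGenerateFamily:
    def test_zero_rate_everyone_matches_ancestor(self):
        fam = generate_family(FamilySpec(n_species=4, p_sub=0.0, short_isoform_prob=0.0, seed=1))
        assert all(r.residues == fam.ancestor for r in fam.records)

    def test_seed_determinism(self):
        a = generate_family(FamilySpec(n_species=6, seed=42))
        b = generate_family(FamilySpec(n_species=6, seed=42))
        assert [r.residues for r in a.records] == [r.residues for r in b.records]
        assert a.true_boundaries == b.true_boundaries
        assert a.true_labels == b.true_labels

    def test_different_seeds_differ(self):
        a = generate_family(FamilySpec(n_species=6, seed=1))
        b = generate_family(FamilySpec(n_species=6, seed=2))
        assert [r.residues for r in a.records] != [r.residues for r in b.records]

    def test_records_consistent_with_true_boundaries(self, small_family):
        for rec in small_family.records:
            b = small_family.true_boundaries[rec.id]
            assert b["ntd"][0] == 0
            assert b["ctd"][1] == len(rec.residues)
            assert b["ntd"][1] == b["core"][0]
            assert b["core"][1] == b["ctd"][0]

    def test_ctd_length_in_realistic_range(self, zero_rate_family):
        rec = zero_rate_family.records[0]
        lo, hi = zero_rate_family.true_boundaries[rec.id]["ctd"]
        assert 90 <= hi - lo <= 100

    def test_short_isoforms_have_true_short_labels(self):
        fam = generate_family(FamilySpec(n_species=30, short_isoform_prob=1.0, seed=5))
        shorts = [r for r in fam.records if fam.true_labels[r.id]["form"] == "short"]
        assert len(shorts) == 30
        for rec in shorts:
            lo, hi = fam.true_boundaries[rec.id]["ctd"]
            assert hi - lo in (5, 7)  # SNQEK or APECARP
            assert rec.residues.endswith(fam.true_labels[rec.id]["ending"])

    def test_paralogs_carry_family_motifs(self):
        fams = [
            ParalogFamilySpec("CtBP1_like", "KEYL", "PADQ"),
            ParalogFamilySpec("CtBP2_like", "KEFF", "LTEQ"),
        ]
        fam = generate_family(
            FamilySpec(n_species=4, paralog_families=fams, short_isoform_prob=0.0, seed=9)
        )
        for rec in fam.records:
            label = fam.true_labels[rec.id]
            lo, hi = fam.true_boundaries[rec.id]["ctd"]
            ctd = rec.residues[lo:hi]
            expected = {"CtBP1_like": ("KEYL", "PADQ"), "CtBP2_like": ("KEFF", "LTEQ")}[
                label["family"]
            ]
            assert ctd.startswith(expected[0])
            assert ctd.endswith(expected[1])

    def test_spacer_indels_tracked_in_alignment(self):
        fam = generate_family(
            FamilySpec(n_species=6, indel_prob=0.2, short_isoform_prob=0.0, seed=21)
        )
        aln = fam.true_alignment
        assert aln.n_columns == len(fam.ancestor)
        for row, rec in zip(aln.records, fam.records):
            assert row.residues.replace("-", "") == rec.residues
        # label recovery still exact: degapped boundaries match segmentation
        for rec in fam.records:
            seg = segment_domains(rec)
            assert seg.ctd == fam.true_boundaries[rec.id]["ctd"]


class TestLabelRecovery:
    def test_isoform_labels_recovered_exactly(self):
        fam = generate_family(FamilySpec(n_species=20, short_isoform_prob=0.5, seed=8))
        for rec in fam.records:
            seg = segment_domains(rec)
            call = classify_isoform(seg, rec)
            truth = fam.true_labels[rec.id]
            assert call.form == truth["form"], rec.id
            if truth["form"] == "short":
                assert call.ending_label == truth["ending"]


class TestClosedFormOracles:
    def test_uniform_weights_expectation(self):
        spec = FamilySpec(spacer_weights={aa: 1.0 for aa in "ACDEFGHIKLMNPQRSTVWY"})
        assert expected_spacer_composition(spec)["frac_pga"] == pytest.approx(3 / 20)

    def test_all_mass_on_proline(self):
        spec = FamilySpec(spacer_weights={"P": 2.0})
        exp = expected_spacer_composition(spec)
        assert exp["frac_pga"] == 1.0
        assert exp["fcr"] == 0.0

    def test_default_weights_design_targets(self):
        exp = expected_spacer_composition(FamilySpec())
        assert exp["frac_pga"] == pytest.approx(0.45)
        assert exp["fcr"] == pytest.approx(0.14)

    def test_spacer_composition_recovery(self):
        """Mean profiled spacer P/G/A over 50 independently seeded species
        lands within +-0.03 of the closed-form expectation."""
        expected = expected_spacer_composition(FamilySpec())["frac_pga"]
        values = []
        for seed in range(50):
            fam = generate_family(
                FamilySpec(n_species=1, p_sub=0.0, short_isoform_prob=0.0, seed=seed)
            )
            rec = fam.records[0]
            spacers = "".join(
                ch for ch, is_spacer in zip(rec.residues, fam.spacer_mask) if is_spacer
            )
            values.append(composition_profile(spacers).frac_pga)
        assert abs(np.mean(values) - expected) <= 0.03

    def test_per_site_identity_matches_closed_form(self):
        """Mean pairwise identity at unprotected sites under star-tree
        substitution at rate 0.1 matches (1-p)^2 + p^2/19 within
        Monte-Carlo tolerance (>= 10,000 site comparisons)."""
        p = 0.1
        expected = expected_pairwise_site_identity(p)
        matches = total = 0
        for seed in range(3):
            fam = generate_family(
                FamilySpec(n_species=12, tree="star", p_sub=p, short_isoform_prob=0.0, seed=seed)
            )
            free = ~fam.protected_mask
            rows = [np.frombuffer(r.residues.encode(), dtype=np.uint8) for r in fam.records]
            for i in range(len(rows)):
                for j in range(i + 1, len(rows)):
                    same = rows[i][free] == rows[j][free]
                    matches += int(same.sum())
                    total += same.size
        assert total >= 10_000
        assert np.mean(matches / total) == pytest.approx(expected, abs=0.01)
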