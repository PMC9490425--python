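"""Allele harmonization: swaps, strand flips, palindromes, audits."""

from __future__ import annotations

import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from mrpipe.exceptions import AnalysisError, ValidationError
from mrpipe.harmonize import (
    HarmonizationStatus,
    complement_alleles,
    harmonize_pair,
    harmonize_sets,
    is_palindromic,
    read_harmonized_tsv,
    write_harmonized_tsv,
)
from mrpipe.summary_io import Role, SnpAssociation, StudySet


def _snp(ea, oa, beta=0.1, se=0.01, p=1e-9, eaf=None, vid="rs1"):
    return SnpAssociation(vid, ea, oa, beta, se, p, eaf=eaf)


class TestAlleleHelpers:
    @pytest.mark.parametrize(
        "allele,comp", [("A", "T"), ("T", "A"), ("C", "G"), ("AG", "TC"), ("gat", "CTA")]
    )
    def test_complement(self, allele, comp):
        assert complement_alleles(allele) == comp

    def test_complement_rejects_non_acgt(self):
        with pytest.raises(ValidationError):
            complement_alleles("N")

    @pytest.mark.parametrize(
        "ea,oa,expected",
        [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
         ("A", "G", False), ("C", "T", False)],
    )
    def test_palindromic_definition(self, ea, oa, expected):
        assert is_palindromic(ea, oa) is expected


class TestHarmonizePair:
    def test_matching_alleles_kept_unchanged(self):
        h = harmonize_pair(_snp("A", "G", beta=0.10), _snp("A", "G", beta=-0.05, se=0.02))
        assert h.status is HarmonizationStatus.KEPT
        assert h.beta_outcome == -0.05
        assert h.se_outcome == 0.02

    def test_swapped_alleles_negate_beta_and_complement_eaf(self):
        h = harmonize_pair(
            _snp("A", "G", beta=0.10, eaf=0.3),
            _snp("G", "A", beta=-0.05, eaf=0.8),
        )
        assert h.status is HarmonizationStatus.ALLELE_FLIPPED
        assert h.beta_outcome == pytest.approx(0.05)
        assert h.eaf_outcome == pytest.approx(0.2)

    def test_strand_flip_preserves_sign_when_aligned(self):
        h = harmonize_pair(_snp("C", "T"), _snp("G", "A", beta=0.03))
        assert h.status is HarmonizationStatus.STRAND_FLIPPED
        assert h.beta_outcome == pytest.approx(0.03)

    def test_strand_flip_plus_swap_negates(self):
        h = harmonize_pair(_snp("C", "T"), _snp("A", "G", beta=0.03))
        assert h.status is HarmonizationStatus.STRAND_FLIPPED
        assert h.beta_outcome == pytest.approx(-0.03)

    def test_palindromic_near_half_frequency_dropped(self):
        h = harmonize_pair(
            _snp("A", "T", eaf=0.50), _snp("A", "T", eaf=0.50), palindromic_eaf_window=0.08
        )
        assert h.status is HarmonizationStatus.DROPPED_PALINDROMIC

    def test_palindromic_missing_eaf_dropped(self):
        h = harmonize_pair(_snp("A", "T", eaf=None), _snp("A", "T", eaf=0.2))
        assert h.status is HarmonizationStatus.DROPPED_PALINDROMIC

    def test_palindromic_concordant_frequencies_kept(self):
        h = harmonize_pair(_snp("A", "T", eaf=0.2), _snp("A", "T", beta=0.04, eaf=0.25))
        assert h.status is HarmonizationStatus.KEPT
        assert h.beta_outcome == pytest.approx(0.04)

    def test_palindromic_discordant_frequencies_strand_resolved(self):
        h = harmonize_pair(_snp("A", "T", eaf=0.2), _snp("A", "T", beta=0.04, eaf=0.75))
        assert h.status is HarmonizationStatus.STRAND_FLIPPED
        assert h.beta_outcome == pytest.approx(-0.04)
        assert h.eaf_outcome == pytest.approx(0.25)

    def test_indel_dropped_incompatible(self):
        h = harmonize_pair(_snp("AT", "A"), _snp("AT", "A", beta=0.03))
        assert h.status is HarmonizationStatus.DROPPED_INCOMPATIBLE

    def test_irreconcilable_alleles_dropped(self):
        h = harmonize_pair(_snp("A", "G"), _snp("A", "C", beta=0.03))
        assert h.status is HarmonizationStatus.DROPPED_INCOMPATIBLE

    def test_variant_mismatch_raises(self):
        with pytest.raises(ValueError):
            harmonize_pair(_snp("A", "G", vid="rs1"), _snp("A", "G", vid="rs2"))

    def test_standard_errors_never_altered(self):
        exp = _snp("A", "G", se=0.013)
        out = _snp("G", "A", beta=0.2, se=0.031)
        h = harmonize_pair(exp, out)
        assert (h.se_exposure, h.se_outcome) == (0.013, 0.031)

    def test_idempotent_on_harmonized_pair(self):
        exp = _snp("A", "G", beta=0.1, eaf=0.3)
        out = _snp("G", "A", beta=-0.05, eaf=0.75)
        h1 = harmonize_pair(exp, out)
        out2 = SnpAssociation("rs1", h1.effect_allele, "G", h1.beta_outcome,
                              h1.se_outcome, 0.5, eaf=h1.eaf_outcome)
        h2 = harmonize_pair(exp, out2)
        assert h2.status is HarmonizationStatus.KEPT
        assert h2.beta_outcome == h1.beta_outcome

    @settings(deadline=None, max_examples=100)
    @given(
        alleles=st.sampled_from([("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]),
        bx=st.floats(-0.5, 0.5),
        by=st.floats(-0.5, 0.5),
        eaf=st.floats(0.01, 0.99),
        swap=st.booleans(),
    )
    def test_recoding_both_records_leaves_pair_invariant(self, alleles, bx, by, eaf, swap):
        """Re-coding to the opposite allele on both sides is a no-op overall."""
        assume(bx != 0)
        ea, oa = alleles
        exp = _snp(ea, oa, beta=bx, eaf=eaf)
        out_ea, out_oa, out_beta, out_eaf = (oa, ea, -by, 1 - eaf) if swap else (ea, oa, by, eaf)
        out = _snp(out_ea, out_oa, beta=out_beta, eaf=out_eaf)
        h = harmonize_pair(exp, out)
        # recode both: swap alleles, negate betas, complement eafs
        exp2 = _snp(oa, ea, beta=-bx, eaf=1 - eaf)
        out2 = _snp(out_oa, out_ea, beta=-out_beta, eaf=1 - out_eaf)
        h2 = harmonize_pair(exp2, out2)
        assert h2.beta_outcome / h2.beta_exposure == pytest.approx(
            h.beta_outcome / h.beta_exposure, rel=1e-12, nan_ok=True
        )


class TestHarmonizeSets:
    def test_intersection_and_audit(self, glycine_like_exposure):
        outcome = StudySet("AD_like", Role.OUTCOME, [
            _snp("A", "G", beta=0.02, se=0.02, p=0.1, vid="rs1"),
            _snp("T", "C", beta=0.01, se=0.02, p=0.2, vid="rs2"),       # swapped+strand
            _snp("G", "C", beta=0.03, se=0.02, p=0.3, eaf=0.21, vid="rs3"),  # palindromic, no exp eaf arbitration needed (eaf 0.20 vs 0.21)
            _snp("T", "A", beta=0.04, se=0.02, p=0.4, eaf=0.5, vid="rs4"),   # palindromic ambiguous
        ])
        res = harmonize_sets(glycine_like_exposure, outcome)
        assert res.audit["absent_from_outcome"] == 1  # rs5
        assert res.audit["dropped_palindromic"] == 1  # rs4
        assert len(res) + len(res.dropped) == 4
        assert [h.variant_id for h in res][0] == "rs1"  # exposure order

    def test_identity_harmonization(self, glycine_like_exposure):
        as_outcome = StudySet(
            "same", Role.OUTCOME, list(glycine_like_exposure.records)
        )
        res = harmonize_sets(glycine_like_exposure, as_outcome)
        for h in res:
            assert h.beta_outcome == h.beta_exposure
            assert h.status in (HarmonizationStatus.KEPT,)

    def test_empty_intersection_raises(self, glycine_like_exposure):
        outcome = StudySet("AD_like", Role.OUTCOME, [_snp("A", "G", vid="rs99")])
        with pytest.raises(AnalysisError, match="glycine_like"):
            harmonize_sets(glycine_like_exposure, outcome)

    def test_all_palindromic_ambiguous_raises(self):
        exp = StudySet("e", Role.EXPOSURE, [_snp("A", "T", eaf=0.5, vid="rs1")])
        out = StudySet("o", Role.OUTCOME, [_snp("A", "T", eaf=0.5, vid="rs1")])
        with pytest.raises(AnalysisError, match="no usable"):
            harmonize_sets(exp, out)

    def test_tsv_round_trip(self, tmp_path, glycine_like_exposure):
        as_outcome = StudySet("same", Role.OUTCOME, list(glycine_like_exposure.records))
        res = harmonize_sets(glycine_like_exposure, as_outcome)
        path = tmp_path / "harm.tsv"
        write_harmonized_tsv(res.instruments, path)
        back = read_harmonized_tsv(path)
        assert [(h.variant_id, h.beta_exposure, h.beta_outcome) for h in back] == [
            (h.variant_id, h.beta_exposure, h.beta_outcome) for h in res.instruments
        ]
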