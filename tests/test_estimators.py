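"""Wald ratio, IVW, weighted median, MR-Egger and OR reporting."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrpipe.exceptions import AnalysisError, DegenerateInstrumentError
from mrpipe.estimators import (
    Method,
    egger,
    ivw,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from mrpipe.estimators import _weighted_median_point

from .conftest import make_instruments, random_instruments
from .oracles import egger_oracle, ivw_oracle, ivw_via_wls, weighted_median_oracle


class TestWaldRatio:
    def test_printed_formula(self):
        (h,) = make_instruments([0.10], [0.05], [0.02])
        wr = wald_ratio(h)
        assert wr.theta == pytest.approx(0.5)
        assert wr.se == pytest.approx(0.2)

    def test_null_numerator(self):
        (h,) = make_instruments([0.10], [0.0], [0.02])
        wr = wald_ratio(h)
        assert wr.theta == 0.0 and wr.se == pytest.approx(0.2)

    def test_negative_exposure_effect_keeps_positive_se(self):
        (h,) = make_instruments([-0.10], [0.05], [0.02])
        wr = wald_ratio(h)
        assert wr.theta == pytest.approx(-0.5)
        assert wr.se == pytest.approx(0.2)

    def test_zero_exposure_effect_raises(self):
        (h,) = make_instruments([0.0], [0.05], [0.02])
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(h)


class TestIvw:
    def test_two_instrument_closed_form(self):
        inst = make_instruments([0.1, 0.2], [0.02, 0.05], [0.01, 0.02])
        est = ivw(inst, "fixed")
        assert est.beta == pytest.approx(0.225, abs=1e-12)
        assert est.se == pytest.approx(1 / math.sqrt(200), abs=1e-12)
        assert est.n_snps == 2

    def test_single_instrument_reduces_to_wald(self):
        inst = make_instruments([0.13], [0.031], [0.017])
        est = ivw(inst, "fixed")
        wr = wald_ratio(inst[0])
        assert est.beta == pytest.approx(wr.theta, abs=1e-14)
        assert est.se == pytest.approx(wr.se, abs=1e-14)

    def test_mre_same_point_estimate_never_smaller_se(self, rng):
        for _ in range(10):
            inst = random_instruments(rng, int(rng.integers(2, 12)))
            fe = ivw(inst, "fixed")
            mre = ivw(inst, "multiplicative_random")
            assert mre.beta == fe.beta
            assert mre.se >= fe.se

    def test_mre_single_instrument_falls_back_with_warning(self):
        inst = make_instruments([0.1], [0.02], [0.01])
        with pytest.warns(UserWarning):
            est = ivw(inst, "multiplicative_random")
        assert est.se == ivw(inst, "fixed").se

    def test_empty_collection_raises(self):
        with pytest.raises(AnalysisError):
            ivw([], "fixed")

    def test_matches_through_origin_wls(self, rng):
        inst = random_instruments(rng, 8)
        bx = [h.beta_exposure for h in inst]
        by = [h.beta_outcome for h in inst]
        sy = [h.se_outcome for h in inst]
        assert ivw(inst).beta == pytest.approx(ivw_via_wls(bx, by, sy), abs=1e-12)


class TestWeightedMedian:
    def test_equal_weights_middle_ratio(self):
        theta = np.array([1.0, 2.0, 3.0])
        w = np.ones(3)
        assert _weighted_median_point(theta, w) == pytest.approx(2.0)

    def test_interpolation_hand_example(self):
        theta = np.array([1.0, 2.0, 10.0])
        w = np.array([0.2, 0.3, 0.5])
        # p = (0.1, 0.35, 0.75); at 0.5: 2 + 8 * 0.15/0.40 = 5.0
        assert _weighted_median_point(theta, w) == pytest.approx(5.0, abs=1e-12)

    def test_order_invariance(self, rng):
        inst = random_instruments(rng, 9)
        perm = list(rng.permutation(9))
        a = weighted_median(inst, n_boot=300, seed=5)
        b = weighted_median([inst[i] for i in perm], n_boot=300, seed=5)
        assert a.beta == pytest.approx(b.beta, abs=1e-14)

    def test_bootstrap_reproducible_with_seed(self, rng):
        inst = random_instruments(rng, 7)
        a = weighted_median(inst, n_boot=500, seed=42)
        b = weighted_median(inst, n_boot=500, seed=42)
        assert (a.se, a.pvalue) == (b.se, b.pvalue)
        c = weighted_median(inst, n_boot=500, seed=43)
        assert c.se != a.se

    def test_requires_three_instruments(self):
        inst = make_instruments([0.1, 0.2], [0.02, 0.05], [0.01, 0.02])
        with pytest.raises(AnalysisError):
            weighted_median(inst)

    def test_small_bootstrap_warns(self, rng):
        inst = random_instruments(rng, 5)
        with pytest.warns(UserWarning):
            weighted_median(inst, n_boot=50, seed=1)


class TestEgger:
    def test_exact_line_through_origin(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        inst = make_instruments(bx, 0.5 * bx, np.full(4, 0.01))
        slope, intercept = egger(inst)
        assert slope.beta == pytest.approx(0.5, abs=1e-12)
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)
        assert intercept.pvalue == pytest.approx(1.0, abs=1e-9)

    def test_matches_wls_oracle(self, rng):
        for _ in range(10):
            inst = random_instruments(rng, int(rng.integers(3, 11)))
            slope, intercept = egger(inst)
            o = egger_oracle(
                [h.beta_exposure for h in inst],
                [h.beta_outcome for h in inst],
                [h.se_outcome for h in inst],
            )
            assert slope.beta == pytest.approx(o["slope"], abs=1e-10)
            assert intercept.beta == pytest.approx(o["intercept"], abs=1e-10)
            assert slope.se == pytest.approx(o["se_slope"], abs=1e-10)
            assert intercept.se == pytest.approx(o["se_intercept"], abs=1e-10)

    def test_requires_three_instruments_and_spread(self):
        with pytest.raises(AnalysisError):
            egger(make_instruments([0.1, 0.2], [0.0, 0.1], [0.01, 0.01]))
        same = make_instruments([0.1, 0.1, 0.1], [0.01, 0.02, 0.03], [0.01, 0.01, 0.01])
        with pytest.raises(AnalysisError, match="collinear"):
            egger(same)

    def test_uses_t_distribution_tail(self, rng):
        inst = random_instruments(rng, 5)
        slope, _ = egger(inst)
        from scipy import stats

        assert slope.pvalue == pytest.approx(
            2 * stats.t.sf(abs(slope.beta / slope.se), 3), abs=1e-12
        )


class TestToOddsRatio:
    def test_null_beta(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1)
        assert or_ == pytest.approx(1.0)
        assert lo == pytest.approx(math.exp(-1.959964 * 0.1), abs=1e-6)
        assert hi == pytest.approx(math.exp(1.959964 * 0.1), abs=1e-6)

    def test_back_transform_consistency_with_reported_interval(self):
        # log-odds 0.2708 with SE 0.09543 corresponds to OR 1.311 (1.087, 1.580)
        or_, lo, hi = to_odds_ratio(0.2708, 0.09543)
        assert or_ == pytest.approx(1.311, abs=2e-3)
        assert lo == pytest.approx(1.087, abs=2e-3)
        assert hi == pytest.approx(1.580, abs=2e-3)

    def test_zero_se_raises(self):
        with pytest.raises(ValueError):
            to_odds_ratio(0.1, 0.0)


class TestAlleleRecodingInvariance:
    @settings(deadline=None, max_examples=30)
    @given(data=st.data())
    def test_sign_flip_of_any_instrument_is_invariant(self, data):
        """Simultaneously negating beta_X and beta_Y of any subset of
        instruments (an allele re-coding) leaves every estimator unchanged."""
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 9))
        inst = random_instruments(rng, k)
        mask = data.draw(
            st.lists(st.booleans(), min_size=k, max_size=k).filter(any)
        )
        flipped = [
            make_instruments(
                [-h.beta_exposure], [-h.beta_outcome], [h.se_outcome], [h.se_exposure],
                ids=[h.variant_id],
            )[0] if m else h
            for h, m in zip(inst, mask)
        ]
        assert ivw(flipped).beta == pytest.approx(ivw(inst).beta, abs=1e-12)
        s0, i0 = egger(inst)
        s1, i1 = egger(flipped)
        assert s1.beta == pytest.approx(s0.beta, abs=1e-12)
        assert i1.beta == pytest.approx(i0.beta, abs=1e-12)
        wm0 = weighted_median(inst, n_boot=100, seed=1)
        wm1 = weighted_median(flipped, n_boot=100, seed=1)
        assert wm1.beta == pytest.approx(wm0.beta, abs=1e-12)
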