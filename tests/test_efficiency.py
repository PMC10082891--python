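"""Deposit histograms, spectrum ratios, sigmoid evaluation and fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jpet_effcal.constants import BSF_REFERENCE
from jpet_effcal.efficiency import (
    DepositionHistogram,
    bsf_eval,
    deposition_histogram,
    efficiency_ratio,
    fit_bsf,
    fit_survival_model,
    normalize_at_mode,
    recover_thinning_curve,
    survival_sample_from_hits,
)


class TestHistogram:
    def test_single_angle_fills_a_single_bin(self):
        h = deposition_histogram([90.0] * 25)
        assert h.counts.sum() == 25
        assert h.counts[h.bin_of(255.5)] == 25

    def test_empty_input_gives_empty_histogram(self):
        h = deposition_histogram([])
        assert h.counts.sum() == 0

    def test_no_counts_beyond_the_compton_edge(self):
        h = deposition_histogram(np.linspace(0.0, 180.0, 5000))
        assert h.counts[h.edges_kev[:-1] >= 341.0].sum() == 0

    def test_normalization_sets_reference_bin_to_unity(self):
        rng = np.random.default_rng(0)
        h = deposition_histogram(rng.uniform(60.0, 180.0, 20000))
        n = normalize_at_mode(h, 270.0)
        assert n.values()[n.bin_of(270.0)] == pytest.approx(1.0)
        # normalization preserves bin-content ratios
        ratios = h.counts[h.counts > 0] / h.counts[h.counts > 0][0]
        ratios_n = n.values()[h.counts > 0] / n.values()[h.counts > 0][0]
        np.testing.assert_allclose(ratios, ratios_n)

    def test_mode_and_reference_conventions_agree_when_mode_is_270(self):
        edges = np.arange(0.0, 350.0, 1.0)
        counts = np.ones(len(edges) - 1)
        counts[270] = 50.0
        h = DepositionHistogram(edges, counts)
        a = normalize_at_mode(h, 270.0)
        b = normalize_at_mode(h, use_global_mode=True)
        np.testing.assert_allclose(a.values(), b.values())

    def test_empty_reference_bin_raises(self):
        h = deposition_histogram([90.0] * 10)
        with pytest.raises(ValueError):
            normalize_at_mode(h, 270.0)


class TestRatio:
    def test_self_ratio_is_unity_everywhere(self):
        rng = np.random.default_rng(1)
        h = deposition_histogram(rng.uniform(30.0, 180.0, 5000))
        pts = efficiency_ratio(h, h)
        np.testing.assert_allclose(pts[:, 1], 1.0)

    def test_empty_simulated_bins_are_excluded_not_infinite(self):
        edges = np.arange(0.0, 10.0, 1.0)
        exp = DepositionHistogram(edges, [1, 2, 3, 0, 5, 0, 7, 8, 9])
        sim = DepositionHistogram(edges, [1, 2, 0, 4, 5, 6, 7, 8, 9])
        pts = efficiency_ratio(exp, sim)
        assert len(pts) == 8 and np.all(np.isfinite(pts))

    def test_binning_mismatch_raises(self):
        a = DepositionHistogram(np.arange(0.0, 5.0), np.ones(4))
        b = DepositionHistogram(np.arange(0.0, 6.0), np.ones(5))
        with pytest.raises(ValueError):
            efficiency_ratio(a, b)


class TestSigmoid:
    def test_published_parameters_reproduce_printed_anchors(self):
        a0, a1, a2, a3 = BSF_REFERENCE
        assert bsf_eval(BSF_REFERENCE, a2) == pytest.approx((a0 + a1) / 2.0, abs=1e-12)
        assert bsf_eval(BSF_REFERENCE, a2) == pytest.approx(0.5865, abs=1e-4)
        assert round(100.0 * bsf_eval(BSF_REFERENCE, 70.0)) == 20
        assert bsf_eval(BSF_REFERENCE, 1e9) == pytest.approx(a1)

    def test_decreasing_convention_mirrors_the_increasing_one(self):
        e = np.linspace(0.0, 340.0, 100)
        inc = bsf_eval(BSF_REFERENCE, e, convention="increasing")
        a0, a1, a2, a3 = BSF_REFERENCE
        dec = bsf_eval(BSF_REFERENCE, 2 * a2 - e, convention="decreasing")
        np.testing.assert_allclose(inc, dec, atol=1e-12)

    @given(
        a0=st.floats(0.0, 0.5),
        a1=st.floats(0.6, 1.2),
        a2=st.floats(80.0, 250.0),
        a3=st.floats(5.0, 60.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_increasing_convention_is_monotone_for_a1_above_a0(self, a0, a1, a2, a3):
        e = np.linspace(0.0, 400.0, 200)
        v = bsf_eval((a0, a1, a2, a3), e)
        assert np.all(np.diff(v) >= 0.0)

    def test_exact_samples_are_recovered_by_the_fit(self):
        e = np.arange(70.0, 271.0, 1.0)
        pts = np.column_stack([e, bsf_eval(BSF_REFERENCE, e), np.full_like(e, 1e-3)])
        fit = fit_bsf(pts)
        np.testing.assert_allclose(fit.params, BSF_REFERENCE, rtol=1e-6)
        assert fit.ndf == len(e) - 4
        assert np.isfinite(fit.errors()).all()

    def test_too_few_points_raise(self):
        e = np.arange(70.0, 79.0, 1.0)
        pts = np.column_stack([e, bsf_eval(BSF_REFERENCE, e), np.full_like(e, 1e-3)])
        with pytest.raises(ValueError):
            fit_bsf(pts)

    def test_confidence_band_scales_with_covariance(self):
        e = np.arange(70.0, 271.0, 2.0)
        pts = np.column_stack([e, bsf_eval(BSF_REFERENCE, e), np.full_like(e, 0.01)])
        fit = fit_bsf(pts)
        band = fit.band_3sigma([100.0, 150.0, 250.0])
        assert np.all(band >= 0.0) and np.all(band < 0.1)


class TestSurvivalRecovery:
    def test_synthetic_bernoulli_recovery_is_unbiased(self):
        rng = np.random.default_rng(21)
        n = 20_000
        dep = np.column_stack(
            [rng.uniform(20, 340, n), rng.uniform(20, 340, n), rng.gamma(2.0, 60.0, n)]
        )
        p = np.clip(bsf_eval(BSF_REFERENCE, dep), 0, 1).prod(axis=1)
        surv = rng.random(n) < p
        fit = fit_survival_model(dep, surv)
        assert fit.a2_kev == pytest.approx(BSF_REFERENCE[2], abs=3.0)
        assert fit.a3_kev == pytest.approx(BSF_REFERENCE[3], abs=3.0)
        assert fit.a1 == pytest.approx(BSF_REFERENCE[1], abs=0.02)
        assert fit.a0 == pytest.approx(BSF_REFERENCE[0], abs=0.04)

    def test_recovery_via_matched_selected_frames(self):
        import pandas as pd

        rng = np.random.default_rng(22)
        n = 15_000
        d1, d2, d3 = rng.uniform(30, 330, n), rng.uniform(30, 330, n), rng.gamma(2.0, 60.0, n)
        dep = np.column_stack([d1, d2, d3])
        p = np.clip(bsf_eval(BSF_REFERENCE, dep), 0, 1).prod(axis=1)
        surv = rng.random(n) < p
        ideal = pd.DataFrame(
            {
                "event_id": np.arange(n),
                "e_true_p1_kev": d1,
                "e_true_p2_kev": d2,
                "e_true_scatter_kev": d3,
                "de_reco_kev": d1,
            }
        )
        fit = recover_thinning_curve(ideal, ideal[surv])
        es = np.linspace(70.0, 270.0, 201)
        dev = np.abs(bsf_eval(fit.params, es) - bsf_eval(BSF_REFERENCE, es))
        assert dev.max() < 0.03

    def test_survival_sample_flags_match_hit_subsetting(self, small_streams):
        ideal, det, _ = small_streams
        dep, surv = survival_sample_from_hits(ideal, det)
        assert len(dep) == len(surv) > 100
        assert dep.shape[1] == 3
        # survival rate must equal the mean modeled probability within 5 sigma
        p = np.clip(bsf_eval(BSF_REFERENCE, dep), 0, 1).prod(axis=1)
        se = np.sqrt(np.maximum(p.mean() * (1 - p.mean()), 1e-6) / len(p))
        assert abs(surv.mean() - p.mean()) < 5.0 * se
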