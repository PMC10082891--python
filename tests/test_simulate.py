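"""Source generation, transport, digitization and dataset reproducibility."""

import numpy as np
import pandas as pd
import pytest

from jpet_effcal.compton import compton_edge, energy_deposit_pdf
from jpet_effcal.constants import E_ANNIH_KEV, E_PROMPT_KEV
from jpet_effcal.simulate import (
    RegistrationModel,
    SmearingModel,
    SourceConfig,
    TransportConfig,
    digitize_hit,
    generate_annihilation_event,
    hit_from_pmt_times,
    pmt_times,
    simulate_both,
    simulate_dataset,
    transport_photon,
)


class TestSource:
    def test_pair_is_exactly_back_to_back_with_expected_energies(self, rng):
        src = SourceConfig(n_events=1)
        for _ in range(50):
            photons = generate_annihilation_event(src, rng)
            energies = [p[0] for p in photons]
            assert energies[:2] == [E_ANNIH_KEV, E_ANNIH_KEV]
            assert energies[2] == E_PROMPT_KEV
            d1, d2 = photons[0][2], photons[1][2]
            assert float(d1 @ d2) == pytest.approx(-1.0, abs=1e-12)

    def test_point_source_emits_from_exact_position(self, rng):
        src = SourceConfig(n_events=1, extent_radius_cm=0.0, position=(1.0, -2.0, 3.0))
        for _ in range(10):
            for _, origin, _, _ in generate_annihilation_event(src, rng):
                np.testing.assert_allclose(origin, [1.0, -2.0, 3.0])

    def test_extended_source_stays_inside_the_ball(self, rng):
        src = SourceConfig(n_events=1, extent_radius_cm=1.58)
        for _ in range(200):
            origin = generate_annihilation_event(src, rng)[0][1]
            assert np.linalg.norm(origin) <= 1.58 + 1e-12


class TestTransport:
    def test_photon_along_axis_escapes(self, geometry, rng):
        photon = (511.0, np.zeros(3), np.array([0.0, 0.0, 1.0]), 0.0)
        assert transport_photon(photon, geometry, TransportConfig(), rng) == []

    def test_energy_conservation_along_the_chain(self, geometry):
        rng = np.random.default_rng(2)
        cfg = TransportConfig(mu_mode="const", mu_const=2.0)  # dense: force interactions
        for k in range(40):
            phi = rng.uniform(0, 2 * np.pi)
            photon = (511.0, np.zeros(3), np.array([np.cos(phi), np.sin(phi), 0.0]), 0.0)
            e = 511.0
            for inter in transport_photon(photon, geometry, cfg, rng):
                assert inter["deposit_kev"] + inter["scattered_energy_kev"] == pytest.approx(
                    e, abs=1e-9
                )
                assert inter["deposit_kev"] <= compton_edge(e) + 1e-9
                e = inter["scattered_energy_kev"]

    def test_single_chord_interaction_probability(self, geometry):
        # radial photons through one strip: empirical rate vs 1 - exp(-mu l)
        rng = np.random.default_rng(3)
        cfg = TransportConfig(mu_mode="const", mu_const=0.3)
        n, hits = 3000, 0
        for _ in range(n):
            photon = (511.0, np.zeros(3), np.array([1.0, 0.0, 0.0]), 0.0)
            inters = transport_photon(photon, geometry, cfg, rng, max_interactions=1)
            hits += bool(inters and inters[0]["strip_id"] == 0)
        # the ray crosses three strips radially (0.7 cm each); first-strip rate
        p = 1.0 - np.exp(-0.3 * 0.7)
        assert abs(hits / n - p) < 3.0 * np.sqrt(p * (1 - p) / n)

    def test_kernel_first_deposits_match_deposition_density(self, geometry):
        # single-interaction transport: no scattered photons, hence no
        # same-strip pile-up that would reshape the first-deposit spectrum
        from scipy.integrate import quad
        from scipy.stats import chisquare

        source = SourceConfig(n_events=400_000, pair_cos_max=0.55)
        smearing = SmearingModel(0.0, 0.0, 0.0)
        ideal, _, _ = simulate_both(
            geometry, source, smearing, RegistrationModel(), None,
            transport=TransportConfig(max_interactions=1), seed=31,
        )
        first = ideal[ideal["truth_origin"].isin([1, 2])]["e_true_kev"].to_numpy()
        first = first[first < compton_edge(511.0)]
        pdf = energy_deposit_pdf(511.0)
        # threshold-free region only: compare shape above 70 keV
        edges = np.linspace(71.0, pdf.delta_e_max - 1.0, 25)
        obs, _ = np.histogram(first, bins=edges)
        exp = np.array(
            [quad(pdf.pdf, lo, hi, limit=200)[0] for lo, hi in zip(edges[:-1], edges[1:])]
        )
        exp *= obs.sum() / exp.sum()
        assert chisquare(obs, exp).pvalue > 0.001


class TestDigitization:
    def test_no_smearing_keeps_values_and_applies_threshold(self, rng):
        smearing = SmearingModel(0.0, 0.0, 0.0)
        reg = RegistrationModel(threshold_kev=70.0)
        hit = {"time_ns": 1.5, "z_cm": 3.0, "deposit_kev": 100.0}
        out = digitize_hit(hit, smearing, reg, rng)
        assert out["e_smeared_kev"] == 100.0 and out["time_ns"] == 1.5 and out["z_cm"] == 3.0
        hit["deposit_kev"] = 50.0
        assert digitize_hit(hit, smearing, reg, rng) is None

    def test_zero_thinning_curve_drops_everything(self, rng):
        smearing = SmearingModel(0.0, 0.0, 0.0)
        reg = RegistrationModel(mode="detector", thinning_curve=lambda e: 0.0)
        hit = {"time_ns": 0.0, "z_cm": 0.0, "deposit_kev": 200.0}
        assert all(digitize_hit(hit, smearing, reg, rng) is None for _ in range(20))

    def test_pmt_times_follow_the_readout_conventions(self, geometry):
        hit = {"time_ns": 2.0, "z_cm": 10.0}
        t_l, t_r = pmt_times(hit, geometry)
        v = geometry.v_eff_cm_per_ns
        assert 0.5 * (t_l + t_r) == pytest.approx(2.0 + geometry.strip_length_cm / (2 * v))
        assert (t_r - t_l) * v / 2.0 == pytest.approx(10.0)
        assert t_r - t_l == pytest.approx(2 * 10.0 / 12.0)  # 1.667 ns at v_eff = 12
        t, z = hit_from_pmt_times(t_l, t_r, geometry)
        assert (t, z) == (pytest.approx(2.0, abs=1e-12), pytest.approx(10.0, abs=1e-12))

    def test_centre_hit_gives_equal_pmt_times(self, geometry):
        t_l, t_r = pmt_times({"time_ns": 0.7, "z_cm": 0.0}, geometry)
        assert t_l == t_r


class TestDataset:
    def test_same_seed_reproduces_tables_exactly(self, geometry):
        src = SourceConfig(n_events=20_000, pair_cos_max=0.55)
        args = (geometry, src, SmearingModel(), RegistrationModel())
        hits_a, truth_a = simulate_dataset(*args, seed=9)
        hits_b, truth_b = simulate_dataset(*args, seed=9)
        pd.testing.assert_frame_equal(hits_a, hits_b)
        pd.testing.assert_frame_equal(truth_a, truth_b)

    def test_unit_thinning_equals_ideal_stream(self, geometry):
        src = SourceConfig(n_events=20_000, pair_cos_max=0.55)
        ideal, det, _ = simulate_both(
            geometry, src, SmearingModel(), RegistrationModel(), lambda e: 1.0, seed=4
        )
        pd.testing.assert_frame_equal(ideal, det)

    def test_detector_stream_is_a_subset_of_ideal(self, small_streams):
        ideal, det, _ = small_streams
        key = ["event_id", "strip_id", "time_ns", "e_true_kev"]
        merged = det.merge(ideal[key], on=key, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()

    def test_hit_level_thinning_recovers_the_injected_curve(self, small_streams):
        from jpet_effcal.constants import BSF_REFERENCE
        from jpet_effcal.efficiency import bsf_eval

        ideal, det, _ = small_streams
        edges = np.arange(0.0, 341.0, 20.0)
        n_i, _ = np.histogram(ideal["e_true_kev"], bins=edges)
        n_d, _ = np.histogram(det["e_true_kev"], bins=edges)
        centres = 0.5 * (edges[:-1] + edges[1:])
        ok = n_i > 200
        ratio = n_d[ok] / n_i[ok]
        # bin-average of the injected curve, compared at 3 binomial sigma
        for c, r, n in zip(centres[ok], ratio, n_i[ok]):
            lo, hi = c - 10.0, c + 10.0
            grid = np.linspace(lo, hi, 21)
            m = ideal["e_true_kev"].between(lo, hi)
            expect = float(np.mean(bsf_eval(BSF_REFERENCE, ideal.loc[m, "e_true_kev"])))
            assert abs(r - expect) < 3.0 * np.sqrt(expect * (1 - expect) / n) + 1e-9

    def test_hits_are_time_sorted_with_bounded_z(self, small_streams, geometry):
        ideal, _, _ = small_streams
        t = ideal["time_ns"].to_numpy()
        assert np.all(np.diff(t) >= 0)
        assert ideal["z_cm"].abs().max() <= geometry.strip_length_cm / 2.0
        assert (ideal["e_smeared_kev"] >= 70.0).all()
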