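"""Ground-truth generators: scenarios, titrations, event streams, tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from atpflux import synthetic
from atpflux.timecourse import gate_events


class TestFluxScenarios:
    def test_glucose_uptake_is_100_everywhere(self, flux_vectors):
        for name, v in flux_vectors.items():
            assert v["HK"] == 100.0, name

    def test_quiescent_lactate_efflux_is_65(self, flux_vectors):
        assert flux_vectors["quiescent"]["LAC_out"] == 65.0

    def test_oxphos_inhibited_lactate_efflux_is_80(self, flux_vectors):
        assert flux_vectors["oxphos_inhibited"]["LAC_out"] == 80.0

    def test_5fu_has_elevated_glycolytic_flux(self, flux_vectors):
        q, f = flux_vectors["quiescent"], flux_vectors["proliferative_5FU"]
        for rxn in ["PFK", "GAPDH", "PK", "LAC_out"]:
            assert f[rxn] > q[rxn], rxn

    def test_oxphos_inhibited_has_reduced_nas_drain(self, flux_vectors):
        assert (
            flux_vectors["oxphos_inhibited"]["R5P_out"]
            < flux_vectors["quiescent"]["R5P_out"]
        )

    def test_scenario_noise_validation(self, flux_vectors):
        with pytest.raises(ValueError, match="autofluorescence"):
            synthetic.ScenarioSpec(
                name="bad",
                flux_vector=flux_vectors["quiescent"],
                atp_trajectory=lambda t: 0.8,
                noise_model={"autofluorescence_fraction": 1.2},
            )


class TestTitration:
    def test_half_saturation_point(self, calib):
        tab = synthetic.gen_calibration_titration(calib, [calib.K_A], noise_sd=0.0)
        assert tab["fret_ratio"].iloc[0] == pytest.approx(1.96, abs=1e-12)

    def test_low_concentration_limit_is_offset(self, calib):
        tab = synthetic.gen_calibration_titration(calib, [1e-9], noise_sd=0.0)
        assert tab["fret_ratio"].iloc[0] == pytest.approx(1.46, abs=1e-6)

    def test_nonpositive_concentration_rejected(self, calib):
        with pytest.raises(ValueError):
            synthetic.gen_calibration_titration(calib, [0.5, -1.0], noise_sd=0.0)


class TestEventStream:
    def test_constant_trajectory_zero_noise_gives_identical_ratios(
        self, flux_vectors, calib
    ):
        scen = synthetic.ScenarioSpec(
            name="const",
            flux_vector=flux_vectors["quiescent"],
            atp_trajectory=lambda t: np.full_like(np.asarray(t, float), 0.8),
            noise_model={"event_cv": 0.0, "mdv_sd": 0.0, "autofluorescence_fraction": 0.0},
            seed=3,
        )
        stream = synthetic.gen_event_stream(scen, 500, 100.0, calib)
        gated = gate_events(stream)
        ratios = gated.ratios()
        assert np.allclose(ratios, ratios[0], atol=1e-12)

    def test_step_down_trajectory_reduces_gated_ratio(self, scenarios, calib):
        scen = scenarios["oxphos_inhibited"]  # 0.8 -> 0.5 mM at t = 300 s
        stream = synthetic.gen_event_stream(scen, 4000, 900.0, calib, seed=5)
        gated = gate_events(stream)
        ev = gated.events
        before = (ev.fret / ev.egfp)[ev.time_s < 300].median()
        after = (ev.fret / ev.egfp)[ev.time_s > 300].median()
        assert before > after

    def test_fixed_seed_bitwise_reproducible(self, scenarios, calib):
        a = synthetic.gen_event_stream(scenarios["quiescent"], 200, 50.0, calib, seed=9)
        b = synthetic.gen_event_stream(scenarios["quiescent"], 200, 50.0, calib, seed=9)
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_input_validation(self, scenarios, calib):
        with pytest.raises(ValueError):
            synthetic.gen_event_stream(scenarios["quiescent"], 0, 50.0, calib)
        with pytest.raises(ValueError):
            synthetic.gen_event_stream(scenarios["quiescent"], 10, -1.0, calib)


class TestIsotopologueTables:
    def test_u12c6_without_natural_abundance_is_all_m0(self, model, flux_vectors):
        tab = synthetic.gen_isotopologue_table(
            flux_vectors["quiescent"], model, tracer="U12C6",
            natural_abundance_per_carbon=0.0, condition="quiescent",
        )
        m0 = tab[tab.mass_shift == 0].set_index("metabolite").amount
        totals = tab.groupby("metabolite").amount.sum()
        assert np.allclose(m0 / totals, 1.0)

    def test_u13c6_labels_lactate_fully(self, model, flux_vectors):
        tab = synthetic.gen_isotopologue_table(
            flux_vectors["quiescent"], model, tracer="U13C6",
            natural_abundance_per_carbon=0.0, condition="quiescent",
        )
        lac = tab[tab.metabolite == "LAC"].set_index("mass_shift").amount
        assert lac[3] / lac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_natural_abundance_matches_binomial_closed_form(self, model, flux_vectors):
        tab = synthetic.gen_isotopologue_table(
            flux_vectors["quiescent"], model, tracer="U12C6",
            natural_abundance_per_carbon=0.011, condition="quiescent",
        )
        g6p = tab[tab.metabolite == "G6P"].set_index("mass_shift").amount
        frac_m1 = float(g6p[1] / g6p.sum())
        assert frac_m1 == pytest.approx(binom.pmf(1, 6, 0.011), rel=1e-9)

    def test_amounts_scale_to_pool_sizes(self, model, flux_vectors):
        tab = synthetic.gen_isotopologue_table(
            flux_vectors["quiescent"], model, condition="quiescent",
        )
        totals = tab.groupby("metabolite").amount.sum()
        for met, pool in synthetic.POOL_SIZES["quiescent"].items():
            assert totals[met] == pytest.approx(pool, rel=1e-9)

    def test_noise_preserves_simplex_and_determinism(self, model, flux_vectors):
        a = synthetic.gen_isotopologue_table(
            flux_vectors["quiescent"], model, mdv_sd=0.02, seed=7, condition="quiescent"
        )
        b = synthetic.gen_isotopologue_table(
            flux_vectors["quiescent"], model, mdv_sd=0.02, seed=7, condition="quiescent"
        )
        pd.testing.assert_frame_equal(a, b)
        assert (a.amount >= 0).all()

    def test_unbalanced_vector_rejected(self, model, flux_vectors):
        v = flux_vectors["quiescent"].copy()
        v["CS"] += 5.0
        with pytest.raises(ValueError, match="balance"):
            synthetic.gen_isotopologue_table(v, model, condition="quiescent")


def test_natural_abundance_matrix_columns_are_distributions():
    M = synthetic.natural_abundance_matrix(6, 0.011)
    assert np.allclose(M.sum(axis=0), 1.0)
    # an M+6 species cannot gain further carbons
    assert M[6, 6] == pytest.approx(1.0)


def test_flux_json_round_trip(tmp_path, flux_vectors):
    path = tmp_path / "flux.json"
    synthetic.write_flux_json(flux_vectors["quiescent"], path)
    loaded = synthetic.load_flux_json(path)
    pd.testing.assert_series_equal(
        loaded, flux_vectors["quiescent"], check_names=False
    )
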