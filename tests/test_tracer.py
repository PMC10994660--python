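"""Isotope-tracer table operations: quantitation, correction, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from atpflux import synthetic, tracer


@pytest.fixture(scope="module")
def tables(model, flux_vectors):
    """Paired U-13C6/U-12C6 tables for two conditions."""
    frames = []
    seed = 100
    for cond in ["quiescent", "proliferative_5FU"]:
        for trc in ["U13C6", "U12C6"]:
            seed += 1
            frames.append(
                synthetic.gen_isotopologue_table(
                    flux_vectors[cond], model, tracer=trc, mdv_sd=0.005,
                    seed=seed, condition=cond,
                )
            )
    return pd.concat(frames, ignore_index=True)


class TestQuantification:
    def test_calibration_line_inversion(self):
        assert tracer.quantify_from_calibration(10.0, slope=2.0) == 5.0
        assert tracer.quantify_from_calibration(3.0, slope=1.0, intercept=3.0) == 0.0
        # areas below the intercept floor at zero
        assert tracer.quantify_from_calibration(1.0, slope=2.0, intercept=5.0) == 0.0
        with pytest.raises(tracer.InvalidCalibrationError):
            tracer.quantify_from_calibration(1.0, slope=0.0)


class TestLabelingFractions:
    def test_known_two_species_split(self):
        t = pd.DataFrame(
            {
                "metabolite": ["LAC"] * 2,
                "condition": ["c"] * 2,
                "tracer": ["U13C6"] * 2,
                "mass_shift": [0, 3],
                "amount": [25.0, 75.0],
            }
        )
        frac = tracer.labeling_fractions(t, "LAC", "c", n_carbons=3)
        assert np.allclose(frac, [0.25, 0, 0, 0.75])
        assert tracer.labeling_rate(t, "LAC", "c") == pytest.approx(0.75)

    def test_all_zero_metabolite_rejected(self):
        t = pd.DataFrame(
            {"metabolite": ["X"], "condition": ["c"], "tracer": ["U13C6"],
             "mass_shift": [0], "amount": [0.0]}
        )
        with pytest.raises(tracer.UndefinedFractionError):
            tracer.labeling_fractions(t, "X", "c")

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, scale):
        t = pd.DataFrame(
            {
                "metabolite": ["M"] * 3,
                "condition": ["c"] * 3,
                "tracer": ["U13C6"] * 3,
                "mass_shift": [0, 1, 2],
                "amount": [1.0, 2.0, 3.0],
            }
        )
        base = tracer.labeling_fractions(t, "M", "c")
        t2 = t.assign(amount=t["amount"] * scale)
        assert np.allclose(tracer.labeling_fractions(t2, "M", "c"), base)


class TestNaturalIsotopeCorrection:
    def test_subtraction_with_zero_floor(self):
        assert tracer.natural_isotope_correct(10.0, 3.0) == 7.0
        assert tracer.natural_isotope_correct(2.0, 5.0) == 0.0
        assert tracer.natural_isotope_correct(4.0, 0.0) == 4.0

    @given(
        st.floats(min_value=0, max_value=100), st.floats(min_value=0, max_value=100)
    )
    @settings(max_examples=50, deadline=None)
    def test_never_negative_and_idempotent_at_floor(self, a, b):
        once = tracer.natural_isotope_correct(a, b)
        assert once >= 0
        if once == 0.0:
            assert tracer.natural_isotope_correct(once, b) == 0.0

    def test_corrected_table_has_reduced_labeled_amounts(self, tables):
        corrected = tracer.correct_table(tables)
        raw = tables[tables.tracer == "U13C6"]
        merged = corrected.merge(
            raw, on=["metabolite", "condition", "mass_shift"], suffixes=("_cor", "_raw")
        )
        labeled = merged[merged.mass_shift >= 1]
        assert (labeled.amount_cor <= labeled.amount_raw + 1e-12).all()
        assert (corrected.amount >= 0).all()

    def test_flags_natural_isotope_heavy_species(self, tables):
        flagged = tracer.flag_high_natural_isotope(tables, threshold=0.05)
        # citrate M+2 carries substantial natural background in the
        # U-12C6 control relative to genuine labeling under U-13C6
        assert any(met == "CIT" for met, _ in flagged)
        # fully labeled glycolytic end products are not flagged
        assert ("LAC", 3) not in flagged

    def test_flag_requires_control_condition(self, tables):
        only13 = tables[tables.tracer == "U13C6"]
        with pytest.raises(ValueError):
            tracer.flag_high_natural_isotope(only13)


class TestPathwaySummaries:
    def test_pathway_total_matches_exhaustive_sum(self, tables, rng):
        # oracle: brute-force double loop over rows
        for pathway in ["glycolysis", "TCA", "PPP"]:
            total = tracer.pathway_total_labeled(tables, pathway, "quiescent")
            brute = 0.0
            for _, row in tables.iterrows():
                if (
                    row.pathway == pathway
                    and row.condition == "quiescent"
                    and row.tracer == "U13C6"
                    and row.mass_shift >= 1
                ):
                    brute += row.amount
            assert total == pytest.approx(brute, rel=1e-12)

    def test_unknown_pathway_rejected(self, tables):
        with pytest.raises(KeyError):
            tracer.pathway_total_labeled(tables, "urea_cycle", "quiescent")

    def test_pathway_totals_additive_over_partition(self, tables):
        conds = "quiescent"
        lab13 = tables[(tables.tracer == "U13C6") & (tables.condition == conds)]
        total_all = float(lab13[lab13.mass_shift >= 1].amount.sum())
        by_pathway = sum(
            tracer.pathway_total_labeled(tables, p, conds)
            for p in lab13.pathway.unique()
        )
        assert by_pathway == pytest.approx(total_all, rel=1e-12)


class TestHeatmapAndRatios:
    def test_heatmap_pseudocount_bounds(self, tables):
        mat = tracer.heatmap_labeling_matrix(tables)
        vals = mat.to_numpy(dtype=float)
        assert np.all(vals >= 1.0) and np.all(vals <= 2.0)

    def test_heatmap_known_entries(self):
        t = pd.DataFrame(
            {
                "metabolite": ["A", "A", "B", "B", "C", "C"],
                "condition": ["c"] * 6,
                "tracer": ["U13C6"] * 6,
                "mass_shift": [0, 1, 0, 1, 0, 1],
                "amount": [1.0, 0.0, 0.0, 1.0, 0.6, 0.4],
            }
        )
        mat = tracer.heatmap_labeling_matrix(t)
        assert mat.loc["A", "c"] == pytest.approx(1.0)  # unlabeled -> 0 + 1
        assert mat.loc["B", "c"] == pytest.approx(2.0)  # fully labeled -> 1 + 1
        assert mat.loc["C", "c"] == pytest.approx(1.4)

    def test_product_substrate_ratio_arithmetic(self):
        t = pd.DataFrame(
            {
                "metabolite": ["FBP", "F6P"],
                "condition": ["c"] * 2,
                "tracer": ["U13C6"] * 2,
                "mass_shift": [6, 6],
                "amount": [30.0, 10.0],
            }
        )
        assert tracer.product_substrate_ratio(t, "FBP", "F6P", "c") == pytest.approx(3.0)

    def test_fbp_f6p_ratio_elevated_under_proliferation(self, tables):
        quiet = tracer.product_substrate_ratio(tables, "FBP", "F6P", "quiescent")
        stress = tracer.product_substrate_ratio(tables, "FBP", "F6P", "proliferative_5FU")
        assert stress > quiet
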