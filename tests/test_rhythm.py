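"""Teacher templates, the correlation screen, phase binning, and integration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transomics import (
    assign_phase,
    average_replicates,
    build_design,
    build_teacher_patterns,
    correlation_screen,
    integrate_omics,
    simulate_metabolites,
)
from transomics.pipeline import evaluate_screen
from transomics.rhythm import PHASE_BINS, hits_to_frame, pattern_shapes


def pattern_by_id(design):
    return {p.pattern_id: p for p in build_teacher_patterns(design)}


class TestTeacherPatterns:
    def test_four_patterns_of_design_length_and_centered(self, design3):
        pats = build_teacher_patterns(design3)
        assert len(pats) == 4
        for p in pats:
            assert len(p.values) == design3.n_points
            assert abs(p.values.mean()) < 1e-12
            assert p.values.std() > 0

    def test_fasting_low_orders_nf2_below_f4_at_same_zt(self, design3):
        p2 = pattern_by_id(design3)["P2_fasting_low"].values
        labels = design3.point_labels
        assert p2[labels.index("NF2_ZT10")] < p2[labels.index("F4_ZT10")]

    def test_diurnal_flips_exactly_at_lights_off(self, design3):
        p1 = pattern_by_id(design3)["P1_diurnal"].values
        for i, pt in enumerate(design3.samples):
            if pt.day != "NF2":
                continue
            expected_high = pt.zt < 11
            assert (p1[i] > 0) == expected_high

    def test_gradual_ramps_down_then_up(self, design3):
        p3 = pattern_shapes(design3)["P3_gradual"]
        fasting = [i for i, p in enumerate(design3.samples) if p.state == "fasting"]
        feeding = [i for i, p in enumerate(design3.samples) if p.state == "feeding"]
        assert (np.diff(p3[fasting]) < 0).all()
        assert (np.diff(p3[feeding]) > 0).all()

    def test_feeding_acute_window_covers_feed_and_next_sample(self, design3):
        p4 = pattern_shapes(design3)["P4_feeding_acute"]
        for i, pt in enumerate(design3.samples):
            expected = pt.day in ("F3", "F4") and pt.zt in (2, 6, 10, 14)
            assert (p4[i] > 0) == expected


class TestScreen:
    def test_feature_equal_to_template_hits_r_1(self, design3):
        pats = build_teacher_patterns(design3)
        p2 = pattern_by_id(design3)["P2_fasting_low"].values
        point_idx = design3.point_of_sample()
        mat = pd.DataFrame(
            [p2[point_idx], -p2[point_idx]], index=["pos", "neg"], columns=design3.sample_ids
        )
        hits = correlation_screen(mat, pats, design3)
        by = {(h.feature_id, h.pattern_id): h for h in hits}
        assert by[("pos", "P2_fasting_low")].r == pytest.approx(1.0)
        assert by[("pos", "P2_fasting_low")].sign == "positive"
        assert by[("neg", "P2_fasting_low")].r == pytest.approx(-1.0)
        assert by[("neg", "P2_fasting_low")].sign == "negative"
        # the perfect match is flagged primary
        assert by[("pos", "P2_fasting_low")].primary

    def test_zero_variance_feature_excluded_with_log(self, design3, caplog):
        mat = pd.DataFrame(
            np.ones((2, 60)), index=["flat", "flat2"], columns=design3.sample_ids
        )
        with caplog.at_level("WARNING"):
            hits = correlation_screen(mat, build_teacher_patterns(design3), design3)
        assert hits == []
        assert "zero-variance" in caplog.text

    def test_threshold_validation(self, design3):
        mat = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 60)),
                           columns=design3.sample_ids)
        with pytest.raises(ValueError):
            correlation_screen(mat, build_teacher_patterns(design3), design3, r_threshold=1.01)

    def test_recall_and_precision_on_planted_classes(self, design3, balanced_fractions):
        """amplitude = 4x log-noise sd, 100 features per class."""
        cv = 0.2
        sigma = np.sqrt(np.log1p(cv**2))
        sim = simulate_metabolites(
            design3,
            n_rois=500,
            class_fractions=balanced_fractions,
            noise_cv=cv,
            amplitude=4 * sigma,
            seed=2024,
        )
        hits = correlation_screen(
            np.log(sim.intensities), build_teacher_patterns(design3), design3
        )
        metrics = evaluate_screen(hits, sim.truth_frame, design3)
        for klass in ("circadian", "fasting_low", "gradual", "feeding_acute"):
            assert metrics[f"recall_{klass}"] >= 0.9, metrics
            assert metrics[f"precision_{klass}"] >= 0.9, metrics

    @given(scale=st.floats(min_value=0.1, max_value=10), shift=st.floats(-5, 5))
    @settings(max_examples=20, deadline=None)
    def test_screen_invariant_to_affine_rescaling(self, scale, shift):
        design = build_design(1)
        pats = build_teacher_patterns(design)
        rng = np.random.default_rng(5)
        base = pd.DataFrame(
            rng.normal(size=(4, design.n_points)), columns=design.sample_ids
        )
        h1 = hits_to_frame(correlation_screen(base, pats, design, r_threshold=0.3))
        h2 = hits_to_frame(
            correlation_screen(base * scale + shift, pats, design, r_threshold=0.3)
        )
        pd.testing.assert_frame_equal(h1.drop(columns="r"), h2.drop(columns="r"))
        assert np.allclose(h1["r"], h2["r"], atol=1e-9)

    def test_noiseless_threshold_1_hits_exactly_matching_classes(self, design3):
        shapes = pattern_shapes(design3)
        point_idx = design3.point_of_sample()
        rows = {f"f_{k}": v[point_idx] for k, v in shapes.items() if k != "P1_diurnal"}
        rows["null"] = np.zeros(len(point_idx)) + np.arange(len(point_idx)) * 1e-9
        mat = pd.DataFrame(rows.values(), index=list(rows), columns=design3.sample_ids)
        hits = correlation_screen(mat, build_teacher_patterns(design3), design3,
                                  r_threshold=1.0 - 1e-12)
        primary = {h.feature_id: h.pattern_id for h in hits if h.primary}
        assert primary == {
            "f_P2_fasting_low": "P2_fasting_low",
            "f_P3_gradual": "P3_gradual",
            "f_P4_feeding_acute": "P4_feeding_acute",
        }


class TestAssignPhase:
    def zt_cosine(self, design, phase):
        zts = np.array([p.zt for p in design.samples], float)
        return np.cos(2 * np.pi * (zts - phase) / 24)

    @pytest.mark.parametrize(
        "phase,expected",
        [(2, "morning ZT2"), (6, "day ZT6"), (10, "afternoon ZT10"),
         (18, "night ZT14-22"), (14, "night ZT14-22")],
    )
    def test_noiseless_cosine_bins(self, design3, phase, expected):
        assert assign_phase(self.zt_cosine(design3, phase), design3) == expected

    def test_tie_goes_to_earliest_zt(self, design1):
        assert assign_phase(np.ones(design1.n_points), design1) == PHASE_BINS[2]

    def test_binning_accuracy_with_noise(self, design3):
        """Phases drawn per bin, noise sd = amplitude/4: >= 85% binned right."""
        rng = np.random.default_rng(99)
        amplitude, noise_sd, n = 1.0, 0.25, 200
        zts = np.array([p.zt for p in design3.samples], float)
        point_idx = np.array(design3.point_of_sample())
        correct = 0
        for _ in range(n):
            phase = float(rng.choice([2, 6, 10, 14, 18, 22]))
            tc = amplitude * np.cos(2 * np.pi * (zts[point_idx] - phase) / 24)
            tc = tc + rng.normal(0, noise_sd, size=tc.shape)
            points = average_replicates(
                pd.DataFrame([tc], index=["f"], columns=design3.sample_ids), design3
            )
            correct += assign_phase(points.loc["f"].values, design3) == PHASE_BINS[phase]
        assert correct / n >= 0.85

    def test_wrong_length_rejected(self, design3):
        with pytest.raises(ValueError):
            assign_phase(np.ones(3), design3)


class TestIntegrate:
    def perfect_hits(self, design):
        pats = build_teacher_patterns(design)
        p1 = pattern_by_id(design)["P1_diurnal"].values
        point_idx = design.point_of_sample()
        gmat = pd.DataFrame([p1[point_idx]], index=["g1"], columns=design.sample_ids)
        mmat = pd.DataFrame([p1[point_idx]], index=["m1"], columns=design.sample_ids)
        gh = correlation_screen(gmat, pats, design, layer="gene")
        mh = correlation_screen(mmat, pats, design, layer="metabolite")
        return gh, mh, average_replicates(gmat, design), average_replicates(mmat, design)

    def test_no_metabolite_hits_gives_empty_table(self, design1):
        gh, _, gp, mp = self.perfect_hits(design1)
        out = integrate_omics(gh, [], gp, mp)
        assert len(out) == 0

    def test_matching_gene_and_metabolite_pair_r_1(self, design1):
        gh, mh, gp, mp = self.perfect_hits(design1)
        out = integrate_omics(gh, mh, gp, mp)
        row = out[(out["pattern_id"] == "P1_diurnal")].iloc[0]
        assert (row["gene_id"], row["metabolite_id"]) == ("g1", "m1")
        assert row["r"] == pytest.approx(1.0)

    def test_pair_count_is_product_within_groups(self, design3, balanced_fractions):
        sim_g = simulate_metabolites(design3, n_rois=60, class_fractions=balanced_fractions,
                                     noise_cv=0.05, amplitude=2.0, seed=1)
        sim_m = simulate_metabolites(design3, n_rois=40, class_fractions=balanced_fractions,
                                     noise_cv=0.05, amplitude=2.0, seed=2)
        pats = build_teacher_patterns(design3)
        gh = correlation_screen(np.log(sim_g.intensities), pats, design3, layer="gene")
        mh = correlation_screen(np.log(sim_m.intensities), pats, design3, layer="metabolite")
        gp = average_replicates(np.log(sim_g.intensities), design3)
        mp = average_replicates(np.log(sim_m.intensities), design3)
        out = integrate_omics(gh, mh, gp, mp)
        expected = 0
        groups = set((h.pattern_id, h.sign) for h in gh) | set(
            (h.pattern_id, h.sign) for h in mh
        )
        for g in groups:
            ng = sum((h.pattern_id, h.sign) == g for h in gh)
            nm = sum((h.pattern_id, h.sign) == g for h in mh)
            expected += ng * nm
        assert len(out) == expected
        assert (out["r"].abs().diff().dropna() <= 1e-12).all()  # sorted by |r| desc
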