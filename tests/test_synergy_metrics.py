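"""Combination index, nonlinear blending, classification, full pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import combosurf.synergy_metrics as sm
from combosurf import (
    BlendingRaySpec,
    Checkerboard,
    RunConfig,
    SurfaceParams,
    SyntheticSpec,
    analyze_combination,
    classify,
    compute_blending,
    compute_ci,
    generate_checkerboard,
    predict_hill,
)
from conftest import random_surface


class TestComputeCI:
    def test_sham_combination_gives_unit_ci(self, rng):
        for _ in range(5):
            einf = rng.uniform(0.0, 0.3)
            c = 10.0 ** rng.uniform(1.5, 2.5)
            h = rng.uniform(0.6, 2.5)
            p = SurfaceParams(1.0, einf, c, h, einf, c, h, 0.0, einf * 0.9)
            res = compute_ci(p, (100 * c, 100 * c))
            assert res.ci == pytest.approx(1.0, abs=1e-6)
            assert res.ci_min_isobole == pytest.approx(1.0, abs=1e-6)

    def test_additive_null_with_distinct_marginals_gives_unit_ci(self, rng):
        for _ in range(10):
            p = random_surface(rng, alpha=(0.0, 0.0))
            res = compute_ci(p, (100 * p.ec50_a, 100 * p.ec50_b))
            assert res.ci == pytest.approx(1.0, abs=1e-6)
            assert res.ci_min_isobole == pytest.approx(1.0, abs=1e-6)

    def test_analytic_interaction_surface_min_ci(self):
        """Full-range unit-slope marginals at alpha = 3: on the 50% contour
        the equation is s + 3 (dA/DA50)(dB/DB50) = 1 with s the CI, whose
        minimum over the contour is exactly 2/3 (attained at equal scaled
        doses)."""
        p = SurfaceParams(1.0, 0.0, 100.0, 1.0, 0.0, 200.0, 1.0, 3.0, 0.0)
        res = compute_ci(p, (1e4, 2e4))
        assert res.ci_min_isobole == pytest.approx(2.0 / 3.0, abs=1e-9)
        assert res.ci == pytest.approx(2.0 / 3.0, abs=1e-9)

    def test_not_available_when_marginal_cannot_reach_half(self):
        p = SurfaceParams(1.0, 0.1, 100.0, 1.0, 0.6, 200.0, 1.0, 2.0, 0.1)
        assert compute_ci(p, (1e4, 2e4)) is None

    def test_not_available_when_half_effect_needs_extrapolation(self):
        p = SurfaceParams(1.0, 0.0, 100.0, 1.0, 0.0, 200.0, 1.0, 0.0, 0.0)
        # marginal A reaches 50% only at 100 nM, beyond a 50 nM grid
        assert compute_ci(p, (50.0, 2e4)) is None

    def test_antagonism_raises_headline_ci_above_one(self):
        p = SurfaceParams(1.0, 0.1, 100.0, 1.2, 0.15, 200.0, 1.5, -0.5, 0.10)
        res = compute_ci(p, (316.0, 632.0))
        assert res.ci > 1.0
        assert res.at == "equipotent"

    def test_scale_invariance_in_drug_a_units(self, rng):
        """Rescaling drug A's concentration axis (doses and ec50 together)
        must leave the CI unchanged."""
        p = random_surface(rng, alpha=(1.0, 3.0))
        res = compute_ci(p, (100 * p.ec50_a, 100 * p.ec50_b))
        for c in (10.0, 0.01):
            q = SurfaceParams(p.e_zero, p.e_inf_a, p.ec50_a * c, p.hill_a,
                              p.e_inf_b, p.ec50_b, p.hill_b, p.alpha, p.e_inf_ab)
            res_c = compute_ci(q, (100 * q.ec50_a, 100 * q.ec50_b))
            assert res_c.ci == pytest.approx(res.ci, abs=1e-8)
            assert res_c.ci_min_isobole == pytest.approx(
                res.ci_min_isobole, abs=1e-8)


class TestComputeBlending:
    def test_constant_ray_blends_to_zero(self, rng):
        """Sham combination along the anti-diagonal: inhibition is constant
        along the ray, so the interior never beats the endpoints."""
        einf = 0.1
        p = SurfaceParams(1.0, einf, 100.0, 1.5, einf, 100.0, 1.5, 0.0, einf)
        ray = BlendingRaySpec(scaling=(1000.0, 1000.0))
        assert compute_blending(p, ray) == pytest.approx(0.0, abs=1e-6)

    def test_constructed_peak_minus_best_endpoint(self, monkeypatch):
        """Mid-ray inhibition 60% against endpoint inhibitions 35%/30%
        must score 60 - 35 = 25 points."""
        x0 = 1.0 / (1.0 + math.sqrt(30.0 / 25.0))
        c = 25.0 / x0**2

        def fake_surface(params, dose_a, dose_b):
            x = np.asarray(dose_a, dtype=float) / 1000.0
            inh = 60.0 - c * (x - x0) ** 2
            return 1.0 - inh / 100.0

        monkeypatch.setattr(sm, "predict_surface", fake_surface)
        p = SurfaceParams(1.0, 0.0, 100.0, 1.0, 0.0, 100.0, 1.0, 0.0, 0.0)
        ray = BlendingRaySpec(scaling=(1000.0, 1000.0))
        assert compute_blending(p, ray) == pytest.approx(25.0, abs=1e-6)

    def test_exhaustive_ray_sweep_oracle(self, rng):
        """Optimized blending matches a 10,001-point exhaustive sweep."""
        for _ in range(5):
            p = random_surface(rng, alpha=(0.5, 5.0))
            sa, sb = 100 * p.ec50_a, 100 * p.ec50_b
            ray = BlendingRaySpec(scaling=(sa, sb))
            got = compute_blending(p, ray)
            xs = np.linspace(0.0, 1.0, 10_001)
            inh = 100.0 * (1.0 - sm.predict_surface(p, xs * sa, (1 - xs) * sb))
            oracle = float(inh[1:-1].max() - max(inh[0], inh[-1]))
            assert got == pytest.approx(oracle, abs=0.1)

    def test_swap_symmetry(self, rng):
        for _ in range(5):
            p = random_surface(rng, alpha=(0.5, 4.0))
            swapped = SurfaceParams(p.e_zero, p.e_inf_b, p.ec50_b, p.hill_b,
                                    p.e_inf_a, p.ec50_a, p.hill_a, p.alpha,
                                    p.e_inf_ab)
            ray = BlendingRaySpec(scaling=(100 * p.ec50_a, 100 * p.ec50_b))
            ray_sw = BlendingRaySpec(scaling=(100 * p.ec50_b, 100 * p.ec50_a))
            assert compute_blending(p, ray) == pytest.approx(
                compute_blending(swapped, ray_sw), abs=1e-8)

    def test_ray_spec_validation(self):
        with pytest.raises(ValueError):
            BlendingRaySpec(scaling=(0.0, 1.0))
        with pytest.raises(ValueError):
            BlendingRaySpec(scaling=(1.0, 1.0), n_fractions=5)
        with pytest.raises(ValueError):
            BlendingRaySpec(scaling=(1.0, 1.0), total_scaled_dose=1.5)


class TestClassify:
    @pytest.mark.parametrize(
        "ci, blending, label, basis",
        [
            (0.30, 36.5, "synergy", "ci"),        # TF-1a
            (0.41, 19.6, "synergy", "ci"),        # HL-60: CI overrides blending
            (None, 8.6, "additivity", "blending"),  # GF-D8: blending fallback
            (1.73, -27.6, "subadditivity", "ci"),   # CMK-86
            (None, 34.9, "synergy", "blending"),
            (None, -27.6, "subadditivity", "blending"),
        ],
    )
    def test_published_panel_examples(self, ci, blending, label, basis):
        assert classify(ci, blending) == (label, basis)

    @pytest.mark.parametrize("ci", [0.7, 1.3])
    def test_ci_boundaries_fall_in_additivity(self, ci):
        assert classify(ci, None) == ("additivity", "ci")

    @pytest.mark.parametrize("blending", [-20.0, 20.0])
    def test_blending_boundaries_fall_in_additivity(self, blending):
        assert classify(None, blending) == ("additivity", "blending")

    def test_both_unavailable_is_error(self):
        with pytest.raises(ValueError):
            classify(None, float("nan"))

    @given(
        ci=st.one_of(st.none(), st.floats(0.01, 10.0)),
        blending=st.one_of(st.none(), st.floats(-100.0, 100.0)),
    )
    @settings(max_examples=200, deadline=None)
    def test_total_and_deterministic(self, ci, blending):
        """classify partitions its domain: always exactly one label, CI basis
        whenever a CI exists."""
        if ci is None and blending is None:
            return
        label, basis = classify(ci, blending)
        assert label in ("synergy", "additivity", "subadditivity")
        assert basis == ("ci" if ci is not None else "blending")
        assert classify(ci, blending) == (label, basis)


class TestAnalyzeCombination:
    lean = RunConfig(hill_restarts=6, surface_restarts=2)

    def test_null_board_labelled_additive(self):
        spec = SyntheticSpec(truth="loewe-null", sigma=0.03, seed=42)
        board, _ = generate_checkerboard(spec)
        report = analyze_combination(board, self.lean)
        assert report.label == "additivity"
        assert report.basis == "ci"
        assert report.ci == pytest.approx(1.0, abs=0.15)

    def test_strong_synergy_board_labelled_synergy(self):
        spec = SyntheticSpec(truth="synergy", sigma=0.03, seed=43)
        board, _ = generate_checkerboard(spec)
        report = analyze_combination(board, self.lean)
        assert report.label == "synergy"
        assert report.basis == "ci"
        assert report.ci < 0.7

    def test_inert_partner_board_is_additive_via_blending(self, rng):
        """Drug B inert: its axis is flat, 50% inhibition is unreachable for
        it, CI is NA, and the blending fallback scores ~0 (additivity)."""
        a = SurfaceParams(1.0, 0.1, 100.0, 1.5, 0.1, 100.0, 1.5, 0.0, 0.1)
        doses = np.concatenate([[0.0], np.geomspace(3.0, 10_000.0, 8)])
        va = predict_hill(a.marginal_a, doses)
        v = np.repeat(va[:, None], doses.size, axis=1)  # B changes nothing
        board = Checkerboard(doses, doses, np.repeat(v[:, :, None], 2, axis=2))
        report = analyze_combination(board, self.lean)
        assert math.isnan(report.ci)
        assert report.basis == "blending"
        assert report.label == "additivity"
        assert abs(report.blending) < 5.0

    def test_report_carries_fit_diagnostics(self):
        spec = SyntheticSpec(truth="loewe-null", sigma=0.03, seed=7)
        board, _ = generate_checkerboard(spec)
        report = analyze_combination(board, self.lean)
        d = report.diagnostics
        assert set(d["surface_params"]) == {
            "e_zero", "e_inf_a", "ec50_a_nM", "hill_a",
            "e_inf_b", "ec50_b_nM", "hill_b", "alpha", "e_inf_ab"}
        assert d["surface_fit"]["converged"] is True
        assert d["ci_available"] is True
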