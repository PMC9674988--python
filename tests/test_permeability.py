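"""Solubility-diffusion pipeline: calibration, cleanup, the resistance
integral, layer scaling and uncertainty combination."""

import math

import numpy as np
import pytest

import permawh as pw
from permawh.constants import NM_PER_PS_TO_CM_PER_H, PS_PER_NM_TO_H_PER_CM
from permawh.permeability import (
    LayerModel,
    calibrate_relative_to_solvent,
    combine_pmfs,
    combine_sets,
    layer_count,
    offset_nonnegative,
    resistance,
    total_permeability,
    trim_edges,
)
from permawh.profiles import DiffusionProfile, PMFProfile


def make_pmf(dG, tag="solvent", z=None, se=None):
    z = np.linspace(0.0, 2.0, len(dG)) if z is None else z
    return PMFProfile(z=z, dG=np.asarray(dG, dtype=float), se=se, reference_tag=tag)


class TestCalibration:
    def test_zero_solvation_changes_only_the_tag(self):
        pmf = make_pmf([1.0, 2.0, 3.0], tag="vacuum")
        out = calibrate_relative_to_solvent(pmf, 0.0)
        assert out.reference_tag == "solvent"
        assert np.allclose(out.dG, pmf.dG)

    def test_environment_equal_to_solvent_calibrates_to_zero(self):
        land = pw.build_landscape(pw.solvent_box_spec())
        grid = np.linspace(0.1, 0.9, 9)
        # the whole box is solvent, so the vacuum-referenced profile equals
        # the solvation free energy everywhere and calibration nulls it
        dgs = pw.reference_solvation(land)
        pmf = make_pmf(np.full(9, dgs), tag="vacuum", z=grid)
        out = calibrate_relative_to_solvent(pmf, dgs)
        assert np.allclose(out.dG, 0.0, atol=1e-9)

    def test_double_calibration_rejected(self):
        pmf = make_pmf([0.0, 1.0, 0.0])
        with pytest.raises(ValueError):
            calibrate_relative_to_solvent(pmf, 1.0)


class TestOffsetAndTrim:
    def test_offset_makes_minimum_exactly_zero(self):
        out = offset_nonnegative(make_pmf([-3.0, -1.0, 2.0]))
        assert out.dG.min() == 0.0
        assert np.allclose(out.dG, [0.0, 2.0, 5.0])
        again = offset_nonnegative(out)
        assert np.allclose(again.dG, out.dG)

    def test_offset_scales_resistance_by_boltzmann_factor(self, thermo):
        """Algebraic oracle: shifting dG by c multiplies R by exp(beta c)."""
        z = np.linspace(0, 2, 21)
        dG = np.sin(z) - 2.0
        dp = DiffusionProfile(z=z, D=np.full(21, 0.5))
        raw = make_pmf(dG - dG.min(), z=z)  # already non-negative
        shifted = make_pmf(dG - dG.min() + 1.7, z=z)
        r1 = resistance(raw, dp, thermo)
        r2 = resistance(shifted, dp, thermo)
        assert r2 / r1 == pytest.approx(math.exp(thermo.beta * 1.7), rel=1e-12)

    def test_trim_replaces_edge_spikes_only(self):
        dG = np.array([9.0, 7.0, 1.0, 1.5, 2.0, 1.0, 8.0, 11.0])
        out = trim_edges(make_pmf(dG), n_edge=2)
        assert np.allclose(out.dG, [1.0, 1.0, 1.0, 1.5, 2.0, 1.0, 1.0, 1.0])
        assert np.array_equal(out.z, np.linspace(0, 2, 8))

    def test_trim_identity_cases(self):
        pmf = make_pmf([1.0, 1.0, 2.0, 1.0, 1.0])
        assert np.allclose(trim_edges(pmf, 0).dG, pmf.dG)
        assert np.allclose(trim_edges(pmf, 1).dG, pmf.dG)
        with pytest.raises(ValueError):
            trim_edges(pmf, 2)


class TestResistance:
    def test_flat_profile_closed_form(self, thermo):
        """dG = 0, D = D0 over length L: R = L/D0 to machine precision."""
        z = np.linspace(0.0, 2.0, 41)
        pmf = make_pmf(np.zeros(41), z=z)
        dp = DiffusionProfile(z=z, D=np.full(41, 0.25))
        assert resistance(pmf, dp, thermo) == pytest.approx(2.0 / 0.25, rel=1e-12)

    def test_gaussian_barrier_matches_fine_quadrature(self, thermo):
        """Independent oracle at 100x resolution within 1e-6 relative."""
        z = np.linspace(0.0, 2.0, 201)
        dG = 8.0 * np.exp(-((z - 1.0) ** 2) / (2 * 0.3**2))
        D = 0.3 + 0.1 * np.cos(z)
        r = resistance(make_pmf(dG, z=z), DiffusionProfile(z=z, D=D), thermo)
        zf = np.linspace(0.0, 2.0, 20_001)
        dGf = 8.0 * np.exp(-((zf - 1.0) ** 2) / (2 * 0.3**2))
        Df = 0.3 + 0.1 * np.cos(zf)
        oracle = np.trapezoid(np.exp(thermo.beta * dGf) / Df, zf)
        assert r == pytest.approx(oracle, rel=1e-6)

    def test_simpson_agrees_with_trapezoid(self, thermo):
        z = np.linspace(0.0, 2.0, 201)
        dG = 5.0 * np.exp(-((z - 1.0) ** 2) / 0.2)
        dp = DiffusionProfile(z=z, D=np.full(201, 0.4))
        r_t = resistance(make_pmf(dG, z=z), dp, thermo, method="trapezoid")
        r_s = resistance(make_pmf(dG, z=z), dp, thermo, method="simpson")
        assert r_s == pytest.approx(r_t, rel=1e-4)

    def test_pointwise_increase_raises_resistance(self, thermo):
        z = np.linspace(0.0, 2.0, 21)
        dp = DiffusionProfile(z=z, D=np.full(21, 0.5))
        base = np.abs(np.sin(2 * z))
        r0 = resistance(make_pmf(base, z=z), dp, thermo)
        bumped = base.copy()
        bumped[7] += 0.5
        assert resistance(make_pmf(bumped, z=z), dp, thermo) > r0

    def test_validation_errors(self, thermo):
        z = np.linspace(0.0, 2.0, 11)
        dp = DiffusionProfile(z=z, D=np.full(11, 0.5))
        with pytest.raises(ValueError, match="solvent-calibrated"):
            resistance(make_pmf(np.zeros(11), tag="vacuum", z=z), dp, thermo)
        with pytest.raises(ValueError, match="offset_nonnegative"):
            resistance(make_pmf(np.full(11, -1.0), z=z), dp, thermo)
        holey = DiffusionProfile(z=z, D=np.where(z == z[5], np.nan, 0.5))
        with pytest.raises(ValueError, match="missing"):
            resistance(make_pmf(np.zeros(11), z=z), holey, thermo)


class TestLayerModel:
    def test_default_stack_is_thirty_bilayers(self):
        mean, se = layer_count(LayerModel())
        assert mean == pytest.approx(30.0)
        # delta-method SE of 12(+-0.4) x 2.5(+-0.5); rounds to 6 at reporting
        assert se == pytest.approx(math.hypot(2.5 * 0.4, 12 * 0.5))
        assert round(se) == 6

    def test_zero_ses_propagate_to_zero(self):
        lm = LayerModel(n_regions_se=0.0, bilayers_per_region_se=0.0)
        assert layer_count(lm)[1] == 0.0

    def test_unit_resistance_single_layer(self, thermo):
        lm = LayerModel(n_regions=1.0, n_regions_se=0.0,
                        bilayers_per_region=1.0, bilayers_per_region_se=0.0)
        res = total_permeability(1.0, lm, thermo, units="h/cm")
        assert res.K_P == pytest.approx(1.0)
        assert res.log10_KP == pytest.approx(0.0)

    def test_eighty_layers_subtract_1_9_log_units(self, thermo):
        lm1 = LayerModel(1.0, 0.0, 1.0, 0.0)
        lm80 = LayerModel(80.0, 0.0, 1.0, 0.0)
        r = 3.7e-9
        a = total_permeability(r, lm1, thermo)
        b = total_permeability(r, lm80, thermo)
        assert a.log10_KP - b.log10_KP == pytest.approx(math.log10(80.0), abs=1e-12)
        assert math.log10(80.0) == pytest.approx(1.9, abs=0.01)

    @pytest.mark.parametrize("n", [2, 5, 30, 80, 1000])
    def test_layer_scaling_linearity(self, n, thermo):
        """log10 K_P(N) - log10 K_P(1) = -log10 N exactly."""
        lm1 = LayerModel(1.0, 0.0, 1.0, 0.0)
        lmn = LayerModel(float(n), 0.0, 1.0, 0.0)
        r = 2.2e-8
        d = total_permeability(r, lmn, thermo).log10_KP - \
            total_permeability(r, lm1, thermo).log10_KP
        assert d == pytest.approx(-math.log10(n), abs=1e-12)

    def test_unit_conversion_consistency(self, thermo):
        assert NM_PER_PS_TO_CM_PER_H == pytest.approx(3.6e8)
        lm = LayerModel(1.0, 0.0, 1.0, 0.0)
        res = total_permeability(1.0, lm, thermo, units="ps/nm")
        assert res.K_P == pytest.approx(3.6e8)
        assert PS_PER_NM_TO_H_PER_CM * NM_PER_PS_TO_CM_PER_H == pytest.approx(1.0)

    def test_nonpositive_resistance_rejected(self, thermo):
        with pytest.raises(ValueError):
            total_permeability(0.0, LayerModel(), thermo)


class TestCombineSets:
    def test_identical_sets_have_zero_se(self):
        pmf = make_pmf([0.0, 1.0, 0.5])
        out = combine_pmfs([pmf, pmf, pmf])
        assert np.allclose(out.se, 0.0)

    def test_constant_offset_halves_in_the_mean(self):
        a = make_pmf([0.0, 1.0, 0.5])
        b = make_pmf([2.0, 3.0, 2.5])
        out = combine_pmfs([a, b])
        assert np.allclose(out.dG, [1.0, 2.0, 1.5])
        assert np.allclose(np.diff(out.dG), np.diff(a.dG))

    def test_known_spread_matches_direct_se(self):
        rng = np.random.default_rng(8)
        base = np.array([0.0, 2.0, 1.0, 0.5])
        sets = [make_pmf(base + rng.standard_normal(4)) for _ in range(5)]
        out = combine_pmfs(sets)
        stack = np.stack([p.dG for p in sets])
        assert np.allclose(out.se, stack.std(axis=0, ddof=1) / np.sqrt(5))

    def test_single_set_warns_about_unreliable_error(self):
        with pytest.warns(UserWarning, match="reliable error"):
            out = combine_pmfs([make_pmf([0.0, 1.0, 0.0])])
        assert out.se is None

    def test_combined_permeability_with_propagation_modes(self, thermo):
        z = np.linspace(0, 2, 21)
        rng = np.random.default_rng(2)
        sets = [make_pmf(np.abs(np.sin(z)) * 5 + 0.2 * rng.standard_normal(21), z=z)
                for _ in range(4)]
        dp = DiffusionProfile(z=z, D=np.full(21, 0.5))
        _, delta = combine_sets(sets, dp, thermo=thermo, propagate="delta")
        _, mc = combine_sets(sets, dp, thermo=thermo, propagate="mc", n_mc=400,
                             rng=np.random.default_rng(0))
        _, none = combine_sets(sets, dp, thermo=thermo, propagate="none")
        assert delta.se_log10_KP > none.se_log10_KP
        assert mc.se_log10_KP == pytest.approx(delta.se_log10_KP, rel=0.5)


class TestEndToEnd:
    def test_full_pipeline_recovers_analytic_permeability(self, mini_pipeline):
        """Sampled PMF + friction-estimated D reproduce the analytic K_P of
        the mini membrane within 0.3 log10 units (factor 2)."""
        est = mini_pipeline["result"].log10_KP
        ref = mini_pipeline["ref_result"].log10_KP
        assert abs(est - ref) < 0.3

    def test_pipeline_solvation_matches_quadrature(self, mini_pipeline):
        ref = pw.reference_solvation(mini_pipeline["land"])
        assert abs(mini_pipeline["dG_solv"] - ref) < 0.3
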