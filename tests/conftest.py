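"""Shared fixtures: landscapes and (expensive) seeded sampler runs.

The heavy runs are session-scoped so the sampling tests and the acceptance
suite reuse the same simulations instead of re-running them.
"""

from __future__ import annotations

import numpy as np
import pytest

import permawh as pw
from permawh.awh import AWHConfig, GridSpec, run_awh
from permawh.friction import combine_walkers, friction_from_run, rolling_median
from permawh.permeability import (
    LayerModel,
    calibrate_relative_to_solvent,
    offset_nonnegative,
    resistance,
    total_permeability,
)
from permawh.profiles import DiffusionProfile, PMFProfile


@pytest.fixture(scope="session")
def thermo():
    return pw.ThermoParams()


@pytest.fixture(scope="session")
def two_state_land():
    return pw.build_landscape(pw.two_state_spec())


@pytest.fixture(scope="session")
def two_state_run(two_state_land, thermo):
    """1D spatial AWH on the asymmetric double well, plus its quadrature ref."""
    grid = GridSpec(0.0, two_state_land.length, n_z=16, lambda_states=1)
    cfg = AWHConfig(input_diffusion_spatial=1.0, force_constant=400.0,
                    covering_min_diameter=0.8, n_walkers=2, target_spec="uniform")
    run = run_awh(two_state_land, grid, cfg, 200_000, [11, 12], thermo=thermo)
    ref = pw.reference_pmf(two_state_land, 0, grid.z_centers, thermo=thermo,
                           umbrella_k=cfg.force_constant, anchor="none")
    return {"run": run, "grid": grid, "cfg": cfg, "ref": ref, "land": two_state_land}


@pytest.fixture(scope="session")
def membrane_run(thermo):
    """2D (spatial x alchemical) AWH on the default membrane toy."""
    spec = pw.default_membrane_spec()
    spec["schedule"] = {"n_states": 7}
    land = pw.build_landscape(spec)
    grid = GridSpec(0.0, land.length, n_z=24, lambda_states=7)
    w = np.ones(7)
    w[0], w[-1] = 6.0, 2.0
    cfg = AWHConfig(input_diffusion_spatial=1.0, input_diffusion_lambda=0.05,
                    force_constant=200.0, covering_min_diameter=0.8,
                    n_walkers=2, target_spec=w)
    integ = pw.IntegratorParams(dt=0.003, tau_t=2.0, mass=1.0)
    run = run_awh(land, grid, cfg, 1_200_000, [31, 32], thermo=thermo,
                  integrator=integ)
    ref = pw.reference_pmf(land, 0, grid.z_centers, thermo=thermo,
                           umbrella_k=cfg.force_constant, anchor="none")
    return {"run": run, "grid": grid, "cfg": cfg, "ref": ref, "land": land}


def mini_membrane_spec():
    """Compact one-barrier membrane used for the end-to-end recovery check."""
    return {
        "length": 2.6,
        "solvent_level": -5.0,
        "boundary": "reflective",
        "barriers": [{"center": 1.0, "height": 18.0, "width": 0.3}],
        "wells": [{"center": 0.45, "depth": 8.0, "width": 0.25}],
        "solvent_region": [1.9, 2.6],
        "schedule": {"n_states": 5},
    }


@pytest.fixture(scope="session")
def mini_pipeline(thermo):
    """Full pipeline on the mini membrane: sampled PMF + estimated D -> K_P,
    with the analytic (quadrature PMF + known free diffusion) counterpart."""
    land = pw.build_landscape(mini_membrane_spec())
    grid = GridSpec(0.0, land.length, n_z=16, lambda_states=5)
    integ = pw.IntegratorParams(dt=0.003, tau_t=0.02, mass=1.0)  # overdamped
    D_free = thermo.kT * integ.tau_t / integ.mass
    w = np.ones(5)
    w[0], w[-1] = 4.0, 2.0
    cfg = AWHConfig(input_diffusion_spatial=D_free, input_diffusion_lambda=0.05,
                    force_constant=200.0, covering_min_diameter=0.8,
                    n_walkers=2, target_spec=w)
    run = run_awh(land, grid, cfg, 1_500_000, [1, 2], thermo=thermo,
                  integrator=integ, friction_blocks=64)
    dG_solv = pw.solvation_estimate(run.bias, land)
    dp = rolling_median(combine_walkers(friction_from_run(run, thermo)), 0.5)
    pmf = offset_nonnegative(
        calibrate_relative_to_solvent(pw.vacuum_referenced_pmf(run.bias), dG_solv)
    )
    result = total_permeability(resistance(pmf, dp, thermo), LayerModel(), thermo)

    ref_dG = pw.reference_pmf(land, 0, grid.z_centers, thermo=thermo,
                              umbrella_k=cfg.force_constant, anchor="solvent")
    ref_pmf = offset_nonnegative(
        PMFProfile(grid.z_centers, ref_dG, reference_tag="solvent")
    )
    ref_dp = DiffusionProfile(grid.z_centers, np.full(grid.n_z, D_free))
    ref_result = total_permeability(resistance(ref_pmf, ref_dp, thermo),
                                    LayerModel(), thermo)
    return {
        "run": run, "land": land, "grid": grid, "cfg": cfg, "integ": integ,
        "D_free": D_free, "dG_solv": dG_solv, "dp": dp, "pmf": pmf,
        "result": result, "ref_result": ref_result, "ref_pmf": ref_pmf,
    }


@pytest.fixture(scope="session")
def flat_friction_run(thermo):
    """Flat landscape, overdamped: the diffusion-recovery workhorse."""
    land = pw.build_landscape(pw.flat_spec(length=5.21, n_lambda=1))
    grid = GridSpec(0.0, 5.21, n_z=24, lambda_states=1)
    integ = pw.IntegratorParams(dt=0.003, tau_t=0.02, mass=1.0)
    D_free = thermo.kT * integ.tau_t / integ.mass
    cfg = AWHConfig(input_diffusion_spatial=D_free, force_constant=200.0,
                    covering_min_diameter=0.8, n_walkers=2, target_spec="uniform")
    run = run_awh(land, grid, cfg, 600_000, [60, 61], thermo=thermo,
                  integrator=integ, friction_blocks=64)
    return {"run": run, "grid": grid, "D_free": D_free, "integ": integ}


@pytest.fixture(scope="session")
def comparison_result():
    """The paired 2D-vs-1D gel-toy comparison (31 seeds, sign test)."""
    from permawh.comparison import two_d_vs_one_d

    return two_d_vs_one_d(n_seeds=31, total_steps=800_000, base_seed=1)


def interior_weighted_mean_diffusion(run, thermo, n_edge: int = 2):
    """Occupancy-weighted mean of the combined D over interior bins."""
    profiles = friction_from_run(run, thermo)
    dp = combine_walkers(profiles)
    occ = np.sum([p.occupancy for p in profiles], axis=0)
    sl = slice(n_edge, -n_edge)
    d = dp.D[sl]
    w = np.where(np.isfinite(d), occ[sl], 0.0)
    return float(np.nansum(np.nan_to_num(d) * w) / w.sum())
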