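"""Stochastic (velocity Langevin) dynamics on toy landscapes.

The integrator is BAOAB with exact Ornstein-Uhlenbeck velocity updates, so
the fluctuation-dissipation balance holds for any friction and the stationary
kinetic energy averages k_B T / 2 per degree of freedom up to O(dt^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .landscape import LandscapeError, ThermoParams, ToyLandscape, forces

__all__ = ["IntegratorParams", "ParticleState", "langevin_step", "simulate_unbiased"]


@dataclass(frozen=True)
class IntegratorParams:
    """Langevin integrator parameters (ps / reduced-mass units).

    ``friction`` is derived as 1/tau_t, mirroring the convention that a
    thermostat time constant of 2 ps corresponds to a friction of 0.5 ps^-1.
    """

    dt: float = 0.003
    tau_t: float = 2.0
    mass: float = 1.0
    n_steps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.dt > 0 and math.isfinite(self.dt)):
            raise LandscapeError(f"dt must be > 0, got {self.dt}")
        if not (self.tau_t > 0 and self.mass > 0):
            raise LandscapeError("tau_t and mass must be > 0")

    @property
    def friction(self) -> float:
        return 1.0 / self.tau_t


@dataclass(frozen=True)
class ParticleState:
    z: float
    v_z: float = 0.0
    theta: float = 0.0
    v_theta: float = 0.0


def _kernel_args(land: ToyLandscape):
    c, h, w = land.feature_arrays()
    import numpy as _np
    traps = land.traps
    return dict(
        featc=c, feath=h, featw=w,
        theta_b=land.theta_barrier,
        trapc=_np.array([t.center for t in traps], dtype=float),
        trapw=_np.array([t.width for t in traps], dtype=float),
        trapd=_np.array([t.depth for t in traps], dtype=float),
        trapph=_np.array([t.phase for t in traps], dtype=float),
        theta_k=land.theta_k, solvent_level=land.solvent_level,
        alpha=land.softcore.alpha, eps_sc=land.softcore.eps_sc,
        L=land.length, reflect=land.boundary == "reflective",
    )


def langevin_step(
    state: ParticleState,
    land: ToyLandscape,
    lam_index: int,
    params: IntegratorParams,
    rng: np.random.Generator,
    thermo: ThermoParams | None = None,
    bias_force: float = 0.0,
    walker_id: int = 0,
    step: int = 0,
) -> ParticleState:
    """One BAOAB step; ``bias_force`` is an extra constant force on z.

    Aborts with a diagnostic naming the walker and step on force overflow.
    """
    thermo = thermo or ThermoParams()
    if not math.isfinite(bias_force):
        raise FloatingPointError(
            f"non-finite bias force on walker {walker_id} at step {step}"
        )
    dt, m, gamma = params.dt, params.mass, params.friction
    kT = thermo.kT
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(kT / m * (1.0 - c1 * c1))
    z, vz, th, vth = state.z, state.v_z, state.theta, state.v_theta
    fz, ft = forces(land, z, th, lam_index)
    fz += bias_force
    if abs(fz) > 1e12 or abs(ft) > 1e12:
        raise FloatingPointError(
            f"force overflow on walker {walker_id} at step {step}: fz={fz:.3e}"
        )
    vz += 0.5 * dt * fz / m
    vth += 0.5 * dt * ft / m
    z += 0.5 * dt * vz
    th += 0.5 * dt * vth
    z, vz = _reflect_py(z, vz, land)
    xi = rng.standard_normal(2)
    vz = c1 * vz + c2 * xi[0]
    vth = c1 * vth + c2 * xi[1]
    z += 0.5 * dt * vz
    th += 0.5 * dt * vth
    z, vz = _reflect_py(z, vz, land)
    th = math.remainder(th, 2 * math.pi)
    fz, ft = forces(land, z, th, lam_index)
    fz += bias_force
    vz += 0.5 * dt * fz / m
    vth += 0.5 * dt * ft / m
    return replace(state, z=z, v_z=vz, theta=th, v_theta=vth)


def _reflect_py(z: float, v: float, land: ToyLandscape):
    L = land.length
    if land.boundary == "periodic":
        return z % L, v
    while z < 0.0 or z > L:
        if z < 0.0:
            z, v = -z, -v
        else:
            z, v = 2.0 * L - z, -v
    return z, v


def simulate_unbiased(
    land: ToyLandscape,
    lam_index: int,
    params: IntegratorParams,
    thermo: ThermoParams | None = None,
    z0: float | None = None,
    stride: int = 10,
    rng: np.random.Generator | None = None,
):
    """Long unbiased run (jitted); returns (z, v_z, theta) sampled every ``stride``.

    Used by the equipartition / Boltzmann-stationarity checks and as the
    brute-force PMF oracle.
    """
    thermo = thermo or ThermoParams()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    n = params.n_steps
    if n <= 0:
        raise ValueError("params.n_steps must be set for simulate_unbiased")
    ka = _kernel_args(land)
    lam = float(land.schedule.values[lam_index])
    n_out = n // stride
    z_out = np.empty(n_out)
    vz_out = np.empty(n_out)
    th_out = np.empty(n_out)
    normals = rng.standard_normal((n, 2))
    _kernels.langevin_run(
        n, stride,
        float(z0 if z0 is not None else land.length / 2), 0.0, 0.0, 0.0, lam,
        ka["featc"], ka["feath"], ka["featw"], ka["theta_b"], ka["trapc"],
        ka["trapw"], ka["trapd"], ka["trapph"], ka["theta_k"], ka["solvent_level"],
        ka["alpha"], ka["eps_sc"], ka["L"], ka["reflect"],
        params.dt, params.friction, params.mass, thermo.kT,
        normals, z_out, vz_out, th_out,
    )
    return z_out, vz_out, th_out
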