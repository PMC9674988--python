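"""Accelerated-weight-histogram (AWH) adaptive-bias sampling.

A shared adaptive bias on a 1D (spatial or alchemical) or 2D
(spatial x alchemical) grid is learned by one or more communicating Langevin
walkers.  Each walker carries a harmonic umbrella reference point (z-bin,
lambda-index); every ``mc_interval`` integrator steps the reference point is
resampled by an exact Gibbs move over the umbrella window and all lambda
states, and every ``samples_per_update`` such samples the shared free-energy
estimate f is updated from the accumulated point weights.

Update rule (weighted-histogram increment, documented here and exercised by
the recovery tests):

    f(m) <- f(m) - kT * ln[ (N rho(m) + dW(m)) / (N rho(m) + n rho(m)) ]

with rho the target distribution, dW the new sample weight at point m, n the
total new sample weight and N the reference weight-histogram size.  The
expected update vanishes when the sampled marginal equals the target, and the
update magnitude scales as 1/N.  In the initial stage N grows by a constant
factor at each covering event; the final stage grows N by the sample count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .constants import KB
from .dynamics import IntegratorParams, _kernel_args
from .friction import ForceSeries
from .landscape import LandscapeError, ThermoParams, ToyLandscape
from .profiles import PMFProfile

__all__ = [
    "GridSpec",
    "AWHConfig",
    "BiasState",
    "WalkerState",
    "AWHRun",
    "make_target",
    "init_bias",
    "bias_force",
    "mc_resample_reference",
    "update_free_energy",
    "covering_check",
    "advance_stage",
    "run_awh",
    "extract_pmf",
    "vacuum_referenced_pmf",
    "solvation_estimate",
    "symmetrize",
]


@dataclass(frozen=True)
class GridSpec:
    """Sampling grid: n_z spatial bins on [z_min, z_max] x lambda states.

    A grid point is the pair (z-bin, lambda-index); the total point count is
    n_z * lambda_states.  ``n_z == 1`` is the degenerate lambda-only grid used
    for solvation runs; otherwise at least 8 spatial bins are required.
    """

    z_min: float
    z_max: float
    n_z: int
    lambda_states: int = 21

    def __post_init__(self) -> None:
        if self.n_z != 1 and self.n_z < 8:
            raise LandscapeError(f"need >= 8 z bins (or exactly 1), got {self.n_z}")
        if self.lambda_states < 1:
            raise LandscapeError("lambda_states must be >= 1")
        if self.n_z > 1 and not (self.z_max > self.z_min):
            raise LandscapeError("z_max must exceed z_min")

    @property
    def z_centers(self) -> np.ndarray:
        if self.n_z == 1:
            return np.array([0.5 * (self.z_min + self.z_max)])
        return np.linspace(self.z_min, self.z_max, self.n_z)

    @property
    def z_spacing(self) -> float:
        if self.n_z == 1:
            return self.z_max - self.z_min if self.z_max > self.z_min else 1.0
        return (self.z_max - self.z_min) / (self.n_z - 1)

    @property
    def n_points(self) -> int:
        return self.n_z * self.lambda_states


@dataclass(frozen=True)
class AWHConfig:
    """AWH sampler configuration.

    Defaults mirror an all-atom production setup (initial error 10 kJ/mol,
    input diffusion 3e-5 nm^2/ps spatial and 5e-5 ps^-1 alchemical, force
    constant 25,000 kJ/mol/nm^2, 24 walkers, 0.8 nm covering diameter).  For
    the bundled toys the input diffusion constants should be set to the toy's
    actual diffusivity (~kT/(m*gamma)); they only control the initial
    histogram size, never the estimated diffusion profile.
    """

    initial_error: float = 10.0
    input_diffusion_spatial: float = 3e-5
    input_diffusion_lambda: float = 5e-5
    force_constant: float = 25000.0
    mc_interval: int = 10
    samples_per_update: int = 10
    covering_min_diameter: float = 0.8
    covering_requires_full_lambda: bool = True
    n_walkers: int = 24
    symmetrize: bool = False
    target_spec: str | np.ndarray = "end-state-weighted"
    growth_factor: float = 3.0

    def __post_init__(self) -> None:
        for name in ("initial_error", "input_diffusion_spatial", "input_diffusion_lambda",
                     "force_constant", "covering_min_diameter", "growth_factor"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise LandscapeError(f"{name} must be positive, got {v}")
        if self.mc_interval < 1 or self.samples_per_update < 1 or self.n_walkers < 1:
            raise LandscapeError("intervals and walker counts must be >= 1")
        if self.mc_interval not in (10, 100):
            warnings.warn(
                f"non-standard mc_interval {self.mc_interval} (typical values: 10 or 100)",
                stacklevel=2,
            )
        if self.growth_factor <= 1:
            raise LandscapeError("growth_factor must exceed 1")


@dataclass
class BiasState:
    """The shared adaptive bias: free-energy estimate, target and histogram size."""

    grid: GridSpec
    f: np.ndarray  # (n_z, n_lambda) free-energy estimate, kJ/mol
    target: np.ndarray  # (n_z, n_lambda), sums to 1
    hist_size: float  # reference weight-histogram size N
    stage: str = "initial"  # {"initial", "final"}
    visit_weights: np.ndarray | None = None
    covering_count: int = 0
    samples_total: float = 0.0
    kT: float = KB * 305.15

    def __post_init__(self) -> None:
        if self.visit_weights is None:
            self.visit_weights = np.zeros_like(self.f)
        s = float(self.target.sum())
        if abs(s - 1.0) > 1e-10:
            raise LandscapeError(f"target must sum to 1, sums to {s}")
        if not self.hist_size > 0:
            raise LandscapeError("histogram size must be positive")

    @property
    def support(self) -> np.ndarray:
        return self.target > 0


@dataclass(frozen=True)
class WalkerState:
    """One walker: continuous coordinates plus its umbrella reference point."""

    z: float
    theta: float = 0.0
    v_z: float = 0.0
    v_theta: float = 0.0
    lambda_ref: int = 0
    z_ref_index: int = 0
    rng: np.random.Generator | None = None
    visited: np.ndarray | None = None  # (n_z, n_lambda) bool since last covering
    covered_min: float = math.inf
    covered_max: float = -math.inf


# ---------------------------------------------------------------------------
# target distributions and initialization
# ---------------------------------------------------------------------------


def make_target(grid: GridSpec, lambda_weights="end-state-weighted",
                spatial: str = "uniform") -> np.ndarray:
    """Normalized product target: uniform along z times per-lambda weights.

    ``lambda_weights`` may be "uniform", "end-state-weighted" (extra weight on
    the end states, most on the fully interacting one) or an explicit
    non-negative weight per lambda state.
    """
    if spatial != "uniform":
        raise LandscapeError(f"only a uniform spatial target is supported, got {spatial!r}")
    n_l = grid.lambda_states
    if isinstance(lambda_weights, str):
        if lambda_weights == "uniform":
            w = np.ones(n_l)
        elif lambda_weights == "end-state-weighted":
            w = np.ones(n_l)
            if n_l > 1:
                w[0] = 4.0
                w[-1] = 2.0
        else:
            raise LandscapeError(f"unknown lambda weighting {lambda_weights!r}")
    else:
        w = np.asarray(lambda_weights, dtype=float)
        if w.shape != (n_l,):
            raise LandscapeError(f"need {n_l} lambda weights, got shape {w.shape}")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise LandscapeError("lambda weights must be finite and >= 0")
        if w.sum() == 0:
            raise LandscapeError("lambda weights must not all be zero")
    target = np.tile(w / w.sum() / grid.n_z, (grid.n_z, 1))
    return target


def crossing_times(grid: GridSpec, cfg: AWHConfig) -> dict:
    """Expected single-walker crossing times (ps) implied by the input diffusion."""
    out = {}
    if grid.n_z > 1:
        L = grid.z_max - grid.z_min
        out["tau_z_ps"] = L * L / (2.0 * cfg.input_diffusion_spatial)
    if grid.lambda_states > 1:
        out["tau_lambda_ps"] = 1.0 / cfg.input_diffusion_lambda
    return out


def initial_hist_size(grid: GridSpec, cfg: AWHConfig,
                      thermo: ThermoParams | None = None,
                      dt: float = 0.003) -> float:
    """Initial reference histogram size N0.

    N0 = (kT / initial_error)^2 * tau_cross / dt_sample, with tau_cross the
    slower of the expected spatial and alchemical crossing times.  Larger
    initial error or faster input diffusion means a smaller N0, hence larger
    first updates.
    """
    thermo = thermo or ThermoParams()
    taus = crossing_times(grid, cfg)
    dt_sample = cfg.mc_interval * dt
    tau = max(taus.values()) if taus else dt_sample
    n0 = (thermo.kT / cfg.initial_error) ** 2 * tau / dt_sample
    return max(n0, 1.0)


def init_bias(grid: GridSpec, cfg: AWHConfig,
              thermo: ThermoParams | None = None, dt: float = 0.003) -> BiasState:
    """Fresh bias: f = 0 everywhere, N from the initial-error rule, initial stage."""
    thermo = thermo or ThermoParams()
    if grid.n_points < 1:
        raise LandscapeError("degenerate grid")
    target = make_target(grid, cfg.target_spec)
    return BiasState(
        grid=grid,
        f=np.zeros((grid.n_z, grid.lambda_states)),
        target=target,
        hist_size=initial_hist_size(grid, cfg, thermo, dt),
        kT=thermo.kT,
    )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def bias_force(bias: BiasState, walker: WalkerState, cfg: AWHConfig) -> float:
    """Harmonic umbrella force on z: -k (z - z_ref), kJ/mol/nm."""
    z_ref = float(bias.grid.z_centers[walker.z_ref_index])
    return -cfg.force_constant * (walker.z - z_ref)


def _gibbs_log_weights(walker, bias, land, cfg, thermo):
    grid = bias.grid
    beta = thermo.beta
    zc = grid.z_centers
    lam_values = (land.schedule.values if grid.lambda_states > 1 else np.zeros(1))
    sigma = math.sqrt(thermo.kT / cfg.force_constant)
    if grid.n_z > 1:
        win = max(1, int(math.ceil(4.0 * sigma / grid.z_spacing)))
        near = int(round((walker.z - zc[0]) / grid.z_spacing))
        lo = max(0, near - win)
        hi = min(grid.n_z - 1, near + win)
    else:
        lo = hi = 0
    from .landscape import potential

    u_l = np.array([
        float(potential(land, walker.z, walker.theta, il)) for il in range(len(lam_values))
    ])
    with np.errstate(divide="ignore"):
        logt = np.where(bias.target > 0, np.log(np.maximum(bias.target, 1e-300)), -1e300)
    du = 0.5 * cfg.force_constant * (walker.z - zc[lo:hi + 1, None]) ** 2
    logw = logt[lo:hi + 1] + beta * bias.f[lo:hi + 1] - beta * (du + u_l[None, :])
    return lo, hi, logw


def mc_resample_reference(walker: WalkerState, bias: BiasState, land: ToyLandscape,
                          cfg: AWHConfig, rng: np.random.Generator,
                          thermo: ThermoParams | None = None) -> WalkerState:
    """Gibbs move of the walker's reference point (z-bin, lambda-index).

    The stationary weight of candidate point m is
    target(m) * exp(beta f(m)) * exp(-beta [k/2 (z - z_m)^2 + U(z, theta, lam_m)]);
    an accepted lambda move switches the walker's governing Hamiltonian.
    """
    thermo = thermo or ThermoParams()
    lo, hi, logw = _gibbs_log_weights(walker, bias, land, cfg, thermo)
    mx = logw.max()
    if not np.isfinite(mx):
        raise RuntimeError(
            "all Gibbs weights vanished; grid points "
            f"z-bins [{lo},{hi}] at z={walker.z:.4f}"
        )
    w = np.exp(logw - mx)
    w = w / w.sum()
    flat = rng.choice(w.size, p=w.ravel())
    iz, il = divmod(flat, w.shape[1])
    return replace(walker, z_ref_index=lo + int(iz), lambda_ref=int(il))


def update_free_energy(bias: BiasState, sample_batch: np.ndarray,
                       cfg: AWHConfig | None = None) -> BiasState:
    """Apply one weighted-histogram update of f from a batch of point weights.

    ``sample_batch``: array (n_samples, n_z, n_lambda) of per-sample weight
    vectors (each summing to ~1), or a pre-summed (n_z, n_lambda) accumulation.
    Mutates and returns ``bias``.
    """
    batch = np.asarray(sample_batch, dtype=float)
    if np.any(~np.isfinite(batch)):
        raise FloatingPointError("NaN/inf in sample weights")
    dW = batch.sum(axis=0) if batch.ndim == 3 else batch
    if cfg is not None and batch.ndim == 3 and batch.shape[0] != cfg.samples_per_update:
        raise LandscapeError(
            f"batch size {batch.shape[0]} != samples_per_update {cfg.samples_per_update}"
        )
    n_tot = float(dW.sum())
    sup = bias.support
    N = bias.hist_size
    rho = bias.target
    with np.errstate(divide="ignore", invalid="ignore"):
        upd = np.log((N * rho + dW) / (N * rho + n_tot * rho))
    bias.f[sup] -= bias.kT * upd[sup]
    bias.f[sup] -= bias.f[sup].min()  # anchor: min over target support is 0
    bias.visit_weights += dW
    bias.samples_total += n_tot
    if bias.stage == "final":
        bias.hist_size += n_tot
    return bias


def covering_check(bias: BiasState, walkers, cfg: AWHConfig) -> bool:
    """True iff qualifying walkers jointly visited every target-supported point.

    A walker qualifies only if, since the last covering, it individually
    visited every supported lambda state (when the flag is on) and spanned a
    spatial diameter of at least ``covering_min_diameter``.
    """
    sup = bias.support
    lam_sup = sup.any(axis=0)
    union = np.zeros_like(sup, dtype=bool)
    spatial_matters = bias.grid.n_z > 1
    for w in walkers:
        visited = w.visited if isinstance(w, WalkerState) else w
        if visited is None:
            continue
        if cfg.covering_requires_full_lambda:
            if not np.all(visited.any(axis=0)[lam_sup]):
                continue
        if spatial_matters and isinstance(w, WalkerState):
            if not (w.covered_max - w.covered_min >= cfg.covering_min_diameter):
                continue
        union |= visited
    return bool(np.all(union[sup]))


def advance_stage(bias: BiasState, covered: bool, cfg: AWHConfig) -> BiasState:
    """Grow the histogram at covering events; exit to the final stage when the
    covering-grown N overtakes the accumulated sample weight."""
    if bias.stage != "initial":
        return bias
    if covered:
        bias.covering_count += 1
        bias.hist_size *= cfg.growth_factor
        if bias.hist_size >= bias.samples_total:
            bias.stage = "final"
    return bias


# ---------------------------------------------------------------------------
# the multi-walker driver
# ---------------------------------------------------------------------------


@dataclass
class AWHRun:
    """Result of an AWH run: bias, per-walker force series and trajectories."""

    bias: BiasState
    force_series: list
    z_traj: np.ndarray  # (n_rounds, n_walkers): walker z at each sample
    lambda_traj: np.ndarray  # (n_rounds, n_walkers): reference lambda index
    metadata: dict
    friction_sums: tuple | None = None  # blocked (S, T) friction accumulators


def run_awh(
    land: ToyLandscape,
    grid: GridSpec,
    cfg: AWHConfig,
    n_steps_per_walker: int,
    seeds,
    thermo: ThermoParams | None = None,
    integrator: IntegratorParams | None = None,
    freeze_bias: bool = False,
    bias: BiasState | None = None,
    friction_blocks: int = 128,
    friction_lambda_index: int | None = 0,
) -> AWHRun:
    """Run communicating AWH walkers and return the shared bias plus series.

    ``seeds`` is one integer per walker (must be distinct): each walker owns a
    counter-based stream keyed by its own seed, so walker i's noise does not
    depend on how many other walkers run.  Fully reproducible.
    """
    thermo = thermo or ThermoParams()
    integrator = integrator or IntegratorParams()
    seeds = [int(s) for s in seeds]
    if len(set(seeds)) != len(seeds):
        raise LandscapeError(f"walker seeds must be distinct, got {seeds}")
    n_w = len(seeds)
    if grid.lambda_states > 1 and grid.lambda_states != land.schedule.n_states:
        raise LandscapeError(
            f"grid has {grid.lambda_states} lambda states but the landscape "
            f"schedule has {land.schedule.n_states}"
        )
    lam_values = land.schedule.values if grid.lambda_states > 1 else np.zeros(1)
    if bias is None:
        bias = init_bias(grid, cfg, thermo, integrator.dt)
    kT = thermo.kT

    gens = [np.random.default_rng(np.random.SeedSequence(s)) for s in seeds]
    zc = grid.z_centers
    n_z, n_l = grid.n_z, grid.lambda_states

    # walker state arrays
    z = np.empty(n_w)
    vz = np.zeros(n_w)
    th = np.empty(n_w)
    vth = np.zeros(n_w)
    lam_idx = np.full(n_w, n_l - 1, dtype=np.int64)  # start fully decoupled
    ref_iz = np.empty(n_w, dtype=np.int64)
    for w, g in enumerate(gens):
        z[w] = g.uniform(grid.z_min, grid.z_max) if n_z > 1 else zc[0]
        th[w] = g.uniform(-math.pi, math.pi)
        ref_iz[w] = int(np.argmin(np.abs(zc - z[w])))
    ka = _kernel_args(land)
    fcz = np.zeros(n_w)
    fct = np.zeros(n_w)
    for w in range(n_w):
        _, fz0, ft0 = _kernels.potential_and_forces(
            z[w], th[w], float(lam_values[lam_idx[w]]), ka["alpha"], ka["eps_sc"],
            ka["featc"], ka["feath"], ka["featw"], ka["theta_b"], ka["trapc"],
            ka["trapw"], ka["trapd"], ka["trapph"], ka["theta_k"], ka["solvent_level"])
        fcz[w] = fz0
        fct[w] = ft0

    sigma = math.sqrt(kT / cfg.force_constant)
    win_bins = max(1, int(math.ceil(4.0 * sigma / grid.z_spacing))) if n_z > 1 else 0
    with np.errstate(divide="ignore"):
        logtarget = np.where(bias.target > 0, np.log(np.maximum(bias.target, 1e-300)), -1e300)

    n_rounds = n_steps_per_walker // cfg.mc_interval
    rounds_per_update = cfg.samples_per_update
    n_updates = n_rounds // rounds_per_update
    dW = np.zeros((n_z, n_l))
    visited = np.zeros((n_w, n_z, n_l), dtype=np.bool_)
    wmin = zc[ref_iz].astype(float).copy()
    wmax = zc[ref_iz].astype(float).copy()

    force_out = np.empty((n_updates * rounds_per_update, n_w))
    bin_out = np.empty_like(force_out, dtype=np.int64)
    lam_out = np.empty_like(bin_out)
    z_out = np.empty_like(force_out)

    n_rounds_total = n_updates * rounds_per_update
    n_blocks = max(1, min(friction_blocks, n_rounds_total))
    rounds_per_block = int(math.ceil(n_rounds_total / n_blocks))
    lam_cond = -1 if friction_lambda_index is None else int(friction_lambda_index)
    if lam_cond >= 0 and n_l == 1:
        lam_cond = 0
    fr_S = np.zeros((n_blocks, n_w, n_z))
    fr_T = np.zeros_like(fr_S)
    fr_Q = np.zeros_like(fr_S)

    n_history = [(0, bias.hist_size)]
    covering_rounds: list[int] = []
    stage_exit_round = None

    for u in range(n_updates):
        r0 = u * rounds_per_update
        r1 = r0 + rounds_per_update
        steps = rounds_per_update * cfg.mc_interval
        normals = np.empty((steps, n_w, 2))
        u_mc = np.empty((rounds_per_update, n_w))
        for w, g in enumerate(gens):
            normals[:, w, :] = g.standard_normal((steps, 2))
            u_mc[:, w] = g.random(rounds_per_update)
        status, bad = _kernels.awh_rounds(
            rounds_per_update, cfg.mc_interval,
            z, vz, th, vth, lam_idx, ref_iz, fcz, fct,
            ka["featc"], ka["feath"], ka["featw"], ka["theta_b"], ka["trapc"],
            ka["trapw"], ka["trapd"], ka["trapph"], ka["theta_k"], ka["solvent_level"],
            ka["alpha"], ka["eps_sc"],
            lam_values, zc, ka["L"], ka["reflect"],
            integrator.dt, integrator.friction, integrator.mass, kT,
            cfg.force_constant, win_bins,
            bias.f, logtarget, dW, visited, wmin, wmax,
            normals, u_mc,
            force_out[r0:r1], bin_out[r0:r1], lam_out[r0:r1], z_out[r0:r1],
            fr_S, fr_T, fr_Q, rounds_per_block, r0, lam_cond,
        )
        if status == 1:
            raise FloatingPointError(f"force overflow: walker {bad} diverged (update {u})")
        if status == 2:
            raise RuntimeError(
                f"all Gibbs weights vanished for walker {bad} at update {u}; "
                f"bias range [{bias.f.min():.3g}, {bias.f.max():.3g}] kJ/mol"
            )
        if cfg.symmetrize and n_z > 1:
            dW = 0.5 * (dW + dW[::-1, :])
        if not freeze_bias:
            update_free_energy(bias, dW)
            if bias.stage == "initial":
                covered = _covering_from_arrays(bias, visited, wmin, wmax, cfg)
                if covered:
                    covering_rounds.append(r1)
                    advance_stage(bias, True, cfg)
                    n_history.append((r1, bias.hist_size))
                    visited[:] = False
                    wmin[:] = zc[ref_iz]
                    wmax[:] = zc[ref_iz]
                    for w in range(n_w):
                        visited[w, ref_iz[w], lam_idx[w]] = True
                    if bias.stage == "final" and stage_exit_round is None:
                        stage_exit_round = r1
        else:
            bias.visit_weights += dW
            bias.samples_total += float(dW.sum())
        dW[:] = 0.0

    series = []
    t = (np.arange(n_updates * rounds_per_update) + 1) * cfg.mc_interval * integrator.dt
    for w in range(n_w):
        series.append(ForceSeries(
            time=t.copy(), force=force_out[:, w].copy(),
            z_bin=bin_out[:, w].copy(), lambda_index=lam_out[:, w].copy(),
        ))

    meta = {
        "seeds": seeds,
        "n_walkers": n_w,
        "n_steps_per_walker": n_steps_per_walker,
        "n_updates": n_updates,
        "initial_hist_size": n_history[0][1],
        "n_history": n_history,
        "covering_rounds": covering_rounds,
        "covering_count": bias.covering_count,
        "stage": bias.stage,
        "stage_exit_round": stage_exit_round,
        "symmetrized": bool(cfg.symmetrize and n_z > 1),
        "friction_blocks": n_blocks,
        "friction_lambda_index": None if lam_cond < 0 else lam_cond,
        **crossing_times(grid, cfg),
    }
    return AWHRun(bias=bias, force_series=series, z_traj=z_out,
                  lambda_traj=lam_out, metadata=meta,
                  friction_sums=(fr_S, fr_T, fr_Q))


def _covering_from_arrays(bias, visited, wmin, wmax, cfg) -> bool:
    sup = bias.support
    lam_sup = sup.any(axis=0)
    union = np.zeros_like(sup, dtype=bool)
    spatial_matters = bias.grid.n_z > 1
    for w in range(visited.shape[0]):
        if cfg.covering_requires_full_lambda and not np.all(
            visited[w].any(axis=0)[lam_sup]
        ):
            continue
        if spatial_matters and not (wmax[w] - wmin[w] >= cfg.covering_min_diameter):
            continue
        union |= visited[w]
    return bool(np.all(union[sup]))


# ---------------------------------------------------------------------------
# extraction and post-processing
# ---------------------------------------------------------------------------


def extract_pmf(bias: BiasState, lam_index: int, anchor: str = "min") -> PMFProfile:
    """1D slice of f along z at one lambda state.

    The lambda=0 slice is "the PMF".  Warns when the bias never left the
    initial stage (the estimate may be far from converged).
    """
    grid = bias.grid
    if not (0 <= lam_index < grid.lambda_states):
        raise IndexError(f"lambda index {lam_index} not on the grid")
    if bias.stage == "initial":
        warnings.warn("bias is still in the AWH initial stage; PMF may be unconverged",
                      stacklevel=2)
    dG = bias.f[:, lam_index].copy()
    tag = "uncalibrated"
    if grid.lambda_states > 1:
        # express relative to the flat decoupled state (the vacuum reference)
        dG -= float(np.mean(bias.f[:, -1]))
        tag = "vacuum"
    if anchor == "min":
        # min-anchoring discards the vacuum offset
        dG -= dG.min()
        tag = "uncalibrated"
    elif anchor != "none":
        raise ValueError(f"unknown anchor {anchor!r}")
    return PMFProfile(z=grid.z_centers.copy(), dG=dG, reference_tag=tag)


def vacuum_referenced_pmf(bias: BiasState) -> PMFProfile:
    """The fully coupled PMF measured relative to the decoupled (vacuum) state."""
    if bias.grid.lambda_states < 2:
        raise LandscapeError("vacuum referencing needs an alchemical dimension")
    return extract_pmf(bias, 0, anchor="none")


def solvation_estimate(bias: BiasState, land: ToyLandscape) -> float:
    """Solvation free energy (coupled minus vacuum) from the lambda dimension.

    Averaged over the solvent-plateau bins: dG_solv = <f(z,0) - f(z,last)>_solv.
    """
    if bias.grid.lambda_states < 2:
        raise LandscapeError("solvation estimate needs an alchemical dimension")
    if bias.grid.n_z == 1:
        return float(bias.f[0, 0] - bias.f[0, -1])
    mask = land.solvent_mask(bias.grid.z_centers)
    if not mask.any():
        raise LandscapeError("no solvent-plateau bins on the grid")
    diff = bias.f[:, 0] - bias.f[:, -1]
    return float(np.mean(diff[mask]))


def symmetrize(pmf: PMFProfile, mode: str = "mirror-about-center") -> PMFProfile:
    """Mirror a PMF about the center of its grid, averaging paired free energies.

    Idempotent; requires a grid symmetric about its midpoint.
    """
    if mode != "mirror-about-center":
        raise ValueError(f"unknown symmetrization mode {mode!r}")
    z = pmf.z
    c = 0.5 * (z[0] + z[-1])
    if np.max(np.abs((z - c) + (z[::-1] - c))) > 1e-9:
        raise LandscapeError("grid is not symmetric about its center")
    dG = 0.5 * (pmf.dG + pmf.dG[::-1])
    se = None
    if pmf.se is not None:
        se = 0.5 * np.sqrt(pmf.se**2 + pmf.se[::-1] ** 2)
    return replace(pmf, dG=dG, se=se)
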