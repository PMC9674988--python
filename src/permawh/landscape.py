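"""Synthetic lambda-coupled free-energy landscapes.

These model systems stand in for an all-atom lamellar barrier: a periodic or
reflective "membrane" profile along z built from Gaussian barriers and wells
on top of a solvent plateau, an alchemical coupling axis lambda on which the
fully decoupled end state is exactly environment-independent, and an optional
slow orthogonal (orientation) degree of freedom theta whose trapping emulates
gel-phase behaviour.

The coupled permeant-environment interaction is split into a barrier-type
(repulsive, non-negative) part P and a well/plateau-type part A.  P is
coupled through an energy-space soft-core transformation derived exactly from
a Beutler-style inverse-12th-power model pair term,

    S(P, lam) = (1 - lam) * P / (1 + alpha*lam*sqrt(P/eps_sc))**2,

which reduces to P at lam=0, vanishes at lam=1 and is capped at
(1-lam)*eps_sc/(alpha*lam)**2 for arbitrarily large P.  A scales linearly
with (1 - lam).  The total potential is therefore identically zero (constant
in z and theta) at the fully decoupled state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB

__all__ = [
    "ThermoParams",
    "SoftCoreParams",
    "LambdaSchedule",
    "GaussianFeature",
    "TrapSpec",
    "ToyLandscape",
    "LandscapeError",
    "build_landscape",
    "potential",
    "forces",
    "reference_pmf",
    "reference_solvation",
    "default_membrane_spec",
    "gel_membrane_spec",
    "two_state_spec",
    "slow_mode_spec",
    "flat_spec",
    "solvent_box_spec",
]

#: reference sigma (nm) at which the soft-core energy scale equals eps0
_SIGMA0 = 0.3
#: reference soft-core energy scale in kJ/mol (about k_B T at 305 K)
_EPS0 = 2.5

MAX_FEATURE_HEIGHT = 200.0  # kJ/mol


class LandscapeError(ValueError):
    """Invalid landscape specification."""


@dataclass(frozen=True)
class ThermoParams:
    """Temperature and the derived inverse energy beta = 1/(k_B T)."""

    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise LandscapeError(f"temperature must be positive, got {self.temperature}")

    @property
    def kT(self) -> float:
        return KB * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.kT


@dataclass(frozen=True)
class SoftCoreParams:
    """Soft-core transformation parameters (alpha dimensionless, sigma in nm)."""

    alpha: float = 0.5
    sigma: float = 0.3

    def __post_init__(self) -> None:
        if not (self.alpha >= 0 and math.isfinite(self.alpha)):
            raise LandscapeError(f"soft-core alpha must be >= 0, got {self.alpha}")
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise LandscapeError(f"soft-core sigma must be > 0, got {self.sigma}")

    @property
    def eps_sc(self) -> float:
        """Energy scale of the soft-core cap, kJ/mol.

        Derived from the model pair term: a larger sigma softens the
        interaction more (lower cap), as in the distance-space transformation.
        """
        return _EPS0 * (_SIGMA0 / self.sigma) ** 6


@dataclass(frozen=True)
class LambdaSchedule:
    """Equidistant alchemical states; index 0 fully coupled, last fully decoupled."""

    n_states: int = 21

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise LandscapeError(f"n_states must be >= 1, got {self.n_states}")

    @property
    def values(self) -> np.ndarray:
        if self.n_states == 1:
            return np.zeros(1)
        return np.linspace(0.0, 1.0, self.n_states)

    coupling_mode: str = "simultaneous"


@dataclass(frozen=True)
class GaussianFeature:
    """One Gaussian barrier (height > 0) or well (height < 0) along z."""

    center: float
    height: float
    width: float

    def __post_init__(self) -> None:
        for name, v in (("center", self.center), ("height", self.height), ("width", self.width)):
            if not math.isfinite(v):
                raise LandscapeError(f"non-finite feature {name}: {v}")
        if abs(self.height) > MAX_FEATURE_HEIGHT:
            raise LandscapeError(
                f"feature height {self.height} exceeds +-{MAX_FEATURE_HEIGHT} kJ/mol"
            )
        if self.width <= 0:
            raise LandscapeError(f"feature width must be > 0, got {self.width}")


@dataclass(frozen=True)
class TrapSpec:
    """One slow orientation trap: inside a Gaussian envelope along z the
    orientation well ``-depth * (1 + cos(theta - phase))/2`` favours
    theta = phase (different z regions may favour different orientations).
    The landscape-wide orientation barrier that makes flips slow lives on
    :class:`ToyLandscape` (``theta_barrier``); all orientation terms scale
    away with decoupling, so orientation relaxes instantly at the decoupled
    end state — the alchemical shortcut a 2D sampler exploits."""

    center: float
    width: float
    depth: float = 10.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise LandscapeError("trap width must be > 0")
        if self.depth < 0:
            raise LandscapeError("trap depth must be >= 0")
        if self.depth > MAX_FEATURE_HEIGHT:
            raise LandscapeError("trap energies exceed the allowed range")


@dataclass(frozen=True)
class ToyLandscape:
    """A lambda-coupled toy membrane landscape on z in [0, L]."""

    length: float = 5.21
    solvent_level: float = -5.0
    barriers: tuple[GaussianFeature, ...] = ()
    wells: tuple[GaussianFeature, ...] = ()
    traps: tuple[TrapSpec, ...] = ()
    theta_barrier: float = 0.0  # global orientation-flip barrier, kJ/mol
    theta_k: float = 0.0  # optional harmonic theta coupling, kJ/mol/rad^2
    softcore: SoftCoreParams = field(default_factory=SoftCoreParams)
    schedule: LambdaSchedule = field(default_factory=LambdaSchedule)
    boundary: str = "reflective"  # or "periodic"
    solvent_region: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.length > 0 and math.isfinite(self.length)):
            raise LandscapeError(f"length must be positive, got {self.length}")
        if not math.isfinite(self.solvent_level):
            raise LandscapeError("solvent_level must be finite")
        if self.boundary not in ("reflective", "periodic"):
            raise LandscapeError(f"unknown boundary convention {self.boundary!r}")
        if self.theta_k < 0 or self.theta_barrier < 0:
            raise LandscapeError("theta_k and theta_barrier must be >= 0")
        if self.theta_barrier > MAX_FEATURE_HEIGHT:
            raise LandscapeError("theta_barrier exceeds the allowed range")

    # --- geometry -----------------------------------------------------

    def map_z(self, z):
        """Map arbitrary z onto [0, L] by the configured boundary convention."""
        z = np.asarray(z, dtype=float)
        L = self.length
        if self.boundary == "periodic":
            out = np.mod(z, L)
        else:  # reflective: triangle-wave fold
            out = np.abs(np.mod(z, 2.0 * L))
            out = np.where(out > L, 2.0 * L - out, out)
        return out if out.ndim else float(out)

    def feature_arrays(self):
        """(centers, signed heights, widths) of all z features, for kernels."""
        feats = list(self.barriers) + list(self.wells)
        c = np.array([f.center for f in feats], dtype=float)
        h = np.array([f.height for f in feats], dtype=float)
        w = np.array([f.width for f in feats], dtype=float)
        return c, h, w

    # --- energies -----------------------------------------------------

    def membrane_profile(self, z):
        """G_mem(z): the fully coupled z-only profile (no theta terms)."""
        z = self.map_z(np.asarray(z, dtype=float))
        g = np.full_like(z, self.solvent_level, dtype=float)
        for f in list(self.barriers) + list(self.wells):
            g = g + f.height * np.exp(-((z - f.center) ** 2) / (2.0 * f.width**2))
        return g

    def trap_envelope(self, z, i: int = 0):
        if not self.traps:
            return np.zeros_like(np.asarray(z, dtype=float))
        z = self.map_z(np.asarray(z, dtype=float))
        t = self.traps[i]
        return np.exp(-((z - t.center) ** 2) / (2.0 * t.width**2))

    def interaction_parts(self, z, theta):
        """Split the fully coupled interaction into (P, A).

        P: barrier-type terms (non-negative), soft-core coupled.
        A: well/plateau-type terms, linearly coupled.
        """
        z = np.asarray(z, dtype=float)
        theta = np.asarray(theta, dtype=float)
        P = np.zeros(np.broadcast_shapes(z.shape, theta.shape))
        A = np.full_like(P, self.solvent_level)
        zm = self.map_z(z)
        for f in self.barriers:
            P = P + f.height * np.exp(-((zm - f.center) ** 2) / (2.0 * f.width**2))
        for f in self.wells:
            A = A + f.height * np.exp(-((zm - f.center) ** 2) / (2.0 * f.width**2))
        if self.theta_barrier > 0:
            P = P + self.theta_barrier * np.sin(theta) ** 2
        for i, t in enumerate(self.traps):
            env = self.trap_envelope(zm, i)
            A = A - env * t.depth * 0.5 * (1.0 + np.cos(theta - t.phase))
        if self.theta_k > 0:
            A = A + 0.5 * self.theta_k * theta**2
        return P, A

    def softcore_couple(self, P, lam_value):
        """Apply the energy-space soft-core transformation to P >= 0."""
        a = self.softcore.alpha * lam_value
        eps = self.softcore.eps_sc
        q = 1.0 + a * np.sqrt(np.maximum(P, 0.0) / eps)
        return (1.0 - lam_value) * P / q**2

    def solvent_mask(self, z, tol: float = 1e-3):
        """Boolean mask of grid points lying on the solvent plateau."""
        z = np.asarray(z, dtype=float)
        if self.solvent_region is not None:
            lo, hi = self.solvent_region
            return (z >= lo) & (z <= hi)
        dev = np.abs(self.membrane_profile(z) - self.solvent_level)
        for i, t in enumerate(self.traps):
            dev = dev + np.abs(self.trap_envelope(z, i)) * t.depth
        return dev < tol

    def solvent_z(self) -> float:
        """A representative solvent-plateau position."""
        zg = np.linspace(0.0, self.length, 2049)
        mask = self.solvent_mask(zg)
        if not mask.any():
            raise LandscapeError("landscape has no solvent plateau region")
        # middle of the largest solvent stretch
        idx = np.flatnonzero(mask)
        return float(zg[idx[len(idx) // 2]])


def build_landscape(spec: dict) -> ToyLandscape:
    """Build a :class:`ToyLandscape` from a plain config mapping.

    Recognised keys: ``length``, ``solvent_level``, ``boundary``,
    ``barriers``/``wells`` (lists of {center, height|depth, width}),
    ``trap`` ({center, width, depth, barrier}), ``theta_k``,
    ``schedule`` ({n_states}), ``softcore`` ({alpha, sigma}),
    ``solvent_region`` ([lo, hi]).
    """
    spec = dict(spec)
    barriers = []
    for b in spec.get("barriers", []) or []:
        h = float(b["height"])
        if h < 0:
            raise LandscapeError("barrier heights must be >= 0; use wells for minima")
        barriers.append(GaussianFeature(float(b["center"]), h, float(b["width"])))
    wells = []
    for w in spec.get("wells", []) or []:
        if "depth" in w:
            h = -abs(float(w["depth"]))
        else:
            h = float(w["height"])
            if h > 0:
                raise LandscapeError("well heights must be <= 0")
        wells.append(GaussianFeature(float(w["center"]), h, float(w["width"])))
    traps = []
    theta_barrier = float(spec.get("theta_barrier", 0.0))
    trap_specs = list(spec.get("traps", []) or [])
    if spec.get("trap"):  # single-trap shorthand; may carry the global barrier
        t = dict(spec["trap"])
        theta_barrier = float(t.pop("barrier", theta_barrier or 12.0))
        trap_specs.append(t)
    for t in trap_specs:
        traps.append(TrapSpec(
            center=float(t["center"]),
            width=float(t["width"]),
            depth=float(t.get("depth", 10.0)),
            phase=float(t.get("phase", 0.0)),
        ))
    sc = spec.get("softcore", {}) or {}
    sched = spec.get("schedule", {}) or {}
    region = spec.get("solvent_region")
    land = ToyLandscape(
        length=float(spec.get("length", 5.21)),
        solvent_level=float(spec.get("solvent_level", -5.0)),
        barriers=tuple(barriers),
        wells=tuple(wells),
        traps=tuple(traps),
        theta_barrier=theta_barrier,
        theta_k=float(spec.get("theta_k", 0.0)),
        softcore=SoftCoreParams(
            alpha=float(sc.get("alpha", 0.5)), sigma=float(sc.get("sigma", 0.3))
        ),
        schedule=LambdaSchedule(n_states=int(sched.get("n_states", 21))),
        boundary=str(spec.get("boundary", "reflective")),
        solvent_region=tuple(float(x) for x in region) if region else None,
    )
    _warn_if_ill_conditioned(land)
    return land


def _warn_if_ill_conditioned(land: ToyLandscape) -> None:
    feats = list(land.barriers) + list(land.wells)
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            sep = abs(feats[i].center - feats[j].center)
            if sep < 0.1 * min(feats[i].width, feats[j].width):
                warnings.warn(
                    "nearly coincident Gaussian features at "
                    f"z={feats[i].center:.3f} and z={feats[j].center:.3f}; "
                    "the landscape may be ill-conditioned",
                    stacklevel=3,
                )


def _lambda_value(land: ToyLandscape, lam_index: int) -> float:
    vals = land.schedule.values
    if not (0 <= lam_index < len(vals)):
        raise IndexError(
            f"lambda index {lam_index} outside schedule with {len(vals)} states"
        )
    return float(vals[lam_index])


def potential(land: ToyLandscape, z, theta, lam_index: int):
    """Total potential U(z, theta, lambda) in kJ/mol.

    ``z`` outside [0, L] is mapped by the landscape's boundary convention.
    """
    lam = _lambda_value(land, lam_index)
    P, A = land.interaction_parts(z, theta)
    return land.softcore_couple(P, lam) + (1.0 - lam) * A


def forces(land: ToyLandscape, z, theta, lam_index: int, h: float = 1e-6):
    """(-dU/dz, -dU/dtheta) by symmetric differences (reference implementation).

    The jitted simulation kernels use analytic derivatives; this helper backs
    the single-step integrator API and consistency tests.
    """
    fz = -(potential(land, z + h, theta, lam_index) - potential(land, z - h, theta, lam_index)) / (
        2 * h
    )
    ft = -(potential(land, z, theta + h, lam_index) - potential(land, z, theta - h, lam_index)) / (
        2 * h
    )
    return fz, ft


# ---------------------------------------------------------------------------
# analytic references (quadrature oracles)
# ---------------------------------------------------------------------------


def _theta_weights(n_theta: int):
    th = np.linspace(-np.pi, np.pi, n_theta, endpoint=False)
    w = np.full(n_theta, 2.0 * np.pi / n_theta)
    return th, w


def reference_pmf(
    land: ToyLandscape,
    lam_index: int,
    grid,
    thermo: ThermoParams | None = None,
    umbrella_k: float | None = None,
    n_theta: int = 256,
    anchor: str = "solvent",
    rtol: float = 1e-8,
):
    """PMF along z at a fixed lambda state by direct quadrature over theta.

    With ``umbrella_k`` set, returns the free energy of the harmonically
    restrained reference states F(m) = -kT ln Int exp(-beta(U + k/2 (z-z_m)^2)),
    which is what an umbrella-based sampler estimates; as k -> inf this tends
    to the point PMF.  Quadrature resolution is doubled until the result is
    converged to ``rtol`` (relative to kT); non-convergence raises with a
    tolerance report.
    """
    thermo = thermo or ThermoParams()
    grid = np.asarray(grid, dtype=float)
    prev = None
    for n in (n_theta, 2 * n_theta, 4 * n_theta, 8 * n_theta):
        cur = _reference_pmf_once(land, lam_index, grid, thermo, umbrella_k, n)
        if prev is not None:
            err = float(np.max(np.abs(cur - prev))) / thermo.kT
            if err < rtol:
                break
        prev = cur
    else:
        raise RuntimeError(
            f"theta quadrature did not converge: last change {err:.3e} kT > rtol {rtol:.1e}"
        )
    pmf = cur
    if anchor == "solvent":
        mask = land.solvent_mask(grid)
        if not mask.any():
            raise LandscapeError("cannot anchor at solvent plateau: none found on grid")
        pmf = pmf - float(np.mean(pmf[mask]))
    elif anchor == "min":
        pmf = pmf - float(np.min(pmf))
    elif anchor != "none":
        raise ValueError(f"unknown anchor rule {anchor!r}")
    return pmf


def _reference_pmf_once(land, lam_index, grid, thermo, umbrella_k, n_theta):
    beta = thermo.beta
    th, wth = _theta_weights(n_theta)
    if umbrella_k is None:
        U = potential(land, grid[:, None], th[None, :], lam_index)
        # log-sum-exp over theta
        m = U.min(axis=1, keepdims=True)
        q = np.sum(np.exp(-beta * (U - m)) * wth[None, :], axis=1)
        return (m[:, 0] - np.log(q) / beta)
    # restrained reference states: additionally integrate over z
    sigma = math.sqrt(thermo.kT / umbrella_k)
    out = np.empty(len(grid))
    for i, zc in enumerate(grid):
        # truncate to the box: reflective walls restrict the configurational
        # integral to [0, L], which matters for the outermost reference points
        lo = max(0.0, zc - 5 * sigma) if land.boundary == "reflective" else zc - 5 * sigma
        hi = min(land.length, zc + 5 * sigma) if land.boundary == "reflective" else zc + 5 * sigma
        zfine = np.linspace(lo, hi, 81)
        U = potential(land, zfine[:, None], th[None, :], lam_index)
        U = U + 0.5 * umbrella_k * (zfine[:, None] - zc) ** 2
        m = U.min()
        q = np.sum(np.exp(-beta * (U - m)) * wth[None, :]) * (zfine[1] - zfine[0])
        out[i] = m - math.log(q) / beta
    return out


def reference_solvation(
    land: ToyLandscape,
    thermo: ThermoParams | None = None,
    n_theta: int = 4096,
) -> float:
    """Solvation free energy of coupling the permeant in the solvent region.

    Computed as a direct partition-function ratio at a solvent-plateau
    position: dG_solv = -kT ln[ Q(lambda=0) / Q(decoupled) ], quadrature over
    theta.  Negative for a favourable solvent.
    """
    thermo = thermo or ThermoParams()
    beta = thermo.beta
    z0 = land.solvent_z()
    th, wth = _theta_weights(n_theta)
    U0 = potential(land, np.full_like(th, z0), th, 0)
    U1 = potential(land, np.full_like(th, z0), th, land.schedule.n_states - 1)
    m0, m1 = U0.min(), U1.min()
    q0 = np.sum(np.exp(-beta * (U0 - m0)) * wth)
    q1 = np.sum(np.exp(-beta * (U1 - m1)) * wth)
    return float((m0 - m1) - math.log(q0 / q1) / beta)


# ---------------------------------------------------------------------------
# bundled landscape specs
# ---------------------------------------------------------------------------


def default_membrane_spec() -> dict:
    """Default half-period membrane: two barriers and one trap well.

    Echoes the qualitative shape of a lamellar skin-barrier PMF: the main
    packing barrier in the chain region (~2.1 nm), a secondary head-group
    barrier (~3.2 nm), a trapping well near the chain ends (~0.8 nm), and a
    solvent plateau towards 5.21 nm.
    """
    return {
        "length": 5.21,
        "solvent_level": -5.0,
        "boundary": "reflective",
        "barriers": [
            {"center": 2.1, "height": 25.0, "width": 0.35},
            {"center": 3.2, "height": 15.0, "width": 0.30},
        ],
        "wells": [{"center": 0.8, "depth": 10.0, "width": 0.35}],
        "solvent_region": [4.4, 5.21],
        "schedule": {"n_states": 21},
        "softcore": {"alpha": 0.5, "sigma": 0.3},
    }


def gel_membrane_spec(n_lambda: int = 7) -> dict:
    """Membrane with slow orientation traps (gel-phase analog).

    A global orientation barrier makes flips at full coupling much slower
    than spatial diffusion (and instantaneous at full decoupling), and two
    enveloped wells favour opposite orientations in different regions — the
    chain-end region binds one orientation, the head-group region the
    other — so a sampler that cannot reorient mis-estimates part of the
    landscape whichever orientation it is stuck in.
    """
    spec = default_membrane_spec()
    spec["theta_barrier"] = 12.0
    spec["traps"] = [
        {"center": 0.8, "width": 0.5, "depth": 10.0, "phase": 0.0},
        {"center": 3.0, "width": 0.4, "depth": 8.0, "phase": 3.141592653589793},
    ]
    spec["schedule"] = {"n_states": n_lambda}
    return spec


def slow_mode_spec() -> dict:
    """Two overlapping opposite-phase orientation traps on a short box.

    Whichever orientation the permeant is stuck in, one of the wells is
    active, so the region between the trap centers stays populated while the
    mean force inside it flips sign with the slow orientation variable.  The
    bin-conditioned force autocovariance therefore has a genuinely slow
    component: friction estimates keep growing (diffusion keeps dropping) as
    the simulation, and with it the autocorrelation block length, grows.
    """
    return {
        "length": 2.0,
        "solvent_level": 0.0,
        "boundary": "reflective",
        "theta_barrier": 12.0,
        "traps": [
            {"center": 0.7, "width": 0.3, "depth": 9.0, "phase": 0.0},
            {"center": 1.05, "width": 0.3, "depth": 9.0, "phase": math.pi},
        ],
        "solvent_region": [1.6, 2.0],
        "schedule": {"n_states": 1},
    }


def two_state_spec() -> dict:
    """Small asymmetric double-well toy for free-energy-difference oracles."""
    return {
        "length": 2.0,
        "solvent_level": 0.0,
        "boundary": "reflective",
        "barriers": [{"center": 1.0, "height": 8.0, "width": 0.18}],
        "wells": [{"center": 1.55, "depth": 4.0, "width": 0.20}],
        "solvent_region": [0.0, 0.45],
        "schedule": {"n_states": 1},
    }


def flat_spec(length: float = 2.0, n_lambda: int = 1) -> dict:
    """Featureless landscape (free diffusion between the walls)."""
    return {
        "length": length,
        "solvent_level": 0.0,
        "boundary": "reflective",
        "solvent_region": [0.0, length],
        "schedule": {"n_states": n_lambda},
    }


def solvent_box_spec(n_lambda: int = 21, solvent_level: float = -5.0, theta_k: float = 0.0) -> dict:
    """Solvent-only box for the 1D alchemical (hydration-analog) leg."""
    return {
        "length": 1.0,
        "solvent_level": solvent_level,
        "boundary": "reflective",
        "theta_k": theta_k,
        "solvent_region": [0.0, 1.0],
        "schedule": {"n_states": n_lambda},
    }
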