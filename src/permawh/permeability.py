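"""The inhomogeneous solubility-diffusion permeability pipeline.

The permeation resistance of a single barrier period is

    R = Int_{z1}^{z2} exp(beta dG_rel.water(z)) / D(z) dz,

with dG_rel.water the free-energy profile calibrated to the solvent
(hydration) reference and D(z) the local diffusion coefficient.  The total
resistance across a lamellar stack scales linearly with the effective number
of bilayers N (30 +- 6 by default, from 12 +- 0.4 lipid regions of
2.5 +- 0.5 bilayers each), and the permeability coefficient is
K_P = 1 / (N R), reported as log10 K_P in cm/h.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .constants import PS_PER_NM_TO_H_PER_CM
from .landscape import ThermoParams
from .profiles import DiffusionProfile, PMFProfile

__all__ = [
    "LayerModel",
    "PermeabilityResult",
    "calibrate_relative_to_solvent",
    "offset_nonnegative",
    "trim_edges",
    "resistance",
    "layer_count",
    "total_permeability",
    "combine_pmfs",
    "combine_sets",
]


@dataclass(frozen=True)
class LayerModel:
    """Effective bilayer count of the lamellar stack: product of two factors."""

    n_regions: float = 12.0
    n_regions_se: float = 0.4
    bilayers_per_region: float = 2.5
    bilayers_per_region_se: float = 0.5

    def __post_init__(self) -> None:
        if self.n_regions <= 0 or self.bilayers_per_region <= 0:
            raise ValueError("layer-model means must be positive")
        if self.n_regions_se < 0 or self.bilayers_per_region_se < 0:
            raise ValueError("layer-model SEs must be >= 0")


def layer_count(lm: LayerModel) -> tuple[float, float]:
    """Total bilayer count mean and SE (first-order propagation of the product)."""
    mean = lm.n_regions * lm.bilayers_per_region
    se = math.hypot(
        lm.bilayers_per_region * lm.n_regions_se,
        lm.n_regions * lm.bilayers_per_region_se,
    )
    return mean, se


@dataclass(frozen=True)
class PermeabilityResult:
    """Permeation resistance and permeability coefficient in reporting units."""

    R: float  # h/cm, total (layer-scaled)
    K_P: float  # cm/h
    log10_KP: float
    se_log10_KP: float
    layer_model: LayerModel
    n_layers: float
    beta: float  # mol/kJ used in the resistance integral

    def __post_init__(self) -> None:
        if not math.isclose(self.K_P * self.R, 1.0, rel_tol=1e-9):
            raise ValueError("K_P must equal 1/R")


def calibrate_relative_to_solvent(pmf: PMFProfile, dG_solv: float) -> PMFProfile:
    """Shift a vacuum-referenced PMF to the solvent (hydration) reference.

    dG_rel.water(z) = dG_vacuum(z) - dG_solv, with dG_solv the solvation free
    energy (coupled minus vacuum) of the same permeant in the reference
    solvent; the result is ~0 wherever the environment equals that solvent.
    """
    if pmf.reference_tag == "solvent":
        raise ValueError("PMF is already solvent-calibrated")
    if pmf.reference_tag != "vacuum":
        raise ValueError(
            f"need a vacuum-referenced PMF, got reference_tag={pmf.reference_tag!r}"
        )
    return replace(pmf, dG=pmf.dG - dG_solv, reference_tag="solvent")


def offset_nonnegative(pmf: PMFProfile) -> PMFProfile:
    """Shift the PMF by an additive constant so it is never below 0 (min = 0)."""
    if not np.all(np.isfinite(pmf.dG)):
        raise ValueError("PMF contains non-finite values")
    return pmf.with_values(pmf.dG - pmf.dG.min())


def trim_edges(pmf: PMFProfile, n_edge: int = 2) -> PMFProfile:
    """Replace the ``n_edge`` outermost values at each end by their inner
    neighbor's value (removes the artificial edge spikes of symmetrized
    sampling); the grid itself is unchanged."""
    if n_edge == 0:
        return pmf
    if n_edge < 0:
        raise ValueError("n_edge must be >= 0")
    if len(pmf.z) <= 2 * n_edge + 1:
        raise ValueError(f"profile of length {len(pmf.z)} too short to trim {n_edge} edges")
    dG = pmf.dG.copy()
    dG[:n_edge] = dG[n_edge]
    dG[-n_edge:] = dG[-n_edge - 1]
    return pmf.with_values(dG)


def _aligned_diffusion(pmf: PMFProfile, dp: DiffusionProfile, tol: float = 1e-9):
    if dp.z.shape == pmf.z.shape and np.max(np.abs(dp.z - pmf.z)) <= tol:
        D = dp.D
    else:
        warnings.warn("diffusion grid differs from the PMF grid; interpolating linearly",
                      stacklevel=3)
        if pmf.z[0] < dp.z[0] - tol or pmf.z[-1] > dp.z[-1] + tol:
            raise ValueError("PMF grid extends beyond the diffusion profile")
        finite = np.isfinite(dp.D)
        D = np.interp(pmf.z, dp.z[finite], dp.D[finite])
        # re-flag regions with no nearby data
        if not finite.all():
            gaps = np.interp(pmf.z, dp.z, finite.astype(float)) < 0.5
            D = np.where(gaps, np.nan, D)
    if np.any(~np.isfinite(D)):
        bad = np.flatnonzero(~np.isfinite(D))
        raise ValueError(f"missing diffusion values inside the integration range "
                         f"at bins {bad.tolist()}")
    if np.any(D <= 0):
        raise ValueError("diffusion must be positive over the integration range")
    return D


def resistance(pmf: PMFProfile, dp: DiffusionProfile,
               thermo: ThermoParams | None = None,
               method: str = "trapezoid") -> float:
    """Single-period resistance R = Int exp(beta dG)/D dz in ps/nm.

    Requires a solvent-calibrated, non-negativity-offset PMF; the diffusion
    profile is linearly interpolated onto the PMF grid when needed.
    ``method`` is "trapezoid" (default) or "simpson".
    """
    thermo = thermo or ThermoParams()
    if pmf.reference_tag != "solvent":
        raise ValueError("PMF must be solvent-calibrated before the resistance integral")
    if pmf.dG.min() < -1e-9:
        raise ValueError("apply offset_nonnegative before integrating")
    D = _aligned_diffusion(pmf, dp)
    integrand = np.exp(thermo.beta * pmf.dG) / D
    if method == "trapezoid":
        return float(np.trapezoid(integrand, pmf.z))
    if method == "simpson":
        from scipy.integrate import simpson

        return float(simpson(integrand, x=pmf.z))
    raise ValueError(f"unknown integration method {method!r}")


def total_permeability(
    R_single: float,
    lm: LayerModel | None = None,
    thermo: ThermoParams | None = None,
    units: str = "ps/nm",
    se_log10_extra: float = 0.0,
) -> PermeabilityResult:
    """Scale a single-period resistance by the layer count and report K_P.

    ``units`` declares the units of ``R_single``: "ps/nm" (simulation units,
    converted internally) or "h/cm" (already in reporting units).
    ``se_log10_extra`` is an optional additional SE contribution on the log10
    scale (e.g. from PMF/diffusion uncertainty propagation), combined in
    quadrature with the layer-count term.
    """
    thermo = thermo or ThermoParams()
    lm = lm or LayerModel()
    if not (R_single > 0 and math.isfinite(R_single)):
        raise ValueError(f"resistance must be positive, got {R_single}")
    if units == "ps/nm":
        R_single_hcm = R_single * PS_PER_NM_TO_H_PER_CM
    elif units == "h/cm":
        R_single_hcm = R_single
    else:
        raise ValueError(f"unknown resistance units {units!r}")
    n, n_se = layer_count(lm)
    R_tot = n * R_single_hcm
    K_P = 1.0 / R_tot
    se_layers = n_se / (n * math.log(10.0))
    return PermeabilityResult(
        R=R_tot,
        K_P=K_P,
        log10_KP=math.log10(K_P),
        se_log10_KP=math.hypot(se_layers, se_log10_extra),
        layer_model=lm,
        n_layers=n,
        beta=thermo.beta,
    )


def combine_pmfs(pmfs) -> PMFProfile:
    """Per-bin mean and SE over independent simulation sets."""
    pmfs = list(pmfs)
    if not pmfs:
        raise ValueError("no PMFs to combine")
    z = pmfs[0].z
    tag = pmfs[0].reference_tag
    for p in pmfs[1:]:
        if p.z.shape != z.shape or np.max(np.abs(p.z - z)) > 1e-9:
            raise ValueError("PMFs are on different grids")
        if p.reference_tag != tag:
            raise ValueError("PMFs have inconsistent reference tags")
    stack = np.stack([p.dG for p in pmfs])
    mean = stack.mean(axis=0)
    if len(pmfs) == 1:
        warnings.warn(
            "a single simulation set does not give a reliable error estimate",
            stacklevel=2,
        )
        se = None
    else:
        se = stack.std(axis=0, ddof=1) / math.sqrt(len(pmfs))
    return PMFProfile(z=z, dG=mean, se=se, reference_tag=tag)


def combine_sets(
    pmfs,
    dp: DiffusionProfile,
    lm: LayerModel | None = None,
    thermo: ThermoParams | None = None,
    propagate: str = "delta",
    n_mc: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[PMFProfile, PermeabilityResult]:
    """Average independent-set PMFs and compute the final permeability.

    Statistical uncertainty of the profiles enters ``se_log10_KP`` either by
    first-order (delta-method) propagation assuming independent bins
    (``propagate="delta"``), by Monte-Carlo resampling of the profiles within
    their SE (``"mc"``), or not at all (``"none"``, layer-count term only).
    """
    thermo = thermo or ThermoParams()
    combined = combine_pmfs(pmfs)
    calibrated = offset_nonnegative(combined)
    R1 = resistance(calibrated, dp, thermo)
    se_extra = 0.0
    if combined.se is not None and propagate != "none":
        if propagate == "delta":
            D = _aligned_diffusion(calibrated, dp)
            w = np.gradient(calibrated.z)
            terms = w * np.exp(thermo.beta * calibrated.dG) / D
            var_R = np.sum((thermo.beta * terms * combined.se) ** 2)
            se_extra = math.sqrt(var_R) / (R1 * math.log(10.0))
        elif propagate == "mc":
            rng = rng or np.random.default_rng(0)
            logs = []
            for _ in range(n_mc):
                pert = calibrated.with_values(
                    calibrated.dG + rng.standard_normal(len(calibrated.z)) * combined.se
                )
                logs.append(math.log10(1.0 / resistance(offset_nonnegative(pert), dp, thermo)))
            se_extra = float(np.std(logs, ddof=1))
        else:
            raise ValueError(f"unknown propagation mode {propagate!r}")
    result = total_permeability(R1, lm, thermo, se_log10_extra=se_extra)
    return combined, result
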