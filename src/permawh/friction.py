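"""Position-dependent friction from bias-force autocorrelation.

The friction metric at a grid bin is the integrated autocovariance of the
pull force sampled while the walker's reference point sits in that bin,

    g(z) = beta^2 * Int_0^inf <dF(t) dF(0)>_z dt,

so that the local diffusion coefficient follows from an Einstein relation,
D(z) = 1/g(z) in nm^2/ps.  The integral is estimated by block averaging:
the series is cut into ``n_blocks`` contiguous time blocks and, per bin,

    Int C dt ~= sum_b S_b(z)^2 / (2 sum_b T_b(z)),

where S_b(z) is the block sum of (F - <F>_z) dt over samples assigned to the
bin and T_b(z) the occupancy time — the blocked time-integral with no
windowing, valid when blocks are much longer than the force correlation time.
Bins never sampled stay NaN (missing), they are not zero-filled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .landscape import ThermoParams
from .profiles import DiffusionProfile, FrictionProfile

__all__ = [
    "ForceSeries",
    "accumulate_friction",
    "friction_from_run",
    "to_diffusion",
    "invert",
    "combine_walkers",
    "rolling_median",
]


@dataclass(frozen=True)
class ForceSeries:
    """Per-walker pull-force time series with its reference-point assignment."""

    time: np.ndarray  # ps, uniform spacing
    force: np.ndarray  # kJ/mol/nm
    z_bin: np.ndarray  # int bin index of the umbrella reference
    lambda_index: np.ndarray  # int

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.force) == len(self.z_bin) == len(self.lambda_index) == n):
            raise ValueError("force series columns must have equal length")
        if n >= 2:
            dt = np.diff(self.time)
            if np.max(np.abs(dt - dt[0])) > 1e-9 * abs(dt[0]):
                raise ValueError("force series must be uniformly spaced in time")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else math.nan


def accumulate_friction(
    series: ForceSeries,
    z_grid: np.ndarray,
    n_blocks: int = 128,
    lambda_index: int | None = 0,
    thermo: ThermoParams | None = None,
    discard_fraction: float = 0.0,
    min_occupancy: int = 8,
) -> FrictionProfile:
    """Blocked friction metric g(z) from one walker's force series.

    ``lambda_index`` restricts the estimate to samples taken at that
    alchemical state (the coupled state by default); pass None to use all.
    ``discard_fraction`` drops the first part of the series (the default 0
    keeps the whole run including the initial stage).  Bins with fewer than
    ``min_occupancy`` samples are flagged missing.
    """
    thermo = thermo or ThermoParams()
    z_grid = np.asarray(z_grid, dtype=float)
    n = len(series.time)
    if n < 2 * n_blocks:
        raise ValueError(
            f"series of {n} samples is shorter than 2 x {n_blocks} blocks"
        )
    start = int(discard_fraction * n)
    f = series.force[start:]
    bins = series.z_bin[start:]
    keep = np.ones(len(f), dtype=bool)
    if lambda_index is not None:
        keep = series.lambda_index[start:] == lambda_index
    dt = series.dt
    n_z = len(z_grid)

    # per-bin mean force over the whole (kept) series
    counts = np.bincount(bins[keep], minlength=n_z).astype(float)
    sums = np.bincount(bins[keep], weights=f[keep], minlength=n_z)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_f = sums / counts

    m = len(f)
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    s2 = np.zeros(n_z)
    occ = np.zeros(n_z)
    for b in range(n_blocks):
        sl = slice(edges[b], edges[b + 1])
        kb = keep[sl]
        if not kb.any():
            continue
        bb = bins[sl][kb]
        df = f[sl][kb] - mean_f[bb]
        s = np.bincount(bb, weights=df * dt, minlength=n_z)
        s2 += s * s
        occ += np.bincount(bb, minlength=n_z).astype(float) * dt
    with np.errstate(invalid="ignore", divide="ignore"):
        integral = s2 / (2.0 * occ)  # (kJ/mol/nm)^2 * ps
    g = thermo.beta**2 * integral
    bad = counts < min_occupancy
    g[bad] = np.nan
    low_info = np.isfinite(g) & (g <= 0)
    if low_info.any():
        warnings.warn(
            f"{int(low_info.sum())} bins have a vanishing force-autocovariance "
            "integral (white-noise floor); flagged as low-information (missing)",
            stacklevel=2,
        )
        g[low_info] = np.nan
    return FrictionProfile(z=z_grid, g=g, occupancy=occ, n_blocks=n_blocks)


def friction_from_run(run, thermo: ThermoParams | None = None,
                      min_occupancy_time: float = 1.0) -> list[FrictionProfile]:
    """Per-walker friction profiles from a sampler run's blocked weight sums.

    This is the run-integrated variant of the friction metric: every sample
    contributed to nearby grid points with its normalized Gibbs weight share
    omega, so slow force components survive reference-point hopping (the
    hard assignment of :func:`accumulate_friction` truncates them when the
    reference moves faster than the force decorrelates).  Bins with less
    than ``min_occupancy_time`` ps of weighted occupancy are flagged missing.
    """
    if run.friction_sums is None:
        raise ValueError("run carries no friction accumulators")
    thermo = thermo or ThermoParams()
    S, T, Q = run.friction_sums
    n_blocks, n_w, _ = S.shape
    z = run.bias.grid.z_centers
    out = []
    for w in range(n_w):
        t_tot = T[:, w, :].sum(axis=0)
        q_tot = Q[:, w, :].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_f = S[:, w, :].sum(axis=0) / t_tot
            s_corr = S[:, w, :] - mean_f[None, :] * T[:, w, :]
            # blocked variance over the squared-weight occupancy: exact for
            # both hard and Gaussian-kernel sample assignment
            g = thermo.beta**2 * (s_corr**2).sum(axis=0) / (2.0 * q_tot)
        g[t_tot < min_occupancy_time] = np.nan
        g[np.isfinite(g) & (g <= 0)] = np.nan
        out.append(FrictionProfile(z=z, g=g, occupancy=t_tot, n_blocks=n_blocks))
    return out


def invert(dp: DiffusionProfile) -> FrictionProfile:
    """D(z) -> g(z) = 1/D(z); missing bins propagate."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return FrictionProfile(z=dp.z, g=1.0 / dp.D)


def to_diffusion(fp: FrictionProfile) -> DiffusionProfile:
    """Einstein relation D(z) = 1/g(z); missing bins propagate as missing."""
    g = fp.g
    finite = np.isfinite(g)
    if np.any(finite & (g <= 0)):
        bad = np.flatnonzero(finite & (g <= 0))
        raise ValueError(f"non-positive friction at bins {bad.tolist()}")
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(finite, 1.0 / g, np.nan)
    return DiffusionProfile(z=fp.z, D=D)


def combine_walkers(profiles) -> DiffusionProfile:
    """Combine per-walker friction profiles into one diffusion profile.

    The combination is an occupancy-weighted mean on the friction scale
    (friction, not diffusion, is the additively estimated quantity); the SE is
    the standard error over the per-walker diffusion values and is NaN where
    fewer than two walkers contribute.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to combine")
    z = profiles[0].z
    for p in profiles[1:]:
        if p.z.shape != z.shape or np.max(np.abs(p.z - z)) > 1e-9:
            raise ValueError("walker profiles are on different grids")
    G = np.stack([p.g for p in profiles])
    W = np.stack([
        p.occupancy if p.occupancy is not None else np.isfinite(p.g).astype(float)
        for p in profiles
    ])
    W = np.where(np.isfinite(G), W, 0.0)
    Gz = np.where(np.isfinite(G), G, 0.0)
    wsum = W.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        g_comb = np.where(wsum > 0, (Gz * W).sum(axis=0) / wsum, np.nan)
        D_comb = np.where(np.isfinite(g_comb) & (g_comb > 0), 1.0 / g_comb, np.nan)
        D_w = np.where(np.isfinite(G), 1.0 / G, np.nan)
    n_eff = np.isfinite(D_w).sum(axis=0)
    se = np.full(len(z), np.nan)
    multi = n_eff >= 2
    if multi.any():
        se[multi] = np.nanstd(D_w[:, multi], axis=0, ddof=1) / np.sqrt(n_eff[multi])
    return DiffusionProfile(z=z, D=D_comb, se=se)


def rolling_median(dp: DiffusionProfile, window: float = 0.2) -> DiffusionProfile:
    """Centered rolling-median filter of width ``window`` nm.

    Edge bins use the truncated window.  Missing bins are ignored inside a
    window; a bin whose window holds no data stays missing.
    """
    z = dp.z
    spacing = float(np.min(np.diff(z)))
    if window < spacing:
        raise ValueError(f"window {window} nm is below the grid spacing {spacing} nm")
    half = window / 2.0
    D = dp.D
    out = np.full_like(D, np.nan)
    for i in range(len(z)):
        sel = np.abs(z - z[i]) <= half + 1e-12
        vals = D[sel]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            out[i] = np.median(vals)
    return DiffusionProfile(z=z, D=out, se=dp.se, median_window=window,
                            comments=dp.comments)
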