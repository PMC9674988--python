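"""Typed free-energy / friction / diffusion profiles and their xvg-style text
format.

Files are plain whitespace-separated columns (z in nm, value, optional SE)
preceded by ``#``/``@`` comment lines.  Structured metadata is carried in
``# key: value`` comments with a versioned header; unknown comment lines are
preserved on read so foreign annotations survive a round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

FORMAT_VERSION = 1

__all__ = [
    "PMFProfile",
    "FrictionProfile",
    "DiffusionProfile",
    "ProfileParseError",
    "read_profile",
    "write_profile",
]


class ProfileParseError(ValueError):
    """Unparseable or inconsistent profile file."""


def _check_grid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or len(z) < 1:
        raise ProfileParseError("profile grid must be a non-empty 1D array")
    if not np.all(np.diff(z) > 0):
        raise ProfileParseError("profile grid must be strictly increasing")
    return z


@dataclass(frozen=True)
class PMFProfile:
    """Free-energy profile dG(z) in kJ/mol on a strictly increasing z grid.

    ``reference_tag`` records the calibration state: "vacuum" (relative to the
    fully decoupled state), "solvent" (relative to the solvent/hydration
    reference) or "uncalibrated" (spatial-only runs with no alchemical leg).
    """

    z: np.ndarray
    dG: np.ndarray
    se: np.ndarray | None = None
    reference_tag: str = "vacuum"
    comments: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", _check_grid(self.z))
        object.__setattr__(self, "dG", np.asarray(self.dG, dtype=float))
        if self.dG.shape != self.z.shape:
            raise ProfileParseError("dG and z must have the same shape")
        if self.se is not None:
            object.__setattr__(self, "se", np.asarray(self.se, dtype=float))
            if self.se.shape != self.z.shape:
                raise ProfileParseError("se and z must have the same shape")
        if self.reference_tag not in ("vacuum", "solvent", "uncalibrated"):
            raise ProfileParseError(f"unknown reference_tag {self.reference_tag!r}")

    def with_values(self, dG, **kw) -> "PMFProfile":
        return replace(self, dG=np.asarray(dG, dtype=float), **kw)


@dataclass(frozen=True)
class FrictionProfile:
    """Per-walker friction metric g(z); D = 1/g is in nm^2/ps.

    Unsampled bins are NaN (flagged missing, never zero-filled).
    ``occupancy`` is the sampled time per bin in ps.
    """

    z: np.ndarray
    g: np.ndarray
    occupancy: np.ndarray | None = None
    n_blocks: int = 128
    comments: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", _check_grid(self.z))
        object.__setattr__(self, "g", np.asarray(self.g, dtype=float))
        if self.g.shape != self.z.shape:
            raise ProfileParseError("g and z must have the same shape")
        with np.errstate(invalid="ignore"):
            if np.any(self.g[np.isfinite(self.g)] <= 0):
                raise ProfileParseError("friction must be > 0 where sampled")


@dataclass(frozen=True)
class DiffusionProfile:
    """Local diffusion coefficient D(z) in nm^2/ps with cross-walker SE."""

    z: np.ndarray
    D: np.ndarray
    se: np.ndarray | None = None
    median_window: float | None = None
    comments: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "z", _check_grid(self.z))
        object.__setattr__(self, "D", np.asarray(self.D, dtype=float))
        if self.D.shape != self.z.shape:
            raise ProfileParseError("D and z must have the same shape")
        with np.errstate(invalid="ignore"):
            if np.any(self.D[np.isfinite(self.D)] <= 0):
                raise ProfileParseError("diffusion must be > 0 where defined")
        if self.se is not None:
            object.__setattr__(self, "se", np.asarray(self.se, dtype=float))
            if self.se.shape != self.z.shape:
                raise ProfileParseError("se and z must have the same shape")


def write_profile(path, profile) -> None:
    """Write a profile as xvg-style text (full double precision)."""
    lines = [f"# permawh-profile-version: {FORMAT_VERSION}"]
    if isinstance(profile, PMFProfile):
        kind, value, se = "pmf", profile.dG, profile.se
        units = "nm kJ/mol"
        lines.append(f"# reference: {profile.reference_tag}")
    elif isinstance(profile, DiffusionProfile):
        kind, value, se = "diffusion", profile.D, profile.se
        units = "nm nm^2/ps"
        if profile.median_window is not None:
            lines.append(f"# median-window-nm: {profile.median_window!r}")
    elif isinstance(profile, FrictionProfile):
        kind, value, se = "friction", profile.g, None
        units = "nm ps/nm^2"
        lines.append(f"# n-blocks: {profile.n_blocks}")
    else:
        raise TypeError(f"cannot write profile of type {type(profile).__name__}")
    lines.insert(1, f"# kind: {kind}")
    lines.append(f"# units: {units}")
    lines.extend(profile.comments)
    ncol = 2 if se is None else 3
    lines.append(f"# columns: {ncol}")
    with open(path, "w") as fh:
        for ln in lines:
            fh.write(ln + "\n")
        for i in range(len(profile.z)):
            row = f"{profile.z[i]:.17g} {value[i]:.17g}"
            if se is not None:
                row += f" {se[i]:.17g}"
            fh.write(row + "\n")


def read_profile(path):
    """Read an xvg-style profile file into its typed profile.

    Raises :class:`ProfileParseError` with the offending line number on a
    non-monotone grid or inconsistent column count.
    """
    meta: dict[str, str] = {}
    extra: list[str] = []
    rows: list[list[float]] = []
    ncol = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#") or line.startswith("@"):
                stripped = line.lstrip("#").strip()
                if ":" in stripped and line.startswith("#"):
                    key, _, val = stripped.partition(":")
                    key = key.strip()
                    if key in ("permawh-profile-version", "kind", "units", "columns",
                               "reference", "median-window-nm", "n-blocks"):
                        meta[key] = val.strip()
                        continue
                extra.append(line)
                continue
            parts = line.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ProfileParseError(f"{path}:{lineno}: bad number: {exc}") from None
            if ncol is None:
                ncol = len(vals)
                if ncol not in (2, 3):
                    raise ProfileParseError(
                        f"{path}:{lineno}: expected 2 or 3 columns, got {ncol}"
                    )
            elif len(vals) != ncol:
                raise ProfileParseError(
                    f"{path}:{lineno}: inconsistent column count ({len(vals)} != {ncol})"
                )
            rows.append(vals)
    if not rows:
        raise ProfileParseError(f"{path}: no data rows")
    data = np.array(rows, dtype=float)
    z, value = data[:, 0], data[:, 1]
    if not np.all(np.diff(z) > 0):
        bad = int(np.argmin(np.diff(z))) + len(extra) + len(meta) + 2
        raise ProfileParseError(f"{path}: non-monotone grid near data row {bad}")
    se = data[:, 2] if data.shape[1] == 3 else None
    kind = meta.get("kind", "pmf")
    comments = tuple(extra)
    if kind == "pmf":
        return PMFProfile(z, value, se=se,
                          reference_tag=meta.get("reference", "vacuum"),
                          comments=comments)
    if kind == "diffusion":
        mw = meta.get("median-window-nm")
        return DiffusionProfile(z, value, se=se,
                                median_window=float(mw) if mw else None,
                                comments=comments)
    if kind == "friction":
        return FrictionProfile(z, value, n_blocks=int(meta.get("n-blocks", 128)),
                               comments=comments)
    raise ProfileParseError(f"{path}: unknown profile kind {kind!r}")
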