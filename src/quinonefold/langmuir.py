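"""Langmuir compression-isotherm workup: surface pressure from tension,
replicate averaging with SD checkpoints every 5 mN/m, per-phospholipid area
normalization, compression modulus, second-derivative collapse detection,
and the physiological-window area-expansion metric.

Conventions: π = γ₀ − γ with γ₀ the clean subphase tension (72.8 mN/m for
the phosphate buffer used in this kind of study); mixed-film areas are
normalized to the phospholipid content as A_N = A / x with x the
phospholipid mole fraction; the compression modulus is Cs⁻¹ = −A·(dπ/dA);
collapse is located at the minimum of d²A/dπ² after local-polynomial
smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "GAMMA0_WATER_BUFFER",
    "IsothermCurve",
    "MeanCurve",
    "ModulusCurve",
    "CollapseResult",
    "SmoothingConfig",
    "surface_pressure",
    "compression_branch",
    "average_replicates",
    "normalize_area",
    "compression_modulus",
    "collapse_pressure",
    "area_expansion",
    "overlap_flag",
]

GAMMA0_WATER_BUFFER = 72.8  # mN/m, aqueous subphase surface tension


@dataclass
class IsothermCurve:
    """One compression isotherm: area per molecule (Å²) vs surface pressure
    (mN/m), with composition metadata."""

    area: np.ndarray
    pressure: np.ndarray
    gamma0: float = GAMMA0_WATER_BUFFER
    composition: float = 1.0  # phospholipid mole fraction x, (0, 1]
    lipid: str = ""
    additive: str = ""

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.area.shape != self.pressure.shape:
            raise ValueError("area and pressure series differ in length")
        if not (0 < self.composition <= 1):
            raise ValueError("composition must lie in (0, 1]")

    @classmethod
    def from_tension(cls, area, gamma, gamma0: float = GAMMA0_WATER_BUFFER,
                     **kw) -> "IsothermCurve":
        return cls(area, surface_pressure(gamma0, np.asarray(gamma)), gamma0,
                   **kw)


@dataclass
class MeanCurve:
    """Replicate-averaged isotherm on a uniform pressure grid with SD
    checkpoints at every 5 mN/m."""

    pressure: np.ndarray
    area_mean: np.ndarray
    sd_pressure: np.ndarray  # checkpoint pressures (0, 5, 10, ... mN/m)
    area_sd: np.ndarray | None  # None for a single replicate
    n_replicates: int = 1
    composition: float = 1.0

    def area_at(self, pressure) -> np.ndarray:
        return np.interp(pressure, self.pressure, self.area_mean)

    def sd_at(self, pressure) -> np.ndarray:
        if self.area_sd is None:
            raise ValueError("SD unavailable for a single replicate")
        return np.interp(pressure, self.sd_pressure, self.area_sd)


@dataclass
class ModulusCurve:
    pressure: np.ndarray
    modulus: np.ndarray  # Cs⁻¹, mN/m

    @property
    def max_modulus(self) -> float:
        return float(np.nanmax(self.modulus))


@dataclass
class CollapseResult:
    collapse_pressure: float | None  # mN/m; None when no collapse detected
    second_derivative_min: float
    grid_step: float
    smoothing_window: int

    @property
    def detected(self) -> bool:
        return self.collapse_pressure is not None


@dataclass(frozen=True)
class SmoothingConfig:
    """Numerical settings for derivative-based isotherm analysis."""

    grid_step: float = 0.25  # mN/m resampling step
    window: int = 11  # odd Savitzky-Golay window (points)
    polyorder: int = 2
    min_curvature: float = 1.0  # |d²A/dπ²| needed to call a collapse (Å²/(mN/m)²)


def surface_pressure(gamma0: float, gamma):
    """π = γ₀ − γ (mN/m). Negative pressures are legal but flagged."""
    pi = np.asarray(gamma0, dtype=float) - np.asarray(gamma, dtype=float)
    if np.any(pi < 0):
        warnings.warn("negative surface pressure: film tension exceeds the "
                      "clean subphase tension")
    if pi.ndim == 0:
        return float(pi)
    return pi


def compression_branch(curve: IsothermCurve) -> IsothermCurve:
    """Compression branch ordered by decreasing area; at duplicated pressures
    the last-visited (smallest) area is retained."""
    order = np.argsort(-curve.area, kind="stable")
    a = curve.area[order]
    p = curve.pressure[order]
    # keep the last occurrence of each pressure value along compression
    keep = np.ones(a.size, dtype=bool)
    seen: dict[float, int] = {}
    for i, pv in enumerate(p):
        key = round(float(pv), 9)
        if key in seen:
            keep[seen[key]] = False
        seen[key] = i
    return IsothermCurve(a[keep], p[keep], curve.gamma0, curve.composition,
                         curve.lipid, curve.additive)


def average_replicates(curves: list[IsothermCurve],
                       grid_step: float = 0.25,
                       sd_every: float = 5.0) -> MeanCurve:
    """Average replicate isotherms on a common uniform pressure grid.

    Area is linearly interpolated onto the overlapping pressure support;
    the sample SD of the area is evaluated at every ``sd_every`` mN/m.
    A single replicate yields ``area_sd=None``.
    """
    if not curves:
        raise ValueError("no replicates")
    branches = [compression_branch(c) for c in curves]
    lo = max(b.pressure.min() for b in branches)
    hi = min(b.pressure.max() for b in branches)
    if hi <= lo:
        raise ValueError("replicates have disjoint pressure ranges")
    grid = np.arange(np.ceil(lo / grid_step) * grid_step, hi + 1e-9, grid_step)
    mats = np.stack([
        np.interp(grid, b.pressure[np.argsort(b.pressure)],
                  b.area[np.argsort(b.pressure)])
        for b in branches])
    mean = mats.mean(axis=0)
    checkpoints = np.arange(0.0, hi + 1e-9, sd_every)
    checkpoints = checkpoints[checkpoints >= lo]
    if len(curves) > 1:
        at = np.stack([np.interp(checkpoints, grid, row) for row in mats])
        sd = at.std(axis=0, ddof=1)
    else:
        sd = None
    return MeanCurve(grid, mean, checkpoints, sd, len(curves),
                     curves[0].composition)


def normalize_area(area, x: float):
    """Area per phospholipid A_N = A / x for phospholipid mole fraction x."""
    if not (0 < x <= 1):
        raise ValueError("mole fraction x must lie in (0, 1]")
    a = np.asarray(area, dtype=float) / x
    return float(a) if a.ndim == 0 else a


def compression_modulus(curve: IsothermCurve,
                        config: SmoothingConfig = SmoothingConfig(),
                        smooth: bool = True) -> ModulusCurve:
    """Cs⁻¹ = −A·(dπ/dA) along the compression branch.

    Central finite differences on the (optionally Savitzky-Golay smoothed)
    π(A) series; one-sided at the endpoints.
    """
    b = compression_branch(curve)
    if b.area.size < 3:
        raise ValueError("need at least 3 points for a modulus")
    a = b.area[::-1]  # ascending area
    p = b.pressure[::-1]
    if smooth and a.size >= config.window:
        p = savgol_filter(p, config.window, config.polyorder)
    dpda = np.gradient(p, a)
    cs = -a * dpda
    return ModulusCurve(p[::-1], cs[::-1])


def collapse_pressure(curve: IsothermCurve,
                      config: SmoothingConfig = SmoothingConfig()
                      ) -> CollapseResult:
    """Collapse pressure π_c as the minimum of d²A/dπ².

    The compression branch is resampled onto a uniform pressure grid,
    smoothed with a local polynomial, and twice differentiated; π_c is the
    grid argmin when it is a pronounced interior feature (curvature below
    −``min_curvature``), otherwise no collapse is reported. Invariant under
    uniform area rescaling up to the detection threshold.
    """
    b = compression_branch(curve)
    order = np.argsort(b.pressure)
    p_sorted = b.pressure[order]
    a_sorted = b.area[order]
    grid = np.arange(p_sorted.min(), p_sorted.max() + 1e-9, config.grid_step)
    if grid.size < config.window:
        raise ValueError("pressure range too short for the smoothing window")
    a_grid = np.interp(grid, p_sorted, a_sorted)
    d2 = savgol_filter(a_grid, config.window, config.polyorder, deriv=2,
                       delta=config.grid_step)
    interior = slice(config.window // 2, grid.size - config.window // 2)
    seg = d2[interior]
    k = int(np.argmin(seg))
    d2_min = float(seg[k])
    pi_c = float(grid[interior][k])
    if d2_min > -config.min_curvature:
        return CollapseResult(None, d2_min, config.grid_step, config.window)
    return CollapseResult(pi_c, d2_min, config.grid_step, config.window)


def area_expansion(mixed: MeanCurve, pure: MeanCurve, x: float,
                   window: tuple[float, float] = (30.0, 35.0),
                   step: float = 0.25) -> float:
    """Percent area expansion of the normalized mixed film over the pure film
    averaged across a surface-pressure window (default the physiological
    30–35 mN/m)."""
    lo, hi = window
    for c in (mixed, pure):
        if c.pressure.min() > lo or c.pressure.max() < hi:
            raise ValueError("window outside the data's pressure range")
    grid = np.arange(lo, hi + 1e-9, step)
    a_mixed = normalize_area(mixed.area_at(grid), x)
    a_pure = pure.area_at(grid)
    return float(100.0 * (a_mixed.mean() - a_pure.mean()) / a_pure.mean())


def overlap_flag(mixed: MeanCurve, pure: MeanCurve, x: float,
                 window: tuple[float, float] = (30.0, 35.0)) -> str:
    """'separated' iff the normalized mean ± 1 SD bands are disjoint at every
    5 mN/m SD checkpoint inside the window, else 'overlapping'."""
    if mixed.area_sd is None or pure.area_sd is None:
        raise ValueError("overlap test requires replicate SDs")
    lo, hi = window
    checkpoints = [p for p in mixed.sd_pressure if lo <= p <= hi]
    if not checkpoints:
        raise ValueError("no SD checkpoints inside the window")
    for p in checkpoints:
        m = normalize_area(float(mixed.area_at(p)), x)
        ms = normalize_area(float(mixed.sd_at(p)), x)
        q = float(pure.area_at(p))
        qs = float(pure.sd_at(p))
        if (m - ms) <= (q + qs) and (q - qs) <= (m + ms):
            return "overlapping"
    return "separated"
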