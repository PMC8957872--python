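"""Synthetic generators for every input the pipeline consumes: NOE peak
tables from known conformers, piecewise-phase compression isotherms with a
known collapse pressure, and chemical-shift tables with a known probe
location.

All generators are pure functions of (parameters, seed). They emulate the
study conditions — volumes proportional to ⟨r⁻⁶⟩ inside a 5 Å detection
limit with multiplicative lognormal noise, monolayer isotherms with a
terminal collapse plateau (default truth 21 mN/m) and Gaussian replicate
scatter on the area, and 0.01 ppm-precision shift lists — so every stage of
the analysis can be exercised against a known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Conformer, group_distance
from .noe import PEAK_COLUMNS, canonical_pair

__all__ = [
    "NoiseModel",
    "IsothermPhaseModel",
    "simulate_peak_table",
    "simulate_isotherm",
    "simulate_shift_table",
    "true_group_distances",
]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise with coefficient of variation ``cv``."""

    cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")

    def factors(self, n: int) -> np.ndarray:
        if self.cv == 0:
            return np.ones(n)
        sigma = math.sqrt(math.log(1.0 + self.cv ** 2))
        rng = np.random.default_rng(self.seed)
        return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=n)


def true_group_distances(conformers, groups: list[str] | None = None,
                         mode: str = "mean") -> dict[tuple[str, str], float]:
    """Effective distance per group pair, ⟨r⁻⁶⟩-pooled over conformers.

    ``mode="mean"`` (default) uses one representative distance per group
    pair — the arithmetic mean over member protons — which is the reading
    the volume calibration presupposes when it anchors the reference pair
    at its 'known distance'. ``mode="r6"`` pools ⟨r⁻⁶⟩ over all member
    proton pairs (the raw NOE physics for equivalent protons).
    """
    if isinstance(conformers, Conformer):
        conformers = [conformers]
    topo = conformers[0].topology
    groups = groups or sorted(topo.proton_groups)
    out: dict[tuple[str, str], float] = {}
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            r6 = [group_distance(c, ga, gb, mode=mode) ** -6.0
                  for c in conformers]
            out[canonical_pair(ga, gb)] = float(np.mean(r6) ** (-1.0 / 6.0))
    return out


def simulate_peak_table(conformers, reference_pair: tuple[str, str],
                        noise: NoiseModel = NoiseModel(),
                        detection_limit: float = 5.0,
                        groups: list[str] | None = None,
                        spectrum: str = "NOESY",
                        environment: str = "synthetic",
                        mode: str = "mean") -> pd.DataFrame:
    """Cross-peak table from a conformer (or ensemble of conformers).

    Volumes follow the r⁻⁶ law on the effective group-pair distance
    (see ``true_group_distances`` for the two distance conventions), scaled
    so the reference pair's volume is exactly 1 before noise; pairs whose
    effective distance exceeds ``detection_limit`` are omitted.
    Deterministic given ``noise.seed``. Emitted plus suppressed pairs
    together exhaust the requested group pairs.
    """
    dists = true_group_distances(conformers, groups, mode=mode)
    ref = canonical_pair(*reference_pair)
    if ref not in dists:
        raise ValueError(f"reference pair {ref} not among requested groups")
    d_ref = dists[ref]
    if d_ref > detection_limit:
        raise ValueError(
            f"reference pair at {d_ref:.2f} Å is beyond the detection limit")
    pairs = [(p, d) for p, d in sorted(dists.items()) if d <= detection_limit]
    fac = NoiseModel(noise.cv, noise.seed).factors(len(pairs))
    rows = []
    for ((ga, gb), d), f in zip(pairs, fac):
        rows.append({"group_a": ga, "group_b": gb,
                     "volume": (d_ref / d) ** 6 * f,
                     "spectrum": spectrum, "environment": environment,
                     "overlap_flag": False})
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


@dataclass(frozen=True)
class IsothermPhaseModel:
    """Piecewise-linear compression isotherm with a terminal collapse plateau.

    ``knots`` are (area Å²/molecule, pressure mN/m) pairs ordered by
    decreasing area; pressure is non-decreasing as area decreases. The last
    segment is the collapse plateau: it starts at the collapse pressure
    (the second-to-last knot) and carries only the small residual pressure
    creep real collapsed films show, which is also what keeps area a
    single-valued function of pressure. The default emulates a lipoquinone
    film collapsing at 21 mN/m.
    """

    knots: tuple[tuple[float, float], ...] = (
        (120.0, 0.0), (90.0, 1.0), (60.0, 8.0), (40.0, 21.0), (24.0, 23.0))
    replicate_sd: float = 0.0  # Å² Gaussian scatter on area

    def __post_init__(self) -> None:
        areas = [a for a, _ in self.knots]
        pres = [p for _, p in self.knots]
        if any(a2 >= a1 for a1, a2 in zip(areas, areas[1:])):
            raise ValueError("knot areas must strictly decrease")
        if any(p2 < p1 for p1, p2 in zip(pres, pres[1:])):
            raise ValueError("pressure must be non-decreasing on compression")

    @property
    def collapse_pressure(self) -> float:
        """Pressure at the plateau onset (the second-to-last knot)."""
        return self.knots[-2][1]

    def pressure_at(self, area: np.ndarray) -> np.ndarray:
        areas = np.array([a for a, _ in self.knots])
        pres = np.array([p for _, p in self.knots])
        # np.interp needs ascending x
        return np.interp(np.asarray(area, dtype=float),
                         areas[::-1], pres[::-1])


def simulate_isotherm(model: IsothermPhaseModel, n_replicates: int = 3,
                      seed: int = 0, n_points: int = 200,
                      composition: float = 1.0) -> pd.DataFrame:
    """Replicate isotherms on a shared area grid with Gaussian area scatter.

    Returns a long table ``replicate, area_A2, pressure_mN_m``; replicate
    r's rows use an independent substream of ``seed`` so permuting seeds
    permutes replicates.
    """
    a_hi = model.knots[0][0]
    a_lo = model.knots[-1][0]
    grid = np.linspace(a_hi, a_lo, n_points)
    pres = model.pressure_at(grid)
    frames = []
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, r])
        area = grid + (rng.normal(0.0, model.replicate_sd, size=grid.size)
                       if model.replicate_sd > 0 else 0.0)
        frames.append(pd.DataFrame({
            "replicate": r, "area_A2": area, "pressure_mN_m": pres}))
    out = pd.concat(frames, ignore_index=True)
    out.attrs["composition"] = composition
    out.attrs["collapse_pressure"] = model.collapse_pressure
    return out


@dataclass(frozen=True)
class ShiftEndpoints:
    """Organic/aqueous endpoint chemical shifts (ppm) per probe proton."""

    organic: dict[str, float] = field(default_factory=lambda: {
        "H_A": 5.02, "H_B": 4.93})
    aqueous: dict[str, float] = field(default_factory=lambda: {
        "H_A": 4.93, "H_B": 4.86})


def simulate_shift_table(true_location: str,
                         endpoints: ShiftEndpoints = ShiftEndpoints(),
                         seed: int = 0,
                         w0_values: tuple[int, ...] = (4, 8, 12, 16, 20),
                         interface_offset: float = 0.015,
                         jitter_sd: float = 0.002,
                         organic_env: str = "isooctane",
                         aqueous_env: str = "D2O") -> pd.DataFrame:
    """Shift table (proton, environment, delta_ppm) for a known location.

    RM-environment shifts sit on the aqueous endpoint (``aqueous``), on the
    organic endpoint (``organic``), or near-but-off the organic endpoint
    (``interface``, offset ~``interface_offset`` ppm). All values carry
    Gaussian read jitter and are reported at the 0.01 ppm precision of a
    printed peak list.
    """
    if true_location not in ("organic", "interface", "aqueous"):
        raise ValueError(f"unknown location {true_location!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for proton, d_org in endpoints.organic.items():
        d_aq = endpoints.aqueous[proton]
        rows.append({"proton": proton, "environment": organic_env,
                     "delta_ppm": round(d_org, 2)})
        rows.append({"proton": proton, "environment": aqueous_env,
                     "delta_ppm": round(d_aq, 2)})
        sign = 1.0 if d_org >= d_aq else -1.0
        for w0 in w0_values:
            if true_location == "organic":
                d = d_org + rng.normal(0.0, jitter_sd)
            elif true_location == "aqueous":
                d = d_aq + rng.normal(0.0, jitter_sd)
            else:
                d = d_org + sign * interface_offset + rng.normal(0.0, jitter_sd)
            rows.append({"proton": proton, "environment": f"w0-{w0}",
                         "delta_ppm": round(d, 2)})
    return pd.DataFrame(rows, columns=["proton", "environment", "delta_ppm"])


def rm_environment_classes(w0_values=(4, 8, 12, 16, 20),
                           organic_env: str = "isooctane",
                           aqueous_env: str = "D2O") -> dict[str, str]:
    """Environment-class map matching simulate_shift_table's labels."""
    envs = {organic_env: "organic", aqueous_env: "aqueous"}
    envs.update({f"w0-{w}": "rm" for w in w0_values})
    return envs
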