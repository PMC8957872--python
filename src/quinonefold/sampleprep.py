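"""Preparative arithmetic: molar mass from a formula, molarity, dilution,
the reverse-micelle water-to-surfactant ratio w₀, pD correction, percent
yield, and molecules-per-micelle loading.

Atomic masses are the IUPAC 2021 conventional standard atomic weights, with
D recognized as ²H (2.014). Full precision is kept internally; rounding to
printed precision belongs to the reporting layer.
"""

from __future__ import annotations

import re

__all__ = [
    "ATOMIC_MASSES",
    "parse_formula",
    "molar_mass",
    "molarity",
    "dilute",
    "w0_ratio",
    "pD_correction",
    "percent_yield",
    "molecules_per_micelle",
]

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Na": 22.990, "Mg": 24.305, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "K": 39.098, "Ca": 40.078, "Ti": 47.867,
    "Fe": 55.845, "Br": 79.904, "I": 126.904,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Element → count for a plain (unparenthesized) molecular formula."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at "
                             f"position {pos}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in ATOMIC_MASSES:
            raise ValueError(f"unknown element symbol {el!r} in {formula!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def molar_mass(formula: str) -> float:
    """Molar mass in g/mol by per-element summation of standard weights."""
    return sum(ATOMIC_MASSES[el] * n for el, n in parse_formula(formula).items())


def molarity(mass_mg: float, molar_mass_g_mol: float, volume_ml: float) -> float:
    """Concentration in mM from mass (mg), molar mass (g/mol), volume (ml)."""
    if mass_mg < 0:
        raise ValueError("mass must be nonnegative")
    if molar_mass_g_mol <= 0:
        raise ValueError("molar mass must be positive")
    if volume_ml <= 0:
        raise ValueError("volume must be positive")
    mmol = mass_mg / molar_mass_g_mol
    return mmol / (volume_ml / 1000.0)


def dilute(conc_mM: float, volume_ul: float, total_volume_ul: float) -> float:
    """Concentration after diluting ``volume_ul`` of stock to
    ``total_volume_ul``."""
    if total_volume_ul <= 0:
        raise ValueError("total volume must be positive")
    if volume_ul < 0 or volume_ul > total_volume_ul:
        raise ValueError("aliquot volume must lie in [0, total volume]")
    return conc_mM * volume_ul / total_volume_ul


def w0_ratio(water_ul: float, water_density_g_ml: float,
             water_molar_mass: float, surfactant_conc_M: float,
             surfactant_volume_ml: float) -> float:
    """w₀ = [water] / [surfactant], the molar loading of the water pool."""
    if surfactant_conc_M <= 0 or surfactant_volume_ml <= 0:
        raise ValueError("surfactant amount must be positive")
    if water_ul < 0:
        raise ValueError("water volume must be nonnegative")
    mol_water = water_ul / 1000.0 * water_density_g_ml / water_molar_mass
    mol_surf = surfactant_conc_M * surfactant_volume_ml / 1000.0
    return mol_water / mol_surf


def pD_correction(meter_pH: float) -> float:
    """pD = meter pH + 0.4 (glass-electrode correction in D₂O)."""
    return meter_pH + 0.4


def percent_yield(product_mmol: float, limiting_mmol: float) -> float:
    """100 × product / limiting reagent (mol basis)."""
    if limiting_mmol <= 0:
        raise ValueError("limiting reagent amount must be positive")
    if product_mmol < 0:
        raise ValueError("product amount must be nonnegative")
    return 100.0 * product_mmol / limiting_mmol


def molecules_per_micelle(solute_mM: float, surfactant_mM: float,
                          aggregation_number: float) -> float:
    """Mean solutes per micelle: solute / (surfactant / N_agg)."""
    if surfactant_mM <= 0 or aggregation_number <= 0:
        raise ValueError("surfactant concentration and aggregation number "
                         "must be positive")
    return solute_mM / (surfactant_mM / aggregation_number)
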