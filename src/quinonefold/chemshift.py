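"""Per-environment chemical-shift tables, Δδ arithmetic, and the
reverse-micelle localization rule.

The localization logic mirrors how 1D shift series are read in
reverse-micelle (RM) studies: a probe whose RM-environment shifts sit on
the aqueous endpoint lives in the water pool; one sitting exactly on the
organic endpoint lives in the bulk organic phase; a probe whose RM shifts
are close to — but measurably offset from — the organic endpoint while far
from the aqueous endpoint resides at the surfactant-water interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "LocalizeConfig",
    "ShiftDelta",
    "shift_difference",
    "localize",
]

SHIFT_COLUMNS = ["proton", "environment", "delta_ppm"]


@dataclass(frozen=True)
class LocalizeConfig:
    """Thresholds (ppm) of the localization rule.

    ``tau_small`` bounds the RM-to-organic offset compatible with an
    interfacial probe; ``tau_large`` is the minimum RM-to-aqueous separation
    required to exclude the water pool; ``tau_zero`` (below the 0.01 ppm
    precision of a printed peak list) separates 'exactly on the organic
    endpoint' (bulk organic) from 'near it' (interface).
    """

    tau_small: float = 0.03
    tau_large: float = 0.05
    tau_zero: float = 0.005


def _delta(table: pd.DataFrame, proton: str, environment: str) -> float:
    rows = table[(table["proton"] == proton)
                 & (table["environment"] == environment)]
    if rows.empty:
        raise KeyError(f"no shift entry for ({proton!r}, {environment!r})")
    return float(rows["delta_ppm"].iloc[0])


@dataclass(frozen=True)
class ShiftDelta:
    proton: str
    env_from: str
    env_to: str
    delta: float  # ppm, signed


def shift_difference(table: pd.DataFrame, proton: str, env_from: str,
                     env_to: str) -> float:
    """Signed Δδ = δ(env_to) − δ(env_from) in ppm."""
    return _delta(table, proton, env_to) - _delta(table, proton, env_from)


def localize(table: pd.DataFrame, protons: list[str],
             env_classes: dict[str, str],
             config: LocalizeConfig = LocalizeConfig()) -> str:
    """Assign a probe location: organic / aqueous / interface / indeterminate.

    ``env_classes`` maps environment labels to {organic, rm, aqueous};
    exactly one organic and one aqueous endpoint are required, plus at
    least one RM environment. Per proton, Δδ magnitudes are averaged over
    the RM environments; all probe protons must agree on the location,
    otherwise the result is indeterminate. The rule is invariant under
    adding a constant to all of a proton's shifts (re-referencing).
    """
    organic = [e for e, c in env_classes.items() if c == "organic"]
    aqueous = [e for e, c in env_classes.items() if c == "aqueous"]
    rms = [e for e, c in env_classes.items() if c == "rm"]
    if len(organic) != 1 or len(aqueous) != 1 or not rms:
        raise ValueError("need exactly one organic endpoint, one aqueous "
                         "endpoint, and at least one RM environment")
    calls = set()
    for proton in protons:
        d_org = [abs(shift_difference(table, proton, organic[0], e))
                 for e in rms]
        d_aq = [abs(shift_difference(table, proton, aqueous[0], e))
                for e in rms]
        a = sum(d_org) / len(d_org)
        b = sum(d_aq) / len(d_aq)
        if a <= config.tau_zero and b >= config.tau_large:
            calls.add("organic")
        elif a <= config.tau_small and b >= config.tau_large:
            calls.add("interface")
        elif b <= config.tau_small and a >= config.tau_large:
            calls.add("aqueous")
        else:
            calls.add("indeterminate")
    if len(calls) == 1:
        return calls.pop()
    return "indeterminate"
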