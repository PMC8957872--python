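"""NOESY/ROESY cross-peak calibration: volume normalization, the
strong/medium/weak intensity classes, their distance bins, and the
continuous isolated-spin-pair (ISPA) distance used as a cross-check.

Calibration convention: the cross-peak of a reference proton pair with known
separation r_ref (the ring-methyl ↔ allylic-methylene pair at ~3.5 Å for the
UQ-2/MK-2 systems) is set to 1 and every volume is standardized against it.
Standardized volumes map to classes — strong (>1.5), medium (0.6–1.5,
boundaries inclusive), weak (<0.6) — and classes to distance bins:
strong < 3 Å, medium 3–4 Å, weak > 4 Å (upper-bounded by the NOE detection
limit unless disabled).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CalibrationConfig",
    "DistanceRestraint",
    "PEAK_COLUMNS",
    "normalize_volumes",
    "classify_intensity",
    "class_to_bounds",
    "ispa_distance",
    "restraints_from_table",
    "canonical_pair",
]

PEAK_COLUMNS = ["group_a", "group_b", "volume", "spectrum", "environment",
                "overlap_flag"]


@dataclass(frozen=True)
class CalibrationConfig:
    """Thresholds of the volume→distance calibration.

    ``weak_upper=None`` leaves weak restraints unbounded above (the literal
    ">4 Å" reading); the default caps them at the 5 Å NOE detection limit.
    ``composite_groups`` maps member labels onto declared composite groups
    (e.g. overlapping methylene protons reported as one group).
    """

    strong_threshold: float = 1.5
    weak_threshold: float = 0.6
    strong_max: float = 3.0
    medium_max: float = 4.0
    contact_floor: float = 1.8  # van der Waals H···H floor
    weak_upper: float | None = 5.0
    r_ref: float = 3.5
    composite_groups: dict[str, str] = field(default_factory=dict)

    def resolve_group(self, label: str) -> str:
        return self.composite_groups.get(label, label)


@dataclass(frozen=True)
class DistanceRestraint:
    """Distance bounds (Å) on an unordered proton-group pair."""

    pair: tuple[str, str]
    lower: float
    upper: float | None  # None = unbounded
    intensity_class: str | None = None
    r_ref: float = 3.5
    source: str = ""

    def contains(self, distance: float) -> bool:
        lo_ok = distance >= self.lower
        up_ok = self.upper is None or distance <= self.upper
        return lo_ok and up_ok


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered pair identity: (a, b) ≡ (b, a)."""
    return (a, b) if a <= b else (b, a)


def _validate_volumes(peaks: pd.DataFrame) -> None:
    bad = peaks.index[~(peaks["volume"] > 0)].tolist()
    if bad:
        raise ValueError(f"nonpositive volume in row(s) {bad}")
    same = peaks.index[peaks["group_a"] == peaks["group_b"]].tolist()
    if same:
        raise ValueError(f"diagonal (self) pair in row(s) {same}")


def normalize_volumes(peaks: pd.DataFrame,
                      reference_pair: tuple[str, str],
                      config: CalibrationConfig = CalibrationConfig()
                      ) -> pd.DataFrame:
    """Standardize volumes against the reference pair, per spectrum.

    Returns a copy of the table (input order preserved) with ``v_norm`` and
    ``intensity_class`` columns; the reference pair maps to exactly 1 within
    each (spectrum, environment) block. Normalizing an already-normalized
    table is the identity.
    """
    missing = [c for c in PEAK_COLUMNS[:2] + ["volume"] if c not in peaks]
    if missing:
        raise ValueError(f"peak table missing column(s) {missing}")
    _validate_volumes(peaks)
    out = peaks.copy()
    ref = canonical_pair(*(config.resolve_group(g) for g in reference_pair))
    pairs = [canonical_pair(config.resolve_group(a), config.resolve_group(b))
             for a, b in zip(out["group_a"], out["group_b"])]
    out["_pair"] = pairs

    keys = [c for c in ("spectrum", "environment") if c in out.columns]
    v_norm = pd.Series(index=out.index, dtype=float)
    for _, block in (out.groupby(keys, sort=False) if keys
                     else [(None, out)]):
        is_ref = block["_pair"] == ref
        if not is_ref.any():
            raise ValueError(
                f"reference pair {ref} absent from peak table block "
                f"{dict(zip(keys, _)) if keys else ''}")
        v_ref = float(block.loc[is_ref, "volume"].iloc[0])
        v_norm[block.index] = block["volume"] / v_ref
    out["v_norm"] = v_norm
    out["intensity_class"] = [classify_intensity(v, config)
                              for v in out["v_norm"]]
    out = out.drop(columns="_pair")
    return out


def classify_intensity(v_norm: float,
                       config: CalibrationConfig = CalibrationConfig()) -> str:
    """strong (> 1.5), medium (0.6–1.5 inclusive), or weak (< 0.6)."""
    if v_norm < 0:
        raise ValueError(f"negative standardized volume {v_norm}")
    if v_norm > config.strong_threshold:
        return "strong"
    if v_norm >= config.weak_threshold:
        return "medium"
    return "weak"


def class_to_bounds(intensity_class: str,
                    config: CalibrationConfig = CalibrationConfig()
                    ) -> tuple[float, float | None]:
    """Distance bin (lower, upper) in Å for an intensity class.

    ``detected`` is accepted for peaks whose volume was not quantified:
    the only information carried is presence inside the detection limit.
    """
    if intensity_class == "strong":
        return (config.contact_floor, config.strong_max)
    if intensity_class == "medium":
        return (config.strong_max, config.medium_max)
    if intensity_class == "weak":
        return (config.medium_max, config.weak_upper)
    if intensity_class == "detected":
        return (config.contact_floor, config.weak_upper)
    raise ValueError(f"unknown intensity class {intensity_class!r}")


def ispa_distance(v_norm: float, r_ref: float = 3.5) -> float:
    """Continuous ISPA distance r = r_ref · v_norm^(−1/6).

    The isolated-spin-pair approximation treats the cross-peak volume as
    proportional to r⁻⁶; this is the continuous oracle the binned
    calibration is checked against.
    """
    if v_norm <= 0 or r_ref <= 0:
        raise ValueError("v_norm and r_ref must be positive")
    return r_ref * v_norm ** (-1.0 / 6.0)


def restraints_from_table(normalized: pd.DataFrame,
                          reference_pair: tuple[str, str],
                          config: CalibrationConfig = CalibrationConfig()
                          ) -> tuple[list[DistanceRestraint], pd.DataFrame]:
    """Distance restraints from a normalized peak table.

    One restraint per unordered pair; the reference pair is the calibrator
    and yields no restraint. Peaks carrying ``overlap_flag`` are excluded
    and returned separately. Duplicate observations of a pair (e.g. NOESY
    and ROESY) are merged by bound intersection; an empty intersection
    triggers a warning and retains the widest compatible bound, flagged.
    """
    if "v_norm" not in normalized or "intensity_class" not in normalized:
        raise ValueError("table is not normalized; run normalize_volumes first")
    ref = canonical_pair(*(config.resolve_group(g) for g in reference_pair))

    flagged = normalized[normalized.get("overlap_flag", False) == True]  # noqa: E712
    usable = normalized.drop(index=flagged.index)

    grouped: dict[tuple[str, str], list[pd.Series]] = {}
    for _, row in usable.iterrows():
        pair = canonical_pair(config.resolve_group(row["group_a"]),
                              config.resolve_group(row["group_b"]))
        if pair == ref:
            continue
        grouped.setdefault(pair, []).append(row)

    restraints = []
    for pair, rows in grouped.items():
        bounds = [class_to_bounds(r["intensity_class"], config) for r in rows]
        lo = max(b[0] for b in bounds)
        ups = [b[1] for b in bounds if b[1] is not None]
        up = min(ups) if ups else None
        source = "+".join(sorted({str(r.get("spectrum", "?")) for r in rows}))
        classes = sorted({r["intensity_class"] for r in rows})
        if up is not None and lo > up:
            warnings.warn(
                f"conflicting intensity classes {classes} for pair {pair}: "
                "empty bound intersection; keeping widest compatible bound")
            lo = min(b[0] for b in bounds)
            up = max(ups) if ups else None
            source += "|conflict"
        restraints.append(DistanceRestraint(
            pair, lo, up, "/".join(classes), config.r_ref, source))
    return restraints, flagged.copy()


def calibration_discrepancy_intervals(
        r_ref: float, config: CalibrationConfig = CalibrationConfig()
        ) -> list[tuple[float, float]]:
    """Distance intervals where the class bins and the exact r⁻⁶ law must
    disagree.

    A pair at true distance d has standardized volume (r_ref/d)⁶; the class
    boundaries therefore sit at a = r_ref·1.5^(−1/6) and
    b = r_ref·0.6^(−1/6), while the bins hand out hard 3 Å and 4 Å edges.
    The disagreement set is the symmetric difference of [a, b] and [3, 4] —
    two slivers around the bin edges, fixed once r_ref is known.
    """
    a = r_ref * config.strong_threshold ** (-1.0 / 6.0)
    b = r_ref * config.weak_threshold ** (-1.0 / 6.0)
    out = []
    for edge, boundary in ((config.strong_max, a), (config.medium_max, b)):
        lo, hi = sorted((edge, boundary))
        if hi > lo:
            out.append((lo, hi))
    return out


def in_discrepancy_sliver(distance: float, r_ref: float,
                          config: CalibrationConfig = CalibrationConfig()
                          ) -> bool:
    return any(lo < distance < hi
               for lo, hi in calibration_discrepancy_intervals(r_ref, config))


def absence_restraints(observed_pairs, groups: list[str],
                       reference_pair: tuple[str, str],
                       detection_limit: float = 5.0
                       ) -> list[DistanceRestraint]:
    """Lower-bound restraints for group pairs with no observed cross peak.

    The absence of a cross peak among monitored groups is read (cautiously)
    as the pair lying beyond the detection limit. This negative information
    is what distinguishes an extended chain from a folded one when all the
    observed contacts are short-range.
    """
    import itertools

    seen = {canonical_pair(*p) for p in observed_pairs}
    seen.add(canonical_pair(*reference_pair))
    out = []
    for ga, gb in itertools.combinations(sorted(groups), 2):
        pair = canonical_pair(ga, gb)
        if pair not in seen:
            out.append(DistanceRestraint(pair, detection_limit, None,
                                         "absent", source="no-cross-peak"))
    return out


def restraints_to_records(restraints: list[DistanceRestraint]) -> list[dict]:
    """JSON-ready records for a restraint set."""
    return [
        {"pair": list(r.pair), "lower_A": r.lower,
         "upper_A": (r.upper if r.upper is not None else None),
         "class": r.intensity_class, "source": r.source}
        for r in restraints
    ]
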