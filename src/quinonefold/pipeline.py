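"""End-to-end NOE → conformation pipeline: peak table in, restraint set and
classified conformer out.

This is the composition the analysis drivers and the recovery experiments
run: volume normalization, class binning, optional absence-of-cross-peak
lower bounds over a monitored group roster, restrained torsion fitting, and
taxonomy assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import (ClassifyConfig, ConformationClass, FitResult,
                    classify_conformation, fit_conformer)
from .noe import (CalibrationConfig, DistanceRestraint, absence_restraints,
                  normalize_volumes, restraints_from_table)
from .topology import Topology

__all__ = ["PeakFitResult", "restraints_from_peaks", "fit_and_classify",
           "DEFAULT_MONITORED_GROUPS"]

# group roster monitored in the UQ-2/MK-2 NOE experiments
DEFAULT_MONITORED_GROUPS = ["H_W", "H_MN", "H_A", "H_B", "H_X", "H_Y",
                            "H_Z", "H_QR"]


@dataclass
class PeakFitResult:
    restraints: list[DistanceRestraint]
    excluded: pd.DataFrame
    fit: FitResult
    conformation: ConformationClass


def restraints_from_peaks(peaks: pd.DataFrame,
                          reference_pair: tuple[str, str],
                          config: CalibrationConfig = CalibrationConfig(),
                          monitored_groups: list[str] | None = None,
                          detection_limit: float = 5.0
                          ) -> tuple[list[DistanceRestraint], pd.DataFrame]:
    """Calibrate a raw peak table into a restraint set.

    With ``monitored_groups`` given, pairs in the roster with no observed
    cross peak contribute beyond-detection-limit lower bounds.
    """
    normalized = normalize_volumes(peaks, reference_pair, config)
    restraints, flagged = restraints_from_table(normalized, reference_pair,
                                                config)
    if monitored_groups:
        observed = list(zip(peaks["group_a"], peaks["group_b"]))
        restraints = restraints + absence_restraints(
            observed, monitored_groups, reference_pair, detection_limit)
    return restraints, flagged


def fit_and_classify(topology: Topology, peaks: pd.DataFrame,
                     reference_pair: tuple[str, str] = ("H_W", "H_MN"),
                     config: CalibrationConfig = CalibrationConfig(),
                     classify_config: ClassifyConfig = ClassifyConfig(),
                     monitored_groups: list[str] | None = None,
                     detection_limit: float = 5.0, seed: int = 0,
                     n_starts: int = 8, maxfev: int = 400) -> PeakFitResult:
    """Run the full peak-table → conformation-label pipeline."""
    if monitored_groups is None:
        monitored_groups = [g for g in DEFAULT_MONITORED_GROUPS
                            if g in topology.proton_groups]
    restraints, flagged = restraints_from_peaks(
        peaks, reference_pair, config, monitored_groups, detection_limit)
    fit = fit_conformer(topology, restraints, seed=seed, n_starts=n_starts,
                        maxfev=maxfev)
    cls = classify_conformation(fit.conformer, classify_config)
    return PeakFitResult(restraints, flagged, fit, cls)
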