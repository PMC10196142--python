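"""Published group-level summaries of the through-device inhalation study.

The clinical study this package models recruited healthy controls
(n = 17), stable COPD patients (S-COPD, n = 13) and COPD patients during
an acute exacerbation (AE-COPD, n = 12).  Each subject performed two
through-device inhalation maneuvers per device (a pressurized
metered-dose inhaler shared by Foster and Trimbow, and the Respimat soft
mist inhaler), and pulmonary / extrathoracic deposition was computed
from each maneuver.  Only group-level summaries were published:
maneuver statistics (mean ± SEM), lung-function percentages of
predicted, and the Bland–Altman repeatability table (bias, p, 95 % LoA,
CR for every group × site × device cell).

Those printed summaries are the only quantitative anchor available, so
they are shipped here as plain data:

* :data:`MANEUVER_STATS` drives the synthetic cohort generator,
* :data:`LUNG_FUNCTION_STATS` + :data:`REFERENCE_VOLUMES` give lung
  volumes in liters,
* :data:`REPEATABILITY_TABLE` is used to validate the Bland–Altman /
  coefficient-of-repeatability arithmetic against 18 independent rows.
"""

from __future__ import annotations

from dataclasses import dataclass

GROUPS = ("Control", "S-COPD", "AE-COPD")
GROUP_SIZES = {"Control": 17, "S-COPD": 13, "AE-COPD": 12}

#: Devices as simulated products. Foster and Trimbow share one physical
#: pMDI maneuver (a single placebo pMDI was used for both in the study).
DEVICES = ("Foster_pMDI", "Trimbow_pMDI", "Spiriva_Respimat")

#: Maneuver class measured at the mouth: the pMDI maneuver feeds both
#: pMDI products, the Respimat maneuver feeds the SMI.
DEVICE_CLASS = {
    "Foster_pMDI": "pMDI",
    "Trimbow_pMDI": "pMDI",
    "Spiriva_Respimat": "Respimat",
}

#: (group, maneuver class) -> parameter -> (mean, SEM).
#: ivc_d in L, pif_d in L/s, t_in and t_bh in s.
MANEUVER_STATS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("Control", "pMDI"): {
        "ivc_d": (3.36, 0.22),
        "pif_d": (2.61, 0.22),
        "t_in": (2.23, 0.22),
        "t_bh": (9.95, 0.12),
    },
    ("Control", "Respimat"): {
        "ivc_d": (3.61, 0.21),
        "pif_d": (2.19, 0.15),
        "t_in": (2.51, 0.23),
        "t_bh": (9.93, 0.16),
    },
    ("S-COPD", "pMDI"): {
        "ivc_d": (2.23, 0.17),
        "pif_d": (1.80, 0.16),
        "t_in": (2.44, 0.26),
        "t_bh": (10.39, 0.10),
    },
    ("S-COPD", "Respimat"): {
        "ivc_d": (2.29, 0.21),
        "pif_d": (1.48, 0.14),
        "t_in": (2.57, 0.27),
        "t_bh": (10.57, 0.18),
    },
    ("AE-COPD", "pMDI"): {
        "ivc_d": (2.06, 0.23),
        "pif_d": (1.79, 0.13),
        "t_in": (2.30, 0.28),
        "t_bh": (9.55, 0.16),
    },
    ("AE-COPD", "Respimat"): {
        "ivc_d": (2.18, 0.21),
        "pif_d": (1.48, 0.12),
        "t_in": (2.52, 0.26),
        "t_bh": (9.44, 0.40),
    },
}

#: group -> parameter -> (mean, SEM), in % of predicted.
LUNG_FUNCTION_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "Control": {"rv_pct": (83, 6), "tlc_pct": (93, 2), "tgv_pct": (119, 5)},
    "S-COPD": {"rv_pct": (152, 15), "tlc_pct": (103, 5), "tgv_pct": (168, 11)},
    "AE-COPD": {"rv_pct": (192, 19), "tlc_pct": (113, 8), "tgv_pct": (193, 15)},
}

#: Predicted absolute volumes (L) used to convert % predicted to liters.
#: Standard adult reference scale; configurable in the cohort config.
REFERENCE_VOLUMES = {"rv": 1.8, "tlc": 6.0, "frc": 3.0}


@dataclass(frozen=True)
class RepeatabilityRow:
    """One published repeatability cell: group x site x device."""

    group: str
    site: str  # "lung" or "et"
    device: str
    n: int
    bias: float
    p: float
    loa_low: float
    loa_high: float
    cr: float


REPEATABILITY_TABLE: list[RepeatabilityRow] = [
    RepeatabilityRow("Control", "lung", "Foster_pMDI", 17, 0.80, 0.02, -1.68, 3.28, 2.87),
    RepeatabilityRow("Control", "lung", "Trimbow_pMDI", 17, 0.70, 0.005, -1.21, 2.61, 2.31),
    RepeatabilityRow("Control", "lung", "Spiriva_Respimat", 17, 1.19, 0.13, -4.86, 7.23, 6.31),
    RepeatabilityRow("Control", "et", "Foster_pMDI", 17, -0.50, 0.046, -2.35, 1.36, 2.05),
    RepeatabilityRow("Control", "et", "Trimbow_pMDI", 17, -0.59, 0.032, -2.62, 1.44, 2.29),
    RepeatabilityRow("Control", "et", "Spiriva_Respimat", 17, -1.35, 0.12, -7.93, 5.22, 6.91),
    RepeatabilityRow("S-COPD", "lung", "Foster_pMDI", 13, -0.89, 0.42, -8.45, 6.67, 7.47),
    RepeatabilityRow("S-COPD", "lung", "Trimbow_pMDI", 13, -1.62, 0.38, -14.20, 10.91, 12.46),
    RepeatabilityRow("S-COPD", "lung", "Spiriva_Respimat", 13, 0.25, 0.83, -7.89, 8.39, 7.84),
    RepeatabilityRow("S-COPD", "et", "Foster_pMDI", 13, 0.89, 0.46, -7.32, 9.11, 8.08),
    RepeatabilityRow("S-COPD", "et", "Trimbow_pMDI", 13, 1.31, 0.26, -6.46, 9.08, 7.90),
    RepeatabilityRow("S-COPD", "et", "Spiriva_Respimat", 13, -1.17, 0.51, -13.28, 10.94, 11.86),
    RepeatabilityRow("AE-COPD", "lung", "Foster_pMDI", 12, 1.91, 0.23, -8.24, 12.06, 10.42),
    RepeatabilityRow("AE-COPD", "lung", "Trimbow_pMDI", 12, 1.80, 0.27, -8.78, 12.38, 10.72),
    RepeatabilityRow("AE-COPD", "lung", "Spiriva_Respimat", 12, 0.72, 0.58, -7.77, 9.21, 8.25),
    RepeatabilityRow("AE-COPD", "et", "Foster_pMDI", 12, -2.06, 0.24, -13.22, 9.10, 11.42),
    RepeatabilityRow("AE-COPD", "et", "Trimbow_pMDI", 12, -2.07, 0.25, -13.57, 9.43, 11.74),
    RepeatabilityRow("AE-COPD", "et", "Spiriva_Respimat", 12, -0.93, 0.52, -10.34, 8.47, 9.19),
]


def group_mean_maneuver(group: str, device: str) -> dict[str, float]:
    """Group-mean maneuver parameters for one simulated product."""
    stats = MANEUVER_STATS[(group, DEVICE_CLASS[device])]
    return {name: mean for name, (mean, _sem) in stats.items()}


def group_mean_lung_volumes(group: str) -> dict[str, float]:
    """Group-mean RV/TLC/FRC in liters from % predicted."""
    lf = LUNG_FUNCTION_STATS[group]
    return {
        "rv": lf["rv_pct"][0] / 100.0 * REFERENCE_VOLUMES["rv"],
        "tlc": lf["tlc_pct"][0] / 100.0 * REFERENCE_VOLUMES["tlc"],
        "frc": lf["tgv_pct"][0] / 100.0 * REFERENCE_VOLUMES["frc"],
    }
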