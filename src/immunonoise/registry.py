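"""Canonical registry of the 28 immunologic parameters of the study cohort.

Each entry records, per patient group (EOP = early-onset periodontitis,
LOP = late-onset periodontitis, VALIDATION = EOP-suspected validation
cohort), the published median, mean and sample standard deviation, in the
units the assays were reported in (neutrophil counts, lymphocyte subset
percentages, cytokine pg/ml, thymidine-uptake dpm x 1e-4, and ELISA units
for serum IgG titers against periodontal bacteria, which may be negative).

Files may use either the canonical short names or the display names; the
cohort reader normalizes both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

GROUPS = ("EOP", "LOP", "VALIDATION")

#: discovery-cohort group sizes and validation-cohort size
GROUP_SIZES = {"EOP": 68, "LOP": 43, "VALIDATION": 51}


@dataclass(frozen=True)
class GroupMoments:
    median: float
    mean: float
    sd: float


@dataclass(frozen=True)
class ParameterRecord:
    name: str
    display: str
    unit: str
    moments: Mapping[str, GroupMoments]  # keyed by group label


def _rec(name, display, unit, lop, eop, val):
    return ParameterRecord(
        name=name,
        display=display,
        unit=unit,
        moments={
            "LOP": GroupMoments(*lop),
            "EOP": GroupMoments(*eop),
            "VALIDATION": GroupMoments(*val),
        },
    )


# (median, mean, sd) triplets per group.
PARAMETER_TABLE: tuple[ParameterRecord, ...] = (
    _rec("chemotaxis", "Neutrophil chemotaxis", "cells",
         (52.60, 56.64, 28.74), (42.15, 44.71, 17.84), (42.00, 40.17, 15.65)),
    _rec("phagocytosis", "Neutrophil phagocytosis", "bacteria/100 cells",
         (4.27, 4.83, 3.25), (2.84, 6.89, 17.95), (4.33, 4.91, 2.32)),
    _rec("adhesion", "Leukocyte adhesion", "cells",
         (71.19, 71.76, 7.77), (60.41, 60.22, 19.24), (70.20, 69.20, 8.33)),
    _rec("CD3_pct", "CD3 lymphocytes", "%",
         (74.00, 61.03, 9.70), (65.70, 65.09, 12.05), (65.20, 62.31, 13.35)),
    _rec("CD4_pct", "CD4 lymphocytes", "%",
         (39.00, 41.63, 7.51), (36.60, 37.28, 10.98), (39.40, 38.16, 9.26)),
    _rec("CD8_pct", "CD8 lymphocytes", "%",
         (28.60, 29.07, 6.62), (25.80, 25.02, 6.09), (21.60, 24.06, 6.49)),
    _rec("CD20_pct", "CD20 lymphocytes", "%",
         (12.30, 16.38, 9.33), (9.95, 13.13, 4.41), (10.90, 11.08, 7.82)),
    _rec("CD4_CD8_ratio", "CD4/CD8 ratio", "ratio",
         (2.40, 2.38, 0.86), (1.42, 1.62, 0.76), (1.60, 1.70, 0.62)),
    _rec("IL1", "Monocytic IL-1 production", "pg/ml",
         (3.50, 5.32, 3.83), (99.00, 436.72, 897.76), (114.50, 422.38, 813.33)),
    _rec("IL2", "Monocytic IL-2 production", "pg/ml",
         (80.00, 118.40, 104.59), (3.40, 3.56, 1.94), (3.80, 8.42, 19.21)),
    _rec("IL4", "Monocytic IL-4 production", "pg/ml",
         (3.90, 4.30, 3.88), (7.80, 9.01, 6.70), (7.70, 7.93, 2.25)),
    _rec("IL6", "Monocytic IL-6 production", "pg/ml",
         (473.00, 503.20, 616.80), (100.00, 1957.74, 4944.28),
         (242.00, 2089.50, 4083.09)),
    _rec("TNFa", "Monocytic TNF-alpha production", "pg/ml",
         (16.65, 42.93, 54.48), (274.70, 358.20, 383.60),
         (437.50, 712.83, 628.82)),
    _rec("IFNg", "Monocytic IFN-gamma production", "pg/ml",
         (9.70, 11.41, 6.01), (32.30, 109.27, 232.45), (12.35, 11.87, 5.52)),
    _rec("antiCD3_blastogenesis", "T-cell blastogenesis (anti-CD3)",
         "dpm x 1e-4",
         (13.90, 15.96, 3.14), (8.90, 12.96, 11.63), (13.50, 13.54, 5.79)),
    _rec("PWM_blastogenesis", "T-cell blastogenesis (PWM)", "dpm x 1e-4",
         (6.50, 7.48, 4.59), (5.60, 8.39, 7.65), (8.60, 9.77, 6.36)),
    _rec("IgG_Aa_Y4", "IgG A.a. (Y4)", "ELISA units",
         (0.57, 0.67, 2.51), (0.33, 0.43, 1.12), (-0.60, 1.05, 3.43)),
    _rec("IgG_Aa_ATCC29523", "IgG A.a. (ATCC29523)", "ELISA units",
         (0.40, 0.84, 1.08), (0.21, 1.36, 2.88), (0.07, 4.84, 23.84)),
    _rec("IgG_Aa_SUNY67", "IgG A.a. (SUNY67)", "ELISA units",
         (0.68, 0.51, 0.49), (0.54, 1.42, 2.59), (-0.18, 0.21, 0.84)),
    _rec("IgG_Co_S3", "IgG C.o. (S3)", "ELISA units",
         (0.24, 0.01, 0.40), (-0.09, 0.11, 0.45), (1.00, 0.76, 5.96)),
    _rec("IgG_Ec_ATCC23834", "IgG E.c. (ATCC23834)", "ELISA units",
         (0.08, 0.22, 0.48), (0.45, 1.04, 1.95), (-0.11, 0.11, 0.41)),
    _rec("IgG_Fn_ATCC25586", "IgG F.n. (ATCC25586)", "ELISA units",
         (-0.06, 0.68, 4.74), (0.33, 3.70, 9.71), (-0.04, 1.06, 4.07)),
    _rec("IgG_Pi_ATCC25611", "IgG P.i. (ATCC25611)", "ELISA units",
         (-0.17, -0.27, 0.18), (-0.15, 0.41, 1.61), (-0.13, -0.01, 0.46)),
    _rec("IgG_Pn_ATCC33563", "IgG P.n. (ATCC33563)", "ELISA units",
         (0.60, 0.26, 1.16), (0.15, 0.53, 1.56), (0.45, 0.30, 0.95)),
    _rec("IgG_Pg_FDC381", "IgG P.g. (FDC381)", "ELISA units",
         (1.59, 4.19, 4.90), (2.98, 7.84, 218.07), (1.54, 6.31, 12.73)),
    _rec("IgG_Pg_SU63", "IgG P.g. (SU63)", "ELISA units",
         (0.52, 2.23, 4.35), (1.41, 6.41, 19.58), (1.01, 2.18, 4.65)),
    _rec("IgG_Td_ATCC35405", "IgG T.d. (ATCC35405)", "ELISA units",
         (-0.05, 0.12, 0.39), (0.23, 0.93, 1.85), (1.27, 0.63, 1.60)),
    _rec("IgG_Ws_ATCC29543", "IgG W.s. (ATCC29543)", "ELISA units",
         (0.37, 0.88, 0.99), (0.33, 14.72, 56.08), (0.35, 5.60, 14.31)),
)

PARAMETER_NAMES: tuple[str, ...] = tuple(r.name for r in PARAMETER_TABLE)

_BY_NAME = {r.name: r for r in PARAMETER_TABLE}
_BY_DISPLAY = {r.display: r.name for r in PARAMETER_TABLE}


def get_parameter(name: str) -> ParameterRecord:
    """Look up a registry record by canonical or display name."""
    key = canonical_name(name)
    return _BY_NAME[key]


def canonical_name(name: str) -> str:
    """Map a canonical or display parameter name to its canonical form.

    Raises KeyError for names outside the registry.
    """
    if name in _BY_NAME:
        return name
    if name in _BY_DISPLAY:
        return _BY_DISPLAY[name]
    raise KeyError(f"unknown parameter name: {name!r}")
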