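"""Published per-animal study inputs used for the volume-agreement analysis.

Four piglets underwent focused-ultrasound ablation of the anterior fornix
with a 4 mm x 10 mm sonication cell.  Lesion volumes were measured twice:
from serial histological sections (area per slide x 200-micron thickness,
summed) and from the thresholded post-treatment MDWI lesion core.  These
printed per-animal values are the inputs to the cohort-level statistics
(paired t-test of the two volume measurements, lesion-to-cell volume ratio,
cohort weight summary).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segmentation import TreatmentCell, treatment_cell_volume
from .stats import StatsResult, paired_t_test

__all__ = [
    "cohort_table",
    "TREATMENT_CELL",
    "volume_agreement_test",
    "lesion_to_cell_ratio",
    "mean_weight",
]

TREATMENT_CELL = TreatmentCell(cross_diameter=4.0, length=10.0)


def cohort_table() -> pd.DataFrame:
    """Per-animal weights and the two lesion-volume measurements (mm^3)."""
    return pd.DataFrame(
        {
            "pig": [1, 2, 3, 4],
            "weight_kg": [5.0, 6.7, 5.3, 6.3],
            "histology_volume_mm3": [315.0, 418.0, 297.0, 351.0],
            "mdwi_core_volume_mm3": [302.0, 432.0, 337.0, 319.0],
        }
    )


def volume_agreement_test(table: pd.DataFrame | None = None) -> StatsResult:
    """Paired t-test: histological vs MDWI lesion-core volumes."""
    t = cohort_table() if table is None else table
    return paired_t_test(t["histology_volume_mm3"], t["mdwi_core_volume_mm3"])


def lesion_to_cell_ratio(table: pd.DataFrame | None = None) -> float:
    """Mean MDWI lesion volume divided by the sonication-cell volume."""
    t = cohort_table() if table is None else table
    return float(t["mdwi_core_volume_mm3"].mean() / treatment_cell_volume(TREATMENT_CELL))


def mean_weight(table: pd.DataFrame | None = None) -> float:
    """Cohort mean body weight (kg)."""
    t = cohort_table() if table is None else table
    return float(np.mean(t["weight_kg"]))
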