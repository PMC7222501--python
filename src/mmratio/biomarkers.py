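"""Cross-cohort harmonization of amyloid and FDG biomarkers.

Amyloid SUVr values are acquired and processed differently per cohort, so raw
values are not comparable. Harmonization divides each participant's SUVr by
the cohort's amyloid-positivity threshold: on the normalized scale, any value
above 1 is amyloid-positive in every cohort. Default thresholds: 0.79 for
INSIGHT-PreAD, 1.11 for ADNI; other cohorts must declare theirs.

FDG metabolism has no established cutoff; the meta-ROI mean (posterior
cingulate, inferior parietal lobule, precuneus, inferior temporal gyrus) is
instead standardized within each cohort (intra-cohort z-score).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import AMYLOID_COLUMN, FDG_COLUMN, CohortTable
from .errors import ConfigurationError, ValidationError
from .residualize import standardize

#: cohort-dialect positivity thresholds (native SUVr scale)
DEFAULT_THRESHOLDS = {"INSIGHT-PreAD": 0.79, "ADNI": 1.11}

#: AD-signature FDG regions averaged into the meta-ROI
AD_META_ROI_REGIONS = (
    "posterior_cingulate",
    "inferior_parietal",
    "precuneus",
    "inferior_temporal",
)


def normalize_suvr(suvr, threshold: float):
    """Divide raw SUVr by the cohort positivity threshold.

    Returns SUVr on the harmonized scale where values >= 1 are
    amyloid-positive. Strictly monotone in ``suvr`` and scale-free:
    ``normalize_suvr(a*s, a*t) == normalize_suvr(s, t)``.
    """
    x = np.asarray(suvr, dtype=float)
    if not np.all(x > 0):
        raise ValidationError("SUVr values must be strictly positive")
    if not threshold > 0:
        raise ValidationError(f"positivity threshold must be positive, got {threshold}")
    out = x / float(threshold)
    return float(out) if np.isscalar(suvr) or out.ndim == 0 else out


def amyloid_positive(suvr_norm) -> np.ndarray:
    """Positivity flag on the normalized scale (>= 1 is positive)."""
    return np.asarray(suvr_norm, dtype=float) >= 1.0


def fdg_meta_roi(region_means, regions: tuple[str, ...] = AD_META_ROI_REGIONS):
    """Average per-region FDG uptake into the meta-ROI mean.

    Accepts one row (vector of ``len(regions)`` values) or a 2-d array /
    DataFrame of rows × regions; permutation of regions does not change the
    result.
    """
    if isinstance(region_means, pd.DataFrame):
        missing = [r for r in regions if r not in region_means.columns]
        if missing:
            raise ValidationError(f"missing FDG region column(s): {missing}")
        values = region_means[list(regions)].to_numpy(dtype=float)
    else:
        values = np.asarray(region_means, dtype=float)
    if values.ndim == 1:
        if values.size != len(regions):
            raise ValidationError(
                f"expected {len(regions)} region values, got {values.size}"
            )
        if not np.isfinite(values).all():
            raise ValidationError("FDG region values must be finite")
        return float(values.mean())
    if values.shape[1] != len(regions):
        raise ValidationError(
            f"expected {len(regions)} region columns, got {values.shape[1]}"
        )
    if not np.isfinite(values).all():
        raise ValidationError("FDG region values must be finite")
    return values.mean(axis=1)


def standardize_fdg(values) -> np.ndarray:
    """Intra-cohort z-score of the FDG meta-ROI (mean 0, sample sd 1).

    Shares the z-scoring convention (n−1 denominator) used for score
    residuals. Must be applied per cohort: concatenating independently
    standardized cohorts does not generally give sd 1.
    """
    return standardize(values)


@dataclass
class BiomarkerPanel:
    """Harmonized biomarkers for one cohort.

    ``frame`` columns: ``suvr_norm`` (> 1 ⇒ amyloid-positive),
    ``amyloid_positive`` (bool), ``fdg_z`` (within-cohort mean 0, sd 1).
    """

    cohort_id: str
    threshold: float
    frame: pd.DataFrame


def harmonize(table: CohortTable, threshold: float | None = None) -> BiomarkerPanel:
    """Build the harmonized biomarker panel for one cohort table.

    ``threshold`` defaults to the cohort's entry in
    :data:`DEFAULT_THRESHOLDS`; unknown cohorts must pass one explicitly.
    """
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS.get(table.cohort_id)
        if threshold is None:
            raise ConfigurationError(
                f"no default amyloid positivity threshold for cohort {table.cohort_id!r}; "
                "declare one explicitly"
            )
    suvr_norm = normalize_suvr(table.data[AMYLOID_COLUMN].to_numpy(), threshold)
    fdg_z = standardize_fdg(table.data[FDG_COLUMN].to_numpy())
    frame = pd.DataFrame(
        {
            "suvr_norm": suvr_norm,
            "amyloid_positive": amyloid_positive(suvr_norm),
            "fdg_z": fdg_z,
        },
        index=table.data.index,
    )
    return BiomarkerPanel(cohort_id=table.cohort_id, threshold=float(threshold), frame=frame)
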