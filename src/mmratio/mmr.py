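"""The meta-memory ratio (MMR).

The MMR quantifies awareness of cognitive decline as the sum of two
standardized, demographically residualized quantities:

* an **objective composite** O — the mean of the z-scored score residuals for
  every objective memory test, each oriented so that higher always means
  better measured memory (error/intrusion counts are sign-flipped);
* a **subjective composite** S — likewise for complaint measures, oriented so
  that higher always means more complaint.

``mmr = O + S``. By construction an MMR near 0 means the complaint matches
the measured performance (accurate awareness); strongly positive values mean
complaint in excess of measured decline (subjective cognitive decline);
strongly negative values mean decline in excess of complaint (low awareness).
Within a cohort the MMR has mean 0 because it is a sum of averages of
zero-mean columns; it is deliberately *not* re-standardized, so its spread
carries information.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .errors import ConfigurationError, ValidationError
from .registry import Registry, ScoreSpec
from .residualize import ResidualMatrix, residualize_cohort


def orient(z, spec: ScoreSpec) -> np.ndarray:
    """Orient one standardized column according to its declared direction.

    ``higher_worse`` objective scores are sign-flipped so that, after
    orientation, higher always means better performance; subjective scores
    (``higher_more_complaint``) pass through unchanged. Orientation is an
    involution: applying the flip twice restores the input.
    """
    x = np.asarray(z, dtype=float)
    if spec.direction in ("higher_better", "higher_more_complaint"):
        return x.copy()
    if spec.direction == "higher_worse":
        return -x
    raise ConfigurationError(f"score {spec.name!r}: unknown direction {spec.direction!r}")


def composite(residuals: ResidualMatrix, registry: Registry, role: str) -> pd.Series:
    """Row-wise mean of the oriented z-columns of one role.

    With a single column of the requested role the composite equals that
    (oriented) column — the single-score MMR variant.
    """
    specs = [s for s in registry.scores if s.role == role]
    if not specs:
        raise ConfigurationError(f"registry declares no {role!r} scores")
    oriented = np.column_stack([orient(residuals.z[s.name], s) for s in specs])
    return pd.Series(oriented.mean(axis=1), index=residuals.z.index, name=role)


@dataclass
class MMRResult:
    """Per-participant composites and MMR for one cohort."""

    cohort_id: str
    frame: pd.DataFrame  # columns: objective, subjective, mmr

    @property
    def objective(self) -> pd.Series:
        return self.frame["objective"]

    @property
    def subjective(self) -> pd.Series:
        return self.frame["subjective"]

    @property
    def mmr(self) -> pd.Series:
        return self.frame["mmr"]


def compute_mmr(objective: pd.Series, subjective: pd.Series, cohort_id: str) -> MMRResult:
    """Sum the two composites into the MMR (``mmr = O + S``, row-wise)."""
    if len(objective) != len(subjective):
        raise ValidationError(
            f"cohort {cohort_id!r}: objective composite has {len(objective)} rows but "
            f"subjective has {len(subjective)}"
        )
    O = pd.Series(np.asarray(objective, dtype=float), index=objective.index, name="objective")
    S = pd.Series(np.asarray(subjective, dtype=float), index=objective.index, name="subjective")
    frame = pd.DataFrame({"objective": O, "subjective": S, "mmr": O + S})
    return MMRResult(cohort_id=cohort_id, frame=frame)


def cohort_mmr(table: CohortTable, residual_type: str = "response") -> MMRResult:
    """Full within-cohort MMR pipeline: residualize → orient → average → sum."""
    residuals = residualize_cohort(table, residual_type=residual_type)
    O = composite(residuals, table.registry, "objective")
    S = composite(residuals, table.registry, "subjective")
    return compute_mmr(O, S, table.cohort_id)


def write_mmr(result: MMRResult, path: str | Path) -> None:
    """Write participant id, cohort, O, S, mmr as CSV."""
    out = result.frame.copy()
    out.insert(0, "cohort", result.cohort_id)
    out.to_csv(path, index=True, index_label="participant_id")


def read_mmr(path: str | Path) -> MMRResult:
    """Read an MMR CSV written by :func:`write_mmr` (one cohort per file)."""
    df = pd.read_csv(path).set_index("participant_id")
    cohorts = df["cohort"].unique()
    if len(cohorts) != 1:
        raise ValidationError(f"{path}: expected one cohort per MMR file, found {list(cohorts)}")
    return MMRResult(cohort_id=str(cohorts[0]), frame=df[["objective", "subjective", "mmr"]])
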