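"""Cohort tables: validated per-participant data for one cohort.

A cohort table holds, per participant, the demographic covariates, every
registered score, and the two imaging biomarkers consumed downstream: an
amyloid-PET SUVr on the cohort's native scale and an FDG-PET meta-ROI mean.
The pipeline is complete-case: rows with any missing registered value are
dropped at ingest and the count reported. "Do not know" questionnaire answers
are treated as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .registry import Registry

AMYLOID_COLUMN = "amyloid_suvr"
FDG_COLUMN = "fdg_meta_roi"
ID_COLUMN = "participant_id"

#: strings treated as missing values on read ("do not know" questionnaire answers)
NA_STRINGS = ("", "NA", "NaN", "nan", "do not know", "Do not know", "DK")


@dataclass
class CohortTable:
    """Complete-case, bounds-validated participant table for one cohort.

    Attributes
    ----------
    cohort_id : cohort label (e.g. ``"ADNI"``).
    data : DataFrame indexed by participant id with demographic, score and
        biomarker columns.
    registry : the score registry the table was validated against.
    n_dropped : rows removed by the completeness filter at construction.
    """

    cohort_id: str
    data: pd.DataFrame
    registry: Registry
    n_dropped: int = 0
    source: str | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.data)

    def required_columns(self) -> tuple[str, ...]:
        demo = self.registry.demographics
        return (*demo.columns, *self.registry.score_names, AMYLOID_COLUMN, FDG_COLUMN)

    def demographic_design(self) -> pd.DataFrame:
        """Encoded (numeric) demographic covariates for this cohort."""
        return self.registry.demographics.encode(self.data)

    def validate(self) -> None:
        """Check column presence, completeness, bounds, and level counts."""
        for col in self.required_columns():
            if col not in self.data.columns:
                raise SchemaError(
                    f"cohort {self.cohort_id!r}: missing required column {col!r}"
                )
        registered = list(self.required_columns())
        if self.data[registered].isna().any().any():
            bad = self.data[registered].isna().any()
            raise ValidationError(
                f"cohort {self.cohort_id!r}: missing values remain in "
                f"{list(bad.index[bad])} after the completeness filter"
            )
        demo = self.registry.demographics
        age = pd.to_numeric(self.data[demo.age], errors="coerce")
        if not (age > 0).all():
            idx = self.data.index[~(age > 0)][0]
            raise ValidationError(
                f"cohort {self.cohort_id!r}, row {idx!r}: age must be strictly positive"
            )
        for col in (demo.gender,) + (() if demo.education_cutoff is not None else (demo.education,)):
            levels = self.data[col].astype(str).unique()
            if len(levels) > 2:
                raise ValidationError(
                    f"cohort {self.cohort_id!r}: column {col!r} has {len(levels)} levels "
                    f"({sorted(levels)}); at most two are allowed"
                )
        for spec in self.registry.scores:
            values = pd.to_numeric(self.data[spec.name], errors="coerce")
            if values.isna().any():
                idx = self.data.index[values.isna()][0]
                raise ValidationError(
                    f"cohort {self.cohort_id!r}, row {idx!r}: score {spec.name!r} "
                    "is not numeric"
                )
            if spec.min_value is not None and (values < spec.min_value).any():
                idx = self.data.index[values < spec.min_value][0]
                raise ValidationError(
                    f"cohort {self.cohort_id!r}, row {idx!r}: score {spec.name!r} value "
                    f"{values.loc[idx]} below declared minimum {spec.min_value}"
                )
            if spec.max_value is not None and (values > spec.max_value).any():
                idx = self.data.index[values > spec.max_value][0]
                raise ValidationError(
                    f"cohort {self.cohort_id!r}, row {idx!r}: score {spec.name!r} value "
                    f"{values.loc[idx]} above declared maximum {spec.max_value}"
                )
            if spec.family == "binomial":
                frac = values - np.floor(values)
                if (frac != 0).any():
                    idx = self.data.index[frac != 0][0]
                    raise ValidationError(
                        f"cohort {self.cohort_id!r}, row {idx!r}: binomial score "
                        f"{spec.name!r} must be integer-valued"
                    )
        for col in (AMYLOID_COLUMN, FDG_COLUMN):
            values = pd.to_numeric(self.data[col], errors="coerce")
            if not np.isfinite(values).all():
                idx = self.data.index[~np.isfinite(values)][0]
                raise ValidationError(
                    f"cohort {self.cohort_id!r}, row {idx!r}: {col!r} is not finite"
                )


def from_dataframe(
    df: pd.DataFrame, registry: Registry, cohort_id: str, source: str | None = None
) -> CohortTable:
    """Validate a raw DataFrame into a :class:`CohortTable`.

    Applies the complete-case filter over all registered columns (dropped-row
    count is recorded on the table) and then runs full validation.
    """
    df = df.copy()
    if ID_COLUMN in df.columns:
        df = df.set_index(ID_COLUMN)
    demo = registry.demographics
    required = (*demo.columns, *registry.score_names, AMYLOID_COLUMN, FDG_COLUMN)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"cohort {cohort_id!r}: missing required column {col!r}")
    n_before = len(df)
    kept = df.dropna(subset=list(required))
    table = CohortTable(
        cohort_id=cohort_id,
        data=kept,
        registry=registry,
        n_dropped=n_before - len(kept),
        source=source,
    )
    table.validate()
    return table


def read_cohort(
    path: str | Path,
    registry: Registry,
    cohort_id: str,
    fdg_regions: tuple[str, ...] | None = None,
) -> CohortTable:
    """Read and validate one cohort table from CSV/TSV.

    The delimiter is inferred from the extension (``.tsv`` → tab). If
    ``fdg_regions`` names per-region FDG columns, their row-wise mean becomes
    the meta-ROI column; otherwise a precomputed ``fdg_meta_roi`` column is
    required.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(
        path, sep=sep, na_values=list(NA_STRINGS), keep_default_na=True, skipinitialspace=True
    )
    if fdg_regions:
        for col in fdg_regions:
            if col not in df.columns:
                raise SchemaError(
                    f"cohort {cohort_id!r}: missing FDG region column {col!r}"
                )
        df[FDG_COLUMN] = df[list(fdg_regions)].mean(axis=1)
    return from_dataframe(df, registry, cohort_id, source=str(path))


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort table to CSV; round-trips exactly for finite numerics."""
    table.data.to_csv(path, index=True, index_label=ID_COLUMN)
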