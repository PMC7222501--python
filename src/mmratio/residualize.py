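"""Demographic residualization of registered scores.

Each score is regressed on age, gender and education with the GLM family its
registry entry declares — one fit per score per cohort, strictly
within-cohort, never pooled — and the residuals are z-scored so that scores
on arbitrary native scales become comparable. Residuals are "response"
residuals (observed − fitted mean) by default; the subsequent z-transformation
absorbs the scale, and response residuals are defined uniformly across
families. Deviance or Pearson residuals can be requested instead and the
choice is recorded in the fit metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable
from .errors import DegenerateInputError, EstimationError
from .registry import Registry, ScoreSpec

RESIDUAL_TYPES = ("response", "deviance", "pearson")
MIN_N = 10


def standardize(values, ddof: int = 1) -> np.ndarray:
    """z-score a vector: subtract the mean, divide by the sample sd (n−1).

    Raises :class:`DegenerateInputError` for vectors of length < 2 or with
    zero variance. Idempotent up to floating point: z(z(v)) == z(v).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise DegenerateInputError(f"expected a 1-d vector, got shape {x.shape}")
    if x.size < 2:
        raise DegenerateInputError(f"need at least 2 values to standardize, got {x.size}")
    if not np.isfinite(x).all():
        raise DegenerateInputError("cannot standardize non-finite values")
    sd = x.std(ddof=ddof)
    if sd == 0 or np.ptp(x) == 0:
        raise DegenerateInputError("cannot standardize a constant vector (zero variance)")
    return (x - x.mean()) / sd


def _design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Intercept + covariate design; constant covariates are dropped.

    A zero-variance covariate carries no demographic signal and is aliased
    with the intercept, so it is removed (and reported in the metadata)
    rather than treated as a rank failure. Genuine collinearity among the
    remaining columns raises, naming an aliased column.
    """
    kept, dropped = [], []
    for col in covariates.columns:
        if np.asarray(covariates[col], dtype=float).std() == 0:
            dropped.append(col)
        else:
            kept.append(col)
    X = np.column_stack(
        [np.ones(len(covariates))] + [np.asarray(covariates[c], dtype=float) for c in kept]
    )
    names = ["const"] + kept
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        for j in range(1, X.shape[1]):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise EstimationError(
                    f"design matrix is rank deficient: column {names[j]!r} is collinear "
                    "with the other covariates"
                )
        raise EstimationError("design matrix is rank deficient")
    return X, names, dropped


def fit_score_glm(
    scores,
    covariates: pd.DataFrame,
    spec: ScoreSpec,
    residual_type: str = "response",
) -> tuple[np.ndarray, dict]:
    """Fit one score's demographic GLM and return (residuals, fit metadata).

    Families: "linear" → Gaussian OLS on the raw score; "binomial" →
    (successes, failures) out of ``spec.n_trials`` with a logit link;
    "logistic" → Bernoulli on the binarized score (``value > binarize_gt``).
    Residuals are on the scale selected by ``residual_type``.
    """
    if residual_type not in RESIDUAL_TYPES:
        raise EstimationError(
            f"unknown residual type {residual_type!r}; allowed: {list(RESIDUAL_TYPES)}"
        )
    y = np.asarray(scores, dtype=float)
    n = y.size
    if n < MIN_N:
        raise EstimationError(f"score {spec.name!r}: need at least {MIN_N} rows, got {n}")
    if len(covariates) != n:
        raise EstimationError(
            f"score {spec.name!r}: {n} scores but {len(covariates)} covariate rows"
        )
    X, names, dropped = _design(covariates)
    meta = {
        "score": spec.name,
        "family": spec.family,
        "residual_type": residual_type,
        "n": int(n),
        "dropped_constant_covariates": dropped,
    }

    if spec.family == "linear":
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        meta["params"] = dict(zip(names, beta.tolist()))
        meta["converged"] = True
        # Gaussian response/deviance/pearson residuals coincide up to a
        # constant scale, which the z-step removes; return raw residuals.
        return resid, meta

    if y.std() == 0:
        raise EstimationError(
            f"score {spec.name!r}: degenerate fit — all values equal {y[0]} "
            f"({spec.family} family has no variation to model)"
        )

    if spec.family == "binomial":
        successes = y - float(spec.min_value)
        endog = np.column_stack([successes, spec.n_trials - successes])
    elif spec.family == "logistic":
        endog = (y > spec.binarize_gt).astype(float)
        if endog.std() == 0:
            raise EstimationError(
                f"score {spec.name!r}: logistic binarization (> {spec.binarize_gt}) "
                "produced a constant outcome"
            )
        meta["binarize_gt"] = spec.binarize_gt
    else:  # pragma: no cover - families validated by ScoreSpec
        raise EstimationError(f"score {spec.name!r}: unsupported family {spec.family!r}")

    model = sm.GLM(endog, X, family=sm.families.Binomial())
    maxiter = 200
    try:
        fit = model.fit(maxiter=maxiter)
    except Exception as exc:
        raise EstimationError(f"score {spec.name!r}: GLM fit failed: {exc}") from exc
    if not fit.converged:
        raise EstimationError(
            f"score {spec.name!r}: IRLS did not converge within {maxiter} iterations"
        )
    resid = {
        "response": np.asarray(fit.resid_response),
        "deviance": np.asarray(fit.resid_deviance),
        "pearson": np.asarray(fit.resid_pearson),
    }[residual_type]
    if not np.isfinite(resid).all() or resid.std() == 0:
        raise EstimationError(
            f"score {spec.name!r}: degenerate {spec.family} fit (separation or perfect fit)"
        )
    meta["params"] = dict(zip(names, np.asarray(fit.params).tolist()))
    meta["converged"] = bool(fit.converged)
    return resid, meta


@dataclass
class ResidualMatrix:
    """Standardized (z-scored) demographic residuals for one cohort.

    ``z`` has one column per registered score; each column has mean 0 and
    sample sd 1 within the cohort. ``fit_metadata`` maps score name to the
    per-fit record (family, coefficients, residual type used).
    """

    cohort_id: str
    z: pd.DataFrame
    fit_metadata: dict = field(default_factory=dict)

    def metadata_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.fit_metadata, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def residualize_cohort(
    table: CohortTable,
    registry: Registry | None = None,
    residual_type: str = "response",
) -> ResidualMatrix:
    """Residualize every registered score within one cohort.

    Fits are performed strictly within-cohort; estimation failures propagate
    annotated with the score name.
    """
    registry = registry if registry is not None else table.registry
    covariates = registry.demographics.encode(table.data)
    columns: dict[str, np.ndarray] = {}
    metadata: dict[str, dict] = {}
    for spec in registry.scores:
        resid, meta = fit_score_glm(
            table.data[spec.name], covariates, spec, residual_type=residual_type
        )
        try:
            columns[spec.name] = standardize(resid)
        except DegenerateInputError as exc:
            raise EstimationError(f"score {spec.name!r}: {exc}") from exc
        metadata[spec.name] = meta
    z = pd.DataFrame(columns, index=table.data.index)
    return ResidualMatrix(cohort_id=table.cohort_id, z=z, fit_metadata=metadata)
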