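"""Inference on the MMR: quadratic-amyloid regression, type-II LRTs, diagnostics.

The headline model is an ordinary least squares fit of the MMR on demographic
covariates, cohort, and the harmonized biomarkers, with a quadratic term for
normalized amyloid SUVr and cohort/biomarker interactions::

    mmr ~ age + gender + education + cohort + fdg + av45 + av45^2
          + av45:fdg + av45:cohort + fdg:cohort

The quadratic enters as a raw square (no centering or orthogonal
polynomials): the fitted vertex −b_lin/(2·b_quad) is then interpretable
directly on the normalized-SUVr axis, where 1 is the amyloid-positivity
boundary.

Terms are tested with type-II likelihood-ratio tests: each term is compared
against the model containing all *other* terms, respecting marginality — a
main effect is tested in models that exclude its interactions, and the linear
and squared amyloid terms are tested jointly as one 2-df effect. Effect sizes
are Cohen's f² from the same nested pair. Per-observation influence
(Cook's distance, hat values) is exposed for outlier screening.

Also here: Welch's t from summary statistics and the Yates-corrected 2×2 χ²
used for cohort-description tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .biomarkers import BiomarkerPanel
from .cohort import CohortTable
from .errors import (
    ContractViolationError,
    DegenerateInputError,
    EstimationError,
    ValidationError,
)
from .mmr import MMRResult

MAIN_TERMS = ("age", "gender", "education", "cohort", "fdg", "av45")
INTERACTION_TERMS = ("av45:fdg", "av45:cohort", "fdg:cohort")
ALL_TERMS = MAIN_TERMS + INTERACTION_TERMS

_REQUIRED_COLUMNS = ("mmr", "age", "gender", "education", "cohort", "suvr_norm", "fdg_z")


def build_model_frame(
    tables: Iterable[CohortTable],
    results: Iterable[MMRResult],
    panels: Iterable[BiomarkerPanel],
) -> pd.DataFrame:
    """Merge per-cohort MMR results, biomarker panels and demographics.

    Returns the cross-cohort analysis frame with columns ``mmr``, ``age``,
    ``gender`` / ``education`` (0/1 indicators, reference level 0),
    ``cohort`` (label) and the harmonized biomarkers.
    """
    by_id = {t.cohort_id: t for t in tables}
    res = {r.cohort_id: r for r in results}
    pan = {p.cohort_id: p for p in panels}
    if set(by_id) != set(res) or set(by_id) != set(pan):
        raise ValidationError(
            f"cohort sets differ: tables={sorted(by_id)}, mmr={sorted(res)}, "
            f"biomarkers={sorted(pan)}"
        )
    pieces = []
    for cid, table in by_id.items():
        demo = table.demographic_design()
        frame = pd.DataFrame(
            {
                "mmr": res[cid].mmr,
                "age": demo["age"],
                "gender": demo["gender"],
                "education": demo["education"],
                "cohort": cid,
                "suvr_norm": pan[cid].frame["suvr_norm"],
                "fdg_z": pan[cid].frame["fdg_z"],
            }
        )
        if frame.isna().any().any():
            bad = sorted(set(res[cid].mmr.index) ^ set(table.data.index))
            raise ValidationError(
                f"cohort {cid!r}: participant ids do not align across inputs: {bad[:10]}"
            )
        pieces.append(frame)
    return pd.concat(pieces, axis=0)


# ---------------------------------------------------------------------------
# design construction


def _prepare(data: pd.DataFrame, cohort_reference: str | None) -> tuple[pd.DataFrame, dict]:
    for col in _REQUIRED_COLUMNS:
        if col not in data.columns:
            raise ValidationError(f"model frame is missing column {col!r}")
    levels = sorted(map(str, pd.unique(data["cohort"].astype(str))))
    if len(levels) > 2:
        raise EstimationError(f"at most two cohorts supported, got {levels}")
    if cohort_reference is None:
        # Prefer INSIGHT-PreAD as reference so the contrast matches the
        # conventional "ADNI vs INSIGHT" reporting; otherwise first sorted.
        cohort_reference = "INSIGHT-PreAD" if "INSIGHT-PreAD" in levels else levels[0]
    elif cohort_reference not in levels:
        raise ValidationError(
            f"cohort_reference {cohort_reference!r} not among cohort levels {levels}"
        )
    contrast = [lv for lv in levels if lv != cohort_reference]
    prep = pd.DataFrame(
        {
            "age": pd.to_numeric(data["age"]).astype(float),
            "gender": pd.to_numeric(data["gender"]).astype(float),
            "education": pd.to_numeric(data["education"]).astype(float),
            "cohort": (data["cohort"].astype(str) != cohort_reference).astype(float),
            "fdg": pd.to_numeric(data["fdg_z"]).astype(float),
            "av45": pd.to_numeric(data["suvr_norm"]).astype(float),
        },
        index=data.index,
    )
    prep["av45_sq"] = prep["av45"] ** 2
    prep["av45:fdg"] = prep["av45"] * prep["fdg"]
    prep["av45:cohort"] = prep["av45"] * prep["cohort"]
    prep["fdg:cohort"] = prep["fdg"] * prep["cohort"]
    info = {
        "cohort_levels": levels,
        "cohort_reference": cohort_reference,
        "cohort_contrast": contrast[0] if contrast else None,
    }
    return prep, info


def _term_columns(term: str, quadratic: bool) -> list[str]:
    if term == "av45":
        return ["av45", "av45_sq"] if quadratic else ["av45"]
    if term in MAIN_TERMS or term in INTERACTION_TERMS:
        return [term]
    raise ValidationError(f"unknown model term {term!r}; known terms: {list(ALL_TERMS)}")


def _design(prep: pd.DataFrame, terms: Sequence[str], quadratic: bool) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"const": np.ones(len(prep))}
    for term in terms:
        for c in _term_columns(term, quadratic):
            cols[c] = prep[c].to_numpy()
    return pd.DataFrame(cols, index=prep.index)


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = []
        for j, name in enumerate(X.columns):
            if name == "const":
                continue
            if np.linalg.matrix_rank(np.delete(X.to_numpy(), j, axis=1)) == rank:
                aliased.append(name)
        raise EstimationError(f"model design is rank deficient; aliased term(s): {aliased}")


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, X).fit()


def _marginality_check(terms_kept: Sequence[str], terms_dropped: Sequence[str]) -> None:
    for dropped in terms_dropped:
        if ":" in dropped:
            continue
        for kept in terms_kept:
            if ":" in kept and dropped in kept.split(":"):
                raise ContractViolationError(
                    f"cannot test {dropped!r} while retaining its interaction {kept!r}: "
                    "type-II marginality requires excluding interactions that contain "
                    "the tested main effect"
                )


class LRTResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def lrt_compare(
    data: pd.DataFrame,
    full_terms: Sequence[str],
    reduced_terms: Sequence[str],
    include_quadratic: bool = True,
    cohort_reference: str | None = None,
) -> LRTResult:
    """Likelihood-ratio test between two explicitly nested term sets.

    Raises :class:`ContractViolationError` if a dropped main effect appears
    inside a retained interaction (marginality violation).
    """
    full_terms, reduced_terms = list(full_terms), list(reduced_terms)
    extra = set(reduced_terms) - set(full_terms)
    if extra:
        raise ContractViolationError(f"reduced model is not nested in full: extra terms {sorted(extra)}")
    dropped = [t for t in full_terms if t not in reduced_terms]
    _marginality_check(reduced_terms, dropped)
    prep, _ = _prepare(data, cohort_reference)
    y = pd.to_numeric(data["mmr"]).to_numpy(dtype=float)
    X_full = _design(prep, full_terms, include_quadratic)
    X_red = _design(prep, reduced_terms, include_quadratic)
    fit_full, fit_red = _ols(y, X_full), _ols(y, X_red)
    stat = 2.0 * (fit_full.llf - fit_red.llf)
    stat = max(stat, 0.0)
    df = X_full.shape[1] - X_red.shape[1]
    if df == 0:
        return LRTResult(0.0, 0, 1.0)
    return LRTResult(float(stat), int(df), float(st.chi2.sf(stat, df)))


def _type2_pair(term: str, terms: Sequence[str]) -> tuple[list[str], list[str]]:
    """(comparison, reduced) term sets for the type-II test of ``term``."""
    terms = list(terms)
    if term not in terms:
        raise ValidationError(f"term {term!r} not in model terms {terms}")
    if ":" in term:
        comparison = terms
    else:
        comparison = [t for t in terms if not (":" in t and term in t.split(":"))]
    reduced = [t for t in comparison if t != term]
    return comparison, reduced


def lrt_type2(
    data: pd.DataFrame,
    term: str,
    terms: Sequence[str] = ALL_TERMS,
    include_quadratic: bool = True,
    cohort_reference: str | None = None,
) -> LRTResult:
    """Type-II likelihood-ratio test of one model term.

    The tested term is dropped from the model containing all other terms;
    marginality is respected by excluding interactions that contain a tested
    main effect from both sides. With the quadratic enabled the ``av45`` term
    is the joint (linear + squared) 2-df effect.
    """
    comparison, reduced = _type2_pair(term, terms)
    return lrt_compare(
        data, comparison, reduced,
        include_quadratic=include_quadratic, cohort_reference=cohort_reference,
    )


def cohens_f2(r2_full: float, r2_reduced: float) -> float:
    """Cohen's f² = (R²_full − R²_reduced) / (1 − R²_full), nonnegative."""
    if r2_full >= 1.0:
        raise DegenerateInputError("R² of the full model is 1; f² is undefined")
    f2 = (r2_full - r2_reduced) / (1.0 - r2_full)
    return 0.0 if abs(f2) < 1e-15 else float(f2)


def quadratic_vertex(b_lin: float, b_quad: float) -> tuple[float, str]:
    """Extremum of ``b_lin*x + b_quad*x²``: (−b_lin/(2·b_quad), kind).

    ``kind`` is "maximum" when the parabola opens downward (b_quad < 0),
    else "minimum". On the normalized-SUVr axis this is the amyloid load at
    which the fitted awareness curve changes direction.
    """
    if b_quad == 0:
        raise DegenerateInputError("no vertex: the squared coefficient is zero")
    return float(-b_lin / (2.0 * b_quad)), ("maximum" if b_quad < 0 else "minimum")


def influence_diagnostics(fit) -> pd.DataFrame:
    """Per-observation Cook's distance and hat (leverage) values of an OLS fit.

    Hat values lie in (0, 1] and sum to the number of model parameters.
    Observations with leverage numerically equal to 1 get infinite Cook's
    distance rather than raising.
    """
    infl = OLSInfluence(fit)
    hat = np.asarray(infl.hat_matrix_diag, dtype=float)
    cooks = np.asarray(infl.cooks_distance[0], dtype=float)
    at_one = hat >= 1.0 - 1e-12
    if at_one.any():
        cooks = cooks.copy()
        cooks[at_one] = np.inf
    index = fit.model.data.row_labels
    return pd.DataFrame({"cooks_distance": cooks, "hat_value": hat}, index=index)


# ---------------------------------------------------------------------------
# full model report


@dataclass
class ModelReport:
    """Fitted MMR model: coefficients, tests, effect sizes, vertex, diagnostics."""

    coefficients: pd.DataFrame  # index: design column; estimate, se, t, p
    lrt_table: pd.DataFrame | None  # index: term; statistic, df, p
    effect_sizes: pd.Series | None  # Cohen's f² per term
    vertex: float | None  # extremum of the full-model quadratic
    vertex_kind: str | None
    vertex_main_effects: float | None  # extremum refit without interactions
    diagnostics: pd.DataFrame | None  # cooks_distance, hat_value per row
    r_squared: float
    loglik: float
    n: int
    terms: tuple[str, ...]
    quadratic: bool
    info: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Coefficient table in report layout: term, estimate, SE, ES, p."""
        rows = []
        for name in self.coefficients.index:
            if name == "const":
                term = None
            elif name in ("av45", "av45_sq"):
                term = "av45"
            else:
                term = name
            rows.append(
                {
                    "term": name,
                    "estimate": self.coefficients.loc[name, "estimate"],
                    "se": self.coefficients.loc[name, "se"],
                    "es": (
                        self.effect_sizes.get(term)
                        if self.effect_sizes is not None and term is not None
                        else np.nan
                    ),
                    "p": (
                        self.lrt_table.loc[term, "p"]
                        if self.lrt_table is not None and term in (self.lrt_table.index if self.lrt_table is not None else [])
                        else np.nan
                    ),
                }
            )
        return pd.DataFrame(rows).set_index("term")

    def to_dict(self) -> dict:
        out = {
            "n": self.n,
            "terms": list(self.terms),
            "quadratic": self.quadratic,
            "r_squared": self.r_squared,
            "loglik": self.loglik,
            "coefficients": {
                name: {
                    "estimate": float(self.coefficients.loc[name, "estimate"]),
                    "se": float(self.coefficients.loc[name, "se"]),
                }
                for name in self.coefficients.index
            },
            "vertex": self.vertex,
            "vertex_kind": self.vertex_kind,
            "vertex_main_effects": self.vertex_main_effects,
            "info": self.info,
        }
        if self.lrt_table is not None:
            out["lrt"] = {
                term: {
                    "statistic": float(self.lrt_table.loc[term, "statistic"]),
                    "df": int(self.lrt_table.loc[term, "df"]),
                    "p": float(self.lrt_table.loc[term, "p"]),
                }
                for term in self.lrt_table.index
            }
        if self.effect_sizes is not None:
            out["effect_sizes"] = {k: float(v) for k, v in self.effect_sizes.items()}
        if self.diagnostics is not None:
            out["diagnostics"] = {
                "max_cooks_distance": float(np.max(self.diagnostics["cooks_distance"])),
                "max_hat_value": float(np.max(self.diagnostics["hat_value"])),
                "hat_sum": float(np.sum(self.diagnostics["hat_value"])),
            }
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def fit_mmr_model(
    data: pd.DataFrame,
    include_quadratic: bool = True,
    interactions: Sequence[str] = INTERACTION_TERMS,
    cohort_reference: str | None = None,
    lrt: bool = True,
    diagnostics: bool = True,
) -> ModelReport:
    """Fit the MMR regression and assemble the full report.

    ``data`` is the merged cross-cohort frame from :func:`build_model_frame`
    (columns mmr, age, gender, education, cohort, suvr_norm, fdg_z; gender
    and education as 0/1 indicators). ``include_quadratic=False`` drops the
    squared amyloid term (the pre-scatterplot linear-only model).
    ``lrt``/``diagnostics`` can be disabled for speed in simulation loops.
    """
    terms = tuple(MAIN_TERMS) + tuple(interactions)
    for t in interactions:
        if t not in INTERACTION_TERMS:
            raise ValidationError(f"unknown interaction term {t!r}")
    if len(data) < 30:
        raise EstimationError(f"need at least 30 rows to fit the MMR model, got {len(data)}")
    prep, info = _prepare(data, cohort_reference)
    uses_cohort = any(t == "cohort" or "cohort" in t.split(":") for t in terms)
    if uses_cohort and prep["cohort"].std() == 0:
        raise EstimationError(
            "cohort terms requested but the data contain a single cohort "
            f"({info['cohort_levels']})"
        )
    y = pd.to_numeric(data["mmr"]).to_numpy(dtype=float)
    X = _design(prep, terms, include_quadratic)
    _check_rank(X)
    fit = _ols(y, X)
    coef = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )

    lrt_table = effect_sizes = None
    if lrt:
        rows, es = {}, {}
        for term in terms:
            comparison, reduced = _type2_pair(term, terms)
            X_c = _design(prep, comparison, include_quadratic)
            X_r = _design(prep, reduced, include_quadratic)
            f_c, f_r = _ols(y, X_c), _ols(y, X_r)
            stat = max(0.0, 2.0 * (f_c.llf - f_r.llf))
            df = X_c.shape[1] - X_r.shape[1]
            rows[term] = {
                "statistic": stat,
                "df": df,
                "p": float(st.chi2.sf(stat, df)) if df else 1.0,
            }
            es[term] = cohens_f2(f_c.rsquared, f_r.rsquared)
        lrt_table = pd.DataFrame(rows).T[["statistic", "df", "p"]]
        effect_sizes = pd.Series(es, name="f2")

    vertex = vertex_kind = vertex_main = None
    if include_quadratic:
        b_lin, b_quad = float(fit.params["av45"]), float(fit.params["av45_sq"])
        if b_quad != 0:
            vertex, vertex_kind = quadratic_vertex(b_lin, b_quad)
        X_main = _design(prep, MAIN_TERMS, True)
        f_main = _ols(y, X_main)
        bq = float(f_main.params["av45_sq"])
        if bq != 0:
            vertex_main, _ = quadratic_vertex(float(f_main.params["av45"]), bq)

    diag = influence_diagnostics(fit) if diagnostics else None

    return ModelReport(
        coefficients=coef,
        lrt_table=lrt_table,
        effect_sizes=effect_sizes,
        vertex=vertex,
        vertex_kind=vertex_kind,
        vertex_main_effects=vertex_main,
        diagnostics=diag,
        r_squared=float(fit.rsquared),
        loglik=float(fit.llf),
        n=int(len(data)),
        terms=terms,
        quadratic=include_quadratic,
        info=info,
    )


# ---------------------------------------------------------------------------
# cohort-description statistics


class WelchResult(NamedTuple):
    statistic: float
    df: float
    pvalue: float


def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> WelchResult:
    """Welch's two-sample t test from summary statistics.

    t = (m1 − m2) / sqrt(s1²/n1 + s2²/n2); df by Welch–Satterthwaite;
    two-sided p. With equal variances and equal n it coincides with the
    pooled-variance t test.
    """
    if n1 < 2 or n2 < 2:
        raise DegenerateInputError("Welch's t requires at least 2 observations per group")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("standard deviations must be nonnegative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        raise DegenerateInputError("both groups have zero variance")
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return WelchResult(float(t), float(df), float(2.0 * st.t.sf(abs(t), df)))


class Chi2Result(NamedTuple):
    statistic: float
    pvalue: float


def chisq_2x2(counts, continuity_correction: bool = True) -> Chi2Result:
    """Pearson χ² on a 2×2 table, Yates continuity correction on by default."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValidationError(f"expected a 2×2 table, got shape {table.shape}")
    if (table < 0).any() or not np.all(table == np.floor(table)):
        raise ValidationError("counts must be nonnegative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateInputError("every margin of the 2×2 table must be positive")
    res = st.chi2_contingency(table, correction=continuity_correction)
    return Chi2Result(float(res[0]), float(res[1]))
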