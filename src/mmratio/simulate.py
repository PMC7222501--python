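"""Two-cohort synthetic data generator.

Emulates the statistical structure the MMR pipeline assumes: two cohorts with
different demographic distributions (one younger and almost uniformly highly
educated, one older with mixed education, mirroring ADNI-SMC vs
INSIGHT-PreAD summary moments), amyloid SUVr on cohort-native scales with
cohort-specific positivity thresholds, an FDG meta-ROI, and observed memory /
complaint scores generated under the declared GLM families.

Generative model (per cohort):

* demographics: age ~ Normal(μ, σ); gender and education Bernoulli;
* raw SUVr ~ truncated Normal(μ, σ) on (0, ∞) (optionally a two-component
  mixture mimicking amyloid-positive/negative subpopulations);
* latent awareness  A = β_lin·x + β_quad·x² + β_fdg·z_fdg + ε,
  where x = SUVr/threshold is the harmonized amyloid load, z_fdg the
  intra-cohort FDG z-score, ε ~ Normal(0, noise_sd);
* a shared cognitive level u ~ Normal(0, shared_sd) splits A symmetrically
  into latent memory  M = u + A/2  and latent complaint  C = −u + A/2, so
  M + C = A exactly: positive awareness excess means complaint beyond
  measured decline;
* each registered score observes M (objective) or C (subjective) through its
  family's link, with demographic effects injected so residualization is
  exercised nontrivially: linear → Gaussian around η; binomial →
  Binomial(n_trials, expit(η)); logistic → Bernoulli(expit(η)), where
  η = intercept + demographic terms ± loading·latent (+ Gaussian jitter).

Ground truth (coefficients and all latents) is returned alongside the tables
so parameter recovery can be scored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats as st
import yaml
from scipy.special import expit

from . import cohort as cohort_io
from .cohort import AMYLOID_COLUMN, FDG_COLUMN, CohortTable
from .errors import ConfigurationError
from .registry import FAMILIES, DemographicSpec, Registry, ScoreSpec
from .residualize import standardize


@dataclass(frozen=True)
class CohortParams:
    """Per-cohort sampling parameters (moments on native scales)."""

    cohort_id: str
    n: int
    age_mean: float
    age_sd: float
    prop_female: float
    prop_higher_ed: float
    suvr_mean: float
    suvr_sd: float
    suvr_threshold: float
    fdg_mean: float = 1.25
    fdg_sd: float = 0.12
    # optional amyloid-positive mixture component
    positive_fraction: float | None = None
    positive_suvr_mean: float | None = None
    positive_suvr_sd: float | None = None

    def __post_init__(self) -> None:
        if self.n < 30:
            raise ConfigurationError(
                f"cohort {self.cohort_id!r}: n must be >= 30 for model-fitting "
                f"scenarios, got {self.n}"
            )
        for name in ("age_sd", "suvr_sd", "fdg_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"cohort {self.cohort_id!r}: {name} must be > 0")
        for name in ("prop_female", "prop_higher_ed"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"cohort {self.cohort_id!r}: {name} must be in [0, 1], got {p}"
                )
        if self.suvr_threshold <= 0:
            raise ConfigurationError(f"cohort {self.cohort_id!r}: suvr_threshold must be > 0")
        if self.positive_fraction is not None:
            if not 0.0 <= self.positive_fraction <= 1.0:
                raise ConfigurationError(
                    f"cohort {self.cohort_id!r}: positive_fraction must be in [0, 1]"
                )
            if self.positive_suvr_mean is None or self.positive_suvr_sd is None:
                raise ConfigurationError(
                    f"cohort {self.cohort_id!r}: mixture requires positive_suvr_mean "
                    "and positive_suvr_sd"
                )


@dataclass(frozen=True)
class Truth:
    """Latent-model coefficients on the harmonized biomarker scales."""

    b_lin: float = 9.0
    b_quad: float = -4.0
    b_fdg: float = 0.5
    noise_sd: float = 1.0
    shared_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.shared_sd < 0:
            raise ConfigurationError("noise_sd and shared_sd must be nonnegative")


@dataclass(frozen=True)
class ScoreGenerator:
    """Mapping from a latent (memory or complaint) to one observed score.

    ``eta = intercept + age_beta·age + gender_beta·[male] +
    education_beta·[lower] ± loading·latent + Normal(0, noise_sd)``; the
    loading sign is flipped automatically for ``higher_worse`` scores. For
    the linear family ``eta`` is the score itself; for binomial/logistic it
    is on the logit scale.
    """

    spec: ScoreSpec
    loading: float = 1.0
    intercept: float = 0.0
    noise_sd: float = 0.0
    age_beta: float = 0.0
    gender_beta: float = 0.0
    education_beta: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError(f"score {self.spec.name!r}: noise_sd must be >= 0")


@dataclass
class SimulationConfig:
    """Full description of a two-cohort simulation scenario."""

    cohorts: tuple[CohortParams, ...]
    truth: Truth = field(default_factory=Truth)
    generators: tuple[ScoreGenerator, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        self.cohorts = tuple(self.cohorts)
        self.generators = tuple(self.generators)
        if not self.cohorts:
            raise ConfigurationError("simulation config declares no cohorts")
        ids = [c.cohort_id for c in self.cohorts]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate cohort ids: {ids}")
        if not self.generators:
            raise ConfigurationError("simulation config declares no score generators")
        # registry construction validates >=1 objective and >=1 subjective
        self.registry

    @property
    def registry(self) -> Registry:
        return Registry(scores=tuple(g.spec for g in self.generators))

    def to_dict(self) -> dict:
        return {
            "cohorts": [dataclasses.asdict(c) for c in self.cohorts],
            "truth": dataclasses.asdict(self.truth),
            "generators": [dataclasses.asdict(g) for g in self.generators],
            "seed": self.seed,
        }


def _battery_generators() -> tuple[ScoreGenerator, ...]:
    """Realistic mixed-family battery: recall count, figure recall, intrusions, complaint."""
    return (
        ScoreGenerator(
            spec=ScoreSpec("recall_total", "objective", "binomial", "higher_better", 0, 48),
            loading=1.0, intercept=2.6, noise_sd=0.3,
            age_beta=-0.02, education_beta=-0.25,
        ),
        ScoreGenerator(
            spec=ScoreSpec("figure_recall", "objective", "linear", "higher_better"),
            loading=2.0, intercept=24.0, noise_sd=2.5,
            age_beta=-0.08, gender_beta=0.5, education_beta=-1.0,
        ),
        ScoreGenerator(
            spec=ScoreSpec("intrusions", "objective", "logistic", "higher_worse"),
            loading=1.0, intercept=-2.6, noise_sd=0.3, age_beta=0.025,
        ),
        ScoreGenerator(
            spec=ScoreSpec("complaint", "subjective", "linear", "higher_more_complaint"),
            loading=1.5, intercept=2.0, noise_sd=1.5, age_beta=0.05,
        ),
    )


def _pair_generators() -> tuple[ScoreGenerator, ...]:
    """Single linear objective/subjective pair with unit loadings.

    Because both links are linear and the latent composites have variance
    close to 1 by construction, the pipeline MMR is an almost unbiased copy
    of latent awareness — the scenario under which raw-coefficient recovery
    is well defined.
    """
    return (
        ScoreGenerator(
            spec=ScoreSpec("memory_score", "objective", "linear", "higher_better"),
            loading=1.0, intercept=25.0, noise_sd=0.15,
            age_beta=-0.05, education_beta=-0.6,
        ),
        ScoreGenerator(
            spec=ScoreSpec("complaint_score", "subjective", "linear", "higher_more_complaint"),
            loading=1.0, intercept=10.0, noise_sd=0.15, age_beta=0.04,
        ),
    )


def _default_cohorts() -> tuple[CohortParams, ...]:
    return (
        CohortParams(
            cohort_id="ADNI", n=158,
            age_mean=71.97, age_sd=5.79,
            prop_female=0.601, prop_higher_ed=0.994,
            suvr_mean=1.01, suvr_sd=0.16, suvr_threshold=1.11,
            fdg_mean=1.30, fdg_sd=0.12,
        ),
        CohortParams(
            cohort_id="INSIGHT-PreAD", n=290,
            age_mean=76.02, age_sd=3.5,
            prop_female=0.631, prop_higher_ed=0.676,
            suvr_mean=0.86, suvr_sd=0.17, suvr_threshold=0.79,
            fdg_mean=1.25, fdg_sd=0.12,
        ),
    )


def default_config(**overrides) -> SimulationConfig:
    """Default scenario: realistic mixed-family battery, cohort moments as
    reported for ADNI-SMC (n=158) and INSIGHT-PreAD (n=290)."""
    kw = dict(cohorts=_default_cohorts(), truth=Truth(), generators=_battery_generators())
    kw.update(overrides)
    return SimulationConfig(**kw)


def recovery_config(**overrides) -> SimulationConfig:
    """Parameter-recovery scenario: same cohorts/truth, linear score pair."""
    kw = dict(cohorts=_default_cohorts(), truth=Truth(), generators=_pair_generators())
    kw.update(overrides)
    return SimulationConfig(**kw)


@dataclass
class SimulationResult:
    tables: dict[str, CohortTable]
    truth: dict
    registry: Registry
    config: SimulationConfig


def _draw_suvr(rng: np.random.Generator, params: CohortParams) -> np.ndarray:
    def trunc(mean, sd, size):
        a = (0.0 - mean) / sd
        return st.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)

    if params.positive_fraction is None:
        return trunc(params.suvr_mean, params.suvr_sd, params.n)
    is_pos = rng.random(params.n) < params.positive_fraction
    out = trunc(params.suvr_mean, params.suvr_sd, params.n)
    n_pos = int(is_pos.sum())
    if n_pos:
        out[is_pos] = trunc(params.positive_suvr_mean, params.positive_suvr_sd, n_pos)
    return out


def simulate_cohorts(config: SimulationConfig, seed: int | None = None) -> SimulationResult:
    """Generate the two cohort tables plus the ground-truth record.

    Identical (config, seed) pairs produce identical output. ``seed``
    overrides ``config.seed`` when given.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ConfigurationError("a seed is required for simulation")
    rng = np.random.default_rng(int(seed))
    registry = config.registry
    truth = config.truth
    tables: dict[str, CohortTable] = {}
    latents: dict[str, dict] = {}

    for params in config.cohorts:
        n = params.n
        age = np.maximum(rng.normal(params.age_mean, params.age_sd, n), 1.0)
        gender = np.where(rng.random(n) < params.prop_female, "F", "M")
        education = np.where(rng.random(n) < params.prop_higher_ed, "higher", "lower")
        suvr = _draw_suvr(rng, params)
        fdg = np.maximum(rng.normal(params.fdg_mean, params.fdg_sd, n), 1e-3)

        x = suvr / params.suvr_threshold
        z_fdg = standardize(fdg)
        awareness = (
            truth.b_lin * x
            + truth.b_quad * x**2
            + truth.b_fdg * z_fdg
            + rng.normal(0.0, truth.noise_sd, n)
        )
        shared = rng.normal(0.0, truth.shared_sd, n) if truth.shared_sd > 0 else np.zeros(n)
        memory = shared + awareness / 2.0
        complaint = -shared + awareness / 2.0

        male = (gender == "M").astype(float)
        lower = (education == "lower").astype(float)
        columns: dict[str, np.ndarray] = {
            "age": age,
            "gender": gender,
            "education": education,
        }
        for gen in config.generators:
            spec = gen.spec
            if spec.family not in FAMILIES:
                raise ConfigurationError(
                    f"score {spec.name!r}: unknown family {spec.family!r} in generator"
                )
            latent = memory if spec.role == "objective" else complaint
            sign = -1.0 if spec.direction == "higher_worse" else 1.0
            eta = (
                gen.intercept
                + gen.age_beta * age
                + gen.gender_beta * male
                + gen.education_beta * lower
                + sign * gen.loading * latent
            )
            if gen.noise_sd > 0:
                eta = eta + rng.normal(0.0, gen.noise_sd, n)
            if spec.family == "linear":
                values = eta
            elif spec.family == "binomial":
                values = spec.min_value + rng.binomial(spec.n_trials, expit(eta))
            else:  # logistic
                values = rng.binomial(1, expit(eta)).astype(float)
            columns[spec.name] = values
        columns[AMYLOID_COLUMN] = suvr
        columns[FDG_COLUMN] = fdg

        ids = [f"{params.cohort_id}-{i:04d}" for i in range(n)]
        df = pd.DataFrame(columns, index=pd.Index(ids, name=cohort_io.ID_COLUMN))
        tables[params.cohort_id] = cohort_io.from_dataframe(
            df.reset_index(), registry, params.cohort_id, source="simulated"
        )
        latents[params.cohort_id] = {
            "suvr_norm": x.tolist(),
            "fdg_z": z_fdg.tolist(),
            "awareness": awareness.tolist(),
            "memory": memory.tolist(),
            "complaint": complaint.tolist(),
            "participant_id": ids,
        }

    truth_record = {
        "coefficients": dataclasses.asdict(truth),
        "seed": int(seed),
        "thresholds": {c.cohort_id: c.suvr_threshold for c in config.cohorts},
        "latents": latents,
    }
    return SimulationResult(tables=tables, truth=truth_record, registry=registry, config=config)


# ---------------------------------------------------------------------------
# config / output I/O


def config_from_dict(doc: dict) -> SimulationConfig:
    if not isinstance(doc, dict) or not doc:
        raise ConfigurationError("simulation config document is empty or not a mapping")
    try:
        cohorts = tuple(CohortParams(**c) for c in doc.get("cohorts", []))
        truth = Truth(**(doc.get("truth") or {}))
        generators = tuple(
            ScoreGenerator(spec=ScoreSpec(**g.pop("spec")), **g)
            for g in (dict(g) for g in doc.get("generators", []))
        )
    except TypeError as exc:
        raise ConfigurationError(f"malformed simulation config: {exc}") from exc
    return SimulationConfig(
        cohorts=cohorts, truth=truth, generators=generators, seed=doc.get("seed")
    )


def read_config(path: str | Path) -> SimulationConfig:
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"could not parse simulation config {path}: {exc}") from exc
    if doc is None:
        raise ConfigurationError(f"simulation config {path} is empty")
    return config_from_dict(doc)


def write_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write cohort CSVs, the registry, and the truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cid, table in result.tables.items():
        path = outdir / f"cohort_{cid}.csv"
        cohort_io.write_cohort(table, path)
        paths[cid] = path
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(result.truth, indent=2), encoding="utf-8")
    paths["truth"] = truth_path
    from .registry import write_registry

    reg_path = outdir / "registry.yaml"
    write_registry(result.registry, reg_path)
    paths["registry"] = reg_path
    return paths
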