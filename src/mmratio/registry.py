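"""Score registry: declarative description of the cohort columns the pipeline consumes.

A registry declares, for every neuropsychological score, its role (objective
memory performance vs. subjective complaint), the GLM family used to remove
demographic effects, the direction of the scale, and — for bounded count
scores — its bounds. Family selection is declared, never inferred from data:
the appropriate family depends on how a test is scored (e.g. a 48-item recall
task is a binomial count, an error tally that is almost always zero is
binarized and fit logistically, a drawing-recall score is treated as Gaussian).

Registries are read from YAML (JSON is a subset of YAML and works unchanged).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError

ROLES = ("objective", "subjective")
FAMILIES = ("linear", "binomial", "logistic")
OBJECTIVE_DIRECTIONS = ("higher_better", "higher_worse")
SUBJECTIVE_DIRECTIONS = ("higher_more_complaint",)


@dataclass(frozen=True)
class ScoreSpec:
    """Declaration of one score column.

    Parameters
    ----------
    name : column name in the cohort table (case-sensitive).
    role : "objective" (memory performance) or "subjective" (complaint).
    family : GLM family used for demographic residualization.
        "binomial" requires integer scores in [min_value, max_value];
        ``max_value - min_value`` defines the number of trials.
        "logistic" binarizes the score as ``value > binarize_gt`` first.
    direction : scale orientation. Objective scores are "higher_better" or
        "higher_worse" (error/intrusion counts); subjective scores are
        "higher_more_complaint".
    min_value, max_value : numeric bounds; required for the binomial family,
        optional elsewhere (enforced at ingest when given).
    binarize_gt : threshold for the logistic binarization rule (default 0,
        i.e. any nonzero count counts as an event).
    """

    name: str
    role: str
    family: str
    direction: str
    min_value: float | None = None
    max_value: float | None = None
    binarize_gt: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(
                f"score {self.name!r}: unknown role {self.role!r}; allowed roles are {list(ROLES)}"
            )
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"score {self.name!r}: unknown family {self.family!r}; "
                f"allowed families are {list(FAMILIES)}"
            )
        allowed = OBJECTIVE_DIRECTIONS if self.role == "objective" else SUBJECTIVE_DIRECTIONS
        if self.direction not in allowed:
            raise ConfigurationError(
                f"score {self.name!r}: direction {self.direction!r} invalid for role "
                f"{self.role!r}; allowed directions are {list(allowed)}"
            )
        if self.family == "binomial":
            if self.min_value is None or self.max_value is None:
                raise ConfigurationError(
                    f"score {self.name!r}: binomial family requires min_value and max_value"
                )
            if not float(self.min_value).is_integer() or not float(self.max_value).is_integer():
                raise ConfigurationError(
                    f"score {self.name!r}: binomial bounds must be integers"
                )
            if not self.max_value > self.min_value:
                raise ConfigurationError(
                    f"score {self.name!r}: binomial family requires max_value > min_value"
                )
        if (
            self.min_value is not None
            and self.max_value is not None
            and self.max_value <= self.min_value
        ):
            raise ConfigurationError(f"score {self.name!r}: max_value must exceed min_value")

    @property
    def n_trials(self) -> int:
        """Number of binomial trials (max_value − min_value)."""
        if self.family != "binomial":
            raise ConfigurationError(f"score {self.name!r} is not binomial")
        return int(self.max_value - self.min_value)


@dataclass(frozen=True)
class DemographicSpec:
    """Names and encodings of the demographic covariates.

    ``age`` is continuous (years, strictly positive). ``gender`` and
    ``education`` are binary categories; the stated reference level is coded 0
    and the other level 1 in design matrices (reference female, reference
    higher education by default). If ``education_cutoff`` is set, the
    education column holds years of schooling and is binarized at ingest:
    ``years >= cutoff`` maps to the "higher" level.
    """

    age: str = "age"
    gender: str = "gender"
    gender_reference: str = "F"
    education: str = "education"
    education_reference: str = "higher"
    education_cutoff: float | None = None

    @property
    def columns(self) -> tuple[str, str, str]:
        return (self.age, self.gender, self.education)

    def encode(self, df: pd.DataFrame) -> pd.DataFrame:
        """Return the numeric covariate frame (age, gender, education).

        gender and education become 0/1 indicators with the declared
        reference level at 0. Education given in years (cutoff declared) is
        binarized first.
        """
        age = pd.to_numeric(df[self.age])
        gender = (df[self.gender].astype(str) != str(self.gender_reference)).astype(float)
        edu_raw = df[self.education]
        if self.education_cutoff is not None:
            lower = pd.to_numeric(edu_raw) < self.education_cutoff
        else:
            lower = edu_raw.astype(str) != str(self.education_reference)
        return pd.DataFrame(
            {"age": age.astype(float), "gender": gender, "education": lower.astype(float)},
            index=df.index,
        )


@dataclass
class Registry:
    """A validated set of score declarations plus the demographic spec."""

    scores: tuple[ScoreSpec, ...]
    demographics: DemographicSpec = field(default_factory=DemographicSpec)

    def __post_init__(self) -> None:
        self.scores = tuple(self.scores)
        names = [s.name for s in self.scores]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"duplicate score names in registry: {dupes}")
        if not self.objective_scores:
            raise ConfigurationError("registry must declare at least one objective score")
        if not self.subjective_scores:
            raise ConfigurationError("registry must declare at least one subjective score")

    @property
    def objective_scores(self) -> tuple[ScoreSpec, ...]:
        return tuple(s for s in self.scores if s.role == "objective")

    @property
    def subjective_scores(self) -> tuple[ScoreSpec, ...]:
        return tuple(s for s in self.scores if s.role == "subjective")

    @property
    def score_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.scores)

    def __getitem__(self, name: str) -> ScoreSpec:
        for s in self.scores:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "demographics": dataclasses.asdict(self.demographics),
            "scores": [dataclasses.asdict(s) for s in self.scores],
        }


def _score_from_dict(entry: dict) -> ScoreSpec:
    if not isinstance(entry, dict):
        raise ConfigurationError(f"score entry must be a mapping, got {type(entry).__name__}")
    known = {f.name for f in dataclasses.fields(ScoreSpec)}
    unknown = set(entry) - known
    if unknown:
        raise ConfigurationError(
            f"score entry {entry.get('name', '?')!r}: unknown keys {sorted(unknown)}"
        )
    missing = {"name", "role", "family", "direction"} - set(entry)
    if missing:
        raise ConfigurationError(
            f"score entry {entry.get('name', '?')!r}: missing required keys {sorted(missing)}"
        )
    return ScoreSpec(**entry)


def registry_from_dict(doc: dict) -> Registry:
    """Build a :class:`Registry` from a parsed YAML/JSON document."""
    if not isinstance(doc, dict) or not doc:
        raise ConfigurationError("registry document is empty or not a mapping")
    if "scores" not in doc:
        raise ConfigurationError("registry document has no 'scores' section")
    demo_doc = doc.get("demographics", {}) or {}
    known = {f.name for f in dataclasses.fields(DemographicSpec)}
    unknown = set(demo_doc) - known
    if unknown:
        raise ConfigurationError(f"demographics section: unknown keys {sorted(unknown)}")
    demographics = DemographicSpec(**demo_doc)
    scores = tuple(_score_from_dict(e) for e in doc["scores"])
    return Registry(scores=scores, demographics=demographics)


def read_registry(path: str | Path) -> Registry:
    """Read a registry from a YAML or JSON file."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"could not parse registry {path}: {exc}") from exc
    if doc is None:
        raise ConfigurationError(f"registry file {path} is empty")
    return registry_from_dict(doc)


def write_registry(registry: Registry, path: str | Path) -> None:
    """Write a registry to YAML (round-trips through :func:`read_registry`)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(registry.to_dict(), fh, sort_keys=False)
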