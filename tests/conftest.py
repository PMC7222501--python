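import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mmratio as mm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_registry() -> mm.Registry:
    """One linear objective + one linear subjective score."""
    return mm.Registry(
        scores=(
            mm.ScoreSpec("memory", "objective", "linear", "higher_better"),
            mm.ScoreSpec("complaint", "subjective", "linear", "higher_more_complaint"),
        )
    )


def make_cohort_frame(n: int, rng: np.random.Generator, scores: dict | None = None) -> pd.DataFrame:
    """Small raw cohort frame with demographics, biomarkers and given score columns."""
    df = pd.DataFrame(
        {
            "participant_id": [f"P{i:03d}" for i in range(n)],
            "age": rng.normal(74, 4, n).round(1),
            "gender": rng.choice(["F", "M"], n),
            "education": rng.choice(["higher", "lower"], n),
            "amyloid_suvr": rng.uniform(0.6, 1.6, n).round(3),
            "fdg_meta_roi": rng.normal(1.25, 0.1, n).round(3),
        }
    )
    for name, values in (scores or {}).items():
        df[name] = values
    return df


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_sim() -> mm.SimulationResult:
    """One default-scenario simulation shared across tests."""
    return mm.simulate_cohorts(mm.default_config(), seed=42)


def pipeline_frame(result: mm.SimulationResult) -> pd.DataFrame:
    """simulate → MMR → harmonize → merged model frame."""
    tables = list(result.tables.values())
    mmrs = [mm.cohort_mmr(t) for t in tables]
    panels = [
        mm.harmonize(t, threshold=result.truth["thresholds"][t.cohort_id]) for t in tables
    ]
    return mm.build_model_frame(tables, mmrs, panels)


@pytest.fixture(scope="session")
def recovery_frame() -> pd.DataFrame:
    """Model frame from the recovery scenario at the default sizes, seed 1."""
    return pipeline_frame(mm.simulate_cohorts(mm.recovery_config(), seed=1))
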