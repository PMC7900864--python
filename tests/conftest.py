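import pandas as pd
import pytest

import vespre


@pytest.fixture(scope="session")
def cohort_small():
    return vespre.generate_cohort(vespre.GeneratorConfig(n_encounters=800, seed=7))


@pytest.fixture(scope="session")
def flags_small(cohort_small):
    return vespre.screen_cohort(cohort_small.encounters, cohort_small.events)


@pytest.fixture(scope="session")
def big_cohort():
    # large enough for Monte-Carlo marginal recovery
    return vespre.generate_cohort(vespre.GeneratorConfig(n_encounters=10_000, seed=21))


@pytest.fixture(scope="session")
def pipeline_result():
    return vespre.run_pipeline(vespre.GeneratorConfig(n_encounters=2500, seed=13))


def make_events(rows, encounter_id="X"):
    """Rows of (t_minutes, kind, code, value) -> event-stream frame."""
    return pd.DataFrame(
        [(encounter_id, t, k, c, v, "") for t, k, c, v in rows],
        columns=["encounter_id", "t_minutes", "kind", "code", "value", "unit"])
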