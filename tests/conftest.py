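import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from riskitems.cohort import fixture_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_table() -> pd.DataFrame:
    """The deterministic 483-episode reference cohort."""
    return fixture_cohort()


@pytest.fixture(scope="session")
def printed_auc_table() -> pd.DataFrame:
    """Frozen per-item AUC table at the published values.

    Items whose AUC is published are entered verbatim; items with published
    sensitivity/specificity use the binary identity AUC = (sens + spec) / 2.
    """
    rows = [
        ("lifetime_history_self_harm", "MSHR", (0.924 + 0.334) / 2),
        ("prior_psychiatric_treatment", "MSHR", 0.65),
        ("benzodiazepines", "MSHR", (0.200 + 0.917) / 2),
        ("self_harm_last_year", "ReACT", 0.63),
        ("cutting", "ReACT", (0.325 + 0.814) / 2),
        ("previous_suicide_attempt", "SADP", 0.61),
        ("previous_psychiatric_care", "SADP", 0.65),
        ("rational_thinking_loss", "SADP", (0.028 + 0.979) / 2),
        ("prev_attempt_or_psych_care", "MSPS", 0.65),
        ("stated_future_intent", "MSPS", 0.57),
        ("lots_of_extraneous_thought", "BIS", 0.59),
        ("rarely_thinks_one_thing", "BIS", 0.43),
        ("rarely_self_controlled", "BIS", (0.823 + 0.346) / 2),
        ("changes_hobbies_frequently", "BIS", (0.270 + 0.804) / 2),
    ]
    return pd.DataFrame(rows, columns=["item_id", "source_scale", "auc"])
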