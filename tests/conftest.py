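import pytest
from hypothesis import settings

from csnq import analysis, simulate
from csnq.records import AlterRecord, EgoRecord

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

WHITE = "European/White-American"
BLACK = "African/Black-American"
ASIAN = "Asian/Asian-American"
HISPANIC = "Hispanic/Latino-American"
MIXED = "Mixed/Biracial"


def make_ego(ego_id="e1", age_months=30.0, races=(WHITE,), languages=("English",), **kw):
    return EgoRecord(
        ego_id=ego_id,
        age_months=age_months,
        races=frozenset(races),
        languages=frozenset(languages),
        **kw,
    )


def make_alter(
    alter_id,
    ego_id="e1",
    relationship="friend",
    contexts=("family",),
    races=None,
    languages=None,
    **kw,
):
    return AlterRecord(
        ego_id=ego_id,
        alter_id=alter_id,
        relationship=relationship,
        contexts=frozenset(contexts),
        races=None if races is None else frozenset(races),
        languages=None if languages is None else frozenset(languages),
        **kw,
    )


@pytest.fixture(scope="session")
def cohort_metrics():
    """Default synthetic cohort, scored once for the whole session."""
    egos, alters = simulate.generate_records(seed=11)
    return analysis.score_cohort(egos, alters)
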