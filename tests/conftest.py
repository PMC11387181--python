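import pytest

from epletmm.registry import AlleleCall, EpletRegistry, SubjectTyping
from epletmm.simulate import generate_fixture_registry, generate_frequency_table

TINY_REGISTRY = {
    "DRB1*01:01": {"r1", "r2"},
    "DRB1*04:05": {"r2", "r3", "r4"},
    "DRB1*15:01": {"r1", "r3", "r5", "r6"},
    "DRB3*02:02": {"r5"},
    "DRB5*01:01": {"r6", "r7"},
    "DQA1*01:01": {"a1"},
    "DQA1*05:01": {"a2", "a3"},
    "DQB1*05:02": {"b1", "b2"},
    "DQB1*03:01": {"b3"},
}


@pytest.fixture()
def tiny_registry():
    return EpletRegistry(TINY_REGISTRY)


@pytest.fixture(scope="session")
def fixture_registry():
    return generate_fixture_registry(seed=0)


@pytest.fixture(scope="session")
def fixture_freq(fixture_registry):
    return generate_frequency_table(fixture_registry, seed=0)


def make_typing(
    subject_id="S1",
    role="recipient",
    pair_id="P1",
    ethnicity="Chinese",
    drb1=("DRB1*01:01", "DRB1*04:05"),
    drb345=(None, None),
    dqa1=("DQA1*01:01", "DQA1*05:01"),
    dqb1=("DQB1*05:02", "DQB1*03:01"),
):
    """Build a fully-typed subject; None in drb345 means a null slot."""

    def d345(v):
        if v is None:
            return AlleleCall("DRB345", "", "null")
        return AlleleCall(v.split("*")[0], v, "two_field")

    return SubjectTyping(
        subject_id=subject_id,
        role=role,
        pair_id=pair_id,
        ethnicity=ethnicity,
        slots={
            "DRB1": [AlleleCall("DRB1", v, "two_field") for v in drb1],
            "DRB345": [d345(v) for v in drb345],
            "DQA1": [AlleleCall("DQA1", v, "two_field") for v in dqa1],
            "DQB1": [AlleleCall("DQB1", v, "two_field") for v in dqb1],
        },
    )
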