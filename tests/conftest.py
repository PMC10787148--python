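import pytest

from actdose import GoalRange, PatientProfile, ProtocolParams


@pytest.fixture
def goal():
    return GoalRange()


@pytest.fixture
def params():
    return ProtocolParams()


@pytest.fixture
def profile_100kg():
    """Apixaban patient, 100 kg, unanticoagulated-reference baseline ACT."""
    return PatientProfile(anticoagulant="apixaban", weight=100.0,
                          baseline_act=120.0)


@pytest.fixture
def exact_params():
    """Protocol with rounding off and wide clamps for exactness checks."""
    return ProtocolParams(bolus_round=0, max_bolus=1e9, max_infusion=1e6)
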