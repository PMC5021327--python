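import numpy as np
import pytest

from myotet import MotorUnit, PredictionConfig, StimulationPattern, TwitchParams


@pytest.fixture
def slow_twitch() -> TwitchParams:
    """A slow-unit-like first twitch (ms, mN)."""
    return TwitchParams(f_max=12.0, t_lead=2.0, t_hc=22.0, t_c=40.0, t_hr=88.0, t_tw=320.0)


@pytest.fixture
def slow_unit(slow_twitch) -> MotorUnit:
    return MotorUnit("S1", "S", slow_twitch, f_mftf=90.0)


@pytest.fixture
def fast_twitch() -> TwitchParams:
    return TwitchParams(f_max=40.0, t_lead=1.5, t_hc=10.0, t_c=18.0, t_hr=40.0, t_tw=150.0)


@pytest.fixture
def fast_unit(fast_twitch) -> MotorUnit:
    return MotorUnit("FF1", "FF", fast_twitch, f_mftf=130.0)


@pytest.fixture
def cfg() -> PredictionConfig:
    return PredictionConfig()


@pytest.fixture
def jittered_pattern() -> StimulationPattern:
    """An 8-pulse train around 12.5 Hz with jittered intervals."""
    rng = np.random.default_rng(11)
    return StimulationPattern.from_ipis(rng.uniform(40.0, 120.0, size=7))
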