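import pytest

from iedose import ImmuneKinetics, RadiosensitivityParams, make_uniform


@pytest.fixture
def params():
    """The worked-example radiosensitivity: alpha=0.15 /Gy, alpha/beta=4 Gy."""
    return RadiosensitivityParams(alpha=0.15, alpha_beta=4.0)


@pytest.fixture
def kinetics():
    """Default immune kinetics: T_D = 3 d, T_IR = 7 d."""
    return ImmuneKinetics(t_d=3.0, t_ir=7.0)


@pytest.fixture
def sched_3x8():
    return make_uniform(3, 8.0, interval=1.0)


@pytest.fixture
def sched_5x6():
    return make_uniform(5, 6.0, interval=1.0)
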