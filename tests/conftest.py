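import pytest

from compskit import spr


@pytest.fixture(scope="session")
def schedule():
    """Five-injection single-cycle schedule, 5 s sampling to keep tests fast."""
    return spr.InjectionSchedule.single_cycle(dt=5.0)


@pytest.fixture(scope="session")
def cp40_params():
    """Replicate-mean rate constants of the lead compound (K_D = 0.7 nM)."""
    return spr.KineticParameters(k_a=1.0e6, k_d=0.7e-3, r_max=50.0)
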