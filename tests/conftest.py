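"""Shared fixtures: expensive deterministic/stochastic runs, computed once."""

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def identity_result():
    """Deterministic IDENTITY gate run at 0.4 M NaCl (4 h)."""
    from yeastgates.gates import run_gate

    return run_gate("identity", {"nacl": 0.4})


@pytest.fixture(scope="session")
def identity_drive(identity_result):
    from yeastgates.stochastic import hybrid_drive

    return hybrid_drive(identity_result.trajectory)


@pytest.fixture(scope="session")
def identity_hybrid_ensemble(identity_drive):
    """300-cell hybrid ensemble of the IDENTITY gate at 0.4 M NaCl."""
    from yeastgates.stochastic import HybridGFPModel, run_ensemble

    return run_ensemble(HybridGFPModel(identity_drive), 300, 4.0, seed=7)


@pytest.fixture(scope="session")
def identity_sensitivity():
    """Full finite-difference sensitivity scan of the IDENTITY gate."""
    from yeastgates.sensitivity import sensitivity_scan

    return sensitivity_scan("identity", {"nacl": 0.4})
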