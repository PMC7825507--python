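import pytest

from rhizograd import SimConfig, calibrate_glucose, run_to_equilibrium


@pytest.fixture(scope="session")
def calibrated():
    """Glucose calibrated once per session to the 10 cm equilibrium anchors."""
    root, solute, diag = calibrate_glucose()
    return root, solute, diag


@pytest.fixture(scope="session")
def calibrated_runs(calibrated):
    """Full-resolution equilibrium runs of the calibrated solute at 10/80 cm."""
    root, solute, _ = calibrated
    r10 = run_to_equilibrium(SimConfig(solute=solute, root=root, depth=10.0))
    r80 = run_to_equilibrium(SimConfig(solute=solute, root=root, depth=80.0))
    return r10, r80
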