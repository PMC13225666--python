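import pytest

from lvcompete.plates import PlateDesign, generate_plate
from lvcompete.fitting import run_staged_protocol


@pytest.fixture(scope="session")
def noiseless_plate():
    """Full 192-well design with zero measurement noise (initial-population
    dispersion retained)."""
    return generate_plate(PlateDesign(noise_sigma=0.0, seed=11))


@pytest.fixture(scope="session")
def noiseless_staged(noiseless_plate):
    """Staged protocol run on the noiseless full-design plate.

    Session-scoped: this is the single most expensive fixture and feeds both
    the parameter-recovery and the degrees-of-freedom checks.
    """
    return run_staged_protocol(noiseless_plate, seed=7, n_starts=3)
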