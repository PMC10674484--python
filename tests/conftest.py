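import numpy as np
import pytest

from lipoagg import DecaySimSpec, HydroConditions

#: Lifetimes (ns) and fractional amplitudes of the tryptophan decay the
#: synthetic generator emulates by default.
TRUE_TAUS = np.array([1.22, 3.66, 7.40])
TRUE_ALPHAS = np.array([0.45, 0.41, 0.14])


@pytest.fixture(scope="session")
def water_cond() -> HydroConditions:
    """Aqueous buffer at 298 K with the tryptophan limit anisotropy."""
    return HydroConditions(viscosity_cP=0.89, temperature_K=298.0, r0=0.260)


@pytest.fixture(scope="session")
def tri_exp_spec() -> DecaySimSpec:
    """Default tri-exponential decay recipe (50 ns window, 1024 channels)."""
    return DecaySimSpec(seed=7)
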