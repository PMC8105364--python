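import numpy as np
import pytest

import gfelute as g

K_REF = g.rate_from_half_life(22.75)  # the reference degradation rate, 1/h


@pytest.fixture
def k_ref() -> float:
    return K_REF


@pytest.fixture
def culture_system() -> g.CultureSystem:
    """The default culture geometry: 1.9 cm² coated area under 0.6 mL."""
    return g.CultureSystem(surface_area=1.9, media_volume=0.6)


@pytest.fixture
def exact_timecourse() -> g.Timecourse:
    """Noiseless single-exponential assay, k = 0.03/h, c0 = 400 ng/mL."""
    t = np.array([8.0, 16.0, 24.0, 48.0, 72.0, 96.0])
    return g.Timecourse(
        condition_label="exact",
        replicate_id="r1",
        samples=tuple(zip(t, 400.0 * np.exp(-0.03 * t))),
    )


@pytest.fixture
def powerlaw_source() -> g.PowerLawFit:
    return g.PowerLawFit(K=0.05, n=0.3, M_infinity=10.0, r_squared=1.0,
                         fit_domain=(0.0, 96.0))
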