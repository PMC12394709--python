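import numpy as np
import pytest

from cephalon.isolation import isolate_traces
from cephalon.synthetic import TaphonomyParams, make_template, render_plate

#: conditions of the standard image-recovery experiment: a half-rotated
#: specimen with background speckle and a tonal gradient
RECOVERY_TAPHONOMY = dict(
    rotation_asymmetry=0.5, speckle_rate=0.0005, tone_gradient=0.15, seed=2
)
RECOVERY_DENSITY = 0.02


@pytest.fixture(scope="session")
def template():
    return make_template(seed=1)


@pytest.fixture(scope="session")
def recovery_plate(template):
    """Plate + ground truth under the standard recovery conditions."""
    return render_plate(
        template, RECOVERY_DENSITY, TaphonomyParams(**RECOVERY_TAPHONOMY)
    )


@pytest.fixture(scope="session")
def recovery_density(recovery_plate):
    plate, _ = recovery_plate
    return isolate_traces(plate)
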