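import numpy as np
import pytest

from limbarch import dti, phantoms

#: muscle-typical diffusion eigenvalues (mm^2/s); FA ~ 0.21, inside the gate
MUSCLE_EVALS = (2.1e-3, 1.6e-3, 1.4e-3)


@pytest.fixture(scope="session")
def const_annulus():
    """Constant-thickness tube: inner r 12.0, outer 13.2 mm (truth 1.2 mm)."""
    profile = phantoms.FasciaProfile(mean_thickness_mm=1.2)
    mask, truth = phantoms.make_fascia_phantom(12.6, profile, (0.3, 0.3, 3.0), 10, seed=0)
    return mask, truth


@pytest.fixture(scope="session")
def const_annulus_fine():
    profile = phantoms.FasciaProfile(mean_thickness_mm=1.2)
    mask, truth = phantoms.make_fascia_phantom(12.6, profile, (0.15, 0.15, 3.0), 10, seed=0)
    return mask, truth


@pytest.fixture(scope="session")
def perturbed_tube():
    profile = phantoms.FasciaProfile(
        mean_thickness_mm=1.2,
        thickness_harmonics=((2, 0.2, None),),
        radius_harmonics=((3, 0.04, None),),
    )
    mask, truth = phantoms.make_fascia_phantom(12.6, profile, (0.3, 0.3, 3.0), 6, seed=7)
    return mask, truth


@pytest.fixture(scope="session")
def pennate30():
    """Unipennate 30 degree phantom tracked end to end, noiseless."""
    mask, tfield, truth = phantoms.make_pennate_phantom(
        (20.0, 20.0, 30.0), 30.0, MUSCLE_EVALS, (2.0, 2.0, 2.0)
    )
    stack = phantoms.simulate_dwi(tfield, phantoms.twenty_direction_table(), 500.0)
    fitted = dti.fit_tensors(stack, mask.binary())
    tracts = dti.track_fibers(fitted, mask.binary(), dti.TrackingParams(target_count=150), seed=42)
    tracts = dti.extrapolate_tracts(tracts, mask)
    tracts = dti.filter_tracts(tracts)
    return mask, tfield, truth, stack, fitted, tracts
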