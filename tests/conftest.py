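import dataclasses

import numpy as np
import pytest

from oculomorph.phantom import (
    EyePhantomSpec,
    default_group_params,
    make_eye_mask,
    sample_cohort,
)

VOX = 0.7


def scaled_groups(n_by_label: dict):
    """Default group parameters with resized (or dropped) groups."""
    out = []
    for gp in default_group_params():
        if gp.group_label in n_by_label:
            out.append(dataclasses.replace(gp, n_eyes=n_by_label[gp.group_label]))
    return out


@pytest.fixture(scope="session")
def sphere_mask():
    """Digitised sphere, diameter 23.2 mm (control-like geometry)."""
    return make_eye_mask(EyePhantomSpec(11.6, 11.6, 11.6, voxel_size=VOX))


@pytest.fixture(scope="session")
def myopic_ellipsoid_mask():
    """Digitised spheroid with axial 25.6 mm / equatorial 24.3 mm diameters."""
    return make_eye_mask(EyePhantomSpec(12.8, 12.15, 12.15, voxel_size=VOX))


@pytest.fixture(scope="session")
def default_cohort():
    return sample_cohort(seed=20240917)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
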