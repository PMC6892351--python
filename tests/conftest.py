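import numpy as np
import pytest

from eegcharge.config import RunConfig
from eegcharge.forward import (SourceSpace, build_source_space,
                               build_spherical_montage, compute_lead_field,
                               default_parcel_spec)
from eegcharge.pipeline import Geometry, build_geometry


@pytest.fixture(scope="session")
def geometry64() -> Geometry:
    """Default 64-channel geometry with the 12-parcel source space."""
    return build_geometry(RunConfig(n_channels=64))


@pytest.fixture(scope="session")
def geometry32() -> Geometry:
    return build_geometry(RunConfig(n_channels=32))


@pytest.fixture(scope="session")
def grid_geometry():
    """64-channel montage over a 64-source localization grid."""
    montage = build_spherical_montage(64, 0.09)
    dirs = build_spherical_montage(16, 1.0).positions
    locs = np.concatenate([dirs * r for r in (0.03, 0.045, 0.06, 0.075)])
    grid = SourceSpace(locations=locs,
                       parcel_labels=("BA10",) * len(locs),
                       depth_class={"BA10": "cortical"})
    lf = compute_lead_field(montage, grid)
    return montage, grid, lf
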