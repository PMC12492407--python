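import numpy as np
import pytest

from loopsom.geometry import build_backbone
from loopsom.synthetic import FluctuationSpec, simulate_fluctuating_trajectory


@pytest.fixture
def helix_frame():
    """Idealized 20-residue alpha-helical backbone."""
    return build_backbone([(-60.0, -45.0, 180.0)] * 20)


@pytest.fixture
def wiggle_trajectory(helix_frame):
    """Small Gaussian-fluctuation trajectory (sigma 0.3 A, 50 frames)."""
    spec = FluctuationSpec(helix_frame, np.full(20, 0.3), n_frames=50, seed=11)
    return simulate_fluctuating_trajectory(spec, "wiggle", 0)
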