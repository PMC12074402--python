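import numpy as np
import pytest

from predetach import synthetic


@pytest.fixture
def checkerboard() -> np.ndarray:
    """64x64 RGB checkerboard with 8-px squares (sharp, high contrast)."""
    board = np.zeros((64, 64, 3), dtype=np.uint8)
    idx = (np.indices((64, 64)).sum(axis=0) // 8) % 2 == 0
    board[idx] = 255
    return board


@pytest.fixture
def canonical_spec() -> synthetic.ScenarioSpec:
    """Reference extraction scenario: tube settles, target cell oscillates
    after a calm plateau, then jumps 120 px and disappears."""
    return synthetic.canonical_scenario(seed=1, n_frames=80,
                                        detachment_frame=60, onset=52)


@pytest.fixture
def canonical_trajectories(canonical_spec):
    return synthetic.generate_trajectories(canonical_spec)
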