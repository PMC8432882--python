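import numpy as np
import pytest

from fascx.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def clean_scene():
    """One noiseless, in-focus synthetic scene shared across tests."""
    spec = SceneSpec(seed=11, blur_sigma=0.0, noise_sd=0.0)
    return generate_scene(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_blob(rng: np.random.Generator, n_px: int = 40, size: int = 40) -> np.ndarray:
    """Random 8-connected pixel blob grown from a seed pixel, as (n, 2) coords."""
    start = (size // 2, size // 2)
    grid = np.zeros((size, size), dtype=bool)
    grid[start] = True
    frontier = [start]
    while grid.sum() < n_px and frontier:
        r, c = frontier[rng.integers(len(frontier))]
        dr, dc = rng.integers(-1, 2, size=2)
        rr, cc = int(np.clip(r + dr, 0, size - 1)), int(np.clip(c + dc, 0, size - 1))
        if not grid[rr, cc]:
            grid[rr, cc] = True
            frontier.append((rr, cc))
    return np.argwhere(grid)
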