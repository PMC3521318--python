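import numpy as np
import pytest

from lightshare.genotypes import load_shipped_genotypes, load_wheat_stages
from lightshare.geometry import organ_tessellate
from lightshare.scene import Scene


@pytest.fixture(scope="session")
def genotypes():
    return load_shipped_genotypes()


@pytest.fixture(scope="session")
def wheat_stages():
    return load_wheat_stages()


def poisson_leaf_scene(
    seed: int,
    lai: float = 1.0,
    leaf_mm: float = 25.0,
    plot: float = 0.5,
    inclination: float = 0.0,
    species: str = "pea",
) -> Scene:
    """Homogeneous canopy of small square leaves at uniform random
    positions and heights over a periodic plot."""
    rng = np.random.default_rng(seed)
    n = int(round(lai * plot * plot / (leaf_mm * 1e-3) ** 2))
    organs = []
    for _ in range(n):
        base = np.array([
            rng.uniform(0, plot), rng.uniform(0, plot), rng.uniform(0.05, 0.45),
        ])
        organs.append(organ_tessellate(
            "stipule", leaf_mm, leaf_mm, inclination, rng.uniform(0, 360),
            base, outline="rect", species=species,
        ))
    return Scene(organs=organs, plot_x=plot, plot_y=plot)
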