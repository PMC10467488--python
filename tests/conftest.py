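"""Shared fixtures: a compact chip layout and fast render configurations.

Classification tests use a scaled-down chip (same five well sizes, tighter
ring radii, coarser pixels) so each render stays small; geometry and
classification logic are identical to the full-size default layout.
"""

import numpy as np
import pytest

from phantomforge.synthetic_data import BandOptics, SceneConfig
from phantomforge.wellclass import ChipLayout


@pytest.fixture(scope="session")
def small_layout() -> ChipLayout:
    return ChipLayout(
        rings=(
            (100.0, 1500.0),
            (250.0, 3000.0),
            (500.0, 4500.0),
            (1000.0, 6500.0),
            (5000.0, 10500.0),
        )
    )


@pytest.fixture
def bright_scene(small_layout) -> SceneConfig:
    """Noiseless scene whose weakest well sits far above the FL threshold."""
    return SceneConfig(layout=small_layout, gain=2.0e-2, noise_sigma=0.0, seed=11)


@pytest.fixture
def film_optics() -> tuple[BandOptics, BandOptics]:
    return BandOptics(mu_a=1.44, mu_s_prime=22.84), BandOptics(mu_a=0.5, mu_s_prime=15.0)
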