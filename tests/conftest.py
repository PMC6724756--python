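import numpy as np
import pytest

from fociquant import ChannelImage, ChannelSpec, SimulationConfig, simulate_image


def draw_disks(shape, disks, amplitude=100.0, background=0.0):
    """Binary-ish image of hard-edged disks: (row, col, radius) triples."""
    img = np.full(shape, background, dtype=np.float64)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for r, c, rad in disks:
        img[(rr - r) ** 2 + (cc - c) ** 2 <= rad * rad] = background + amplitude
    return img


def easy_scene(seed=0, n_nuclei=50, channels=None, size=320, **kw):
    """A well-spaced, high-SNR scene: the recovery-test regime."""
    channels = channels or (ChannelSpec("probeA", zero_inflation=0.2, mean_count=5.0),)
    cfg = SimulationConfig(
        image_height=size,
        image_width=size,
        n_nuclei=n_nuclei,
        channels=tuple(channels),
        seed=seed,
        **kw,
    )
    return simulate_image(cfg)


def half_amp_tolerance(spec: ChannelSpec, sigma: float = 1.0) -> float:
    return 0.5 * spec.effective_amplitude(sigma)


@pytest.fixture(scope="session")
def default_scene():
    return easy_scene(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def as_image(arr, name="img") -> ChannelImage:
    return ChannelImage(np.asarray(arr, dtype=np.float64), name)
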