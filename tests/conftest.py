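import numpy as np
import pytest

from tumourtrace.simulate import SimConfig, simulate_plate


def rasterize_disk(radius_px: float, pad: int = 4) -> np.ndarray:
    """Boolean mask of a disk rasterized at pixel centres (the pixel-count
    oracle used against the measured morphometrics)."""
    n = int(np.ceil(radius_px)) * 2 + 1 + 2 * pad
    c = n // 2
    yy, xx = np.ogrid[:n, :n]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2


def random_component(rng: np.random.Generator, size: int = 32) -> np.ndarray:
    """A random 8-connected component: largest component of a random mask."""
    from skimage import measure as skmeasure

    mask = rng.random((size, size)) < 0.45
    labelled = skmeasure.label(mask, connectivity=2)
    if labelled.max() == 0:
        out = np.zeros((size, size), dtype=bool)
        out[size // 2, size // 2] = True
        return out
    counts = np.bincount(labelled.ravel())[1:]
    return labelled == (int(np.argmax(counts)) + 1)


@pytest.fixture(scope="session")
def tiny_plate_config() -> SimConfig:
    """Noiseless, non-overlapping scenario small enough for fast pipelines."""
    return SimConfig(
        image_size=(384, 384),
        n_planes=3,
        plane_spacing=50.0,
        pixel_size=2.0,
        n_objects=5,
        radius_range=(30.0, 60.0),
        growth_rate=0.05,
        days=(1, 7, 14),
        doses=(0.0, 10.0),
        noise_sd=0.0,
        min_separation=260.0,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def tiny_plate(tiny_plate_config):
    return simulate_plate(tiny_plate_config, n_replicates=2)
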