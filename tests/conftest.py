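import numpy as np
import pytest

from dropmetry.geometry import calibrate
from dropmetry.synthetic import (
    GeneratorConfig,
    RenderSpec,
    generate_records,
    render_droplet,
)


@pytest.fixture(scope="session")
def microruler_calibration():
    """The 10 mm / 1028 px micro-ruler calibration."""
    return calibrate(10.0, 1028.0)


@pytest.fixture(scope="session")
def design_dataset():
    """1758 synthetic print records at the default noise level."""
    return generate_records(1758, GeneratorConfig(noise_cv=0.02, seed=42))


@pytest.fixture(scope="session")
def hemisphere_render():
    """A clean D=2 mm, theta=90 deg render with its analytic ground truth."""
    spec = RenderSpec(diameter_mm=2.0, theta_deg=90.0, noise=0.0, seed=3)
    image, truth, circle_px, baseline_px = render_droplet(spec)
    return spec, image, truth, circle_px, baseline_px


@pytest.fixture(scope="session")
def render_dir(tmp_path_factory, microruler_calibration):
    """Three clean rendered droplet PNGs on disk plus their ground truths."""
    from dropmetry.io import write_image

    out = tmp_path_factory.mktemp("renders")
    specs = [
        RenderSpec(diameter_mm=d, theta_deg=t, noise=0.0, seed=i)
        for i, (d, t) in enumerate([(2.0, 90.0), (1.6, 75.0), (2.8, 110.0)])
    ]
    paths, truths = [], []
    for i, spec in enumerate(specs):
        image, truth, _, _ = render_droplet(spec)
        path = out / f"droplet_{i}.png"
        write_image(image, path)
        paths.append(path)
        truths.append(truth)
    return paths, truths


def uniform_image(value=128, shape=(64, 64)):
    return np.full(shape, value, dtype=np.uint8)
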