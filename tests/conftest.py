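import numpy as np
import pytest

from ecmquant import synthgen


def random_spheroid_spec(rng: np.random.Generator, seed: int) -> synthgen.SpheroidSpec:
    """One draw from the study conditions used for end-to-end recovery."""
    halo = float(rng.uniform(100, 150))
    return synthgen.SpheroidSpec(
        image_size_px=(384, 384),
        core_radius_px=float(rng.uniform(40, 70)),
        halo_cell_count=int(rng.integers(100, 300)),
        halo_outer_radius_px=halo,
        single_cell_count=int(rng.integers(10, 31)),
        single_cell_min_dist_px=halo + 40.0,
        nucleus_radius_px=float(rng.uniform(4, 6)),
        snr=float(rng.uniform(5, 10)),
        illumination_gradient_amplitude=float(rng.uniform(0, 0.3)),
        seed=seed,
    )


@pytest.fixture(scope="session")
def clean_spheroid():
    """Noise-free, gradient-free spheroid field with halo and singles."""
    spec = synthgen.SpheroidSpec(
        snr=np.inf, illumination_gradient_amplitude=0.0, single_cell_count=25, seed=11
    )
    stack, truth = synthgen.make_spheroid_image(spec)
    return spec, stack, truth
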