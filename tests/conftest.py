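import numpy as np
import pytest

from bmdetect.phantom import PhantomConfig, generate_scan


def small_config(**overrides) -> PhantomConfig:
    """A desk-scale phantom grid for fast unit tests.

    96x96 in-plane at 0.9 mm keeps the 5 mm lesion floor several pixels
    wide, so the size/visibility invariants are the same as at full scale.
    """
    base = dict(
        grid=(20, 96, 96),
        pixel_size_mm=(0.9, 0.9),
        slice_thickness_mm=3.0,
        n_lesions=2,
        lesion_diameter_range_mm=(6.0, 12.0),
        n_vessels=2,
        noise_sigma=0.0,
        seed=0,
    )
    base.update(overrides)
    return PhantomConfig(**base)


@pytest.fixture(scope="session")
def clean_phantom():
    """One noise-free small phantom with two lesions, shared across tests."""
    cfg = small_config(seed=42)
    volume, truth = generate_scan(cfg, scan_id="clean")
    return cfg, volume, truth
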