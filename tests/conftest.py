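import numpy as np
import pytest

from hipmetrics.phantom import (
    PhantomConfig,
    PhantomGeometryError,
    RaterModel,
    construct_landmarks,
    generate_dataset,
)


def sample_feasible_config(rng, image_size=256, rotation=True, **kwargs):
    """Rejection-sample a phantom config whose angle triple is constructible."""
    while True:
        cfg = PhantomConfig(
            image_height=image_size,
            image_width=image_size,
            ce_deg=float(rng.uniform(-5, 40)),
            tonnis_deg=float(rng.uniform(-5, 24)),
            sharp_deg=float(rng.uniform(25, 58)),
            rotation_deg=float(rng.uniform(-8, 8)) if rotation else 0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
            **kwargs,
        )
        try:
            ann = construct_landmarks(cfg)
        except (PhantomGeometryError, ValueError):
            continue
        return cfg, ann


@pytest.fixture(scope="session")
def small_dataset():
    """A 25-image phantom dataset with default rater jitter."""
    return generate_dataset(25, seed=101)


@pytest.fixture(scope="session")
def clean_dataset():
    """A noiseless 10-image dataset with zero rater jitter (consensus == truth)."""
    return generate_dataset(
        10, rater_model=RaterModel.zero(), seed=202, noise_sigma=0.0
    )
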