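"""Shared fixtures.

The heavier fixtures (fitted detectors, whole synthetic experiments) are
session-scoped: several test modules reuse the same fitted template bank
and generated fields instead of regenerating them.
"""

from __future__ import annotations

import numpy as np
import pytest

from standcount import (
    FieldConfig,
    SeedlingCounter,
    generate_experiment,
    generate_plot,
)
from standcount.pipeline import sample_patch_centers


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_field():
    """A 2-plot default-conditions field with truth (weeds and overlap on)."""
    config = FieldConfig(n_plots=2, seed=3)
    experiment = generate_experiment(config)
    image, truth = generate_plot(config, 0)
    return config, experiment, image, truth


@pytest.fixture(scope="session")
def fitted_counter(small_field):
    """A SeedlingCounter fitted on the small field's truth patches."""
    config, experiment, _image, _truth = small_field
    counter = SeedlingCounter(random_state=config.seed)
    centers = sample_patch_centers(experiment, n_patches=300)
    images = [experiment.plot_image(i) for i in sorted(centers)]
    counter.fit(images, [centers[i] for i in sorted(centers)])
    return counter
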