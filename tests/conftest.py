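import numpy as np
import pytest

import tetraclass as tc
from tetraclass import classify as clf
from tetraclass import synthetic_data as synth


@pytest.fixture(scope="session")
def small_model():
    """A modest trained + calibrated model shared across the suite.

    3,000 panels (mode mix proportional to the default configuration) are
    enough for the forest to rank bimodality cleanly; the ROC threshold is
    calibrated on 600 labeled held-out panels.
    """
    training = tc.generate_training_set(1500, 750, 750, rng_seed=20240101)
    model = clf.train_bimodality_model(training, rng_seed=7)
    labeled = tc.generate_labeled_eval_set(300, 300, rng_seed=20240102)
    clf.calibrate_threshold(model, labeled)
    return model


def make_planted_panels(true_class: str, n: int, seed: int, noise_sd: float = 0.05):
    """Panels from architectures planted with a known complexity class."""
    rng = np.random.default_rng(seed)
    panels = []
    for _ in range(n):
        arch = synth.architecture_for_class(true_class, rng_seed=rng,
                                            noise_sd=noise_sd)
        genotypes = tc.simulate_tetrad_genotypes(40, rng_seed=rng)
        panels.append(tc.compute_phenotypes(genotypes, arch, rng_seed=rng))
    return panels
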