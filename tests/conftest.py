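import numpy as np
import pytest

import strokepred as sp


@pytest.fixture(scope="session")
def small_basis():
    """A 60-region x 8-component basis, cheap enough for repeated fits."""
    return sp.generate_component_basis(60, 8, smoothness=0.5, seed=11)


@pytest.fixture(scope="session")
def small_study(small_basis):
    """A complete low-dimensional synthetic study with modest noise."""
    dataset, truth = sp.generate_disconnections(
        small_basis, n_patients=62, n_active=3, noise_sd=0.005, seed=21,
        k_active=3, outcome_noise_sd=0.5, latent_factor_corr=0.5,
    )
    scores = sp.estimate_component_scores(dataset, small_basis)
    battery = sp.generate_motor_battery(truth, truth.mixing_weights, seed=21,
                                        test_noise_sd=0.1)
    return {
        "basis": small_basis,
        "dataset": dataset,
        "truth": truth,
        "scores": scores,
        "battery": battery,
    }


@pytest.fixture(scope="session")
def full_scale_study():
    """One study at the clinical scale: 62 patients, 372 regions, 46 components."""
    basis = sp.generate_component_basis(372, 46, smoothness=0.5, seed=7)
    dataset, truth = sp.generate_disconnections(
        basis, n_patients=62, n_active=5, noise_sd=0.01, seed=7
    )
    scores = sp.estimate_component_scores(dataset, basis)
    battery = sp.generate_motor_battery(truth, truth.mixing_weights, seed=7)
    return {
        "basis": basis,
        "dataset": dataset,
        "truth": truth,
        "scores": scores,
        "battery": battery,
    }
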