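"""Shared fixtures: reference parameter sets and synthetic datasets.

The expensive objects (the noiseless effector-memory recovery fit in
particular) are session-scoped so several tests can share them.
"""

import dataclasses

import numpy as np
import pytest

from memokin.labelling.inference import BrdUKi67Model
from memokin.labelling.spec import resolve_steady_state
from memokin.synthetic import (
    LabellingTruth,
    chimera_truth_preset,
    generate_chimera_dataset,
    generate_labelling_dataset,
    labelling_spec_preset,
)


@pytest.fixture(scope="session")
def tem_spec():
    return labelling_spec_preset("tem")


@pytest.fixture(scope="session")
def tem_space(tem_spec):
    return resolve_steady_state(tem_spec)


@pytest.fixture(scope="session")
def tem_kappa(tem_space):
    return tem_space.kappa_model


@pytest.fixture(scope="session")
def noiseless_labelling_data(tem_spec):
    truth = LabellingTruth(spec=tem_spec, sigma=0.0, mice_per_timepoint=1)
    return generate_labelling_dataset(truth, seed=0)


@pytest.fixture(scope="session")
def tem_recovery_fit(noiseless_labelling_data, tem_kappa):
    """KH fit to noiseless effector-memory data: the self-consistency
    recovery experiment."""
    model = BrdUKi67Model(
        noiseless_labelling_data,
        structure="KH",
        s_week=0.07,
        kappa_obs=tem_kappa,
        khat=12,
        bhat=2,
        death_ratio=1.0,
    )
    return model.fit(seed=1, n_starts=8, rss_tol=1e-10)


@pytest.fixture(scope="session")
def tem_chimera_truth():
    return chimera_truth_preset("tem")


@pytest.fixture(scope="session")
def noiseless_chimera_data(tem_chimera_truth):
    truth = dataclasses.replace(
        tem_chimera_truth, sigma_logcount=0.0, sigma_chimerism=0.0, mice_per_age=1
    )
    return generate_chimera_dataset(truth, seed=1)


@pytest.fixture(scope="session")
def noisy_chimera_data(tem_chimera_truth):
    return generate_chimera_dataset(tem_chimera_truth, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
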