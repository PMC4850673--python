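"""Shared fixtures.

The expensive objects (training simulation, labeled instances, trained
ensemble, evaluation simulation on disk) are session-scoped so the
acceptance tests can share one realistic V34-like world: 2 x 250 bp
reads, 430 nt amplicons, 15 references at 90-97 % identity.
"""
from __future__ import annotations

import warnings

import numpy as np
import pytest

import iped
from iped._align import ReferenceSet
from iped.features import SELECTED_FEATURES
from iped.simulate import write_sim

SEED = 7


@pytest.fixture(scope="session")
def refs_v34():
    return iped.synthetic_references(n_refs=15, length=430, seed=SEED)


@pytest.fixture(scope="session")
def profile_v34():
    return iped.profile_from_preset("v34")


@pytest.fixture(scope="session")
def training_bundle_v34(refs_v34, profile_v34):
    """Labeled, balanced training bundle at the stated 5,000/15,000 caps."""
    sim = iped.simulate_mock(refs_v34, 15000, profile_v34, seed=SEED + 1)
    contigs, _ = iped.merge_pairs(sim.pairs)
    X, y, _ = iped.build_labeled_instances(contigs, ReferenceSet(refs_v34))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return iped.build_training_bundle(X, y, seed=SEED, names=SELECTED_FEATURES)


@pytest.fixture(scope="session")
def model_v34(training_bundle_v34):
    return iped.train_ensemble(training_bundle_v34, seed=SEED)


@pytest.fixture(scope="session")
def simdir_v34(tmp_path_factory, refs_v34, profile_v34):
    """20,000 evaluation pairs, written in the on-disk layout."""
    sim = iped.simulate_mock(refs_v34, 20000, profile_v34, seed=SEED)
    out = tmp_path_factory.mktemp("sim_v34")
    write_sim(sim, out)
    return out


@pytest.fixture(scope="session")
def small_world():
    """A tiny, fast simulated dataset for unit tests (120 nt amplicons)."""
    refs = iped.synthetic_references(n_refs=5, length=120, seed=1)
    profile = iped.ErrorProfile(read_len=70, amplicon_len=120)
    sim = iped.simulate_mock(refs, 400, profile, seed=2)
    contigs, _ = iped.merge_pairs(sim.pairs)
    return {"refs": refs, "profile": profile, "sim": sim, "contigs": contigs}


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
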