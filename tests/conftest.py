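"""Shared fixtures: small synthetic compound sets and trained bundles.

Heavy objects (trained classifier bundles) are session-scoped so the suite
trains each model once. Sizes are deliberately small: 4 scaffold classes of
20 compounds and 3 selectivity classes of 40, with 5-fold x 2-repeat CV and
150-tree forests, enough for the separability properties under test.
"""

import numpy as np
import pytest
from hypothesis import settings

import herbiscreen as hs
from herbiscreen import workflows as wf
from herbiscreen.chem_io import relabel

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

CV_FAST = {"folds": 5, "repeats": 2}
SEED = 11


@pytest.fixture(scope="session")
def moa_set() -> hs.CompoundSet:
    return hs.generate_scaffold_classes(
        hs.SyntheticSpec(n_classes=4, n_per_class=20, seed=SEED)
    )


@pytest.fixture(scope="session")
def moa_bundle(moa_set):
    bundle, test_ids, excluded = wf.train_moa_bundle(
        moa_set, split=hs.SplitSpec(seed=SEED), cv=CV_FAST, n_trees=150
    )
    return bundle, test_ids, excluded


@pytest.fixture(scope="session")
def sel_set() -> hs.CompoundSet:
    return hs.generate_selectivity_set(
        hs.SyntheticSpec(n_per_class=40, seed=SEED)
    )


@pytest.fixture(scope="session")
def sel_bundle(sel_set):
    bundle, test_ids, excluded = wf.train_selectivity_bundle(
        sel_set, split=hs.SplitSpec(seed=SEED), cv=CV_FAST, n_trees=150
    )
    return bundle, test_ids, excluded


@pytest.fixture(scope="session")
def dual_label_set(moa_set) -> hs.CompoundSet:
    """Scaffold classes carrying both MoA and selectivity labels."""
    sel_cycle = {"A": "BL", "B": "G", "C1": "NS", "E": "BL"}
    records = [
        relabel(r, selectivity_label=sel_cycle[r.moa_label])
        for r in moa_set
    ]
    return hs.CompoundSet(records, provenance="dual-labelled synthetic set")


@pytest.fixture(scope="session")
def dual_bundles(dual_label_set):
    """(selectivity bundle, moa bundle) trained on the same compound set."""
    split = hs.SplitSpec(seed=SEED)
    sel, _, _ = wf.train_selectivity_bundle(
        dual_label_set, split=split, cv=CV_FAST, n_trees=150
    )
    moa, _, _ = wf.train_moa_bundle(
        dual_label_set, split=split, cv=CV_FAST, n_trees=150
    )
    return sel, moa


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)
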