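import warnings

import numpy as np
import pytest

import fossiltrend as ft
from fossiltrend.synthetic_data import SimConfig, sim_fbd_tree, sim_traits


@pytest.fixture(autouse=True)
def _quiet_zero_length_warnings():
    """Synthetic fossil trees legitimately carry zero-length attachments."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="zero-length terminal")
        yield


@pytest.fixture
def three_tip_tree():
    return ft.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def fossil_tree():
    """A 3-tip tree with one extinct tip (B at 0.5 Ma)."""
    return ft.read_newick("((A:1,B:0.5):1,C:2);")


@pytest.fixture
def small_fbd_tree():
    cfg = SimConfig(
        min_tips=10, max_tips=14, origin=12, birth=0.3, death=0.1, psi=0.15
    )
    return sim_fbd_tree(cfg, seed=1)


@pytest.fixture
def medium_fbd_tree():
    cfg = SimConfig(min_tips=60, max_tips=100, origin=36)
    return sim_fbd_tree(cfg, seed=2)


def make_bm_dataset(tree, sigma2=0.002, theta=2.66, seed=0, se=0.0):
    y = sim_traits(tree, "BM", {"sigma2": sigma2, "theta": theta}, seed=seed)
    n = tree.n_tips
    return ft.TraitDataset(
        species=list(tree.tip_labels),
        mean=y.to_numpy(),
        n=np.ones(n, int),
        se=np.full(n, float(se)),
    )


@pytest.fixture
def bm_dataset(small_fbd_tree):
    return make_bm_dataset(small_fbd_tree, sigma2=0.3, theta=1.0, seed=7)
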