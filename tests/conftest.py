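import numpy as np
import pytest

import isletvasc as iv


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_islet():
    """Overlap-free synthetic human islet, small enough for fast tests."""
    arch = iv.synthesize_islet(40, target_diameter=47, seed=11)
    return arch


@pytest.fixture(scope="session")
def small_grid(small_islet):
    return iv.rasterize(small_islet)


@pytest.fixture(scope="session")
def small_vascularized(small_grid):
    """Small islet grid with a few capillaries grown for 40 MCS."""
    pool = iv.generate_initial_capillaries(small_grid, n_per_axis=3, seed=12)
    paths = iv.select_capillary_subset(pool, 5, seed=13)
    cfg = iv.CPMConfig(n_mcs=40, checkpoint_every=5)
    vgrid, report = iv.evolve_capillaries(small_grid, paths, cfg, seed=14)
    return vgrid, paths, report


def make_grid(shape, boxes=()):
    """Empty medium grid with optional labeled boxes: (label, type, slices)."""
    labels = np.zeros(shape, dtype=np.int32)
    max_label = max([lab for lab, _, _ in boxes], default=0)
    type_of = np.zeros(max_label + 1, dtype=np.int8)
    for lab, typ, sl in boxes:
        labels[sl] = lab
        type_of[lab] = typ
    return iv.LabeledGrid(labels, type_of)
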