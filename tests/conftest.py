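"""Shared fixtures: small synthetic complexes and maps, generated at test time."""

import numpy as np
import pytest

from maplink import (
    AtomicModel,
    FitSearchConfig,
    ToyComplexSpec,
    build_fit_library,
    make_toy_complex,
    simulate_crosslinks,
    simulate_map,
)


def random_ca_model(n=40, seed=0, chain="A", box=30.0) -> AtomicModel:
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, box, size=(n, 3))
    return AtomicModel(
        np.array([chain] * n, dtype=object),
        np.arange(1, n + 1),
        np.array(["ALA"] * n, dtype=object),
        np.array(["CA"] * n, dtype=object),
        np.array(["C"] * n, dtype=object),
        pos,
    )


@pytest.fixture(scope="session")
def small_truth():
    """3-subunit toy complex, 30 residues each (fast unit-test scale;
    large enough that pairs beyond the 45 Å decoy band exist)."""
    return make_toy_complex(ToyComplexSpec(
        n_subunits=3, residues_per_subunit=30, seed=13))


@pytest.fixture(scope="session")
def small_map(small_truth):
    return simulate_map(small_truth.model, resolution=8.0, voxel_size=2.0,
                        padding=10.0)


@pytest.fixture(scope="session")
def small_xl(small_truth):
    return simulate_crosslinks(small_truth, n_true=6, decoy_fraction=0.5, seed=3)


@pytest.fixture(scope="session")
def small_libraries(small_truth, small_map):
    """Fit libraries holding the ground-truth placement plus alternatives."""
    mass = small_truth.spec.total_mass()
    libs = {}
    for lab in small_truth.subunit_labels():
        cfg = FitSearchConfig(n_searches=3000, seed=5, target_mass=mass,
                              refine_top=60, max_candidates=12)
        libs[lab] = build_fit_library(small_truth.canonical[lab], small_map,
                                      cfg, resolution=8.0, subunit=lab)
    return libs
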