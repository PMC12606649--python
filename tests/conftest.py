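"""Shared fixtures: toy structures, a small synthetic cohort, reduced grids."""

import numpy as np
import pytest

from fespred import mlcore, synthetic
from fespred.datasetio import FeaturizerConfig, build_design_matrix
from fespred.structio import AtomRecord, Residue, Structure


@pytest.fixture(scope="session")
def fe2s2_toy():
    return synthetic.make_toy_structure(synthetic.ToyStructureSpec(seed=5))


@pytest.fixture(scope="session")
def mono_toy():
    spec = synthetic.ToyStructureSpec(site_kind="mono_fe", seed=5)
    return synthetic.make_toy_structure(spec)


@pytest.fixture(scope="session")
def structure_pool():
    """A pool of randomized toy structures for geometry property tests."""
    rng = np.random.default_rng(1234)
    pool = []
    for i in range(12):
        n = int(rng.integers(3, 12))
        seq = ("CYS", "CYS", "CYS", "CYS") + tuple(rng.choice(
            ["GLY", "ALA", "SER", "HIS", "LYS", "ASP", "TRP"], size=n))
        shells = tuple(np.round(rng.uniform(3.5, 20.0, size=n), 3))
        kind = "mono_fe" if i % 4 == 0 else "fe2s2"
        pool.append(synthetic.make_toy_structure(synthetic.ToyStructureSpec(
            site_kind=kind, sequence=seq, shells=shells, seed=i,
            structure_id=f"pool{i}")))
    return pool


@pytest.fixture(scope="session")
def small_dataset():
    spec = synthetic.SyntheticRPSpec(n_proteins=8, mutants_per_protein=2, seed=3)
    return synthetic.make_synthetic_dataset(spec)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    return build_design_matrix(small_dataset.entries, FeaturizerConfig(r1=11, r2=4),
                               structures=small_dataset.structures)


@pytest.fixture(scope="session")
def tiny_grid():
    """Two-configuration grid for fast inner selection in tests."""
    return [{"max_depth": 3, "n_estimators": 60, "learning_rate": 0.2,
             "min_child_weight": 1},
            {"max_depth": 4, "n_estimators": 60, "learning_rate": 0.2,
             "min_child_weight": 5}]


@pytest.fixture(scope="session")
def one_config():
    return [{"max_depth": 4, "n_estimators": 100, "learning_rate": 0.1,
             "min_child_weight": 1}]


@pytest.fixture
def fast_cv():
    return mlcore.CVConfig(outer_folds=5, inner_folds=3, repeats=1, base_seed=0)


def build_structure(residue_specs, hetero_specs, structure_id="manual",
                    resolution=None):
    """Hand-build a Structure from ((code, key, ((name, element, xyz), ...)), ...)."""
    def _mk(code, key, atoms, het):
        recs = tuple(AtomRecord(atom_name=n, element=e,
                                coords=np.asarray(c, float), residue_key=key,
                                het_flag=het) for n, e, c in atoms)
        from fespred.structio import STANDARD_AA
        return Residue(three_letter_code=code, residue_key=key, atoms=recs,
                       is_standard_aa=code in STANDARD_AA)

    residues = [_mk(c, k, a, False) for c, k, a in residue_specs]
    hetero = [_mk(c, k, a, True) for c, k, a in hetero_specs]
    return Structure(id=structure_id, residues=residues, hetero_groups=hetero,
                     resolution=resolution)
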