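import numpy as np
import pytest

from batropy.topology import (AtomTable, BATTrajectory, build_bat_tree,
                              join_complex)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_chain(n_atoms, mass=12.011):
    """n-atom linear chain topology."""
    atoms = AtomTable.from_masses([mass] * n_atoms)
    bonds = [(i, i + 1) for i in range(n_atoms - 1)]
    return atoms, bonds


def make_random_topology(n_atoms, seed):
    """Random branched tree topology whose atoms 0-1-2 form a bonded chain
    (so (0, 1, 2) is always a valid root triple)."""
    r = np.random.default_rng(seed)
    bonds = [(0, 1), (1, 2)]
    for a in range(3, n_atoms):
        bonds.append((int(r.integers(0, a)), a))
    return AtomTable.from_masses([12.011] * n_atoms), bonds


def random_bat_values(tree, n_frames, rng):
    """Geometrically safe random BAT values for round-trip tests."""
    vals = np.empty((n_frames, tree.n_dofs))
    for i, d in enumerate(tree.dofs):
        if d.kind in ("bond", "ext_bond"):
            vals[:, i] = 0.15 + 0.02 * rng.standard_normal(n_frames)
        elif d.kind in ("angle", "ext_angle"):
            # keep angles safely inside (0, pi): values outside flip the
            # dependent dihedral branch by pi, which is a property of the
            # coordinates, not an estimator defect
            vals[:, i] = np.clip(
                np.pi / 2 + 0.4 * rng.standard_normal(n_frames), 0.3,
                np.pi - 0.3)
        else:
            vals[:, i] = rng.uniform(-np.pi, np.pi, n_frames)
    return vals


def make_complex(n_a, n_b, seed_a=1, seed_b=2):
    atoms_a, bonds_a = make_random_topology(n_a, seed_a)
    atoms_b, bonds_b = make_random_topology(n_b, seed_b)
    tree_a = build_bat_tree(atoms_a, bonds_a, (0, 1, 2))
    tree_b = build_bat_tree(atoms_b, bonds_b, (0, 1, 2)).offset_atoms(n_a)
    return tree_a, tree_b, join_complex(tree_a, tree_b,
                                        (n_a, n_a + 1, n_a + 2))


def periodic_abs_diff(a, b, periodic_mask):
    """Elementwise |a-b| with wrap-around on periodic columns."""
    d = np.abs(a - b)
    dp = d[:, periodic_mask]
    d[:, periodic_mask] = np.minimum(dp, 2 * np.pi - dp)
    return d
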