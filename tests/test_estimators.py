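"""Histogram entropy/MI estimators against closed forms and invariants."""

import numpy as np
import pytest
from scipy import constants

from batropy.estimators import (HistogramSpec, entropy_1d, entropy_2d,
                                external_reference_entropy,
                                momentum_entropy, mutual_information,
                                pairwise_mi_matrix)
from batropy.topology import AtomTable, BATTrajectory, DOFDescriptor

N = 200_000
SPEC = HistogramSpec()


def _gauss_pair(rho, sigma, n, seed):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    L = np.linalg.cholesky([[1.0, rho], [rho, 1.0]])
    return (z @ L.T) * sigma


class TestEntropy1D:
    def test_uniform_torsion_recovers_ln_2pi(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-np.pi, np.pi, N)
        s = float(entropy_1d(x, "torsion", SPEC))
        assert s == pytest.approx(np.log(2 * np.pi), abs=5e-3)

    def test_gaussian_torsion_recovers_closed_form(self):
        sigma = 0.3
        rng = np.random.default_rng(1)
        x = rng.normal(0.0, sigma, N)
        s = float(entropy_1d(x, "torsion", SPEC))
        assert s == pytest.approx(0.5 * np.log(2 * np.pi * np.e * sigma**2),
                                  abs=0.02)

    def test_degenerate_bond_warns(self):
        x = np.full(1000, 0.15)
        with pytest.warns(UserWarning, match="single bin"):
            s = float(entropy_1d(x, "bond", SPEC))
        assert np.isfinite(s)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            entropy_1d([], "torsion", SPEC)

    def test_miller_madow_adds_occupancy_correction(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-np.pi, np.pi, 5000)
        plain = float(entropy_1d(x, "torsion", SPEC))
        mm = float(entropy_1d(x, "torsion",
                              HistogramSpec(miller_madow=True)))
        assert mm - plain == pytest.approx((SPEC.bins_1d - 1) / (2 * 5000),
                                           rel=0.05)


class TestEntropy2D:
    def test_independent_uniform_pair(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-np.pi, np.pi, N)
        y = rng.uniform(-np.pi, np.pi, N)
        s = float(entropy_2d(x, y, ("torsion", "torsion"), SPEC))
        assert s == pytest.approx(2 * np.log(2 * np.pi), abs=0.02)

    def test_correlated_gaussian_pair(self):
        sigma, rho = 0.3, 0.8
        xy = _gauss_pair(rho, sigma, N, 4)
        s = float(entropy_2d(xy[:, 0], xy[:, 1], ("torsion", "torsion"), SPEC))
        expected = (np.log(2 * np.pi * np.e) + np.log(sigma**2)
                    + 0.5 * np.log(1 - rho**2))
        assert s == pytest.approx(expected, abs=0.05)

    def test_perfectly_correlated_pair_warns(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(-np.pi, np.pi, 10_000)
        with pytest.warns(UserWarning, match="one-dimensional"):
            entropy_2d(x, x, ("torsion", "torsion"), SPEC)


class TestMutualInformation:
    def test_independent_uniforms_near_zero(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(-np.pi, np.pi, N)
        y = rng.uniform(-np.pi, np.pi, N)
        mi = mutual_information(x, y, ("torsion", "torsion"), SPEC)
        # plug-in MI under independence ~ (k-1)^2/(2n)
        assert 0.0 <= mi < 2 * (SPEC.bins_2d - 1) ** 2 / (2 * N)

    @pytest.mark.parametrize("rho", [0.3, 0.8])
    def test_gaussian_mi_closed_form(self, rho):
        xy = _gauss_pair(rho, 0.5, N, 7)
        mi = mutual_information(xy[:, 0], xy[:, 1], ("torsion", "torsion"),
                                SPEC)
        assert mi == pytest.approx(-0.5 * np.log(1 - rho**2), abs=0.03)

    def test_identical_samples_saturate_at_binned_marginal(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(-np.pi, np.pi, 100_000)
        mi = mutual_information(x, x, ("torsion", "torsion"), SPEC)
        # independent discrete oracle: MI(X;X) = H(binned X)
        counts, _ = np.histogram(x, bins=SPEC.bins_2d, range=(-np.pi, np.pi))
        p = counts / counts.sum()
        h_binned = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mi == pytest.approx(h_binned, abs=1e-10)
        assert mi == pytest.approx(np.log(SPEC.bins_2d), abs=0.01)

    @pytest.mark.parametrize("kinds,loc", [
        (("bond", "bond"), 0.15),
        (("angle", "angle"), np.pi / 2),
        (("bond", "angle"), None),
    ])
    def test_jacobian_reference_cancels_exactly(self, kinds, loc):
        xy = _gauss_pair(0.6, 0.02 if "bond" in kinds else 0.2, 50_000, 9)
        locs = {"bond": 0.15, "angle": np.pi / 2}
        x = xy[:, 0] * (0.02 if kinds[0] == "bond" else 0.2) / xy[:, 0].std() \
            + locs[kinds[0]]
        y = xy[:, 1] * (0.02 if kinds[1] == "bond" else 0.2) / xy[:, 1].std() \
            + locs[kinds[1]]
        with_j = mutual_information(x, y, kinds, SPEC, use_jacobian=True)
        without = mutual_information(x, y, kinds, SPEC, use_jacobian=False)
        assert abs(with_j - without) < 1e-12

    def test_symmetry(self):
        xy = _gauss_pair(0.5, 0.4, 20_000, 10)
        a = mutual_information(xy[:, 0], xy[:, 1], ("torsion", "torsion"), SPEC)
        b = mutual_information(xy[:, 1], xy[:, 0], ("torsion", "torsion"), SPEC)
        assert a == pytest.approx(b, abs=1e-12)


class TestPairwiseMatrix:
    def _chain_traj(self, rho, sigma, n, seed, d=3):
        corr = rho ** np.abs(np.subtract.outer(np.arange(d), np.arange(d)))
        L = np.linalg.cholesky(corr * sigma**2)
        z = np.random.default_rng(seed).standard_normal((n, d))
        dofs = tuple(DOFDescriptor("torsion", ()) for _ in range(d))
        return BATTrajectory(z @ L.T, dofs)

    def test_markov_chain_mi_values(self):
        traj = self._chain_traj(0.8, 0.5, N, 11)
        m = pairwise_mi_matrix(traj, SPEC).values
        mi_adj = -0.5 * np.log(1 - 0.64)
        mi_skip = -0.5 * np.log(1 - 0.64**2)
        assert m[0, 1] == pytest.approx(mi_adj, abs=0.03)
        assert m[1, 2] == pytest.approx(mi_adj, abs=0.03)
        assert m[0, 2] == pytest.approx(mi_skip, abs=0.03)
        assert np.allclose(m, m.T)

    def test_independent_dofs_near_zero(self):
        rng = np.random.default_rng(12)
        vals = rng.uniform(-np.pi, np.pi, (N, 3))
        dofs = tuple(DOFDescriptor("torsion", ()) for _ in range(3))
        m = pairwise_mi_matrix(BATTrajectory(vals, dofs), SPEC).values
        iu = np.triu_indices(3, 1)
        assert np.all(m[iu] < 3 * (SPEC.bins_2d - 1) ** 2 / (2 * N))

    def test_two_dof_matrix_matches_pair_estimator(self):
        traj = self._chain_traj(0.7, 0.4, 20_000, 13, d=2)
        m = pairwise_mi_matrix(traj, SPEC).values
        mi = mutual_information(traj.values[:, 0], traj.values[:, 1],
                                ("torsion", "torsion"), SPEC)
        assert m[0, 1] == pytest.approx(mi, abs=1e-12)


class TestAnalyticTerms:
    def test_momentum_entropy_is_constant(self):
        atoms = AtomTable.from_masses([12.011, 1.008, 15.999, 14.007])
        a = float(momentum_entropy(atoms, 300.0))
        b = float(momentum_entropy(atoms, 300.0))
        assert a == b

    def test_momentum_entropy_cancels_for_identical_composition(self):
        masses_a, masses_b = [12.011, 1.008, 15.999], [14.007, 1.008]
        s_ab = float(momentum_entropy(
            AtomTable.from_masses(masses_a + masses_b), 300.0))
        s_a = float(momentum_entropy(AtomTable.from_masses(masses_a), 300.0))
        s_b = float(momentum_entropy(AtomTable.from_masses(masses_b), 300.0))
        assert s_ab - (s_a + s_b) == pytest.approx(0.0, abs=1e-10)

    def test_momentum_entropy_temperature_scaling(self):
        atoms = AtomTable.from_masses([12.011] * 7)
        dbl = float(momentum_entropy(atoms, 600.0))
        one = float(momentum_entropy(atoms, 300.0))
        assert dbl - one == pytest.approx(1.5 * 7 * np.log(2.0), abs=1e-10)

    def test_external_reference_default_concentration(self):
        # independent evaluation: V° = 1e24 nm^3/L / (N_A molecules/L)
        v_nm3 = 1e24 / constants.N_A
        expected = np.log(8 * np.pi**2 * v_nm3)
        assert float(external_reference_entropy(1.0)) == pytest.approx(
            expected, abs=1e-12)

    def test_external_reference_volume_doubling_adds_ln2(self):
        a = float(external_reference_entropy(volume_nm3=1.0))
        b = float(external_reference_entropy(volume_nm3=2.0))
        assert b - a == pytest.approx(np.log(2.0), abs=1e-12)

    def test_external_reference_deterministic(self):
        assert float(external_reference_entropy(0.5)) == float(
            external_reference_entropy(0.5))
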