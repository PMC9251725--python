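"""Binding decomposition: bookkeeping, recovery, diagnostics, reporting."""

import numpy as np
import pytest

from batropy.decomposition import (BindingEntropyModel, DecompositionResult,
                                   TERM_NAMES, bound_terms,
                                   convergence_series, select_root_set,
                                   span_table, unbound_terms)
from batropy.estimators import HistogramSpec, R_GAS
from batropy.synthetic import (SyntheticSpec, toy_binding_generator,
                               two_regime_trajectory)
from batropy.topology import BATTrajectory, DOFDescriptor

SPEC = HistogramSpec()


@pytest.fixture(scope="module")
def null_system():
    bound, ua, ub, ref = toy_binding_generator(
        4, 4, [], y_narrow_factor=None, n_frames=10_000, seed=6)
    return bound, ua, ub, ref


@pytest.fixture(scope="module")
def toy_fit():
    bound, ua, ub, ref = toy_binding_generator(
        5, 4, [("AB", 0.8), ("AY", 0.6)], y_narrow_factor=10.0,
        n_frames=100_000, seed=11)
    model = BindingEntropyModel(
        bound, ua, ub, reference_volume_nm3=ref["reference_volume_nm3"])
    return model, model.fit(), ref


class TestBookkeeping:
    def test_total_is_exact_signed_sum(self, toy_fit):
        _, res, _ = toy_fit
        r = res.result
        total = (r.dS1D_A + r.dS1D_B + r.dS1D_Y - r.dI2D_AA - r.dI2D_BB
                 - r.I2D_YY - r.I2_AB - r.I2_AY - r.I2_BY)
        assert r.dS_total == pytest.approx(total, abs=1e-12)

    def test_identity_holds_for_arbitrary_terms(self):
        rng = np.random.default_rng(0)
        vals = dict(zip(TERM_NAMES, rng.normal(0, 5, 9)))
        r = DecompositionResult(**vals)
        signed = (vals["dS1D_A"] + vals["dS1D_B"] + vals["dS1D_Y"]
                  - vals["dI2D_AA"] - vals["dI2D_BB"] - vals["I2D_YY"]
                  - vals["I2_AB"] - vals["I2_AY"] - vals["I2_BY"])
        assert r.dS_total == pytest.approx(signed, abs=1e-12)


class TestUnboundBoundTerms:
    def _traj(self, cov, seed, kinds=None, subsystems=None, n=50_000):
        from batropy.synthetic import sample_gaussian_bat
        d = cov.shape[0]
        kinds = kinds or ("torsion",) * d
        spec = SyntheticSpec(kinds, np.zeros(d), cov, n, seed,
                             subsystems=subsystems)
        return sample_gaussian_bat(spec)

    def test_rejects_external_dofs(self):
        dofs = (DOFDescriptor("ext_torsion", (), "Y"),
                DOFDescriptor("torsion", (), "A"))
        traj = BATTrajectory(np.zeros((10, 2)), dofs)
        with pytest.raises(ValueError, match="external"):
            unbound_terms(traj, SPEC)

    def test_independent_molecule_has_tiny_coupling(self):
        traj = self._traj(np.eye(4) * 0.25, 1)
        ub = unbound_terms(traj, SPEC)
        # spurious MI per tree edge ~ (k-1)^2/(2n)
        assert ub.i2d < 3 * 3 * (SPEC.bins_2d - 1) ** 2 / (2 * 50_000)

    def test_chain_coupling_matches_closed_form(self):
        rho = 0.8
        corr = rho ** np.abs(np.subtract.outer(np.arange(3), np.arange(3)))
        traj = self._traj(corr * 0.25, 2, n=200_000)
        ub = unbound_terms(traj, SPEC)
        expected = -2 * 0.5 * np.log(1 - rho**2)  # two adjacent edges
        assert ub.i2d == pytest.approx(expected, abs=0.05)

    def test_single_dof_molecule(self):
        traj = BATTrajectory(np.random.default_rng(3).uniform(-3, 3, (100, 1)),
                             (DOFDescriptor("torsion", ()),))
        ub = unbound_terms(traj, SPEC)
        assert ub.i2d == 0.0

    def test_bound_requires_six_y_dofs(self):
        dofs = (DOFDescriptor("torsion", (), "A"),
                DOFDescriptor("ext_torsion", (), "Y"))
        traj = BATTrajectory(np.zeros((10, 2)), dofs)
        with pytest.raises(ValueError, match="6 Y DOFs"):
            bound_terms(traj, SPEC)

    def test_category_sums_conserve_total(self, toy_fit):
        model, _, _ = toy_fit
        bt = bound_terms(model.bound, SPEC)
        assert sum(bt.category_sums.values()) == pytest.approx(
            bt.mist.i2d_total, abs=1e-12)


class TestDecomposition:
    def test_topology_mismatch_reports_first_dof(self, toy_fit):
        model, _, _ = toy_fit
        dofs = list(model.unbound_a.dofs)
        dofs[2] = DOFDescriptor("torsion", ())  # angle slot mislabeled
        bad = BindingEntropyModel(
            model.bound, BATTrajectory(model.unbound_a.values, tuple(dofs)),
            model.unbound_b)
        with pytest.raises(ValueError, match="subsystem A DOF 2"):
            bad.fit()

    def test_coupled_terms_recovered(self, toy_fit):
        _, res, ref = toy_fit
        for term in TERM_NAMES:
            tol = max(0.1, 0.1 * abs(ref[term]))  # dev-scale n, wide band
            assert res.terms_R[term] == pytest.approx(ref[term], abs=tol), term

    def test_uncoupled_categories_stay_small(self, toy_fit):
        _, res, _ = toy_fit
        assert abs(res.I2D_YY) < 0.05
        assert abs(res.I2_BY) < 0.05

    def test_momentum_entropy_never_enters(self, toy_fit):
        _, res, _ = toy_fit
        assert set(res.terms_R) == {*TERM_NAMES, "dS_total"}


class TestRootSetSelection:
    def _factory(self, width_by_cand, n=20_000):
        rng = np.random.default_rng(5)
        kinds = ("ext_bond", "ext_angle", "ext_torsion", "ext_angle",
                 "ext_torsion", "ext_torsion")
        dofs = tuple(DOFDescriptor(k, (), "Y") for k in kinds)
        base = rng.standard_normal((n, 6))

        def factory(cand):
            w = width_by_cand[cand]
            vals = np.empty_like(base)
            vals[:, 0] = 0.5 + 0.02 * base[:, 0]
            vals[:, [1, 3]] = np.pi / 2 + w * base[:, [1, 3]]
            vals[:, [2, 4, 5]] = w * base[:, [2, 4, 5]]
            return BATTrajectory(vals, dofs)

        return factory

    def test_min_and_max_pick_different_candidates(self):
        widths = {(0, 1, 2): 0.05, (1, 2, 3): 0.3}
        factory = self._factory(widths)
        chosen_min, table = select_root_set(list(widths), factory, SPEC,
                                            criterion="min")
        chosen_max, _ = select_root_set(list(widths), factory, SPEC,
                                        criterion="max")
        assert chosen_min == (0, 1, 2)  # narrower Y -> smaller dS1D_Y
        assert chosen_max == (1, 2, 3)
        assert len(table) == 2
        assert table["dS1D_Y"].notna().all()

    def test_single_candidate_trivial(self):
        widths = {(0, 1, 2): 0.1}
        chosen, table = select_root_set(list(widths), self._factory(widths),
                                        SPEC)
        assert chosen == (0, 1, 2) and len(table) == 1

    def test_bad_criterion_rejected(self):
        with pytest.raises(ValueError, match="criterion"):
            select_root_set([(0, 1, 2)], lambda c: None, SPEC,
                            criterion="best")


class TestConvergence:
    def test_block_ends_and_final_point(self, null_system):
        bound, ua, ub, ref = null_system
        series = convergence_series(
            bound, ua, ub, n_blocks=10,
            reference_volume_nm3=ref["reference_volume_nm3"])
        assert series.block_ends.tolist() == list(range(1000, 10_001, 1000))
        full = BindingEntropyModel(
            bound, ua, ub,
            reference_volume_nm3=ref["reference_volume_nm3"]).fit()
        for term, arr in series.terms.items():
            assert arr[-1] == full.terms_R[term]

    def test_shuffled_final_point_equals_full_sample(self, null_system):
        bound, ua, ub, ref = null_system
        series = convergence_series(
            bound, ua, ub, n_blocks=5, shuffled=True, seed=3,
            reference_volume_nm3=ref["reference_volume_nm3"])
        full = BindingEntropyModel(
            bound, ua, ub,
            reference_volume_nm3=ref["reference_volume_nm3"]).fit()
        # a frame permutation leaves every histogram unchanged
        for term, arr in series.terms.items():
            assert arr[-1] == pytest.approx(full.terms_R[term], abs=1e-12)

    def test_too_few_frames_rejected(self, null_system):
        bound, ua, ub, _ = null_system
        short = BATTrajectory(bound.values[:10], bound.dofs)
        with pytest.raises(ValueError, match="too few frames"):
            convergence_series(short, ua, ub, n_blocks=10)

    def test_two_regime_shifts_unshuffled_series(self, null_system):
        bound, ua, ub, ref = null_system
        # regime switch in one A-subsystem torsion at the midpoint
        tor = next(i for i, d in enumerate(bound.dofs)
                   if d.kind == "torsion" and d.subsystem == "A")
        vals = bound.values.copy()
        half = vals.shape[0] // 2
        vals[half:, tor] += 5 * 0.5  # 5 sigma shift (default sigma 0.5 wraps
        vals[:, tor] = np.mod(vals[:, tor] + np.pi, 2 * np.pi) - np.pi
        switched = BATTrajectory(vals, bound.dofs)
        kw = dict(reference_volume_nm3=ref["reference_volume_nm3"])
        plain = convergence_series(switched, ua, ub, n_blocks=10, **kw)
        shuf = convergence_series(switched, ua, ub, n_blocks=10,
                                  shuffled=True, seed=9, **kw)
        dev_plain = abs(plain.terms["dS1D_A"][0] - plain.final("dS1D_A"))
        dev_shuf = abs(shuf.terms["dS1D_A"][0] - shuf.final("dS1D_A"))
        assert dev_plain > 0.3     # first block misses the second substate
        assert dev_shuf < 0.1      # shuffling removes the slow switch


class TestSpanTable:
    def _result(self, rng, n_dofs=20):
        vals = dict(zip(TERM_NAMES, rng.normal(0, 3, 9)))
        return DecompositionResult(**vals, n_dofs=n_dofs)

    def test_identical_results_have_zero_spans(self):
        rng = np.random.default_rng(7)
        r = self._result(rng)
        st = span_table([r, r, r])
        assert (st.spans == 0).all()
        assert st.percent["dS_total"] == 100.0

    def test_spans_match_brute_force(self):
        rng = np.random.default_rng(8)
        results = [self._result(rng) for _ in range(5)]
        st = span_table(results)
        for term in ("dS_total", *TERM_NAMES):
            col = [r.term_dict()[term] for r in results]
            assert st.spans[term] == pytest.approx(max(col) - min(col),
                                                   abs=1e-12)
        assert st.percent["dS_total"] == 100.0
        expected = 100 * st.spans / st.spans["dS_total"]
        assert np.allclose(st.percent, expected)

    def test_dof_normalization(self):
        rng = np.random.default_rng(9)
        results = [self._result(rng, n_dofs=10), self._result(rng, n_dofs=40)]
        st = span_table(results, normalize_by_dofs=True)
        raw = span_table(results)
        a = results[0].term_dict()["dS1D_A"] / 10
        b = results[1].term_dict()["dS1D_A"] / 40
        assert st.spans["dS1D_A"] == pytest.approx(abs(a - b), abs=1e-12)
        assert not np.allclose(st.spans, raw.spans)

    def test_fewer_than_two_rejected(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError, match="at least 2"):
            span_table([self._result(rng)])


class TestReporting:
    def test_summary_contains_all_terms_and_units(self, toy_fit):
        _, res, _ = toy_fit
        text = res.summary()
        for term in TERM_NAMES:
            assert term in text
        assert "kJ/mol" in text and "300" in text

    def test_unit_conversions(self, toy_fit):
        _, res, _ = toy_fit
        r_val = res.terms_R["dS_total"]
        assert res.terms_J_per_mol_K["dS_total"] == pytest.approx(
            r_val * R_GAS)
        assert res.minus_T_dS_kJ_per_mol["dS_total"] == pytest.approx(
            -300.0 * r_val * R_GAS / 1000.0)

    def test_to_frame_shape(self, toy_fit):
        _, res, _ = toy_fit
        df = res.to_frame()
        assert len(df) == 10  # 9 terms + total
        assert {"term", "value_R", "minus_T_dS_kJ_per_mol"} <= set(df.columns)
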