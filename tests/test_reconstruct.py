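import numpy as np
import pytest

from hetasym import connectome as cn
from hetasym import dynamics as dy
from hetasym import metrics as mt
from hetasym import reconstruct as rc
from hetasym import simulate as sm
from hetasym.exceptions import StabilityError, ValidationError


def _consistent_instance(n, seed, h=None):
    """Noiseless (J, W) pair exactly consistent with J_ij = h_i C_ij."""
    rng = np.random.default_rng(seed)
    C = rng.lognormal(0, 1, (n, n))
    np.fill_diagonal(C, 0.0)
    if h is None:
        h = rng.uniform(0.5, 2.0, n)
    J = h[:, None] * C
    np.fill_diagonal(J, -rng.uniform(1, 2, n))
    W = cn.make_symmetric(C)
    return h, C, J, W


class TestDDC:
    def test_unbiased_on_two_node_ou(self):
        J = -np.eye(2)
        traj = sm.simulate_linear(J, sigma=0.01, duration=5000.0, dt=0.001, seed=3, burn_in=20.0)
        J_hat = rc.ddc_estimate(traj)
        assert np.linalg.norm(J_hat - J) / np.linalg.norm(J) < 0.05

    def test_three_node_asymmetric_correlation(self):
        J = np.array([[-1.0, 0.5, 0.0], [0.0, -1.3, 0.6], [0.3, 0.0, -0.9]])
        traj = sm.simulate_linear(J, sigma=0.02, duration=5000.0, dt=0.001, seed=4, burn_in=20.0)
        J_hat = rc.ddc_estimate(traj)
        assert mt.element_correlation(J, J_hat, "full") > 0.99

    def test_no_coupling_yields_no_spurious_offdiagonal(self):
        conn = cn.generate_synthetic_connectome(5, 0.8, 0.7, seed=6)
        params = dy.default_modelA(conn, G=0.0)
        traj = sm.simulate(params, 400.0, dt=0.001, seed=6)
        J_hat = rc.ddc_estimate(traj)
        off = np.mean(np.abs(J_hat[~np.eye(5, dtype=bool)]))
        diag = np.mean(np.abs(np.diag(J_hat)))
        assert off < 0.05 * diag

    def test_error_decreases_with_duration(self):
        J = np.array([[-1.0, 0.5, 0.0], [0.0, -1.3, 0.6], [0.3, 0.0, -0.9]])
        errs = []
        for duration in (100.0, 1000.0, 5000.0):
            traj = sm.simulate_linear(J, 0.02, duration, dt=0.001, seed=8, burn_in=20.0)
            errs.append(mt.relative_error(J, rc.ddc_estimate(traj), "full"))
        assert errs[0] > errs[1] > errs[2]

    def test_too_few_samples_rejected(self):
        traj = sm.Trajectory(S=np.zeros((10, 3)), dt=0.001, t0=0, seed=0,
                             model_tag="x", sigma=0.0)
        with pytest.raises(ValidationError):
            rc.ddc_estimate(traj)


class TestRegression:
    def test_pair_combinatorics(self):
        _, _, J, W = _consistent_instance(3, 0)
        reg = rc.build_regression(J, W)
        assert reg.M.shape == (3, 3)
        assert reg.W_vec.shape == (3,)

    def test_rows_have_at_most_two_nonzeros(self):
        _, _, J, W = _consistent_instance(7, 1)
        reg = rc.build_regression(J, W)
        assert np.all(np.count_nonzero(reg.M, axis=1) <= 2)
        for r, (i, j) in enumerate(reg.pairs):
            assert reg.M[r, i] == J[i, j] and reg.M[r, j] == J[j, i]

    def test_symmetric_consistent_system_solved_by_unit_y(self):
        rng = np.random.default_rng(2)
        Wfull = cn.make_symmetric(rng.lognormal(0, 1, (5, 5)))
        np.fill_diagonal(Wfull, 0.0)
        J = Wfull.copy()
        reg = rc.build_regression(J, Wfull)
        assert np.allclose(reg.M @ np.ones(5), reg.W_vec)

    def test_asymmetric_W_rejected(self):
        _, C, J, _ = _consistent_instance(4, 3)
        with pytest.raises(ValidationError):
            rc.build_regression(J, C)


class TestSpatialSeparation:
    @pytest.mark.parametrize("n,seed", [(3, 0), (5, 1), (29, 2)])
    def test_exact_identifiability(self, n, seed):
        h, C, J, W = _consistent_instance(n, seed)
        dec = rc.spatial_separation(J, W)
        assert np.max(np.abs(dec.h_hat - h)) < 1e-10 * np.max(h)
        assert np.max(np.abs(dec.C_hat - C)) < 1e-10
        # plug back: the recovered pieces reproduce the off-diagonal Jacobian
        off = ~np.eye(n, dtype=bool)
        assert np.allclose((dec.h_hat[:, None] * dec.C_hat)[off], J[off])

    def test_fig2_example_vector(self):
        h = np.array([1.0, 2.0, 0.5, 1.5, 0.8])
        h_in, C, J, W = _consistent_instance(5, 7, h=h)
        dec = rc.spatial_separation(J, W)
        assert np.allclose(dec.h_hat, h, atol=1e-10)

    def test_homogeneous_symmetric_case(self):
        rng = np.random.default_rng(5)
        C = cn.make_symmetric(rng.lognormal(0, 1, (6, 6)))
        np.fill_diagonal(C, 0.0)
        J = C.copy()
        dec = rc.spatial_separation(J, C)
        assert np.allclose(dec.y_hat, 1.0, atol=1e-12)
        assert np.allclose(dec.C_hat, C, atol=1e-12)

    def test_relabeling_equivariance(self):
        h, C, J, W = _consistent_instance(6, 9)
        dec = rc.spatial_separation(J, W)
        p = np.random.default_rng(0).permutation(6)
        dec_p = rc.spatial_separation(J[np.ix_(p, p)], W[np.ix_(p, p)])
        assert np.allclose(dec_p.h_hat, dec.h_hat[p])
        assert np.allclose(dec_p.C_hat, dec.C_hat[np.ix_(p, p)])

    def test_invariants_of_decomposition(self):
        h, C, J, W = _consistent_instance(8, 11)
        dec = rc.spatial_separation(J, W)
        off = ~np.eye(8, dtype=bool)
        assert np.allclose(dec.C_hat[off], (dec.y_hat[:, None] * dec.J_hat)[off], atol=1e-12)
        assert np.allclose(dec.h_hat * dec.y_hat, 1.0)
        assert np.all(np.diag(dec.C_hat) == 0)

    def test_hdf5_roundtrip(self, tmp_path):
        _, _, J, W = _consistent_instance(5, 13)
        dec = rc.spatial_separation(J, W)
        p = tmp_path / "dec.h5"
        dec.save(p)
        back = rc.Decomposition.load(p)
        assert np.array_equal(back.h_hat, dec.h_hat)
        assert back.cond_M == dec.cond_M


class TestBaselines:
    def test_no_asymmetry_exact_when_truth_is_symmetric(self):
        rng = np.random.default_rng(4)
        W = cn.make_symmetric(rng.lognormal(0, 1, (6, 6)))
        np.fill_diagonal(W, 0.0)
        h = rng.uniform(0.5, 2, 6)
        J = h[:, None] * W
        assert np.allclose(rc.baseline_no_asymmetry(J, W), h)

    def test_no_asymmetry_biased_on_asymmetric_truth(self):
        h, C, J, W = _consistent_instance(10, 5)
        h_base = rc.baseline_no_asymmetry(J, W)
        full = rc.spatial_separation(J, W)
        assert mt.relative_error(h, h_base, "vector") > mt.relative_error(h, full.h_hat, "vector")

    def test_no_asymmetry_row_scaling(self):
        h, C, J, W = _consistent_instance(5, 6)
        h1 = rc.baseline_no_asymmetry(J, W)
        J2 = J.copy()
        J2[2] *= 3.0
        h2 = rc.baseline_no_asymmetry(J2, W)
        assert h2[2] == pytest.approx(3 * h1[2])

    def test_no_heterogeneity_recovers_scalar_instance(self):
        rng = np.random.default_rng(8)
        C = rng.lognormal(0, 1, (6, 6))
        np.fill_diagonal(C, 0.0)
        J = 2.0 * C
        W = cn.make_symmetric(C)
        h, C_hat, hist = rc.baseline_no_heterogeneity(J, W)
        assert h == pytest.approx(2.0, abs=1e-8)
        assert np.allclose(C_hat, C, atol=1e-7)
        assert hist[-1] < 1e-12

    def test_no_heterogeneity_loss_monotone_and_positive_when_misspecified(self):
        h, C, J, W = _consistent_instance(8, 10)
        _, _, hist = rc.baseline_no_heterogeneity(J, W)
        assert np.all(np.diff(hist) <= 1e-12)
        assert hist[-1] > 1e-6


class TestParameterRecovery:
    def test_modelA_roundtrip_from_exact_inputs(self, conn10):
        params = dy.default_modelA(conn10, G=0.1)  # non-saturated operating point
        gt = dy.ground_truth(params)
        fp = gt.fixed_point
        dec = rc.Decomposition(J_hat=gt.J, y_hat=1 / gt.h, h_hat=gt.h,
                               C_hat=conn10.C.copy(), cond_M=1.0, residual=0.0)
        rec = rc.recover_modelA_params(dec, fp.S_star, params)
        assert not rec.failed
        assert np.max(np.abs(rec.first - params.w)) < 1e-6
        assert np.max(np.abs(rec.second - params.I)) < 1e-6
        assert np.max(np.abs(rec.x_star_hat - fp.x_star)) < 1e-6

    def test_homogeneous_truth_gives_constant_vectors(self, conn10):
        params = dy.ModelAParams(conn=conn10, w=0.1, I=0.31, G=0.1)
        gt = dy.ground_truth(params)
        dec = rc.Decomposition(J_hat=gt.J, y_hat=1 / gt.h, h_hat=gt.h,
                               C_hat=conn10.C.copy(), cond_M=1.0, residual=0.0)
        rec = rc.recover_modelA_params(dec, gt.fixed_point.S_star, params)
        assert np.ptp(rec.first) < 1e-8
        assert np.ptp(rec.second) < 1e-8

    def test_saturated_gain_reported_not_raised(self, conn10):
        params = dy.default_modelA(conn10, G=0.1)
        gt = dy.ground_truth(params)
        y = (1 / gt.h).copy()
        y[0] = 1.0 / (params.gamma * params.G * (1 - gt.fixed_point.S_star[0]) * params.a)
        dec = rc.Decomposition(J_hat=gt.J, y_hat=y, h_hat=1 / y,
                               C_hat=conn10.C.copy(), cond_M=1.0, residual=0.0)
        rec = rc.recover_modelA_params(dec, gt.fixed_point.S_star, params)
        assert any(i == 0 for i, _ in rec.failed)
        assert np.isnan(rec.second[0]) and not np.isnan(rec.second[1])

    def test_modelB_roundtrip_from_exact_inputs(self, conn10):
        params = dy.default_modelB(conn10, G=0.1)
        gt = dy.ground_truth(params)
        dec = rc.Decomposition(J_hat=gt.J, y_hat=1 / gt.h, h_hat=gt.h,
                               C_hat=conn10.C.copy(), cond_M=1.0, residual=0.0)
        rec = rc.recover_modelB_params(dec, gt.fixed_point.S_star, params)
        assert np.max(np.abs(rec.first - params.tau)) < 1e-6
        assert np.max(np.abs(rec.second - params.b_vec)) < 1e-6

    def test_modelB_requires_positive_h(self, conn10):
        params = dy.default_modelB(conn10, G=0.1)
        gt = dy.ground_truth(params)
        h_bad = gt.h.copy()
        h_bad[3] = -1.0
        dec = rc.Decomposition(J_hat=gt.J, y_hat=1 / h_bad, h_hat=h_bad,
                               C_hat=conn10.C.copy(), cond_M=1.0, residual=0.0)
        with pytest.raises(ValidationError):
            rc.recover_modelB_params(dec, gt.fixed_point.S_star, params)

    def test_modelB_end_to_end_recovery_tracks_mapping(self, conn10):
        params = dy.default_modelB(conn10, G=0.7)
        gt = dy.ground_truth(params)
        traj = sm.simulate(params, 2000.0, dt=0.001, seed=21)
        dec = rc.spatial_separation(rc.ddc_estimate(traj), cn.make_symmetric(conn10.C))
        rec = rc.recover_modelB_params(dec, traj.S.mean(axis=0), params)
        assert np.corrcoef(rec.first, params.tau)[0, 1] > 0.95


def _stable_decomposition(seed=12):
    h, C, J, W = _consistent_instance(4, seed)
    C *= 0.2  # weaken coupling so the shifted Jacobian is Hurwitz
    J = h[:, None] * C
    np.fill_diagonal(J, 0.0)
    J -= 4.0 * np.eye(4)
    W = cn.make_symmetric(C)
    assert np.max(np.linalg.eigvals(J).real) < 0
    return rc.spatial_separation(J, W), J


class TestResimulateLinear:
    def test_fc_matches_lyapunov_theory(self):
        dec, J = _stable_decomposition()
        traj = rc.resimulate_linear(dec, sigma=0.05, duration=800.0, dt=0.001, seed=2)
        fc_emp = mt.functional_connectivity(traj)
        fc_th = mt.functional_connectivity(mt.lyapunov_covariance(J, 0.05))
        assert np.max(np.abs(fc_emp - fc_th)) < 0.1

    def test_zero_noise_is_identically_zero(self):
        dec, _ = _stable_decomposition()
        traj = rc.resimulate_linear(dec, sigma=0.0, duration=60.0, dt=0.001, seed=2)
        assert np.all(traj.S == 0)

    def test_seed_determinism(self):
        dec, _ = _stable_decomposition()
        a = rc.resimulate_linear(dec, 0.05, 80.0, dt=0.001, seed=5)
        b = rc.resimulate_linear(dec, 0.05, 80.0, dt=0.001, seed=5)
        assert np.array_equal(a.S, b.S)

    def test_unstable_jacobian_rejected(self):
        h, C, J, W = _consistent_instance(4, 12)
        J = J + 10.0 * np.eye(4)
        dec = rc.Decomposition(J_hat=J, y_hat=1 / h, h_hat=h, C_hat=C,
                               cond_M=1.0, residual=0.0)
        with pytest.raises(StabilityError):
            rc.resimulate_linear(dec, 0.01, 60.0)
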