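"""PC dimension reduction: weighted matrix, component selection, transform."""
import numpy as np
import pytest
import scipy.linalg

from pcgmm.datatypes import LDMatrix, SimulationSpec, TraitCorrelation, ValidationError
from pcgmm.simulate import generate_two_sample
from pcgmm.transform import (
    pc_reduce,
    select_components,
    transform_associations,
    weighted_correlation_matrix,
)

from conftest import ar1_ld, make_summary


class TestWeightedCorrelationMatrix:
    def test_single_variant(self):
        data = make_summary([[0.3, -0.2]], [[0.1, 0.1]], [0.1], [0.05])
        psi = weighted_correlation_matrix(data, ar1_ld(1, 0.0))
        w = (0.3 + 0.2) / 0.05
        assert psi.shape == (1, 1)
        assert psi[0, 0] == pytest.approx(w**2)

    def test_identity_ld_unit_weights(self):
        # |beta| summing to se_y makes every weight exactly 1
        data = make_summary([[0.05]], [[0.1]], [0.0], [0.05])
        data = make_summary(np.full((4, 1), 0.05), np.full((4, 1), 0.1),
                            np.zeros(4), np.full(4, 0.05))
        psi = weighted_correlation_matrix(data, ar1_ld(4, 0.0))
        np.testing.assert_allclose(psi, np.eye(4))

    def test_three_variant_hand_computation(self):
        beta_x = np.array([[0.2, -0.1], [0.1, 0.1], [-0.3, 0.0]])
        se_y = np.array([0.05, 0.1, 0.2])
        data = make_summary(beta_x, np.full((3, 2), 0.1), np.zeros(3), se_y)
        ld = ar1_ld(3, 0.5)
        psi = weighted_correlation_matrix(data, ld)
        w = np.array([0.3 / 0.05, 0.2 / 0.1, 0.3 / 0.2])
        for i in range(3):
            for j in range(3):
                assert psi[i, j] == pytest.approx(w[i] * w[j] * 0.5 ** abs(i - j))


class TestSelectComponents:
    def test_identity_needs_all_components(self):
        _, _, p = select_components(np.eye(5), 0.99)
        assert p == 5

    def test_rank_one_needs_one(self):
        v = np.arange(1.0, 5.0)
        _, _, p = select_components(np.outer(v, v), 0.9)
        assert p == 1

    def test_ar1_matches_independent_eigen_cumsum(self):
        rho = ar1_ld(20, 0.9).rho
        loadings, eigval, p = select_components(rho, 0.99)
        ev = np.sort(scipy.linalg.eigh(rho, eigvals_only=True))[::-1]
        frac = np.cumsum(ev) / ev.sum()
        expected_p = int(np.argmax(frac >= 0.99)) + 1
        assert p == expected_p
        np.testing.assert_allclose(eigval[:p], ev[:p], rtol=1e-10)
        assert loadings.shape == (20, p)

    @pytest.mark.parametrize("t1,t2", [(0.5, 0.9), (0.9, 0.99), (0.99, 0.9999)])
    def test_threshold_monotonicity(self, t1, t2, rng):
        a = rng.normal(size=(15, 15))
        psi = a @ a.T
        _, _, p1 = select_components(psi, t1)
        _, _, p2 = select_components(psi, t2)
        assert p1 <= p2

    def test_nonfinite_rejected(self):
        psi = np.eye(3)
        psi[0, 1] = psi[1, 0] = np.nan
        with pytest.raises(ValidationError):
            select_components(psi, 0.99)

    def test_sign_convention(self, rng):
        a = rng.normal(size=(10, 10))
        loadings, _, p = select_components(a @ a.T, 1.0)
        for c in range(p):
            col = loadings[:, c]
            assert col[np.argmax(np.abs(col))] > 0


class TestTransformAssociations:
    def test_identity_reduces_to_marginals(self, rng):
        j = 5
        se_y = np.abs(rng.normal(size=j)) + 0.1
        data = make_summary(rng.normal(size=(j, 2)), np.full((j, 2), 0.1),
                            rng.normal(size=j), se_y)
        red = transform_associations(data, ar1_ld(j, 0.0), np.eye(j))
        np.testing.assert_allclose(red.beta_y_pc, data.beta_y, atol=1e-12)
        np.testing.assert_allclose(red.omega_yy, np.diag(se_y**2), atol=1e-12)

    def test_orthonormal_full_rank_is_invertible_reparameterization(self, rng):
        j = 6
        q, _ = np.linalg.qr(rng.normal(size=(j, j)))
        data = make_summary(rng.normal(size=(j, 1)), np.full((j, 1), 0.1),
                            rng.normal(size=j), np.full(j, 0.1))
        red = transform_associations(data, ar1_ld(j, 0.0), q)
        np.testing.assert_allclose(q @ red.beta_y_pc, data.beta_y, atol=1e-8)

    def test_recovers_joint_model_coefficients(self, rng):
        # marginal betas constructed as rho @ gamma: full PC set recovers gamma projection
        j = 8
        ld = ar1_ld(j, 0.6)
        gamma = rng.normal(size=j)
        data = make_summary(rng.normal(size=(j, 1)), np.full((j, 1), 0.1),
                            ld.rho @ gamma, np.full(j, 0.1))
        loadings, _, p = select_components(ld.rho, 1.0)
        red = transform_associations(data, ld, loadings)
        # S^-1 L' rho gamma = S^-1 (L' rho L) (pseudo-coords of gamma) = L' gamma when full rank
        np.testing.assert_allclose(red.beta_y_pc, loadings.T @ gamma, atol=1e-8)

    def test_omega_yy_symmetric_psd(self, rng):
        j = 12
        ld = ar1_ld(j, 0.8)
        data = make_summary(rng.normal(size=(j, 2)), np.full((j, 2), 0.1),
                            rng.normal(size=j), np.abs(rng.normal(size=j)) + 0.05)
        red = pc_reduce(data, ld, variance_threshold=0.999)
        np.testing.assert_allclose(red.omega_yy, red.omega_yy.T, atol=1e-12)
        assert np.linalg.eigvalsh(red.omega_yy).min() >= -1e-10

    def test_trait_correlation_scales_cross_blocks(self, rng):
        j = 6
        ld = ar1_ld(j, 0.3)
        data = make_summary(rng.normal(size=(j, 2)), np.full((j, 2), 0.1),
                            rng.normal(size=j), np.full(j, 0.1))
        tc = TraitCorrelation(np.array([[1.0, 0.6], [0.6, 1.0]]))
        red0 = pc_reduce(data, ld, variance_threshold=1.0)
        red1 = pc_reduce(data, ld, variance_threshold=1.0, trait_cor=tc)
        np.testing.assert_allclose(red1.omega_xx[0, 0], red0.omega_xx[0, 0])
        np.testing.assert_allclose(red1.omega_xx[0, 1], 0.6 * red0.omega_xx[0, 1]
                                   if np.any(red0.omega_xx[0, 1]) else red1.omega_xx[0, 1])
        # cross block equals 0.6 x the correlation-1 sandwich
        base = pc_reduce(data, ld, variance_threshold=1.0,
                         trait_cor=TraitCorrelation(np.array([[1.0, 1.0 - 1e-12],
                                                              [1.0 - 1e-12, 1.0]])))
        np.testing.assert_allclose(red1.omega_xx[0, 1], 0.6 * base.omega_xx[0, 1], rtol=1e-6)


def test_variance_formula_matches_replicate_covariance(small_sim_ld):
    """omega_yy from the sandwich formula tracks the empirical covariance of
    beta_y_pc across independent simulation replicates (key correctness check
    of the variance construction)."""
    ld = small_sim_ld
    j = ld.n_variants
    spec = SimulationSpec(xi=1.0, kappa2=0.0, n_x=2000, n_y=2000,
                          n_instruments=j, n_causal=15)
    chol = np.linalg.cholesky(ld.rho + 1e-10 * np.eye(j))
    from pcgmm.simulate import causal_indices
    causal = causal_indices(j, 6, 15)
    rng = np.random.default_rng(77)

    # fix loadings from a reference replicate so all replicates share the basis
    sim0 = generate_two_sample(spec, ld, rng=rng, chol=chol, causal_idx=causal)
    red0 = pc_reduce(sim0.data, ld, variance_threshold=0.999, trait_cor=sim0.trait_cor)
    loadings = red0.loadings
    # retained components must carry LD eigenvalues well above the 1/n
    # sampling noise of the correlation matrix, else the marginal-beta
    # covariance model is not applicable
    assert red0.p <= 20

    reps = 400
    bypc = np.empty((reps, red0.p))
    pred = np.zeros((red0.p, red0.p))
    for r in range(reps):
        sim = generate_two_sample(spec, ld, rng=rng, chol=chol, causal_idx=causal)
        red = transform_associations(sim.data, ld, loadings, trait_cor=sim.trait_cor)
        bypc[r] = red.beta_y_pc
        pred += red.omega_yy
    pred /= reps
    emp = np.cov(bypc, rowvar=False)
    ratio = np.trace(emp) / np.trace(pred)
    assert ratio == pytest.approx(1.0, abs=0.1)
    diag_ratio = np.diag(emp) / np.diag(pred)
    assert np.median(diag_ratio) == pytest.approx(1.0, abs=0.1)


def test_singular_gram_matrix_rejected(rng):
    j = 6
    data = make_summary(rng.normal(size=(j, 1)), np.full((j, 1), 0.1),
                        rng.normal(size=j), np.full(j, 0.1))
    loadings = np.column_stack([np.ones(j), np.ones(j) + 1e-15])
    with pytest.raises(ValidationError, match="singular|threshold"):
        transform_associations(data, ar1_ld(j, 0.0), loadings)
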