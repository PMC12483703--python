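"""Structural least-squares updates: SVD, GSVD, and SMACOF variants."""

import numpy as np
import pytest

from ordmap.updates import (
    Configuration,
    build_smacof_system,
    distances,
    mdu_update,
    pca_update,
    raw_stress,
    rmdu_update,
    rrr_update,
    stress,
)


def frob(a):
    return float(np.sum(a**2))


class TestPCAUpdate:
    def test_exact_rank_two_reproduction(self, rng):
        u = rng.normal(0, 1, (8, 2))
        v = rng.normal(0, 1, (5, 2))
        z = u @ v.T
        conf = pca_update(z, 2)
        np.testing.assert_allclose(conf.U @ conf.V.T, z, atol=1e-10)

    def test_beats_random_rank_one_candidates(self, rng):
        z = rng.normal(0, 1, (6, 4))
        conf = pca_update(z, 1)
        best = frob(z - conf.U @ conf.V.T)
        u = rng.normal(0, 1, (2000, 6))
        v = rng.normal(0, 1, (2000, 4))
        losses = ((z[None] - u[:, :, None] * v[:, None, :]) ** 2).sum(axis=(1, 2))
        assert best <= losses.min() + 1e-12

    def test_column_permutation_equivariance(self, rng):
        z = rng.normal(0, 1, (7, 5))
        perm = rng.permutation(5)
        f1 = pca_update(z, 2)
        f2 = pca_update(z[:, perm], 2)
        np.testing.assert_allclose(
            (f1.U @ f1.V.T)[:, perm], f2.U @ f2.V.T, atol=1e-10
        )

    def test_orthogonality_structure(self, rng):
        z = rng.normal(0, 1, (9, 6))
        conf = pca_update(z, 3)
        # symmetric split: U'U = V'V = diag(singular values)
        np.testing.assert_allclose(
            conf.U.T @ conf.U, np.diag(np.diag(conf.U.T @ conf.U)), atol=1e-10
        )
        np.testing.assert_allclose(conf.U.T @ conf.U, conf.V.T @ conf.V, atol=1e-10)

    def test_rank_deficient_warns(self, rng):
        z = np.outer(rng.normal(0, 1, 6), rng.normal(0, 1, 4))
        with pytest.warns(RuntimeWarning):
            pca_update(z, 3)


class TestRRRUpdate:
    def test_full_rank_reduces_to_ols_projection(self, rng):
        x = rng.normal(0, 1, (20, 3))
        z = rng.normal(0, 1, (20, 4))
        conf = rrr_update(z, x, 3)
        proj = x @ np.linalg.solve(x.T @ x, x.T @ z)
        np.testing.assert_allclose(x @ conf.B @ conf.V.T, proj, atol=1e-10)

    def test_identity_predictors_coincide_with_pca(self, rng):
        z = rng.normal(0, 1, (6, 5))
        c1 = rrr_update(z, np.eye(6), 2)
        c2 = pca_update(z, 2)
        np.testing.assert_allclose(c1.U @ c1.V.T, c2.U @ c2.V.T, atol=1e-10)

    def test_beats_random_candidates(self, rng):
        x = rng.normal(0, 1, (20, 3))
        z = rng.normal(0, 1, (20, 4))
        conf = rrr_update(z, x, 1)
        best = frob(z - x @ conf.B @ conf.V.T)
        for _ in range(2000):
            b = rng.normal(0, 1, (3, 1))
            v = rng.normal(0, 1, (4, 1))
            assert best <= frob(z - x @ b @ v.T) + 1e-12

    def test_rank_deficient_predictors_raise(self, rng):
        x = rng.normal(0, 1, (10, 2))
        x = np.hstack([x, x[:, :1]])  # collinear
        with pytest.raises(ValueError, match="collinear"):
            rrr_update(rng.normal(0, 1, (10, 3)), x, 1)


class TestSmacofSystem:
    def test_all_positive_reduces_to_raw_stress_quantities(self, rng):
        u = rng.normal(0, 1, (6, 2))
        v = rng.normal(0, 1, (3, 2))
        delta = np.abs(rng.normal(1, 0.3, (6, 3)))
        sys_ = build_smacof_system(-delta, Configuration(u, v))
        np.testing.assert_array_equal(sys_.A, delta)
        np.testing.assert_array_equal(sys_.W, np.ones_like(delta))

    def test_negative_branch_majorizer_dominates_raw_stress(self, rng):
        """With negative dissimilarities, the adjusted (A, W) stress plus its
        anchoring constant dominates raw STRESS, touching at the anchor."""
        u0 = rng.normal(0, 1, (5, 2))
        v0 = rng.normal(0, 1, (3, 2))
        z = rng.normal(0, 1.2, (5, 3))  # working responses, mixed signs
        delta = -z
        assert (delta < 0).any()
        sys_ = build_smacof_system(z, Configuration(u0, v0))
        const = raw_stress(delta, u0, v0) - stress(sys_, u0, v0)
        for _ in range(25):
            up = u0 + rng.normal(0, 0.5, u0.shape)
            vp = v0 + rng.normal(0, 0.5, v0.shape)
            assert stress(sys_, up, vp) + const >= raw_stress(delta, up, vp) - 1e-8

    def test_eps_insensitivity_of_converged_configuration(self, rng):
        u = rng.normal(0, 1, (8, 2))
        v = rng.normal(0, 1, (3, 2))
        z = rng.normal(0.5, 1.0, (8, 3))

        def converge(eps):
            conf = Configuration(u.copy(), v.copy())
            for _ in range(300):
                sys_ = build_smacof_system(z, conf, eps=eps)
                conf = mdu_update(sys_, conf)
            return conf

        c1, c2 = converge(1e-8), converge(5e-9)
        assert np.abs(c1.U - c2.U).max() < 1e-4
        assert np.abs(c1.V - c2.V).max() < 1e-4


class TestMDUUpdate:
    def test_zero_stress_fixed_point(self, rng):
        u = rng.normal(0, 1, (6, 2))
        v = rng.normal(0, 1, (3, 2))
        delta = distances(u, v)  # all positive, exactly fitting
        conf = Configuration(u, v)
        sys_ = build_smacof_system(-delta, conf)
        new = mdu_update(sys_, conf)
        assert np.abs(new.U - u).max() < 1e-10
        assert np.abs(new.V - v).max() < 1e-10

    def test_raw_stress_monotone_over_sweeps(self, rng):
        z = rng.normal(0, 1.5, (8, 3))
        delta = -z
        conf = Configuration(rng.normal(0, 1, (8, 2)), rng.normal(0, 1, (3, 2)))
        prev = raw_stress(delta, conf.U, conf.V)
        for _ in range(50):
            sys_ = build_smacof_system(z, conf)
            # each sweep also decreases its own weighted stress
            before = stress(sys_, conf.U, conf.V)
            conf = mdu_update(sys_, conf)
            after = stress(sys_, conf.U, conf.V)
            assert after <= before + 1e-9
            cur = raw_stress(delta, conf.U, conf.V)
            assert cur <= prev + 1e-9
            prev = cur

    def test_final_stress_beats_random_configurations(self, rng):
        z = np.abs(rng.normal(1.0, 0.5, (8, 3)))  # positive dissimilarities
        delta = z
        conf = Configuration(rng.normal(0, 1, (8, 2)), rng.normal(0, 1, (3, 2)))
        for _ in range(400):
            sys_ = build_smacof_system(-delta, conf)
            conf = mdu_update(sys_, conf)
        final = raw_stress(delta, conf.U, conf.V)
        for _ in range(1000):
            u = rng.normal(0, 1, (8, 2))
            v = rng.normal(0, 1, (3, 2))
            assert final <= raw_stress(delta, u, v) + 1e-9

    def test_translation_invariance_of_stress(self, rng):
        u = rng.normal(0, 1, (6, 2))
        v = rng.normal(0, 1, (3, 2))
        z = rng.normal(0, 1, (6, 3))
        sys_ = build_smacof_system(z, Configuration(u, v))
        shift = np.array([2.5, -1.0])
        assert stress(sys_, u, v) == pytest.approx(
            stress(sys_, u + shift, v + shift), rel=1e-12
        )


class TestRMDUUpdate:
    def test_identity_predictors_equal_mdu(self, rng):
        n, r = 6, 3
        conf = Configuration(rng.normal(0, 1, (n, 2)), rng.normal(0, 1, (r, 2)))
        z = rng.normal(0, 1, (n, r))
        sys_ = build_smacof_system(z, conf)
        free = mdu_update(sys_, conf)
        restr = rmdu_update(sys_, np.eye(n), conf)
        np.testing.assert_allclose(free.U, restr.U, atol=1e-10)
        np.testing.assert_allclose(free.V, restr.V, atol=1e-10)

    def test_constrained_stress_monotone(self, rng):
        n, p, r = 12, 3, 4
        x = rng.normal(0, 1, (n, p))
        z = rng.normal(0, 1.2, (n, r))
        delta = -z
        b = rng.normal(0, 1, (p, 2))
        conf = Configuration(x @ b, rng.normal(0, 1, (r, 2)), B=b)
        prev = raw_stress(delta, conf.U, conf.V)
        for _ in range(50):
            sys_ = build_smacof_system(z, conf)
            conf = rmdu_update(sys_, x, conf)
            np.testing.assert_allclose(conf.U, x @ conf.B, atol=1e-12)
            cur = raw_stress(delta, conf.U, conf.V)
            assert cur <= prev + 1e-9
            prev = cur

    def test_noiseless_recovery_of_coefficients(self, rng):
        """Exact dissimilarities from a known B are recovered up to rotation."""
        n, p, r = 40, 3, 6
        x = rng.normal(0, 1, (n, p))
        b_true = rng.normal(0, 1, (p, 2))
        v_true = rng.normal(0, 1.5, (r, 2))
        delta = distances(x @ b_true, v_true)
        conf = Configuration(
            x @ (b_true + 0.3 * rng.normal(0, 1, b_true.shape)),
            v_true + 0.3 * rng.normal(0, 1, v_true.shape),
        )
        for _ in range(2000):
            sys_ = build_smacof_system(-delta, conf)
            conf = rmdu_update(sys_, x, conf)
        # orthogonal Procrustes of B_hat onto B_true, after matching the
        # translation absorbed in V
        bh = conf.B
        m = bh.T @ b_true
        uu, _, vv = np.linalg.svd(m)
        rot = uu @ vv
        resid = np.abs(bh @ rot - b_true).max()
        assert resid < 1e-3
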