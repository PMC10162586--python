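"""Blahut-Arimoto solver: updates, descent, restarts, functionals."""

import itertools

import numpy as np
import pytest

import ibkit as ib
from ibkit.solver import _support_quantities


def hand_objective(q, joint, alpha, beta):
    """Objective computed directly with numpy, independent of the solver."""
    keep = joint.x_support
    pxy = joint.matrix[keep]
    px = pxy.sum(axis=1)
    qm = px @ q
    pos = qm > 0
    h_m = float(-np.sum(qm[pos] * np.log2(qm[pos])))
    posq = q > 0
    row_h = -np.where(posq, q * np.log2(np.where(posq, q, 1.0)), 0.0).sum(axis=1)
    h_mgx = float(px @ row_h)
    qmy = q.T @ pxy
    i_my = ib.matrix_mutual_information(qmy)
    return h_m - alpha * h_mgx - beta * i_my


class TestInitializeEncoder:
    def test_deterministic_in_seed_tuple(self):
        params = ib.GIBParams(alpha=1.0, m_cardinality=3, seed=5)
        a = ib.initialize_encoder(params, 4, restart_index=2, beta_index=7)
        b = ib.initialize_encoder(params, 4, restart_index=2, beta_index=7)
        np.testing.assert_array_equal(a.q, b.q)
        c = ib.initialize_encoder(params, 4, restart_index=3, beta_index=7)
        assert not np.array_equal(a.q, c.q)

    def test_single_cluster_degenerate(self):
        params = ib.GIBParams(alpha=1.0, m_cardinality=1)
        enc = ib.initialize_encoder(params, 5, restart_index=0)
        np.testing.assert_array_equal(enc.q, np.ones((5, 1)))

    def test_dib_initialization_is_one_hot(self):
        params = ib.GIBParams(alpha=0.0, m_cardinality=4, seed=1)
        enc = ib.initialize_encoder(params, 10, restart_index=0)
        assert enc.is_deterministic()

    def test_simplex_sampler_is_uniform_in_mean(self):
        """Coordinate means of 10,000 simplex-uniform rows are ~ 1/3."""
        params = ib.GIBParams(alpha=1.0, m_cardinality=3, seed=0)
        enc = ib.initialize_encoder(params, 10_000, restart_index=0)
        np.testing.assert_allclose(enc.q.mean(axis=0), 1 / 3, atol=0.02)


class TestGIBIteration:
    def test_beta_zero_update_returns_marginal(self):
        joint = ib.random_joint(3, 3, seed=2)
        params = ib.GIBParams(alpha=1.0, beta=0.0, m_cardinality=3, seed=2)
        enc = ib.initialize_encoder(params, 3, restart_index=0)
        px, _, _ = _support_quantities(joint)
        qm = px @ enc.q
        out = ib.gib_iteration(enc, joint, params)
        np.testing.assert_allclose(out.q, np.tile(qm, (3, 1)), atol=1e-12)

    def test_dib_update_is_one_hot(self):
        joint = ib.random_joint(4, 3, seed=3)
        params = ib.GIBParams(alpha=0.0, beta=2.0, m_cardinality=3, seed=3)
        enc = ib.initialize_encoder(params, 4, restart_index=0)
        out = ib.gib_iteration(enc, joint, params)
        assert out.is_deterministic()

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0, 2.0])
    def test_monotone_descent(self, alpha):
        """The objective never increases across iterations, any alpha."""
        for seed in range(10):
            joint = ib.random_joint(4, 3, seed=seed)
            params = ib.GIBParams(
                alpha=alpha, beta=2.5, m_cardinality=3, seed=seed
            )
            enc = ib.initialize_encoder(params, 4, restart_index=0)
            obj = ib.objective(enc, joint, params)
            for _ in range(30):
                enc = ib.gib_iteration(enc, joint, params)
                new = ib.objective(enc, joint, params)
                assert new <= obj + 1e-10
                obj = new

    def test_alpha_one_matches_classic_ib_update(self):
        """The alpha=1 update coincides with the textbook IB update
        q(m|x) proportional to q(m) 2^(-beta d(x,m)), coded directly."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            n_x, n_y, n_m = rng.integers(2, 5, size=3)
            joint = ib.random_joint(int(n_x), int(n_y), seed=int(rng.integers(1e6)))
            beta = float(rng.uniform(0.0, 5.0))
            q = rng.dirichlet(np.ones(n_m), size=n_x)
            params = ib.GIBParams(alpha=1.0, beta=beta, m_cardinality=int(n_m))

            pxy = joint.matrix
            px = pxy.sum(axis=1)
            pygx = pxy / px[:, None]
            qm = px @ q
            qygm = (q.T @ pxy) / qm[:, None]
            d = np.array(
                [[ib.kl_divergence(pygx[x], qygm[m]) for m in range(n_m)]
                 for x in range(int(n_x))]
            )
            classic = qm[None, :] * 2.0 ** (-beta * d)
            classic /= classic.sum(axis=1, keepdims=True)

            out = ib.gib_iteration(ib.Encoder(q), joint, params)
            assert np.max(np.abs(out.q - classic)) < 1e-12


class TestEmptyClusterReseeding:
    def test_reseed_option_refills_emptied_clusters(self):
        """At small beta the hard update collapses most clusters; with the
        re-seeding option every cluster ends up occupied again."""
        joint = ib.random_joint(6, 3, seed=0)
        px, _, _ = _support_quantities(joint)
        base = ib.GIBParams(alpha=0.0, beta=0.1, m_cardinality=3, seed=0)
        enc = ib.initialize_encoder(base, 6, restart_index=0)
        collapsed = ib.gib_iteration(enc, joint, base)
        assert np.any(px @ collapsed.q <= 0)  # the plain update empties clusters

        reseeding = ib.GIBParams(
            alpha=0.0, beta=0.1, m_cardinality=3, seed=0,
            reseed_empty_clusters=True,
        )
        refilled = ib.gib_iteration(enc, joint, reseeding)
        assert np.all(px @ refilled.q > 0)
        assert refilled.is_deterministic()


class TestObjective:
    def test_constant_encoder_objective_is_zero(self):
        joint = ib.random_joint(3, 3, seed=4)
        q = np.zeros((3, 3))
        q[:, 0] = 1.0
        params = ib.GIBParams(alpha=1.0, beta=3.0, m_cardinality=3)
        assert ib.objective(ib.Encoder(q), joint, params) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_identity_encoder_on_noiseless_channel(self):
        joint = ib.joint_from_matrix([[0.5, 0], [0, 0.5]])
        params = ib.GIBParams(alpha=1.0, beta=1.0, m_cardinality=2)
        assert ib.objective(ib.Encoder(np.eye(2)), joint, params) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_alpha_one_objective_equals_rate_minus_relevance(self):
        """At alpha=1 the objective is I(M:X) - beta I(M:Y), with both
        informations recomputed from the composed joints."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            joint = ib.random_joint(3, 4, seed=int(rng.integers(1e6)))
            q = rng.dirichlet(np.ones(3), size=3)
            beta = float(rng.uniform(0, 4))
            params = ib.GIBParams(alpha=1.0, beta=beta, m_cardinality=3)
            px = joint.matrix.sum(axis=1)
            i_mx = ib.matrix_mutual_information(q * px[:, None])
            i_my = ib.matrix_mutual_information(q.T @ joint.matrix)
            assert ib.objective(ib.Encoder(q), joint, params) == pytest.approx(
                i_mx - beta * i_my, abs=1e-10
            )


class TestSolveFixedBeta:
    def test_beta_zero_compresses_everything(self):
        joint = ib.random_joint(3, 3, seed=5)
        params = ib.GIBParams(alpha=1.0, beta=0.0, m_cardinality=3, seed=5)
        sol = ib.solve_fixed_beta(joint, params)
        assert sol.i_mx == pytest.approx(0.0, abs=1e-6)
        assert sol.i_my == pytest.approx(0.0, abs=1e-6)

    def test_large_beta_recovers_all_relevant_information(self):
        joint = ib.binary_symmetric_joint(0.1)
        params = ib.GIBParams(alpha=1.0, beta=1000.0, m_cardinality=2, seed=0)
        sol = ib.solve_fixed_beta(joint, params)
        assert sol.i_my == pytest.approx(ib.mutual_information(joint), abs=1e-3)

    def test_invalid_cardinality_rejected(self):
        with pytest.raises(ValueError):
            ib.GIBParams(m_cardinality=0)

    def test_zero_mass_rows_excluded_from_support(self):
        joint = ib.joint_from_matrix([[0.4, 0.1], [0.0, 0.0], [0.1, 0.4]])
        params = ib.GIBParams(alpha=1.0, beta=5.0, seed=1)
        sol = ib.solve_fixed_beta(joint, params)
        assert sol.encoder.n_x == 2  # only the two supported x rows

    def test_dib_attains_exhaustive_optimum_on_small_joints(self):
        """With 20 restarts the DIB solution matches brute-force enumeration
        of every hard encoder, checked with a hand-rolled objective."""
        for seed in range(10):
            joint = ib.random_joint(2, 2, seed=seed)
            params = ib.GIBParams(
                alpha=0.0, beta=5.0, m_cardinality=2, n_restarts=20, seed=seed
            )
            sol = ib.solve_fixed_beta(joint, params)
            best = min(
                hand_objective(np.eye(2)[list(assign)], joint, 0.0, 5.0)
                for assign in itertools.product(range(2), repeat=2)
            )
            assert sol.objective == pytest.approx(best, abs=1e-9)


class TestSolutionFunctionals:
    def test_identity_and_constant_encoders(self):
        joint = ib.joint_from_matrix([[0.25, 0.25], [0.25, 0.25]])
        i_mx, i_my, h_m, h_mgx = ib.solution_functionals(
            ib.Encoder(np.eye(2)), joint
        )
        assert (h_m, h_mgx, i_mx) == pytest.approx((1.0, 0.0, 1.0), abs=1e-12)
        const = np.zeros((2, 2))
        const[:, 1] = 1.0
        vals = ib.solution_functionals(ib.Encoder(const), joint)
        assert vals == pytest.approx((0.0, 0.0, 0.0, 0.0), abs=1e-12)

    def test_information_identities_and_dpi(self):
        """I(M:X) = H(M) - H(M|X) and the data-processing inequality hold
        for random encoders on random joints."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            joint = ib.random_joint(3, 3, seed=int(rng.integers(1e6)))
            q = rng.dirichlet(np.ones(3), size=3)
            i_mx, i_my, h_m, h_mgx = ib.solution_functionals(
                ib.Encoder(q), joint
            )
            assert i_mx == pytest.approx(h_m - h_mgx, abs=1e-9)
            assert i_my <= i_mx + 1e-9
            assert i_my <= ib.mutual_information(joint) + 1e-9
            assert min(i_mx, i_my, h_m, h_mgx) >= -1e-12
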