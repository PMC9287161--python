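import numpy as np
import pytest

from sigcrf import crf
from sigcrf.crf import CrfParams, NEG
from sigcrf.model import Model, predict
from sigcrf.types import OrganismGroup, SpClass

from tests.helpers import (TinySpace, brute_force_lattice, enumerate_paths,
                           path_log_score, random_tiny_space)


def tiny_params(c, phi=None, allowed=None):
    if phi is None:
        phi = np.zeros((c, c))
    if allowed is not None:
        phi = np.where(allowed, phi, NEG)
    return CrfParams(W_psi=np.eye(c), b_psi=np.zeros(c), phi=phi)


def all_true_space(c):
    return TinySpace(np.ones((c, c), dtype=bool), np.ones(c, dtype=bool),
                     np.ones(c, dtype=bool))


class TestEmissions:
    def test_zero_hidden_zero_bias(self):
        params = CrfParams(W_psi=np.ones((4, 3)), b_psi=np.zeros(3),
                           phi=np.zeros((3, 3)))
        assert np.all(crf.emissions(np.zeros((5, 4)), params) == 0)

    def test_identity_projection(self):
        params = tiny_params(3)
        h = np.eye(3)[[0, 2, 1]]
        np.testing.assert_array_equal(crf.emissions(h, params), h)

    def test_matches_matrix_product(self, rng):
        w = rng.normal(size=(2, 3))
        b = rng.normal(size=3)
        h = rng.normal(size=(3, 2))
        params = CrfParams(W_psi=w, b_psi=b, phi=np.zeros((3, 3)))
        np.testing.assert_allclose(crf.emissions(h, params), h @ w + b)

    def test_dimension_mismatch(self):
        params = tiny_params(3)
        with pytest.raises(ValueError):
            crf.emissions(np.zeros((5, 7)), params)


class TestLogPartition:
    def test_single_state_chain(self):
        space = all_true_space(1)
        em = np.array([[1.0], [2.0], [3.0]])
        assert crf.log_partition(em, tiny_params(1), space) == pytest.approx(6.0)

    def test_two_state_unconstrained_zero_scores(self):
        space = all_true_space(2)
        em = np.zeros((2, 2))
        assert crf.log_partition(em, tiny_params(2), space) == \
            pytest.approx(np.log(4.0))

    def test_no_path_raises(self):
        space = TinySpace(np.zeros((2, 2), dtype=bool),
                          np.array([True, False]), np.array([False, True]))
        with pytest.raises(crf.NoPathError):
            crf.log_partition(np.zeros((2, 2)), tiny_params(2), space)


class TestOracleEquivalence:
    """Exhaustive-enumeration agreement on random instances."""

    N_INSTANCES = 200

    def test_random_instances(self):
        rng = np.random.default_rng(20240901)
        checked = 0
        while checked < self.N_INSTANCES:
            c = int(rng.integers(2, 10))
            t_len = int(rng.integers(1, 6))
            space = random_tiny_space(rng, c)
            em = rng.normal(size=(t_len, c)) * 2
            phi_raw = rng.normal(size=(c, c)) * 2
            params = tiny_params(c, phi_raw, space.allowed)
            phi = np.where(space.allowed, phi_raw, NEG)
            ref = brute_force_lattice(space, em, phi)
            if ref is None:
                with pytest.raises(crf.NoPathError):
                    crf.log_partition(em, params, space)
                continue
            log_z, marg_ref, best, paths, scores = ref
            assert crf.log_partition(em, params, space) == \
                pytest.approx(log_z, abs=1e-8)
            np.testing.assert_allclose(
                crf.marginals(em, params, space), marg_ref, atol=1e-8)
            vit = crf.viterbi(em, params, space)
            assert path_log_score(tuple(vit), em, phi) == pytest.approx(best)
            # multitag NLL against enumeration over consistent paths
            sets = [frozenset(map(int, rng.choice(
                c, size=int(rng.integers(1, c + 1)), replace=False)))
                for _ in range(t_len)]
            consistent = [s for p, s in zip(paths, scores)
                          if all(p[t] in sets[t] for t in range(t_len))]
            if consistent:
                nll_ref = log_z - np.logaddexp.reduce(np.array(consistent))
                assert crf.multitag_nll(em, params, space, sets) == \
                    pytest.approx(nll_ref, abs=1e-8)
            else:
                with pytest.raises(crf.NoPathError):
                    crf.multitag_nll(em, params, space, sets)
            checked += 1


class TestMarginals:
    def test_single_path_one_hot(self):
        # chain grammar 0 -> 1 -> 2 admits exactly one path
        allowed = np.zeros((3, 3), dtype=bool)
        allowed[0, 1] = allowed[1, 2] = True
        space = TinySpace(allowed, np.array([True, False, False]),
                          np.array([False, False, True]))
        marg = crf.marginals(np.zeros((3, 3)), tiny_params(3, np.zeros((3, 3)), allowed), space)
        np.testing.assert_array_equal(marg, np.eye(3))

    def test_uniform_two_state(self):
        space = all_true_space(2)
        marg = crf.marginals(np.zeros((4, 2)), tiny_params(2), space)
        np.testing.assert_allclose(marg, 0.5)

    def test_unreachable_state_marginal_exactly_zero(self):
        allowed = np.zeros((3, 3), dtype=bool)
        allowed[0, 1] = allowed[1, 1] = True
        # state 2 can never be visited
        space = TinySpace(allowed, np.array([True, False, False]),
                          np.array([False, True, False]))
        marg = crf.marginals(np.ones((4, 3)), tiny_params(3, np.zeros((3, 3)), allowed), space)
        assert (marg[:, 2] == 0.0).all()
        # start state is position-1 only
        assert (marg[1:, 0] == 0.0).all()


class TestViterbi:
    def test_dominant_emissions(self):
        space = all_true_space(3)
        em = np.array([[9.0, 0, 0], [0, 9.0, 0], [0, 0, 9.0]])
        np.testing.assert_array_equal(
            crf.viterbi(em, tiny_params(3), space), [0, 1, 2])

    def test_tie_break_deterministic(self):
        space = all_true_space(4)
        em = np.zeros((5, 4))
        path = crf.viterbi(em, tiny_params(4), space)
        np.testing.assert_array_equal(path, 0)
        again = crf.viterbi(em, tiny_params(4), space)
        np.testing.assert_array_equal(path, again)


class TestMultitagNll:
    def test_full_sets_zero(self, rng):
        space = all_true_space(3)
        em = rng.normal(size=(4, 3))
        sets = [frozenset({0, 1, 2})] * 4
        assert crf.multitag_nll(em, tiny_params(3), space, sets) == \
            pytest.approx(0.0, abs=1e-12)

    def test_singletons_reduce_to_path_nll(self, rng):
        space = all_true_space(3)
        em = rng.normal(size=(4, 3))
        params = tiny_params(3, rng.normal(size=(3, 3)))
        path = [0, 2, 1, 1]
        sets = [frozenset({s}) for s in path]
        phi = params.phi
        expected = crf.log_partition(em, params, space) - \
            path_log_score(path, em, phi)
        assert crf.multitag_nll(em, params, space, sets) == \
            pytest.approx(expected, abs=1e-10)

    def test_monotone_in_set_growth(self, rng):
        space = all_true_space(4)
        em = rng.normal(size=(5, 4))
        params = tiny_params(4, rng.normal(size=(4, 4)))
        sets = [frozenset({int(rng.integers(4))}) for _ in range(5)]
        nll = crf.multitag_nll(em, params, space, sets)
        assert 0 < np.exp(-nll) <= 1
        for t in range(5):
            grown = list(sets)
            grown[t] = frozenset(range(4))
            assert crf.multitag_nll(em, params, space, grown) <= nll + 1e-12

    def test_infeasible_names_position(self, space):
        model = Model.init(seed=0)
        em = np.zeros((5, space.n_states))
        # an SP-class-only set at position 3 after a NO_SP-only prefix
        no_sp = frozenset(space.state_ids_of_class(SpClass.NO_SP))
        spi_n = frozenset({space.state_id(SpClass.SEC_SPI, "N")})
        sets = [no_sp, no_sp, spi_n, no_sp, no_sp]
        with pytest.raises(crf.NoPathError, match="position 3"):
            crf.multitag_nll(em, model.params, space, sets)


class TestClassProbs:
    def test_all_mass_on_no_sp(self, space):
        ids = space.state_ids_of_class(SpClass.NO_SP)
        marg = np.zeros((6, space.n_states))
        marg[:, ids[0]] = 1.0
        probs = crf.class_probs(marg, space)
        assert probs[list(SpClass).index(SpClass.NO_SP)] == pytest.approx(1.0)
        assert probs.sum() == pytest.approx(1.0)

    def test_two_class_split(self, space):
        a = space.state_ids_of_class(SpClass.NO_SP)[0]
        b = space.state_ids_of_class(SpClass.SEC_SPI)[0]
        marg = np.zeros((5, space.n_states))
        marg[:, a], marg[:, b] = 0.7, 0.3
        probs = crf.class_probs(marg, space)
        assert probs[list(SpClass).index(SpClass.NO_SP)] == pytest.approx(0.7)
        assert probs[list(SpClass).index(SpClass.SEC_SPI)] == pytest.approx(0.3)

    def test_matches_direct_summation(self, space, rng):
        marg = rng.dirichlet(np.ones(space.n_states), size=7)
        probs = crf.class_probs(marg, space)
        for gi, g in enumerate(SpClass):
            ids = space.state_ids_of_class(g)
            direct = sum(marg[t, i] for t in range(7) for i in ids) / 7
            assert probs[gi] == pytest.approx(direct, abs=1e-12)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_within_class_permutation(self, space, rng):
        marg = rng.dirichlet(np.ones(space.n_states), size=5)
        probs = crf.class_probs(marg, space)
        perm = np.arange(space.n_states)
        ids = space.state_ids_of_class(SpClass.TAT_SPII)
        perm[ids] = ids[::-1]  # reverse within one class
        probs2 = crf.class_probs(marg[:, perm], space)
        np.testing.assert_allclose(probs, probs2, atol=1e-12)


class TestInferCs:
    def test_spi_path(self, space):
        n = space.state_id(SpClass.SEC_SPI, "N")
        h = space.state_id(SpClass.SEC_SPI, "H")
        c = space.state_id(SpClass.SEC_SPI, "C")
        o = space.state_id(SpClass.SEC_SPI, "O")
        path = [n] * 5 + [h] * 10 + [c] * 7 + [o] * 8
        assert crf.infer_cs(path, space) == 22

    def test_all_mature(self, space):
        i = space.state_id(SpClass.NO_SP, "I")
        assert crf.infer_cs([i] * 30, space) is None

    def test_spii_path(self, space):
        cls = SpClass.SEC_SPII
        path = ([space.state_id(cls, "N")] * 3
                + [space.state_id(cls, "H")] * 12
                + [space.state_id(cls, "L1"), space.state_id(cls, "L2"),
                   space.state_id(cls, "L3")]
                + [space.state_id(cls, "O")] * 10)
        assert crf.infer_cs(path, space) == 18


@pytest.fixture(scope="module")
def model():
    return Model.init(seed=5)


class TestPredict:
    def test_invariants(self, model):
        p = predict("MKKLLLLLLASAMGGDDEE", OrganismGroup.EUKARYA, model)
        assert p.class_probs.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(p.marginals.sum(axis=1), 1.0, atol=1e-9)
        for a, b in zip(p.path[:-1], p.path[1:]):
            assert model.space.allowed[a, b]

    def test_length_one(self, model):
        p = predict("M", OrganismGroup.UNKNOWN, model)
        assert len(p.path) == 1
        assert p.cs is None or p.cs == 1

    def test_nonstandard_residues_do_not_crash(self, model):
        p = predict("MBZXUOKLLA", OrganismGroup.GRAM_NEG, model)
        assert p.class_probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_sequence_errors(self, model):
        with pytest.raises(ValueError):
            predict("", OrganismGroup.UNKNOWN, model)


class TestMarginalsVjp:
    def test_finite_differences(self, rng):
        c, t_len = 5, 4
        space = random_tiny_space(rng, c)
        space.allowed |= np.eye(c, dtype=bool)
        space.start_allowed[:] = True
        space.end_allowed[:] = True
        em = rng.normal(size=(t_len, c))
        phi_raw = rng.normal(size=(c, c))
        params = tiny_params(c, phi_raw, space.allowed)
        grad = rng.normal(size=(t_len, c))

        def loss(em_, phi_):
            p = crf.marginals(em_, CrfParams(np.eye(c), np.zeros(c), phi_),
                              space)
            return float((grad * p).sum())

        d_em, d_phi = crf.marginals_vjp(em, params, space, grad)
        eps = 1e-6
        for t in range(t_len):
            for s in range(c):
                e2 = em.copy()
                e2[t, s] += eps
                fd = (loss(e2, params.phi) - loss(em, params.phi)) / eps
                assert d_em[t, s] == pytest.approx(fd, abs=1e-4)
        for i in range(c):
            for j in range(c):
                if not space.allowed[i, j]:
                    assert d_phi[i, j] == 0.0
                    continue
                p2 = params.phi.copy()
                p2[i, j] += eps
                fd = (loss(em, p2) - loss(em, params.phi)) / eps
                assert d_phi[i, j] == pytest.approx(fd, abs=1e-4)
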