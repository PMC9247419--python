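import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from connscale import (
    AsymmetryConfig,
    asymmetry_permutation_test,
    pair_asymmetry,
    resample_weights_to_normal,
    total_asymmetry,
)
from connscale.synthetic import child_seed
from conftest import build_connectome, star_tree


def _random_connectome(rng, R=10, p=0.5, asym=0.0, species="toy"):
    left = {
        (i, j): float(rng.integers(1, 100))
        for i in range(R)
        for j in range(i + 1, R)
        if rng.random() < p
    }
    if asym > 0:
        right = {k: max(1.0, round(w * np.exp(asym * rng.standard_normal()))) for k, w in left.items()}
    else:
        right = dict(left)
    return build_connectome(R, left, right, species=species)


class TestResampleWeights:
    def test_target_moments(self):
        rng = np.random.default_rng(0)
        conn = _random_connectome(rng, R=20, p=0.6)
        out = resample_weights_to_normal(conn, AsymmetryConfig())
        for hemi in ("left", "right"):
            idx = out.hemisphere_nodes(hemi)
            sub = out.weights[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), 1)
            w = sub[iu][sub[iu] != 0]
            assert len(w) >= 100
            assert abs(w.mean() - 1.0) <= 0.01
            assert abs(w.std(ddof=0) - 0.2) <= 0.01

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        conn = _random_connectome(rng, R=8, p=0.7)
        out = resample_weights_to_normal(conn, AsymmetryConfig())
        idx = conn.hemisphere_nodes("left")
        iu = np.triu_indices(len(idx), 1)
        mask = conn.weights[np.ix_(idx, idx)][iu] > 0
        before = conn.weights[np.ix_(idx, idx)][iu][mask]
        after = out.weights[np.ix_(idx, idx)][iu][mask]
        assert np.array_equal(np.argsort(before, kind="stable"), np.argsort(after, kind="stable"))

    def test_global_rescale_invariance(self):
        rng = np.random.default_rng(2)
        conn = _random_connectome(rng, R=8, p=0.7)
        scaled = conn.copy()
        scaled.weights *= 10.0
        out1 = resample_weights_to_normal(conn, AsymmetryConfig())
        out2 = resample_weights_to_normal(scaled, AsymmetryConfig())
        assert np.allclose(out1.weights, out2.weights)

    def test_too_few_edges_rejected(self):
        conn = build_connectome(3, {(0, 1): 1.0})
        with pytest.raises(ValueError, match="need >= 2"):
            resample_weights_to_normal(conn, AsymmetryConfig())


class TestPairAsymmetry:
    def test_identical_profiles_score_zero(self):
        score, n = pair_asymmetry(np.array([1.0, 0.5, 0.0]), np.array([1.0, 0.5, 0.0]))
        assert score == 0.0
        assert n == 2

    def test_hand_computed_weighted(self):
        # A connects to {B: 1.0, C: 0.5}; A' to {B': 0.8, C': 0.5}
        score, n = pair_asymmetry(np.array([1.0, 0.5]), np.array([0.8, 0.5]))
        assert score == pytest.approx(0.1, abs=1e-12)
        assert n == 2

    def test_shared_only_restriction(self):
        # A': {B': 0.8} only, so the C connection is not shared
        score, n = pair_asymmetry(np.array([1.0, 0.5]), np.array([0.8, 0.0]))
        assert score == pytest.approx(0.2, abs=1e-12)
        assert n == 1

    def test_no_shared_connection_flags_pair(self):
        score, n = pair_asymmetry(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert score is None and n == 0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(0, 10, allow_nan=False), st.floats(0, 10, allow_nan=False)),
            min_size=1,
            max_size=12,
        )
    )
    def test_score_symmetric_and_nonnegative(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        s_ab, n_ab = pair_asymmetry(a, b)
        s_ba, n_ba = pair_asymmetry(b, a)
        assert n_ab == n_ba
        assert (s_ab is None) == (s_ba is None)
        if s_ab is not None:
            assert s_ab == pytest.approx(s_ba, abs=1e-12)
            assert s_ab >= 0

    def test_binary_mode_jaccard_complement(self):
        score, _ = pair_asymmetry(
            np.array([1.0, 1.0, 0.0]), np.array([1.0, 0.0, 1.0]), mode="binary"
        )
        assert score == pytest.approx(1 - 1 / 3)


class TestTotalAsymmetry:
    def test_mirror_connectome_scores_exactly_zero(self):
        rng = np.random.default_rng(3)
        conn = _random_connectome(rng, R=12, p=0.5, asym=0.0)
        res = total_asymmetry(conn, AsymmetryConfig())
        assert res.species_mean == 0.0
        assert (res.pair_scores["score"].dropna() == 0.0).all()

    def test_species_mean_is_mean_of_pair_scores(self):
        rng = np.random.default_rng(4)
        conn = _random_connectome(rng, R=10, p=0.6, asym=0.3)
        res = total_asymmetry(conn, AsymmetryConfig())
        eligible = res.pair_scores["score"].dropna()
        assert res.species_mean == pytest.approx(eligible.mean())
        assert (eligible >= 0).all()

    def test_monotone_in_perturbation_amplitude(self):
        means = []
        for eps in (0.01, 0.05, 0.1):
            rng = np.random.default_rng(5)  # same base topology/weights each time
            conn = _random_connectome(rng, R=12, p=0.6, asym=eps)
            means.append(total_asymmetry(conn, AsymmetryConfig()).species_mean)
        assert means[0] < means[1] < means[2]

    def test_hemisphere_swap_symmetry(self):
        rng = np.random.default_rng(6)
        R = 10
        left = {(i, j): float(rng.integers(1, 50)) for i in range(R) for j in range(i + 1, R) if rng.random() < 0.5}
        right = {k: float(rng.integers(1, 50)) for k in left}
        a = total_asymmetry(build_connectome(R, left, right), AsymmetryConfig())
        b = total_asymmetry(build_connectome(R, right, left), AsymmetryConfig())
        assert a.species_mean == pytest.approx(b.species_mean, abs=1e-12)

    def test_monotone_rescale_invariance(self):
        rng = np.random.default_rng(7)
        conn = _random_connectome(rng, R=10, p=0.6, asym=0.2)
        scaled = conn.copy()
        scaled.weights = conn.weights**2  # monotone on non-negative weights
        a = total_asymmetry(conn, AsymmetryConfig())
        b = total_asymmetry(scaled, AsymmetryConfig())
        assert a.species_mean == pytest.approx(b.species_mean, abs=1e-12)


def _species_set(seed, n_species=8, trait_coupling=0.0):
    """Small study: connectomes whose asymmetry optionally tracks a trait."""
    rng = np.random.default_rng(seed)
    tree = star_tree(n_species)
    trait = {}
    conns = {}
    for i, sp in enumerate(tree.leaf_labels):
        u = i / (n_species - 1)
        trait[sp] = float(u)
        asym = 0.05 + trait_coupling * u + 0.0  # coupling 0 → no size relation
        conns[sp] = _random_connectome(
            rng, R=8, p=0.7, asym=asym if asym > 0 else 0.0, species=sp
        )
    return tree, trait, conns


class TestPermutationTest:
    def test_extreme_observed_gives_minimal_p(self):
        tree, trait, conns = _species_set(0, trait_coupling=0.6)
        config = AsymmetryConfig(n_permutations=30, seed=1)
        res = asymmetry_permutation_test(conns, trait, tree, config)
        assert res.p_value >= 1 / 31
        if np.all(res.null_betas < res.observed_beta):
            assert res.p_value == pytest.approx(1 / 31)

    def test_deterministic_per_seed(self):
        tree, trait, conns = _species_set(1, trait_coupling=0.4)
        config = AsymmetryConfig(n_permutations=20, seed=9)
        r1 = asymmetry_permutation_test(conns, trait, tree, config)
        r2 = asymmetry_permutation_test(conns, trait, tree, config)
        assert np.array_equal(r1.null_betas, r2.null_betas)
        assert r1.p_value == r2.p_value

    def test_p_uniform_under_null(self):
        """With no asymmetry-trait coupling, permutation p-values ~ uniform."""
        pvals = []
        for rep in range(30):
            tree, trait, conns = _species_set(child_seed(50, rep), trait_coupling=0.0)
            config = AsymmetryConfig(n_permutations=49, seed=child_seed(51, rep))
            pvals.append(asymmetry_permutation_test(conns, trait, tree, config).p_value)
        stat = stats.kstest(pvals, "uniform")
        assert stat.pvalue > 0.01
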