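"""Allocation samplers against exact enumeration, prior recovery, determinism."""

import itertools

import numpy as np
import pytest
from scipy.special import gammaln

from mutselpip import MutationParams, McmcConfig, mutsel_bc, run_chain
from mutselpip.mcmc import (
    AllocationState,
    ChainState,
    gibbs_allocation_sweep,
    rle_decode,
    update_branch_lengths,
    update_mutation_params,
    update_weights,
    weighted_allocation_sweep,
)
from mutselpip.pip import allocation_probability
from mutselpip.simulate import make_design, simulate_alignment


def exact_allocation_posterior(logliks: np.ndarray, K: int) -> dict[tuple, float]:
    """Enumerate p(z | D) under the flat-Dirichlet (Polya urn) prior.

    p(z) ~ Gamma(K)/Gamma(N+K) * prod_k Gamma(1 + eta_k), times the
    per-site likelihoods of the assigned components.
    """
    N = logliks.shape[0]
    out = {}
    for z in itertools.product(range(K), repeat=N):
        eta = np.bincount(z, minlength=K)
        logp = gammaln(1.0 + eta).sum() + sum(logliks[n, z[n]] for n in range(N))
        out[z] = logp
    mx = max(out.values())
    total = sum(np.exp(v - mx) for v in out.values())
    return {z: np.exp(v - mx) / total for z, v in out.items()}


TWO_SITE_LOGLIKS = np.log(np.array([[0.7, 0.3], [0.2, 0.8]]))


def joint_frequencies_gibbs(n_sweeps, seed):
    rng = np.random.default_rng(seed)
    state = AllocationState.from_z(np.array([0, 0]), K=2)
    counts = {}
    for _ in range(n_sweeps):
        gibbs_allocation_sweep(state, TWO_SITE_LOGLIKS, rng)
        key = tuple(state.z)
        counts[key] = counts.get(key, 0) + 1
    return {z: c / n_sweeps for z, c in counts.items()}


def joint_frequencies_weighted(n_sweeps, seed):
    rng = np.random.default_rng(seed)
    state = AllocationState.from_z(np.array([0, 0]), K=2)
    counts = {}
    for _ in range(n_sweeps):
        w = update_weights(state.eta, rng)
        weighted_allocation_sweep(state, TWO_SITE_LOGLIKS, w, rng)
        key = tuple(state.z)
        counts[key] = counts.get(key, 0) + 1
    return {z: c / n_sweeps for z, c in counts.items()}


class TestAllocationSamplers:
    def test_single_component_is_a_fixed_point(self, rng):
        state = AllocationState.from_z(np.zeros(5, dtype=int), K=1)
        logliks = -np.abs(rng.normal(size=(5, 1)))
        gibbs_allocation_sweep(state, logliks, rng)
        assert np.all(state.z == 0)
        weighted_allocation_sweep(state, logliks, np.array([1.0]), rng)
        assert np.all(state.z == 0)

    def test_polya_urn_weighting(self):
        # 5 sites, equal likelihoods; updating the first site sees
        # post-decrement counts (3, 1), hence probabilities (4/6, 2/6)
        rng = np.random.default_rng(123)
        logliks = np.zeros((5, 2))
        hits = 0
        reps = 20000
        for _ in range(reps):
            state = AllocationState.from_z(np.array([0, 0, 0, 0, 1]), K=2)
            # freeze the other sites by observing only the first draw:
            eta = state.eta.copy()
            eta[state.z[0]] -= 1
            w = (eta + 1.0) * 1.0
            p = w / w.sum()
            hits += rng.random() < p[0]
        se = np.sqrt((2 / 3) * (1 / 3) / reps)
        assert abs(hits / reps - 2 / 3) < 4 * se

    def test_degenerate_weights_force_one_component(self, rng):
        state = AllocationState.from_z(np.array([1, 0, 2]), K=3)
        logliks = np.zeros((3, 3))
        weighted_allocation_sweep(state, logliks, np.array([1.0, 0.0, 0.0]), rng)
        assert np.all(state.z == 0)

    def test_weighted_allocation_probability_combines_weights_and_likelihoods(self):
        # w = (0.25, 0.75) and likelihood ratio 3:1 -> probabilities (0.5, 0.5)
        rng = np.random.default_rng(99)
        logliks = np.log(np.array([[3.0, 1.0]]))
        w = np.array([0.25, 0.75])
        draws = np.empty(20000, dtype=int)
        for m in range(draws.size):
            state = AllocationState.from_z(np.array([0]), K=2)
            weighted_allocation_sweep(state, logliks, w, rng)
            draws[m] = state.z[0]
        se = np.sqrt(0.25 / draws.size)
        assert abs((draws == 0).mean() - 0.5) < 4 * se

    @pytest.mark.parametrize("sampler", ["gibbs", "weighted"])
    def test_two_site_fixture_matches_enumerated_posterior(self, sampler):
        exact = exact_allocation_posterior(TWO_SITE_LOGLIKS, K=2)
        freqs = (joint_frequencies_gibbs if sampler == "gibbs" else joint_frequencies_weighted)(
            30000, seed=42
        )
        for z, p in exact.items():
            assert freqs.get(z, 0.0) == pytest.approx(p, abs=0.02)

    def test_counts_stay_consistent(self, rng):
        state = AllocationState.from_z(rng.integers(3, size=50), K=3)
        logliks = rng.normal(size=(50, 3))
        for _ in range(10):
            gibbs_allocation_sweep(state, logliks, rng)
            state.check()
            w = update_weights(state.eta, rng)
            weighted_allocation_sweep(state, logliks, w, rng)
            state.check()


class TestWeightUpdates:
    def test_prior_draw_when_counts_empty(self):
        rng = np.random.default_rng(1)
        draws = np.array([update_weights(np.zeros(4, dtype=int), rng) for _ in range(20000)])
        np.testing.assert_allclose(draws.mean(axis=0), 0.25, atol=0.01)

    def test_posterior_mean_with_occupied_counts(self):
        rng = np.random.default_rng(2)
        eta = np.array([100, 0])
        draws = np.array([update_weights(eta, rng) for _ in range(20000)])
        # conjugate posterior Dirichlet(1 + eta): mean (1 + eta_k)/(K + N)
        expect = 101 / 102
        var = expect * (1 - expect) / 103
        se = np.sqrt(var / draws.shape[0])
        assert abs(draws[:, 0].mean() - expect) < 4 * se


class TestParameterMoves:
    def test_identity_proposal_always_accepted(self, rng):
        state = ChainState(
            allocation=AllocationState.from_z(np.array([0]), K=1),
            mut=MutationParams.uniform(),
            edge_lengths=np.array([0.1]),
        )
        state.logliks = np.zeros((1, 1))
        for _ in range(10):
            state, accepted = update_mutation_params(state, None, rng, lam=0.0)
            assert accepted
        np.testing.assert_allclose(state.mut.rho, 1 / 6)

    def test_mutation_prior_recovery_under_constant_likelihood(self):
        # with the likelihood forced constant, the MH moves must sample
        # the flat Dirichlet priors on rho and phi
        rng = np.random.default_rng(3)
        state = ChainState(
            allocation=AllocationState.from_z(np.array([0]), K=1),
            mut=MutationParams.uniform(),
            edge_lengths=np.array([0.1]),
        )
        state.logliks = np.zeros((1, 1))
        rhos, phis = [], []
        for _ in range(40000):
            state, _ = update_mutation_params(state, None, rng, lam=2.0)
            rhos.append(state.mut.rho)
            phis.append(state.mut.phi)
        rhos, phis = np.array(rhos), np.array(phis)
        np.testing.assert_allclose(rhos.mean(axis=0), 1 / 6, atol=0.02)
        np.testing.assert_allclose(phis.mean(axis=0), 1 / 4, atol=0.02)
        # flat Dirichlet variances: p(1-p)/(K+1)
        np.testing.assert_allclose(rhos.var(axis=0), (1 / 6) * (5 / 6) / 7, atol=0.005)
        np.testing.assert_allclose(phis.var(axis=0), (1 / 4) * (3 / 4) / 5, atol=0.01)

    def test_branch_length_prior_recovery(self):
        rng = np.random.default_rng(4)
        state = ChainState(
            allocation=AllocationState.from_z(np.array([0]), K=1),
            mut=MutationParams.uniform(),
            edge_lengths=np.full(5, 0.1),
        )
        state.logliks = np.zeros((1, 1))
        samples = []
        for _ in range(20000):
            state, _ = update_branch_lengths(state, None, rng, lam=3.0, prior_mean=0.1)
            samples.append(state.edge_lengths.copy())
        samples = np.array(samples).ravel()
        assert samples.mean() == pytest.approx(0.1, abs=0.01)
        assert samples.min() > 0

    def test_seeded_reproducibility_of_moves(self):
        def run(seed):
            rng = np.random.default_rng(seed)
            state = ChainState(
                allocation=AllocationState.from_z(np.array([0]), K=1),
                mut=MutationParams.uniform(),
                edge_lengths=np.array([0.1, 0.2]),
            )
            state.logliks = np.zeros((1, 1))
            for _ in range(50):
                state, _ = update_mutation_params(state, None, rng, lam=1.0)
                state, _ = update_branch_lengths(state, None, rng, lam=1.0)
            return state.mut.rho, state.edge_lengths

        r1, l1 = run(7)
        r2, l2 = run(7)
        np.testing.assert_array_equal(r1, r2)
        np.testing.assert_array_equal(l1, l2)


@pytest.fixture(scope="module")
def fixture_data():
    pset = mutsel_bc(0.9)
    design = make_design(5, 2, 12, 0, pset, rng=11, mean_branch=0.4)
    aln, _ = simulate_alignment(design, 11)
    return aln, design.tree, pset, design.mut


class TestRunChain:
    def test_fixed_theta_k1_trace_is_constant(self, fixture_data):
        aln, tree, pset, mut = fixture_data
        from mutselpip.profiles import ProfileSet

        single = ProfileSet(pset.components[:1])
        trace = run_chain(aln, tree, single, McmcConfig(n_sweeps=50, mutation_params=mut), 0)
        assert np.all(trace.z == 0)

    def test_sampler_variants_agree(self, fixture_data):
        aln, tree, pset, mut = fixture_data
        probs = {}
        for sampler in ("weighted", "gibbs"):
            cfg = McmcConfig(sampler=sampler, n_sweeps=20000, thin=1, mutation_params=mut)
            trace = run_chain(aln, tree, pset, cfg, 17)
            probs[sampler] = allocation_probability(trace).table
        assert np.abs(probs["weighted"] - probs["gibbs"]).max() < 0.02

    def test_same_seed_gives_identical_trace_files(self, fixture_data, tmp_path):
        aln, tree, pset, mut = fixture_data
        from mutselpip.profiles import ProfileSet

        pset3 = ProfileSet(pset.components[:3])
        cfg = McmcConfig(n_sweeps=100, mutation_params=mut,
                         update_mutation=True, update_branch_lengths=True)
        paths = []
        for tag in ("a", "b"):
            trace = run_chain(aln, tree, pset3, cfg, 23)
            p = tmp_path / f"{tag}.trace.tsv"
            trace.write_tsv(p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_chain_validation(self, fixture_data):
        aln, tree, pset, mut = fixture_data
        with pytest.raises(ValueError):
            run_chain(aln, tree, pset, McmcConfig(n_sweeps=10, burn_in=10), 0)
        with pytest.raises(ValueError):
            run_chain(aln, tree, pset, McmcConfig(sampler="bogus"), 0)


def test_allocation_recovery_with_peaked_profiles():
    # strong constraint (peakedness 0.9) on an informative tree: the true
    # component should dominate the posterior allocation at most sites
    pset = mutsel_bc(0.9)
    design = make_design(16, 6, 100, 0, pset, rng=31, mean_branch=0.3)
    assert design.tree.total_length >= 5
    aln, _ = simulate_alignment(design, 31)
    cfg = McmcConfig(n_sweeps=1500, mutation_params=design.mut)
    trace = run_chain(aln, design.tree, pset, cfg, 32)
    table = allocation_probability(trace).table
    true_prob = table[np.arange(100), design.allocation_main]
    assert (true_prob > 0.9).mean() >= 0.8


def test_rle_round_trip(rng):
    z = rng.integers(5, size=200)
    from mutselpip.mcmc import _rle

    np.testing.assert_array_equal(rle_decode(_rle(z)), z)
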