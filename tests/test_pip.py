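"""PIP statistic, entropy, shift calls, and evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutselpip import (
    AllocationProbabilities,
    allocation_entropy,
    allocation_probability,
    classify_sites,
    confusion_metrics,
    pip,
    precision_recall_curve,
)
from mutselpip.mcmc import McmcTrace


def make_trace(z_draws: np.ndarray, K: int) -> McmcTrace:
    M = z_draws.shape[0]
    return McmcTrace(
        z=z_draws,
        loglik=np.zeros(M),
        weights=None,
        rho=np.tile(np.full(6, 1 / 6), (M, 1)),
        phi=np.tile(np.full(4, 0.25), (M, 1)),
        sweep_index=np.arange(M),
        K=K,
    )


class TestAllocationProbability:
    def test_certain_allocation(self):
        trace = make_trace(np.full((10, 3), 1), K=4)
        table = allocation_probability(trace).table
        np.testing.assert_array_equal(table, np.tile([0, 1, 0, 0], (3, 1)))

    def test_counting_example(self):
        # 4 draws for one site allocated to components (1, 1, 2, 3)
        trace = make_trace(np.array([[0], [0], [1], [2]]), K=3)
        np.testing.assert_allclose(
            allocation_probability(trace).table[0], [0.5, 0.25, 0.25]
        )

    def test_rows_sum_to_one(self, rng):
        trace = make_trace(rng.integers(5, size=(40, 7)), K=5)
        table = allocation_probability(trace).table
        np.testing.assert_allclose(table.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            allocation_probability(make_trace(np.empty((0, 3), dtype=int), K=2))


def point_mass(k, K):
    v = np.zeros(K)
    v[k] = 1.0
    return v


class TestPip:
    def test_identical_point_masses_give_one(self):
        assert pip(point_mass(2, 8), point_mass(2, 8)) == 1.0

    def test_disjoint_supports_give_zero(self):
        assert pip(point_mass(0, 8), point_mass(1, 8)) == 0.0

    def test_half_half_over_same_components_gives_half(self):
        v = np.array([0.5, 0.5] + [0.0] * 6)
        assert pip(v, v) == 0.5

    def test_uniform_over_sixty_components(self):
        v = np.full(60, 1 / 60)
        assert pip(v, v) == pytest.approx(1 / 60, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pip(np.ones(3) / 3, np.ones(4) / 4)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(2, 12), st.integers(0, 2**31 - 1))
    def test_symmetry_permutation_invariance_cauchy_schwarz(self, K, seed):
        r = np.random.default_rng(seed)
        a, b = r.dirichlet(np.ones(K)), r.dirichlet(np.ones(K))
        assert pip(a, b) == pytest.approx(pip(b, a), abs=1e-12)
        perm = r.permutation(K)
        assert pip(a[perm], b[perm]) == pytest.approx(pip(a, b), abs=1e-12)
        assert 0.0 <= pip(a, b) <= np.sqrt(pip(a, a) * pip(b, b)) + 1e-12
        assert pip(a, a) <= 1.0 + 1e-12


class TestEntropy:
    def test_point_mass_zero(self):
        assert allocation_entropy(point_mass(3, 8)) == 0.0

    def test_uniform_is_log_k(self):
        assert allocation_entropy(np.full(8, 1 / 8)) == pytest.approx(np.log(8), abs=1e-12)

    def test_two_component_split(self):
        assert allocation_entropy(np.array([0.5, 0.5, 0, 0])) == pytest.approx(
            np.log(2), abs=1e-12
        )


def tables_from_pips(pips):
    """Two K=2 allocation tables whose per-site PIP equals the given values.

    With a = (p, 1-p) and b = (1, 0), PIP = p.
    """
    pips = np.asarray(pips, dtype=float)
    A = np.stack([pips, 1 - pips], axis=1)
    B = np.tile([1.0, 0.0], (pips.size, 1))
    return AllocationProbabilities(A, "a"), AllocationProbabilities(B, "b")


class TestClassifySites:
    def test_inclusive_threshold(self):
        pa, pb = tables_from_pips([0.0, 0.04, 0.05, 0.051, 1.0])
        report = classify_sites(pa, pb, threshold=0.05)
        np.testing.assert_allclose(report.pip_values, [0.0, 0.04, 0.05, 0.051, 1.0])
        np.testing.assert_array_equal(report.called_sites, [1, 2, 3])

    def test_zero_threshold_flags_only_exact_zero(self):
        pa, pb = tables_from_pips([0.0, 0.01, 0.5])
        report = classify_sites(pa, pb, threshold=0.0)
        np.testing.assert_array_equal(report.called_sites, [1])

    def test_self_comparison_of_concentrated_allocations(self, rng):
        # concentrated allocation vs itself: PIP near 1, nothing flagged
        table = np.full((20, 4), 0.02)
        table[np.arange(20), rng.integers(4, size=20)] = 0.94
        pa = AllocationProbabilities(table, "x")
        report = classify_sites(pa, pa, threshold=0.05)
        assert report.called_sites.size == 0
        assert np.all(report.pip_values > 0.85)

    def test_entropy_filter_suppresses_diffuse_sites(self):
        # site 1: clear shift (point masses on different components)
        # site 2: low PIP purely from diffuse allocation in both partitions
        A = np.array([[1.0, 0, 0, 0], [0.25, 0.25, 0.25, 0.25]])
        B = np.array([[0, 1.0, 0, 0], [0.25, 0.25, 0.25, 0.25]])
        pa, pb = AllocationProbabilities(A, "a"), AllocationProbabilities(B, "b")
        plain = classify_sites(pa, pb, threshold=0.3)
        np.testing.assert_array_equal(plain.called_sites, [1, 2])
        filtered = classify_sites(pa, pb, threshold=0.3, entropy_max=0.5)
        np.testing.assert_array_equal(filtered.called_sites, [1])

    def test_shape_mismatch_rejected(self):
        pa, _ = tables_from_pips([0.1, 0.2])
        pb = AllocationProbabilities(np.full((2, 4), 0.25), "b")
        with pytest.raises(ValueError):
            classify_sites(pa, pb)


class TestConfusionMetrics:
    def test_perfect_calls(self):
        m = confusion_metrics(np.array([1, 2, 3]), {1, 2, 3}, n_sites=10)
        assert m["TPR"] == 1.0 and m["FPR"] == 0.0 and m["precision"] == 1.0

    def test_shifted_sites_design_arithmetic(self):
        # 80 true shifts among 759 sites; 70 detected plus 14 false calls
        truth = set(range(1, 81))
        calls = np.array(list(range(1, 71)) + list(range(100, 114)))
        m = confusion_metrics(calls, truth, n_sites=759)
        assert m["TPR"] == pytest.approx(0.875)
        assert m["FPR"] == pytest.approx(14 / 679)
        assert m["precision"] == pytest.approx(70 / 84)

    def test_no_calls(self):
        m = confusion_metrics(np.array([]), {1, 2}, n_sites=5)
        assert m["TPR"] == 0.0 and m["FPR"] == 0.0 and m["precision"] == 0.0

    def test_empty_truth_gives_nan_tpr(self):
        m = confusion_metrics(np.array([1]), set(), n_sites=5)
        assert np.isnan(m["TPR"]) and m["FPR"] == pytest.approx(0.2)


class TestPrecisionRecallCurve:
    def test_truth_everywhere_gives_unit_precision(self):
        curve = precision_recall_curve(np.array([0.1, 0.5, 0.9]), {1, 2, 3})
        assert all(p == 1.0 for _, p, _ in curve if _ >= 0.1)

    def test_two_point_sweep(self):
        curve = dict(
            (t, (p, r)) for t, p, r in precision_recall_curve(np.array([0.01, 0.9]), {1})
        )
        assert curve[0.01] == (1.0, 1.0)
        assert curve[0.9] == (0.5, 1.0)
        assert curve[0.0] == (0.0, 0.0)

    def test_recall_monotone_in_threshold(self, rng):
        pips = rng.random(30)
        truth = set(int(s) for s in rng.choice(30, size=8, replace=False) + 1)
        curve = precision_recall_curve(pips, truth)
        recalls = [r for _, _, r in curve]
        assert all(r2 >= r1 for r1, r2 in zip(recalls, recalls[1:]))


def test_allocation_table_round_trip(tmp_path, rng):
    table = rng.dirichlet(np.ones(5), size=12)
    pa = AllocationProbabilities(table, "subclade")
    path = tmp_path / "alloc.tsv"
    pa.write_tsv(path)
    back = AllocationProbabilities.read_tsv(path, "subclade")
    np.testing.assert_allclose(back.table, table, atol=1e-15)
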