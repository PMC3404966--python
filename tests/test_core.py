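"""Unit and property tests for the antagonism statistic."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from mirantag.core import (
    StandardizedPair,
    _null_pool,
    antagonism_coefficient,
    antagonism_pvalue,
    fraction_below,
    scan_all_pairs,
    zscore,
)
from mirantag.errors import DegenerateInputError, SchemaError
from mirantag.simulate import simulate_pair

from conftest import make_planted_set


# ---------------------------------------------------------------- z-score


def test_zscore_symmetric_sequence():
    assert np.allclose(zscore([1, 2, 3]), [-1, 0, 1])


def test_zscore_rejects_degenerate_inputs():
    with pytest.raises(DegenerateInputError):
        zscore([5, 5, 5])
    with pytest.raises(DegenerateInputError):
        zscore([1.0, 2.0])


@given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=50, unique=True))
def test_zscore_is_idempotent(values):
    z = zscore(values)
    assert np.allclose(zscore(z), z, atol=1e-12)
    assert abs(z.mean()) < 1e-9 and abs(z.std(ddof=1) - 1) < 1e-9


# ---------------------------------------------------------- fraction_below


def _pair(x, y):
    return StandardizedPair(np.asarray(x, float), np.asarray(y, float))


def test_fraction_below_counts_strictly_below_the_line():
    pair = _pair([-1, 0, 1], [-1, 0, 1])
    assert fraction_below(pair, 0.0) == pytest.approx(1 / 3)
    assert fraction_below(pair, 100.0) == 1.0
    assert fraction_below(pair, -100.0) == 0.0


def test_fraction_below_matches_naive_loop(rng):
    x, y = zscore(rng.normal(size=50)), zscore(rng.normal(size=50))
    pair = StandardizedPair(x, y)
    b = float(np.median(x + y))
    naive = sum(1 for xi, yi in zip(x, y) if xi + yi < b) / 50
    assert fraction_below(pair, b) == pytest.approx(naive, abs=0)


@given(st.floats(-4, 4), st.floats(-4, 4))
def test_fraction_below_is_a_step_cdf(b1, b2):
    g = np.random.default_rng(7)
    pair = StandardizedPair.from_raw(g.normal(size=20), g.normal(size=20))
    lo, hi = sorted((b1, b2))
    assert fraction_below(pair, lo) <= fraction_below(pair, hi)
    s = pair.sums
    assert fraction_below(pair, float(s.min())) == 0.0
    assert fraction_below(pair, float(s.max()) + 1e-9) == 1.0


# ------------------------------------------------- antagonism coefficient


def oracle_coefficient(x, y, n_shuffles, seed):
    """Exhaustive double-loop reference: every candidate b over all sums.

    Reproduces the implementation's shuffle-draw protocol (sorted vectors,
    permutation/inverse pairs), then searches the union of observed and
    shuffled sums by direct counting with strict ``<``.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    g = np.random.default_rng(seed)
    n_draws = (n_shuffles + 1) // 2
    perms = g.permuted(np.tile(np.arange(n), (n_draws, 1)), axis=1)
    sx, sy = np.sort(x), np.sort(y)
    null_vectors = [sy[p] for p in perms]
    null_vectors += [sy[np.argsort(p)] for p in perms[: n_shuffles - n_draws]]
    obs = [float(x[i] + y[i]) for i in range(n)]
    null_sums = [float(sx[i] + v[i]) for v in null_vectors for i in range(n)]
    best = 0.0
    for b in set(obs) | set(null_sums):
        f_obs = sum(1 for s in obs if s < b) / len(obs)
        f_null = sum(1 for s in null_sums if s < b) / len(null_sums)
        best = max(best, f_obs - f_null)
    return best


@pytest.mark.parametrize("n,k,seed", [(5, 1, 0), (8, 3, 1), (10, 4, 2), (12, 5, 3), (12, 2, 4)])
def test_coefficient_matches_exhaustive_oracle(n, k, seed):
    g = np.random.default_rng(100 + seed)
    pair = StandardizedPair.from_raw(g.normal(size=n), g.normal(size=n))
    a, b_star = antagonism_coefficient(pair, n_null_shuffles=k, rng=np.random.default_rng(seed))
    assert a == pytest.approx(oracle_coefficient(pair.x, pair.y, k, seed), abs=1e-12)
    assert b_star in set(pair.sums)


def test_coefficient_invariant_to_swapping_x_and_y(rng):
    x, y = rng.normal(size=25), rng.normal(size=25)
    a1 = antagonism_coefficient(StandardizedPair.from_raw(x, y), 100, rng=np.random.default_rng(5))
    a2 = antagonism_coefficient(StandardizedPair.from_raw(y, x), 100, rng=np.random.default_rng(5))
    assert a1[0] == pytest.approx(a2[0], abs=1e-12)


def test_coefficient_invariant_to_joint_relabelling(rng):
    x, y = rng.normal(size=25), rng.normal(size=25)
    perm = rng.permutation(25)
    a1 = antagonism_coefficient(StandardizedPair.from_raw(x, y), 100, rng=np.random.default_rng(5))
    a2 = antagonism_coefficient(
        StandardizedPair.from_raw(x[perm], y[perm]), 100, rng=np.random.default_rng(5)
    )
    assert a1[0] == pytest.approx(a2[0], abs=1e-12)


def test_anti_diagonal_pair_gives_single_step_nonnegative_coefficient(rng):
    x = rng.normal(size=20)
    pair = StandardizedPair.from_raw(x, -x)
    assert np.allclose(pair.sums, 0.0, atol=1e-12)  # one step in F_obs
    a, _ = antagonism_coefficient(pair, 100, rng=rng)
    assert a >= 0.0


def test_coefficient_vanishes_for_independent_pairs_at_large_n():
    values = []
    for r in range(200):
        g = np.random.default_rng([21, r])
        pair = StandardizedPair.from_raw(g.normal(size=1000), g.normal(size=1000))
        values.append(antagonism_coefficient(pair, 100, rng=g)[0])
    assert np.mean(values) < 0.1


def test_coefficient_rejects_bad_shuffle_count(rng):
    pair = StandardizedPair.from_raw(rng.normal(size=10), rng.normal(size=10))
    with pytest.raises(ValueError):
        antagonism_coefficient(pair, n_null_shuffles=0, rng=rng)


# ----------------------------------------------------- permutation p-value


def test_pvalue_smoothing_with_single_permutation():
    # a clean triangular pair beats one null draw: PV = (1+0)/(1+1) = 1/2
    sim = simulate_pair(50, 0.0, seed=3)
    pair = StandardizedPair.from_raw(sim.x, sim.y)
    score = antagonism_pvalue(pair, n_permutations=1, rng=np.random.default_rng(3))
    assert score.pvalue == 0.5


def test_pvalue_bounds_and_determinism():
    sim = simulate_pair(30, 0.2, seed=9)
    pair = StandardizedPair.from_raw(sim.x, sim.y)
    s1 = antagonism_pvalue(pair, n_permutations=99, rng=np.random.default_rng(1))
    s2 = antagonism_pvalue(pair, n_permutations=99, rng=np.random.default_rng(1))
    assert s1.pvalue == s2.pvalue and s1.coefficient == s2.coefficient
    assert 1 / 100 <= s1.pvalue <= 1.0
    assert -1.0 <= s1.coefficient <= 1.0


def test_strong_pattern_detected_at_one_hundred_samples():
    sim = simulate_pair(100, 0.0, seed=11)
    pair = StandardizedPair.from_raw(sim.x, sim.y)
    score = antagonism_pvalue(pair, n_permutations=500, rng=np.random.default_rng(11))
    assert score.pvalue <= 0.05


@pytest.mark.parametrize("null_kind", ["gaussian", "self_permutation"])
def test_pvalues_uniform_under_the_null(null_kind):
    """Fraction of p <= 0.05 stays near 0.05 when x and y are unrelated."""
    pvals = []
    for r in range(400):
        g = np.random.default_rng([41, r])
        x = g.normal(size=40)
        y = g.permutation(x) if null_kind == "self_permutation" else g.normal(size=40)
        pair = StandardizedPair.from_raw(x, y)
        pvals.append(antagonism_pvalue(pair, n_permutations=200, rng=g).pvalue)
    frac = np.mean(np.asarray(pvals) <= 0.05)
    assert 0.02 <= frac <= 0.08


# ------------------------------------------------------------------- scan


def test_scan_scores_every_pair(planted_set):
    scores = scan_all_pairs(planted_set, n_permutations=50, rng=0)
    assert len(scores) == 3 * 4
    assert all(s.qvalue is not None for s in scores)


def test_scan_recovers_planted_pair():
    expr = make_planted_set(n_mirna=5, n_gene=5, n_samples=60, seed=2)
    scores = scan_all_pairs(expr, n_permutations=500, rng=7)
    best = min(scores, key=lambda s: (s.pvalue, -abs(s.coefficient)))
    assert (best.mirna_id, best.gene_id) == ("mir0", "g0")


def test_scan_parallel_matches_serial(planted_set):
    serial = scan_all_pairs(planted_set, n_permutations=50, rng=3, n_jobs=1)
    parallel = scan_all_pairs(planted_set, n_permutations=50, rng=3, n_jobs=2)
    assert [s.pvalue for s in serial] == [s.pvalue for s in parallel]


def test_scan_rejects_empty_matrix(planted_set):
    import pandas as pd
    from mirantag.io import PairedExpressionSet

    empty = planted_set.mrna_matrix.iloc[:0]
    with pytest.raises(SchemaError):
        scan_all_pairs(
            PairedExpressionSet(planted_set.mirna_matrix, empty), n_permutations=10, rng=0
        )
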