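"""Reproducibility correlation, paired t, sign-flip permutation machinery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster

from cytopanel.stats import (
    control_correlation,
    enumerate_sign_flips,
    paired_t,
    permutation_analysis,
    permutation_null,
    permutation_pvalue,
    value_to_beat,
    wilcoxon_min_p,
)


# -- control correlation -----------------------------------------------------


def test_duplicate_and_negated_vectors():
    v = [10.0, 20.0, 5.0, 40.0]
    cc = control_correlation({"a": v, "b": v, "c": [-x for x in v]})
    assert cc.R.loc["a", "b"] == pytest.approx(1.0)
    assert cc.R.loc["a", "c"] == pytest.approx(-1.0)


def test_correlation_matrix_is_symmetric_psd():
    rng = np.random.default_rng(6)
    vectors = {f"r{i}": rng.random(12) for i in range(8)}
    cc = control_correlation(vectors)
    R = cc.R.values
    assert np.allclose(R, R.T)
    assert np.allclose(np.diag(R), 1.0)
    assert np.abs(R).max() <= 1 + 1e-12
    assert np.linalg.eigvalsh(R).min() > -1e-10


def test_two_donor_groups_recovered_by_clustering():
    """Complete linkage on distances between correlation rows separates two
    synthetic donor groups with high within- and low between-correlation."""
    rng = np.random.default_rng(7)
    base1, base2 = rng.random(20) * 50, rng.random(20) * 50
    vectors = {}
    for i in range(3):
        vectors[f"g1_{i}"] = base1 + rng.normal(0, 0.5, 20)
        vectors[f"g2_{i}"] = base2 + rng.normal(0, 0.5, 20)
    cc = control_correlation(vectors)
    labels = fcluster(cc.linkage_matrix, 2, criterion="maxclust")
    groups = {run[:2] for run in cc.runs}
    by_group = {g: {labels[i] for i, r in enumerate(cc.runs) if r.startswith(g)}
                for g in groups}
    assert all(len(s) == 1 for s in by_group.values())
    assert by_group["g1"] != by_group["g2"]


def test_zero_variance_run_flagged():
    cc = control_correlation({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0],
                              "c": [3.0, 1.0, 2.0]})
    assert cc.zero_variance_runs == ["b"]
    assert np.isnan(cc.R.loc["a", "b"])
    assert cc.R.loc["a", "c"] == cc.R.loc["c", "a"]


def test_single_run_rejected():
    with pytest.raises(ValueError):
        control_correlation({"a": [1.0, 2.0]})


# -- paired t ----------------------------------------------------------------


def test_paired_t_against_t_distribution_oracle():
    """Differences (1, 2, 3): t = 2*sqrt(3) = 3.4641, p = 2*SF_t2(t)."""
    control = np.array([10.0, 20.0, 30.0])
    treated = control + np.array([1.0, 2.0, 3.0])
    res = paired_t(treated, control)
    assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-4)
    assert res.p == pytest.approx(2 * sps.t.sf(2 * np.sqrt(3), df=2), abs=1e-9)
    assert res.p == pytest.approx(0.0742, abs=5e-4)


def test_paired_t_zero_variance_degenerate():
    res = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
    assert res.degenerate and res.p == 1.0


def test_paired_t_label_swap_negates_t():
    rng = np.random.default_rng(8)
    a, b = rng.random(5), rng.random(5)
    r1, r2 = paired_t(a, b), paired_t(b, a)
    assert r1.t == pytest.approx(-r2.t)
    assert r1.p == pytest.approx(r2.p)


def test_paired_t_input_validation():
    with pytest.raises(ValueError):
        paired_t([1.0], [2.0, 3.0])
    with pytest.raises(ValueError):
        paired_t([1.0], [2.0])


# -- sign flips --------------------------------------------------------------


@pytest.mark.parametrize("n, expected", [(1, 0), (2, 1), (3, 3), (4, 7), (5, 15)])
def test_flip_counts(n, expected):
    assert len(enumerate_sign_flips(n)) == expected == 2 ** (n - 1) - 1


def test_flips_pairwise_nonequivalent_under_negation():
    flips = enumerate_sign_flips(4)
    seen = set()
    for v in flips:
        key = tuple(v)
        assert key not in seen and tuple(-v) not in seen
        seen.add(key)


def test_flips_plus_identity_and_negations_cover_all_sign_vectors():
    n = 4
    flips = enumerate_sign_flips(n)
    everything = {tuple(v) for v in flips}
    everything |= {tuple(-v) for v in flips}
    everything |= {(1,) * n, (-1,) * n}
    assert everything == set(itertools.product((1, -1), repeat=n))


# -- permutation null --------------------------------------------------------


def _make_tests(rng, n_endpoints, n_donors=3, treatment="drug", effect=0.0):
    donors = [f"D{i}" for i in range(1, n_donors + 1)]
    shared = rng.normal(0, 1, n_donors)  # induces endpoint correlation
    tests = {}
    for e in range(n_endpoints):
        noise = rng.normal(0, 0.5, n_donors)
        control = {d: 10.0 + shared[i] + noise[i] for i, d in enumerate(donors)}
        treated = {
            d: control[d] + effect + rng.normal(0, 0.5) for d in donors
        }
        tests[(treatment, f"ep{e}")] = (treated, control)
    return tests


def test_pooled_size_is_three_per_test_at_three_donors():
    rng = np.random.default_rng(9)
    tests = _make_tests(rng, n_endpoints=7)
    results, pooled = permutation_analysis(tests)
    assert len(pooled) == 3 * 7
    assert all(len(r.permuted_ps) == 3 for r in results)
    assert all(r.included for r in results)


def test_tests_below_three_pairs_are_excluded():
    rng = np.random.default_rng(10)
    tests = _make_tests(rng, n_endpoints=2)
    treated, control = tests[("drug", "ep0")]
    treated = dict(treated)
    treated["D3"] = np.nan  # only 2 complete pairs remain
    tests[("drug", "ep0")] = (treated, control)
    results, pooled = permutation_analysis(tests)
    by_ep = {r.endpoint: r for r in results}
    assert not by_ep["ep0"].included
    assert np.isnan(by_ep["ep0"].perm_p)
    assert len(pooled) == 3  # only ep1 contributes


def test_flips_are_joint_across_endpoints():
    """Two perfectly correlated endpoints get identical permuted p-values."""
    rng = np.random.default_rng(11)
    donors = ["D1", "D2", "D3"]
    control = {d: float(i) for i, d in enumerate(donors)}
    treated = {d: control[d] + rng.normal(1.0, 0.3) for d in donors}
    tests = {
        ("t", "a"): (treated, control),
        ("t", "b"): ({d: 2 * v for d, v in treated.items()},
                     {d: 2 * v for d, v in control.items()}),
    }
    results, _ = permutation_analysis(tests)
    a, b = (r for r in results if r.endpoint in ("a", "b"))
    assert np.allclose(sorted(a.permuted_ps), sorted(b.permuted_ps))


def test_real_p_rank_uniform_under_global_null():
    """Under the null the real p is exchangeable with its 3 permuted ones:
    its rank is uniform over 4 positions across simulated cohorts."""
    rng = np.random.default_rng(12)
    ranks = np.zeros(4)
    for _ in range(400):
        tests = _make_tests(rng, n_endpoints=1)
        results, _ = permutation_analysis(tests)
        r = results[0]
        ranks[int(sum(p < r.real_p for p in r.permuted_ps))] += 1
    chi2 = ((ranks - 100.0) ** 2 / 100.0).sum()
    assert chi2 < sps.chi2.ppf(0.999, df=3)


def test_permutation_null_empty_rejected():
    with pytest.raises(ValueError):
        permutation_null({})


# -- pooled permutation p-value ----------------------------------------------


def test_permutation_pvalue_formula_cases():
    assert permutation_pvalue(0.01, [0.3, 0.6, 0.9]) == pytest.approx(0.25)
    assert permutation_pvalue(0.95, [0.3, 0.6, 0.9]) == pytest.approx(1.0)


def test_permutation_pvalue_brute_force_counting():
    rng = np.random.default_rng(13)
    pooled = rng.random(1000)
    for real_p in rng.random(100):
        b = sum(1 for q in pooled if q < real_p)
        assert permutation_pvalue(real_p, pooled) == pytest.approx((b + 1) / 1001)
        b_le = sum(1 for q in pooled if q <= real_p)
        assert permutation_pvalue(real_p, pooled, strict=False) == pytest.approx(
            (b_le + 1) / 1001
        )


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(0, 1), st.floats(0, 1), st.integers(0, 2**31 - 1))
def test_perm_p_monotone_and_bounded(p1, p2, seed):
    pooled = np.random.default_rng(seed).random(50)
    lo, hi = sorted((p1, p2))
    assert permutation_pvalue(lo, pooled) <= permutation_pvalue(hi, pooled)
    assert permutation_pvalue(lo, pooled) >= 1 / 51


# -- value to beat -----------------------------------------------------------


def test_value_to_beat_unattainable_at_m3():
    assert value_to_beat([0.2, 0.5, 0.8], alpha=0.05) is None


def test_value_to_beat_m99_is_fourth_smallest():
    rng = np.random.default_rng(14)
    pooled = rng.random(99)
    assert value_to_beat(pooled, 0.05) == pytest.approx(np.sort(pooled)[3])


def test_value_to_beat_exhaustive_scan_property():
    """Every real p strictly below the threshold attains perm_p < alpha and
    no real p at/above it does (scanned on random pooled lists)."""
    rng = np.random.default_rng(15)
    for m in (39, 99, 500):
        pooled = rng.random(m)
        alpha = 0.05
        v = value_to_beat(pooled, alpha)
        probes = np.concatenate([pooled, rng.random(50), [v - 1e-12, v + 1e-12]])
        for p in probes:
            perm = permutation_pvalue(p, pooled)
            if p < v:
                assert perm < alpha
            elif p > v:
                assert perm >= alpha
            # p == v: a tie with a pooled value, resolved by the counting
            # convention (significant under strict counting)


# -- Wilcoxon floor ----------------------------------------------------------


@pytest.mark.parametrize("n, expected", [(1, 1.0), (3, 0.25), (5, 0.0625)])
def test_wilcoxon_min_p_known_values(n, expected):
    assert wilcoxon_min_p(n) == pytest.approx(expected)


@pytest.mark.parametrize("n", [3, 5, 8])
def test_wilcoxon_min_p_matches_scipy_exact(n):
    """The most extreme sample (all shifts positive) attains the floor."""
    data = np.arange(1, n + 1, dtype=float)
    res = sps.wilcoxon(data, mode="exact")
    assert wilcoxon_min_p(n) == pytest.approx(res.pvalue)


def test_wilcoxon_min_p_range_checked():
    with pytest.raises(ValueError):
        wilcoxon_min_p(0)
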