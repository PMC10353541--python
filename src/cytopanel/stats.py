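"""Statistics for small paired donor cohorts.

Three layers, matching how a qualification study is analyzed:

1. **Reproducibility** — Pearson correlation of gate-percentage vectors
   across negative-control runs, clustered by complete-linkage on the
   Euclidean distances between rows of the correlation matrix.
2. **Paired t-tests** — each treatment vs its reference condition on
   donor-paired, replicate-averaged endpoint values.
3. **Exhaustive sign-flip permutation correction** — with N donors there
   are only 2^(N-1) - 1 unique treated/control label swaps (a global
   swap gives the same two-sided t), so the full null is enumerable. The
   same flip vector is applied jointly to every endpoint of a treatment,
   preserving the correlation structure between endpoints. All permuted
   p-values are pooled into one null distribution and each real p is
   scored as (b + 1) / (m + 1), b = permuted p-values below it. Standard
   multiplicity corrections assume independent tests; gate percentages
   are strongly dependent (one population's percentage moves several
   others), which is why this design is used instead.

Tests with fewer than 3 complete donor pairs are excluded.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

MIN_COMPLETE_PAIRS = 3


# --------------------------------------------------------------------------
# reproducibility of negative controls
# --------------------------------------------------------------------------


@dataclass
class ControlCorrelation:
    """Pearson R over control runs plus a complete-linkage dendrogram."""

    runs: list[str]
    R: pd.DataFrame
    linkage_matrix: np.ndarray | None
    zero_variance_runs: list[str] = field(default_factory=list)


def control_correlation(control_vectors: Mapping[str, Sequence[float]]) -> ControlCorrelation:
    """Correlate gate-percentage vectors across negative-control runs.

    Runs with zero variance have undefined correlations; they are kept
    in the matrix as NaN rows/columns and reported in
    ``zero_variance_runs`` rather than silently dropped.
    """
    runs = list(control_vectors)
    if len(runs) < 2:
        raise ValueError("need at least 2 control runs")
    X = np.asarray([np.asarray(control_vectors[r], float) for r in runs])
    if len({x.size for x in X}) != 1:
        raise ValueError("control vectors must have equal length")
    sd = X.std(axis=1)
    zero_var = [r for r, s in zip(runs, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    for r in zero_var:
        i = runs.index(r)
        R[i, :] = np.nan
        R[:, i] = np.nan
        R[i, i] = 1.0
    Rdf = pd.DataFrame(R, index=runs, columns=runs)
    ok = [i for i, r in enumerate(runs) if r not in zero_var]
    lm = None
    if len(ok) >= 2:
        lm = linkage(pdist(R[np.ix_(ok, ok)], metric="euclidean"), method="complete")
    return ControlCorrelation(runs, Rdf, lm, zero_var)


# --------------------------------------------------------------------------
# paired t
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    n: int
    degenerate: bool = False  # zero variance of the paired differences


def paired_t(treated: Sequence[float], control: Sequence[float]) -> TTestResult:
    """Classical paired t on donor-wise differences, two-sided.

    A zero-variance difference vector is degenerate: the result carries
    p = 1 and the flag set (so degenerate permuted statistics stay in
    the pooled null conservatively instead of shrinking it).
    """
    treated = np.asarray(treated, float)
    control = np.asarray(control, float)
    if treated.size != control.size:
        raise ValueError("treated and control must pair the same donors")
    d = treated - control
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        return TTestResult(float("nan"), 1.0, n, degenerate=True)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TTestResult(float(t), float(p), n)


# --------------------------------------------------------------------------
# exhaustive sign-flip machinery
# --------------------------------------------------------------------------


def enumerate_sign_flips(n_donors: int) -> list[np.ndarray]:
    """All unique treated/control label swaps for n paired donors.

    Sign vectors in {+1, -1}^n, collapsed under global negation (a full
    swap reproduces the same two-sided t) and excluding the identity:
    2^(n-1) - 1 vectors, each with the first entry fixed at +1.
    """
    if n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    flips = []
    for tail in itertools.product((1, -1), repeat=n_donors - 1):
        v = np.array((1,) + tail, dtype=int)
        if (v == 1).all():
            continue  # identity
        flips.append(v)
    return flips


@dataclass
class PermutationResult:
    """Permutation outcome for one (treatment, endpoint) paired t-test."""

    treatment: str
    endpoint: str
    n_pairs: int
    included: bool
    real_t: float = float("nan")
    real_p: float = float("nan")
    permuted_ps: list[float] = field(default_factory=list)
    n_below: int = 0  # own permuted p-values strictly below real_p
    perm_p: float = float("nan")  # pooled permutation p-value


def permutation_null(
    endpoint_tests: Mapping[tuple[str, str], tuple[Mapping[str, float], Mapping[str, float]]],
) -> list[float]:
    """Pooled permuted p-values for a collection of paired tests.

    See :func:`permutation_analysis`; this returns only the pooled null.
    """
    results, pooled = permutation_analysis(endpoint_tests)
    return pooled


def permutation_analysis(
    endpoint_tests: Mapping[tuple[str, str], tuple[Mapping[str, float], Mapping[str, float]]],
    strict: bool = True,
) -> tuple[list[PermutationResult], list[float]]:
    """Exhaustive sign-flip permutation analysis over many paired tests.

    ``endpoint_tests`` maps (treatment, endpoint) to a pair of
    donor-keyed value mappings (treated, control). For each treatment the
    unique sign flips over its donors are enumerated once, and each flip
    is applied jointly to every endpoint of that treatment so the
    dependence between endpoints survives into the null. The permuted
    p-values of every included test are pooled; each real p is scored
    against that pooled null as (b + 1) / (m + 1).

    Tests with fewer than 3 complete donor pairs are excluded: they
    contribute nothing to the pool and carry no permutation p-value.
    """
    if not endpoint_tests:
        raise ValueError("empty test collection")
    results: list[PermutationResult] = []
    pooled: list[float] = []

    by_treatment: dict[str, list[tuple[str, Mapping, Mapping]]] = {}
    for (treatment, endpoint), (treated, control) in endpoint_tests.items():
        by_treatment.setdefault(treatment, []).append((endpoint, treated, control))

    for treatment, tests in by_treatment.items():
        donor_sets = []
        prepared = []
        for endpoint, treated, control in tests:
            donors = sorted(
                d
                for d in set(treated) & set(control)
                if np.isfinite(treated[d]) and np.isfinite(control[d])
            )
            diffs = np.array([treated[d] - control[d] for d in donors])
            prepared.append((endpoint, donors, diffs))
            donor_sets.append(donors)
        all_donors = sorted(set().union(*donor_sets))
        flips = enumerate_sign_flips(len(all_donors))
        donor_pos = {d: i for i, d in enumerate(all_donors)}

        for endpoint, donors, diffs in prepared:
            n = len(donors)
            if n < MIN_COMPLETE_PAIRS:
                results.append(PermutationResult(treatment, endpoint, n, included=False))
                continue
            real = _t_pvalue(diffs)
            permuted = []
            for flip in flips:
                signs = np.array([flip[donor_pos[d]] for d in donors])
                if (signs == 1).all() or (signs == -1).all():
                    # flip restricted to this endpoint's donors collapses
                    # onto the identity class; skip to keep permutations
                    # unique for the test
                    continue
                permuted.append(_t_pvalue(diffs * signs)[1])
            res = PermutationResult(
                treatment,
                endpoint,
                n,
                included=True,
                real_t=real[0],
                real_p=real[1],
                permuted_ps=permuted,
                n_below=int(sum(p < real[1] for p in permuted)),
            )
            results.append(res)
            pooled.extend(permuted)

    for res in results:
        if res.included:
            res.perm_p = permutation_pvalue(res.real_p, pooled, strict=strict)
    return results, pooled


def _t_pvalue(diffs: np.ndarray) -> tuple[float, float]:
    n = diffs.size
    sd = diffs.std(ddof=1)
    if sd == 0:
        return float("nan"), 1.0  # degenerate: conservative, retained
    t = diffs.mean() / (sd / math.sqrt(n))
    return float(t), float(2.0 * sps.t.sf(abs(t), df=n - 1))


def permutation_pvalue(real_p: float, pooled: Sequence[float], strict: bool = True) -> float:
    """Pooled permutation p-value: (b + 1) / (m + 1).

    ``b`` counts pooled permuted p-values below the real one — strictly
    below by default; ``strict=False`` switches to at-or-below counting
    (the more conservative convention of the permutation-p literature).
    """
    pooled = np.asarray(pooled, float)
    if pooled.size == 0:
        raise ValueError("pooled permuted p-value list is empty")
    b = int((pooled < real_p).sum()) if strict else int((pooled <= real_p).sum())
    return (b + 1) / (pooled.size + 1)


def value_to_beat(pooled: Sequence[float], alpha: float = 0.05) -> float | None:
    """Largest real-p threshold that still attains perm_p < alpha.

    Returns v such that every real p strictly below v satisfies
    (b + 1)/(m + 1) < alpha; ``None`` when even b = 0 cannot reach alpha
    (e.g. m = 3 and alpha = 0.05: the smallest possible perm_p is 0.25).
    """
    pooled = np.asarray(pooled, float)
    if pooled.size == 0:
        raise ValueError("pooled permuted p-value list is empty")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    m = pooled.size
    b_max = -1
    while b_max + 1 < m and (b_max + 2) / (m + 1) < alpha:
        b_max += 1
    if b_max < 0:
        return None
    return float(np.sort(pooled)[b_max])


def wilcoxon_min_p(n: int) -> float:
    """Minimum attainable two-sided exact signed-rank p-value for n pairs.

    Computed by enumerating the exact null distribution of the positive
    rank sum over all 2^n sign assignments. Equals 2 / 2^n — e.g. 0.25 at
    n = 3, which is why a rank test cannot reach conventional
    significance in a three-donor design.
    """
    if not 1 <= n <= 20:
        raise ValueError("n must be in [1, 20]")
    # distribution of W+ = sum of ranks with positive sign
    counts = np.zeros(n * (n + 1) // 2 + 1)
    counts[0] = 1.0
    for rank in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[rank:] = counts[: counts.size - rank]
        counts = counts + shifted
    total = counts.sum()  # 2^n
    cdf = np.cumsum(counts)
    sf = total - np.concatenate(([0.0], cdf[:-1]))  # P(W >= w)
    best = 1.0
    for w in range(counts.size):
        if counts[w] == 0:
            continue
        p = 2.0 * min(cdf[w], sf[w]) / total
        best = min(best, min(p, 1.0))
    return float(best)
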