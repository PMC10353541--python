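"""Spillover estimation, compensation, titration, interference screen."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from cytopanel.controls import (
    SpilloverMatrix,
    TitrationCurve,
    compensate,
    estimate_spillover,
    interference_screen,
    robust_sd,
    select_optimal_dilution,
    stain_index,
)
from cytopanel.synthetic import (
    SampleMetadata,
    apply_spillover,
    simulate_sample,
    simulate_single_stains,
    simulate_unstained,
)


def _planted_spillover(detectors, rng=None):
    """A diagonally dominant spillover matrix with a known 0.15 entry."""
    S = np.eye(len(detectors))
    rng = rng or np.random.default_rng(42)
    mask = rng.random(S.shape) < 0.25
    S[mask] = rng.uniform(0.02, 0.12, mask.sum())
    np.fill_diagonal(S, 1.0)
    S[0, 1] = 0.15
    return SpilloverMatrix(list(detectors), S)


# -- estimation --------------------------------------------------------------


def test_clean_single_stains_give_identity(spec1, panel1):
    ss = simulate_single_stains(spec1, n_events=4000)
    uns = simulate_unstained(replace(spec1, n_events=4000))
    est = estimate_spillover(ss, uns)
    assert np.allclose(est.matrix, np.eye(len(panel1.detectors)), atol=0.01)


def test_planted_coefficient_recovered(spec1, panel1):
    sm = _planted_spillover(panel1.detectors)
    spec = replace(spec1, spillover=sm, n_events=10_000)
    ss = simulate_single_stains(spec, n_events=10_000)
    uns = simulate_unstained(spec)
    est = estimate_spillover(ss, uns)
    assert abs(est.matrix[0, 1] - 0.15) < 0.01
    assert np.max(np.abs(est.matrix - sm.matrix)) < 0.02


def test_estimation_error_shrinks_with_event_count(spec1, panel1):
    sm = _planted_spillover(panel1.detectors)
    spec = replace(spec1, spillover=sm)
    uns = simulate_unstained(replace(spec, n_events=20_000))
    errs = []
    for n in (1_000, 50_000):
        est = estimate_spillover(simulate_single_stains(spec, n_events=n), uns)
        errs.append(np.max(np.abs(est.matrix - sm.matrix)))
    assert errs[1] < errs[0]


def test_detector_relabeling_invariance(spec1, panel1):
    sm = _planted_spillover(panel1.detectors)
    spec = replace(spec1, spillover=sm)
    ss = simulate_single_stains(spec, n_events=5_000)
    uns = simulate_unstained(replace(spec, n_events=5_000))
    est = estimate_spillover(ss, uns)
    perm = list(reversed(panel1.detectors))
    uns_perm = uns.copy()
    uns_perm.fluorescence = uns.fluorescence[perm]
    est_perm = estimate_spillover(ss, uns_perm)
    assert np.allclose(est_perm.reorder(panel1.detectors).matrix, est.matrix)


def test_unseparable_single_stain_names_channel(spec1, panel1):
    ss = simulate_single_stains(spec1, n_events=4000)
    uns = simulate_unstained(replace(spec1, n_events=4000))
    det = panel1.detectors[2]
    broken = ss[det].copy()
    broken.fluorescence[det] = uns.fluorescence[det].values[: broken.n_events]
    ss[det] = broken
    with pytest.raises(ValueError, match=det):
        estimate_spillover(ss, uns)


# -- compensation ------------------------------------------------------------


def test_identity_compensation_is_noop(unstim_pair1, panel1):
    full, _ = unstim_pair1
    out = compensate(full, SpilloverMatrix.identity(panel1.detectors))
    assert np.allclose(out.fluorescence.values, full.fluorescence.values)


def test_two_channel_linear_system_oracle():
    """Compensation of one event equals the hand-solved 2x2 system."""
    from cytopanel.synthetic import EventMatrix

    S = np.array([[1.0, 0.1], [0.05, 1.0]])
    observed = np.array([110.0, 25.0])
    # independent oracle: Cramer's rule on true @ S = observed
    det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
    true_f = (observed[0] * S[1, 1] - observed[1] * S[1, 0]) / det
    true_p = (observed[1] * S[0, 0] - observed[0] * S[0, 1]) / det
    em = EventMatrix(
        SampleMetadata("D1", "Unstimulated", "fully-stained", 1, 1),
        pd.DataFrame({"FSC-A": [1.0], "FSC-H": [1.0], "SSC-A": [1.0]}),
        pd.DataFrame({"FITC": [observed[0]], "PE": [observed[1]]}),
    )
    out = compensate(em, SpilloverMatrix(["FITC", "PE"], S))
    assert out.fluorescence.loc[0, "FITC"] == pytest.approx(true_f)
    assert out.fluorescence.loc[0, "PE"] == pytest.approx(true_p)


def test_spillover_compensation_round_trip(unstim_pair1, panel1):
    full, _ = unstim_pair1
    sm = _planted_spillover(panel1.detectors)
    back = compensate(apply_spillover(full, sm), sm)
    rel = np.abs(back.fluorescence.values - full.fluorescence.values) / np.maximum(
        np.abs(full.fluorescence.values), 1e-9
    )
    assert rel.max() < 1e-6


def test_compensation_is_linear(unstim_pair1, panel1):
    full, iso = unstim_pair1
    sm = _planted_spillover(panel1.detectors)
    a, b = 2.0, 3.0
    combo = full.copy()
    combo.fluorescence = a * full.fluorescence + b * iso.fluorescence
    lhs = compensate(combo, sm).fluorescence.values
    rhs = (
        a * compensate(full, sm).fluorescence.values
        + b * compensate(iso, sm).fluorescence.values
    )
    assert np.allclose(lhs, rhs)


def test_singular_matrix_rejected(unstim_pair1, panel1):
    full, _ = unstim_pair1
    n = len(panel1.detectors)
    S = np.ones((n, n))
    np.fill_diagonal(S, 1.0)
    with pytest.raises(np.linalg.LinAlgError):
        compensate(full, SpilloverMatrix(panel1.detectors, S))


def test_spillover_csv_round_trip(tmp_path, panel1):
    sm = _planted_spillover(panel1.detectors)
    path = tmp_path / "spill.csv"
    sm.to_csv(path)
    loaded = SpilloverMatrix.from_csv(path)
    assert loaded.detectors == sm.detectors
    assert np.allclose(loaded.matrix, sm.matrix)


# -- stain index / titration -------------------------------------------------


def test_stain_index_of_identical_samples_is_zero():
    rng = np.random.default_rng(0)
    neg = rng.lognormal(np.log(100), 0.5, 5000)
    assert stain_index(neg, neg) == pytest.approx(0.0)


def test_stain_index_constructed_value():
    """Negative median 100 / robust-SD 10 and positive median 1100 score 50."""
    rng = np.random.default_rng(1)
    neg = 100.0 + 10.0 * rng.standard_normal(20_000)  # robust-SD ~ 10
    pos = 1100.0 + rng.standard_normal(20_000)
    stained = np.concatenate([neg, pos])
    si = stain_index(stained, neg)
    expected = (np.median(pos) - np.median(neg)) / (2 * robust_sd(neg))
    assert si == pytest.approx(expected, rel=1e-2)
    assert si == pytest.approx(50.0, rel=0.05)


def test_stain_index_scale_invariance():
    rng = np.random.default_rng(2)
    neg = rng.lognormal(np.log(100), 0.4, 5000)
    pos = rng.lognormal(np.log(5000), 0.4, 5000)
    stained = np.concatenate([neg, pos])
    si1 = stain_index(stained, neg)
    si2 = stain_index(7.0 * stained, 7.0 * neg)
    assert si2 == pytest.approx(si1, rel=1e-9)


def test_stain_index_zero_spread_flagged():
    with pytest.warns(UserWarning, match="robust-SD"):
        assert np.isnan(stain_index(np.arange(10.0), np.ones(10)))


@pytest.mark.parametrize(
    "indices, expected",
    [
        ([30, 50, 45, 20, 5, 1], 5),
        ([30, 50, 50, 20, 5, 1], 25),  # tie between Dil 5 and Dil 25 -> 25
        ([30, 20, 10, 5, 2, 1], 1),  # monotone decreasing -> stock
    ],
)
def test_select_optimal_dilution(indices, expected):
    curve = TitrationCurve("CD3-BV570", [1, 5, 25, 125, 625, 3125], indices)
    assert select_optimal_dilution(curve) == expected
    assert curve.optimal_dilution == expected


def test_titration_curve_requires_increasing_dilutions():
    with pytest.raises(ValueError):
        TitrationCurve("x", [1, 5, 5], [1, 2, 3])
    with pytest.raises(ValueError):
        select_optimal_dilution(TitrationCurve("x", [1, 5], [np.nan, np.nan]))


# -- interference screen -----------------------------------------------------


def test_identical_samples_not_flagged(unstim_pair1):
    uns = unstim_pair1[1]
    report = interference_screen(uns, uns)
    assert np.allclose(report.scores, 0.0)
    assert not report.flags.any()


def test_single_channel_shift_flags_only_that_channel(spec1):
    uns = simulate_unstained(spec1)
    target = "CD4-PE"
    rsd = robust_sd(uns.fluorescence[target].values)
    treated = uns.copy()
    treated.fluorescence[target] = treated.fluorescence[target] + 5.0 * rsd
    report = interference_screen(treated, uns)
    assert report.flagged_detectors() == [target]
    idx = report.detectors.index(target)
    assert report.scores[idx] == pytest.approx(5.0, abs=0.2)


def test_score_equivariance_under_common_offset(spec1):
    uns = simulate_unstained(spec1)
    treated = uns.copy()
    treated.fluorescence["CD4-PE"] = treated.fluorescence["CD4-PE"] + 500.0
    r1 = interference_screen(treated, uns)
    shift_t = treated.copy()
    shift_u = uns.copy()
    shift_t.fluorescence = shift_t.fluorescence + 250.0
    shift_u.fluorescence = shift_u.fluorescence + 250.0
    r2 = interference_screen(shift_t, shift_u)
    assert np.allclose(r1.scores, r2.scores)


def test_flags_vanish_along_dilution_series(spec1):
    """An intrinsically fluorescent drug stops interfering once diluted."""
    from cytopanel.synthetic import serial_dilution_factors, simulate_interfering_drug

    uns = simulate_unstained(spec1)
    gains = {"CD4-PE": 50.0, "CD8a-FITC": 30.0, "CD19-PE-Cy7": 20.0}
    n_flagged = []
    for dil in serial_dilution_factors(10, 4):
        treated = simulate_interfering_drug(uns, gains, 10.0 / dil, seed=9)
        n_flagged.append(len(interference_screen(treated, uns).flagged_detectors()))
    assert all(a >= b for a, b in zip(n_flagged, n_flagged[1:]))
    assert n_flagged[0] >= 1
    assert n_flagged[-1] == 0
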