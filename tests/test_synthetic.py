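"""Generating process of the synthetic PBMC cohorts."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from cytopanel.controls import SpilloverMatrix
from cytopanel.synthetic import (
    SampleMetadata,
    SyntheticSpec,
    TruthPopulation,
    apply_spillover,
    default_spec,
    final_concentration,
    serial_dilution_factors,
    simulate_cohort,
    simulate_interfering_drug,
    simulate_sample,
    truth_activation_fractions,
    validate_spec,
)


def test_same_seed_is_bit_identical(spec1):
    md = SampleMetadata("D2", "LPS/PHA-M", "fully-stained", 1, 1)
    a = simulate_sample(spec1, md)
    b = simulate_sample(spec1, md)
    assert a.scatter.equals(b.scatter)
    assert a.fluorescence.equals(b.fluorescence)
    assert a.truth.equals(b.truth)


def test_population_counts_match_multinomial_expectation():
    """Truth-label counts stay within 3 binomial SDs of their expectation."""
    fracs = {"T": 0.6, "B": 0.1, "NK": 0.1, "mono": 0.2}
    pops = [
        TruthPopulation(name, f, "monocyte" if name == "mono" else "lymphocyte",
                        {"CD45": "pos"})
        for name, f in fracs.items()
    ]
    spec = default_spec(1, n_events=100_000, seed=5)
    spec = replace(spec, populations=pops, donor_effect_sd=0.0,
                   debris_fraction=0.0, doublet_fraction=0.0)
    s = simulate_sample(spec, SampleMetadata("D1", "Unstimulated", "fully-stained", 1, 1))
    counts = s.truth["population"].value_counts()
    n = spec.n_events
    for name, f in fracs.items():
        sd = np.sqrt(n * f * (1 - f))
        assert abs(counts[name] - n * f) < 3 * sd, name


def test_dead_fraction_matches_viability_signal(spec1, panel1):
    """A 3:1 live:dead mixture shows ~25% viability-dye-high singlets."""
    s = simulate_sample(spec1, SampleMetadata("D1", "Unstimulated", "fully-stained", 1, 1))
    singlet = ~s.truth["population"].isin(["debris", "doublet"])
    dye = s.fluorescence[panel1.viability_detector][singlet.values]
    high = (dye > 2000).mean()
    assert abs(high - 0.25) < 0.01
    assert abs(s.truth.loc[singlet, "is_dead"].mean() - 0.25) < 0.01


def test_event_conservation(spec1):
    """debris + doublets + singlets account for exactly n_events."""
    s = simulate_sample(spec1, SampleMetadata("D1", "Unstimulated", "fully-stained", 1, 1))
    vc = s.truth["population"].value_counts()
    n_debris = vc.get("debris", 0)
    n_doublet = vc.get("doublet", 0)
    assert s.n_events == spec1.n_events
    assert n_debris == round(spec1.n_events * spec1.debris_fraction)
    assert n_doublet == round(spec1.n_events * spec1.doublet_fraction)


def test_isotype_shares_cell_draw_and_has_background_markers(unstim_pair1, panel1):
    full, iso = unstim_pair1
    # same underlying cells: identical scatter, truth and viability signal
    assert full.scatter.equals(iso.scatter)
    assert full.truth.equals(iso.truth)
    viab = panel1.viability_detector
    cells = ~full.truth["population"].isin(["debris"]).values
    assert np.allclose(
        full.fluorescence[viab].values[cells], iso.fluorescence[viab].values[cells]
    )
    # marker channels carry only background: medians near the background
    # median regardless of the cells' true marker states
    b_mask = (full.truth["population"] == "B cells").values
    cd19 = panel1.detector_for_marker("CD19")
    assert np.median(full.fluorescence[cd19].values[b_mask]) > 1000
    assert np.median(iso.fluorescence[cd19].values[b_mask]) < 300


def test_cohort_layout(spec1):
    small = replace(spec1, n_events=500)
    cohort = simulate_cohort(small, 2, ["Unstimulated", "LPS/PHA-M"], 2)
    assert len(cohort) == 2 * 2 * 2 * 2  # donors x conditions x reps x stains
    ids = [s.metadata.sample_id for s in cohort]
    assert len(set(ids)) == len(ids)


def test_activation_effect_raises_true_positive_fraction(spec1):
    base = truth_activation_fractions(spec1, "Unstimulated")
    act = truth_activation_fractions(spec1, "PMA/Ionomycin")
    for pop in ("B cells", "CD4 T conv"):
        for marker in ("CD25", "CD154"):
            assert act[pop][marker] > base[pop][marker]
    md_u = SampleMetadata("D1", "Unstimulated", "fully-stained", 1, 1)
    md_a = SampleMetadata("D1", "PMA/Ionomycin", "fully-stained", 1, 1)
    s_u = simulate_sample(spec1, md_u)
    s_a = simulate_sample(spec1, md_a)
    for s, expect in ((s_u, base), (s_a, act)):
        m = (s.truth["population"] == "CD4 T conv").values
        observed = s.truth.loc[m, "act_CD25"].mean()
        assert abs(observed - expect["CD4 T conv"]["CD25"]) < 0.03


@pytest.mark.parametrize(
    "field, value, fragment",
    [
        ("n_events", 0, "n_events"),
        ("dead_fraction", 1.5, "dead_fraction"),
        ("donor_effect_sd", -1.0, "donor_effect_sd"),
    ],
)
def test_invalid_spec_is_rejected_naming_the_field(spec1, field, value, fragment):
    with pytest.raises(ValueError, match=fragment):
        validate_spec(replace(spec1, **{field: value}))


def test_fraction_sum_rejected(spec1):
    pops = [TruthPopulation("a", 0.7), TruthPopulation("b", 0.7)]
    with pytest.raises(ValueError, match="population_fractions"):
        validate_spec(replace(spec1, populations=pops))


# -- spillover forward model ------------------------------------------------


def test_apply_spillover_identity(unstim_pair1, panel1):
    full, _ = unstim_pair1
    out = apply_spillover(full, SpilloverMatrix.identity(panel1.detectors))
    assert np.allclose(out.fluorescence.values, full.fluorescence.values)
    assert out.truth.equals(full.truth)


def test_apply_spillover_single_event():
    """True (1000, 0) with 10% FITC->PE spill reads 100 in PE."""
    from cytopanel.synthetic import EventMatrix

    md = SampleMetadata("D1", "Unstimulated", "fully-stained", 1, 1)
    em = EventMatrix(
        md,
        pd.DataFrame({"FSC-A": [1.0], "FSC-H": [1.0], "SSC-A": [1.0]}),
        pd.DataFrame({"FITC": [1000.0], "PE": [0.0]}),
    )
    S = SpilloverMatrix(["FITC", "PE"], np.array([[1.0, 0.1], [0.0, 1.0]]))
    out = apply_spillover(em, S)
    assert out.fluorescence.loc[0, "PE"] == pytest.approx(100.0)
    assert out.fluorescence.loc[0, "FITC"] == pytest.approx(1000.0)


def test_spillover_dimension_mismatch(unstim_pair1):
    full, _ = unstim_pair1
    S = SpilloverMatrix(["X", "Y"], np.eye(2))
    with pytest.raises(ValueError):
        apply_spillover(full, S)


# -- interfering drug -------------------------------------------------------


def test_drug_zero_concentration_is_identity(unstim_pair1):
    full, _ = unstim_pair1
    out = simulate_interfering_drug(full, {"CD4-PE": 100.0}, 0.0)
    assert np.allclose(out.fluorescence.values, full.fluorescence.values)


def test_drug_shifts_only_listed_channels(unstim_pair1):
    full, _ = unstim_pair1
    out = simulate_interfering_drug(full, {"CD4-PE": 100.0}, 50.0, seed=3)
    assert (
        np.median(out.fluorescence["CD4-PE"]) > np.median(full.fluorescence["CD4-PE"])
    )
    assert np.allclose(out.fluorescence["CD3-BV570"], full.fluorescence["CD3-BV570"])
    assert out.scatter.equals(full.scatter)


def test_drug_dilution_series_monotone(unstim_pair1):
    """Median shift decays monotonically along a 10-fold dilution series."""
    full, _ = unstim_pair1
    base = np.median(full.fluorescence["CD4-PE"])
    shifts = []
    for dil in serial_dilution_factors(10, 3):
        out = simulate_interfering_drug(full, {"CD4-PE": 10.0}, 100.0 / dil, seed=3)
        shifts.append(np.median(out.fluorescence["CD4-PE"]) - base)
    assert all(a >= b for a, b in zip(shifts, shifts[1:]))


def test_negative_concentration_rejected(unstim_pair1):
    with pytest.raises(ValueError):
        simulate_interfering_drug(unstim_pair1[0], {"CD4-PE": 1.0}, -1.0)


# -- dose arithmetic ---------------------------------------------------------


@pytest.mark.parametrize(
    "stock, mrd, expected",
    [(10.0, 10, 1.0), (7.3, 1, 7.3), (10e-3, 10, 1e-3)],
)
def test_final_concentration(stock, mrd, expected):
    assert final_concentration(stock, mrd) == pytest.approx(expected)


@pytest.mark.parametrize(
    "fold, steps, expected",
    [
        (5, 5, [1, 5, 25, 125, 625, 3125]),
        (7, 0, [1]),
        (10, 3, [1, 10, 100, 1000]),
    ],
)
def test_serial_dilution_factors(fold, steps, expected):
    assert serial_dilution_factors(fold, steps) == expected


def test_dose_arithmetic_rejects_bad_inputs():
    with pytest.raises(ValueError):
        final_concentration(1.0, 0.5)
    with pytest.raises(ValueError):
        serial_dilution_factors(1.0, 3)
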