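"""Derived readouts: geometric MFI, stimulation indices, endpoint tables.

The stimulation index (SI) is the fold change of a readout in a treated
or activated sample relative to its reference condition (unstimulated
PBMC, or the matching vehicle control for a nanoparticle treatment).
Replicates are averaged *before* the ratio is taken, so the SI compares
technical-repeat means rather than averaging per-replicate ratios.

Endpoints assembled per (donor, treatment):

* percent-of-live SI per population,
* for populations carrying activation markers: the SI and the raw
  replicate-averaged value of each activation-quadrant percentage, and
  the SI of each activation marker's whole-population gMFI.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

QUADRANT_ORDER = ("--", "+-", "-+", "++")


def gmfi(values: np.ndarray, return_details: bool = False):
    """Geometric mean fluorescence intensity: exp(mean(log(values))).

    Non-positive values (possible after compensation) are excluded from
    the log average; if more than half the events are non-positive the
    statistic is undefined and NaN is returned with the flag set.
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("gmfi of an empty sample")
    positive = values[values > 0]
    n_excluded = values.size - positive.size
    flagged = n_excluded > 0.5 * values.size
    if flagged:
        warnings.warn(
            f"gMFI undefined: {n_excluded}/{values.size} non-positive values"
        )
        result = float("nan")
    else:
        result = float(np.exp(np.mean(np.log(positive))))
    if return_details:
        return result, n_excluded, flagged
    return result


def stimulation_index(
    treated_reps: Sequence[float], reference_reps: Sequence[float]
) -> float:
    """Fold change of replicate means: mean(treated) / mean(reference).

    NaN (with a warning) when the reference mean is zero.
    """
    treated = np.asarray(treated_reps, float)
    reference = np.asarray(reference_reps, float)
    if treated.size == 0 or reference.size == 0:
        raise ValueError("treated and reference replicate lists must be nonempty")
    ref_mean = np.nanmean(reference)
    if ref_mean == 0:
        warnings.warn("reference mean is zero; stimulation index undefined")
        return float("nan")
    return float(np.nanmean(treated) / ref_mean)


# --------------------------------------------------------------------------
# endpoint extraction from gating results
# --------------------------------------------------------------------------


def endpoint_values(stats_collection: Iterable) -> pd.DataFrame:
    """Tidy per-replicate endpoint values from a GateStats collection.

    One row per (donor, condition, replicate, endpoint); endpoints are
    ``<population>|pct_of_live``, ``<population>|quad_<q>_pct`` and
    ``<population>|gmfi_<marker>``.
    """
    rows = []
    for gs in stats_collection:
        md = gs.metadata
        base = {
            "donor": md.donor_id,
            "condition": md.condition,
            "replicate": md.replicate_index,
        }
        for _, r in gs.populations.iterrows():
            rows.append(
                {**base, "endpoint": f"{r['population']}|pct_of_live",
                 "value": r["pct_of_live"]}
            )
        for _, r in gs.quadrants.iterrows():
            rows.append(
                {**base, "endpoint": f"{r['population']}|quad_{r['quadrant']}_pct",
                 "value": np.nan if r["empty"] else r["pct"]}
            )
        for _, r in gs.gmfis.iterrows():
            rows.append(
                {**base, "endpoint": f"{r['population']}|gmfi_{r['marker']}",
                 "value": r["gmfi"]}
            )
    return pd.DataFrame(rows)


def replicate_averaged(endpoints: pd.DataFrame) -> pd.DataFrame:
    """Average endpoint values over technical replicates."""
    return (
        endpoints.groupby(["donor", "condition", "endpoint"], as_index=False)["value"]
        .mean()
    )


# --------------------------------------------------------------------------
# SI table assembly
# --------------------------------------------------------------------------


def assemble_si_tables(
    stats_collection: Iterable,
    reference_rule: Mapping[str, str] | None = None,
    default_reference: str = "Unstimulated",
    treatments: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-donor stimulation-index table for a cohort.

    ``reference_rule`` maps a treatment condition to its reference
    condition (e.g. AmBisome -> Dextrose vehicle); anything unmapped is
    compared against ``default_reference``. Every (donor, treatment,
    endpoint) combination appears; missing inputs yield NaN values with
    the ``flagged`` column set rather than silently dropped rows.
    """
    stats_list = list(stats_collection)
    reference_rule = dict(reference_rule or {})
    avg = replicate_averaged(endpoint_values(stats_list))
    conditions = sorted(avg["condition"].unique())
    donors = sorted(avg["donor"].unique())
    endpoints = sorted(avg["endpoint"].unique())
    if treatments is None:
        references = set(reference_rule.values()) | {default_reference}
        treatments = [c for c in conditions if c not in references]
    lookup = {
        (r.donor, r.condition, r.endpoint): r.value for r in avg.itertuples(index=False)
    }

    missing_refs = [
        t for t in treatments
        if reference_rule.get(t, default_reference) not in conditions
    ]
    if missing_refs:
        raise ValueError(
            f"missing reference condition for treatments: {missing_refs}"
        )

    rows = []
    for donor in donors:
        for treat in treatments:
            ref = reference_rule.get(treat, default_reference)
            for ep in endpoints:
                tv = lookup.get((donor, treat, ep), np.nan)
                rv = lookup.get((donor, ref, ep), np.nan)
                population, metric = ep.split("|", 1)
                # SI endpoint
                if np.isnan(tv) or np.isnan(rv) or rv == 0:
                    si, si_flag = np.nan, True
                else:
                    si, si_flag = tv / rv, False
                rows.append(
                    {
                        "donor": donor,
                        "treatment": treat,
                        "reference": ref,
                        "population": population,
                        "endpoint": f"{metric}_SI",
                        "value": si,
                        "flagged": si_flag,
                    }
                )
                # raw replicate-averaged quadrant percentages (the
                # activation-quadrant heat-map values) are also endpoints
                if metric.startswith("quad_"):
                    rows.append(
                        {
                            "donor": donor,
                            "treatment": treat,
                            "reference": ref,
                            "population": population,
                            "endpoint": f"{metric}_avg",
                            "value": tv,
                            "flagged": bool(np.isnan(tv)),
                        }
                    )
    return pd.DataFrame(rows)


def plot_si_heatmap(si_table: pd.DataFrame, endpoint_suffix: str = "pct_of_live_SI",
                    ax=None):
    """Heat map of stimulation indices (populations x donor/treatment).

    A reporting convenience over the SI table; the CSV values are the
    contract, the rendering is cosmetic. Requires matplotlib.
    """
    import matplotlib.pyplot as plt

    sub = si_table[si_table["endpoint"] == endpoint_suffix].copy()
    sub["column"] = sub["donor"] + " / " + sub["treatment"]
    pivot = sub.pivot_table(index="population", columns="column", values="value")
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.9 * pivot.shape[1], 1 + 0.5 * pivot.shape[0]))
    im = ax.imshow(pivot.values, aspect="auto", cmap="coolwarm", vmin=0, vmax=2)
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    ax.figure.colorbar(im, ax=ax, label=endpoint_suffix)
    ax.set_title("Stimulation index")
    return ax
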