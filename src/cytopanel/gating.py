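"""Hierarchical gating: execute a panel's gate tree on compensated samples.

Events flow top-down through the tree. Scatter gates (main-cells
rectangle, singlet band, monocyte/lymphocyte morphology split) are
data-driven or fixed-boundary; marker gates compare one channel to a
threshold taken from a condition-matched isotype control (a high
quantile of the isotype distribution, i.e. the negative-staining
boundary). The viability gate is *exclusive*: its members (dead cells)
are removed from all downstream gating, and "live" means the survivors.

Boundary convention everywhere: value strictly greater than the
threshold is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from cytopanel.panel_model import (
    GateNode,
    PanelDefinition,
    THRESHOLD_KINDS,
)
from cytopanel.readouts import gmfi
from cytopanel.synthetic import EventMatrix


@dataclass
class GatingConfig:
    """Tunable gating parameters.

    * ``isotype_quantile`` — quantile of the isotype distribution used as
      the positive/negative boundary (0.995 = 0.5% false-positive rate).
    * ``main_cells_trim`` — per-axis percentile window kept by the
      main-cells scatter gate, plus a fixed FSC floor to drop debris.
    * ``singlet_ratio_band`` — FSC-H/FSC-A window accepted as singlets.
    * ``viability_threshold`` — fixed dye boundary between live and dead.
    * ``mono_lymph_boundary_fsc`` — FSC-A boundary of the monocyte (above)
      vs lymphocyte (at/below) morphology split.
    """

    isotype_quantile: float = 0.995
    main_cells_trim: tuple[float, float] = (0.02, 0.995)
    fsc_floor: float = 20_000.0
    singlet_ratio_band: tuple[float, float] = (0.8, 1.2)
    viability_threshold: float = 2_000.0
    mono_lymph_boundary_fsc: float = 90_000.0


@dataclass
class ThresholdSet:
    """Numeric thresholds per gate id plus activation-channel thresholds.

    ``provenance`` records, per entry, either ("isotype-quantile",
    isotype sample id, quantile) or ("fixed-value",).
    """

    thresholds: dict[str, float]
    provenance: dict[str, tuple] = field(default_factory=dict)

    def __getitem__(self, gate_id: str) -> float:
        return self.thresholds[gate_id]

    def activation_threshold(self, detector: str) -> float:
        return self.thresholds[f"activation:{detector}"]

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds,
            "provenance": {k: list(v) for k, v in self.provenance.items()},
        }


@dataclass
class GateStats:
    """Per-sample gating results.

    ``populations`` is tidy (one row per population: count, parent count,
    percent-of-parent, percent-of-live, empty-parent flag). ``quadrants``
    and ``gmfis`` hold activation statistics for populations that carry
    activation markers. Percentages over an empty parent are reported as
    0 with ``empty_parent`` set, so tables stay rectangular.
    """

    sample_id: str
    metadata: object
    populations: pd.DataFrame
    quadrants: pd.DataFrame
    gmfis: pd.DataFrame
    gate_counts: dict[str, int]
    live_count: int
    total_events: int


QUADRANT_ORDER = ("--", "+-", "-+", "++")


def quadrant_stats(
    values_a: np.ndarray, values_b: np.ndarray, thr_a: float, thr_b: float
) -> tuple[float, float, float, float]:
    """Percentages of (-/-), (+/-), (-/+), (+/+) relative to two thresholds.

    The first sign refers to ``values_a``. Strictly greater than the
    threshold counts as positive. The four percentages sum to 100.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or a.size != b.size:
        raise ValueError("values_a and values_b must be nonempty and equal-length")
    pa = a > thr_a
    pb = b > thr_b
    n = a.size
    return (
        100.0 * np.sum(~pa & ~pb) / n,
        100.0 * np.sum(pa & ~pb) / n,
        100.0 * np.sum(~pa & pb) / n,
        100.0 * np.sum(pa & pb) / n,
    )


# --------------------------------------------------------------------------
# structural gate evaluation
# --------------------------------------------------------------------------


def _topological_order(panel: PanelDefinition) -> list[GateNode]:
    order, seen = [], set()
    nodes = list(panel.gate_tree.values())
    while nodes:
        progressed = False
        for g in list(nodes):
            if g.parent is None or g.parent in seen:
                order.append(g)
                seen.add(g.id)
                nodes.remove(g)
                progressed = True
        if not progressed:
            raise ValueError("gate tree is not a tree (cycle or missing parent)")
    return order


def _node_condition(
    node: GateNode,
    sample: EventMatrix,
    thresholds: ThresholdSet | None,
    config: GatingConfig,
) -> np.ndarray:
    fsc_a = sample.scatter["FSC-A"].values
    if node.kind == "scatter-region":
        if node.region == "monocyte":
            return fsc_a > config.mono_lymph_boundary_fsc
        if node.region == "lymphocyte":
            return fsc_a <= config.mono_lymph_boundary_fsc
        # main-cells: percentile-trimmed rectangle plus FSC floor
        lo, hi = config.main_cells_trim
        ssc = sample.scatter["SSC-A"].values
        cond = np.ones(sample.n_events, bool)
        for vals in (fsc_a, ssc):
            qlo, qhi = np.quantile(vals, [lo, hi])
            cond &= (vals >= qlo) & (vals <= qhi)
        return cond & (fsc_a >= config.fsc_floor)
    if node.kind == "singlet":
        ratio = sample.scatter["FSC-H"].values / np.maximum(fsc_a, 1e-12)
        lo, hi = config.singlet_ratio_band
        return (ratio >= lo) & (ratio <= hi)
    if node.kind == "viability-exclusion":
        thr = (
            thresholds.thresholds.get(node.id, config.viability_threshold)
            if thresholds is not None
            else config.viability_threshold
        )
        return sample.fluorescence[node.channels[0]].values > thr
    if node.kind in THRESHOLD_KINDS:
        if thresholds is None or node.id not in thresholds.thresholds:
            raise KeyError(f"missing threshold for gate {node.id!r}")
        vals = sample.fluorescence[node.channels[0]].values
        thr = thresholds[node.id]
        if node.kind == "threshold-positive":
            return vals > thr
        return vals <= thr  # negative and low gates keep the dim events
    if node.kind == "quadrant":
        if thresholds is None:
            raise KeyError(f"missing thresholds for quadrant gate {node.id!r}")
        a = sample.fluorescence[node.channels[0]].values > thresholds[f"{node.id}:a"]
        b = sample.fluorescence[node.channels[1]].values > thresholds[f"{node.id}:b"]
        want = node.quadrant or "++"
        pa = a if want[0] == "+" else ~a
        pb = b if want[1] == "+" else ~b
        return pa & pb
    raise ValueError(f"unknown gate kind {node.kind!r}")


def gate_masks(
    sample: EventMatrix,
    panel: PanelDefinition,
    thresholds: ThresholdSet | None,
    config: GatingConfig,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-gate membership and pass-through masks.

    ``members[g]`` are the events in gate *g*; ``passed[g]`` is what g's
    children inherit (equal to members for inclusive gates; parent minus
    members for the exclusive viability gate).
    """
    members: dict[str, np.ndarray] = {}
    passed: dict[str, np.ndarray] = {}
    for node in _topological_order(panel):
        base = (
            np.ones(sample.n_events, bool) if node.parent is None else passed[node.parent]
        )
        cond = _node_condition(node, sample, thresholds, config)
        members[node.id] = base & cond
        passed[node.id] = (
            base & ~members[node.id] if node.polarity == "exclusive" else members[node.id]
        )
    return members, passed


def live_mask(
    sample: EventMatrix,
    panel: PanelDefinition,
    thresholds: ThresholdSet | None = None,
    config: GatingConfig | None = None,
) -> np.ndarray:
    """Live singlet cells: survivors of the viability-exclusion gate.

    Only the trunk (root -> ... -> viability gate) is evaluated, so no
    marker thresholds are needed — this is how an isotype control is
    pre-gated before its marker distributions set the thresholds.
    """
    config = config or GatingConfig()
    viab = next(g for g in panel.gate_tree.values() if g.kind == "viability-exclusion")
    trunk = [viab]
    while trunk[-1].parent is not None:
        trunk.append(panel.gate_tree[trunk[-1].parent])
    mask = np.ones(sample.n_events, bool)
    for node in reversed(trunk):
        cond = _node_condition(node, sample, thresholds, config)
        members = mask & cond
        mask = mask & ~members if node.polarity == "exclusive" else members
    return mask


# --------------------------------------------------------------------------
# isotype thresholds
# --------------------------------------------------------------------------


def fit_isotype_thresholds(
    isotype: EventMatrix,
    panel: PanelDefinition,
    quantile: float | None = None,
    config: GatingConfig | None = None,
) -> ThresholdSet:
    """Set every marker threshold from a condition-matched isotype control.

    The isotype sample is first gated through scatter/singlet/viability;
    each threshold-kind gate (and each activation channel) then gets the
    ``quantile`` (default 0.995) of the isotype distribution on its
    channel among those live singlets. The isotype antibodies carry no
    specific binding, so this quantile is the negative-staining boundary.
    The viability gate keeps its fixed configured threshold.
    """
    config = config or GatingConfig()
    q = config.isotype_quantile if quantile is None else quantile
    live = live_mask(isotype, panel, None, config)
    if live.sum() == 0:
        raise ValueError("isotype sample has no live singlet events to fit thresholds")
    iso_id = isotype.metadata.sample_id
    thresholds: dict[str, float] = {}
    provenance: dict[str, tuple] = {}
    for g in panel.gate_tree.values():
        if g.kind in THRESHOLD_KINDS:
            vals = isotype.fluorescence[g.channels[0]].values[live]
            thresholds[g.id] = float(np.quantile(vals, q))
            provenance[g.id] = ("isotype-quantile", iso_id, q)
        elif g.kind == "viability-exclusion":
            thresholds[g.id] = config.viability_threshold
            provenance[g.id] = ("fixed-value",)
    for marker in panel.activation_markers:
        det = panel.detector_for_marker(marker)
        key = f"activation:{det}"
        thresholds[key] = float(np.quantile(isotype.fluorescence[det].values[live], q))
        provenance[key] = ("isotype-quantile", iso_id, q)
    return ThresholdSet(thresholds, provenance)


# --------------------------------------------------------------------------
# gate-tree execution
# --------------------------------------------------------------------------


def apply_gate_tree(
    sample: EventMatrix,
    panel: PanelDefinition,
    thresholds: ThresholdSet,
    config: GatingConfig | None = None,
) -> GateStats:
    """Gate one compensated sample and collect all population statistics."""
    config = config or GatingConfig()
    members, passed = gate_masks(sample, panel, thresholds, config)
    viab = next(g for g in panel.gate_tree.values() if g.kind == "viability-exclusion")
    live = passed[viab.id]
    n_live = int(live.sum())

    pop_rows = []
    quad_rows = []
    gmfi_rows = []
    for rule in panel.populations:
        leaf = rule.path[-1]
        pop_mask = members[leaf] if panel.gate_tree[leaf].polarity != "exclusive" else passed[leaf]
        count = int(pop_mask.sum())
        parent_gate = panel.gate_tree[leaf].parent
        if parent_gate is None:
            parent_count = sample.n_events
        else:
            parent_count = int(passed[parent_gate].sum())
        empty_parent = parent_count == 0
        pop_rows.append(
            {
                "population": rule.name,
                "count": count,
                "parent_count": parent_count,
                "pct_of_parent": 0.0 if empty_parent else 100.0 * count / parent_count,
                "pct_of_live": 0.0 if n_live == 0 else 100.0 * count / n_live,
                "empty_parent": empty_parent,
            }
        )
        if rule.activation_markers and count > 0:
            det_a = panel.detector_for_marker(rule.activation_markers[0])
            det_b = panel.detector_for_marker(rule.activation_markers[1])
            vals_a = sample.fluorescence[det_a].values[pop_mask]
            vals_b = sample.fluorescence[det_b].values[pop_mask]
            pcts = quadrant_stats(
                vals_a,
                vals_b,
                thresholds.activation_threshold(det_a),
                thresholds.activation_threshold(det_b),
            )
            for quad, pct in zip(QUADRANT_ORDER, pcts):
                quad_rows.append(
                    {
                        "population": rule.name,
                        "marker_a": rule.activation_markers[0],
                        "marker_b": rule.activation_markers[1],
                        "quadrant": quad,
                        "pct": pct,
                        "empty": False,
                    }
                )
            for marker, vals in zip(rule.activation_markers, (vals_a, vals_b)):
                value, n_excluded, flagged = gmfi(vals, return_details=True)
                gmfi_rows.append(
                    {
                        "population": rule.name,
                        "marker": marker,
                        "gmfi": value,
                        "n_excluded_nonpositive": n_excluded,
                        "flagged": flagged,
                    }
                )
        elif rule.activation_markers:
            for quad in QUADRANT_ORDER:
                quad_rows.append(
                    {
                        "population": rule.name,
                        "marker_a": rule.activation_markers[0],
                        "marker_b": rule.activation_markers[1],
                        "quadrant": quad,
                        "pct": 0.0,
                        "empty": True,
                    }
                )
            for marker in rule.activation_markers:
                gmfi_rows.append(
                    {
                        "population": rule.name,
                        "marker": marker,
                        "gmfi": float("nan"),
                        "n_excluded_nonpositive": 0,
                        "flagged": True,
                    }
                )

    return GateStats(
        sample_id=sample.metadata.sample_id,
        metadata=sample.metadata,
        populations=pd.DataFrame(pop_rows),
        quadrants=pd.DataFrame(quad_rows),
        gmfis=pd.DataFrame(gmfi_rows),
        gate_counts={gid: int(m.sum()) for gid, m in members.items()},
        live_count=n_live,
        total_events=sample.n_events,
    )
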