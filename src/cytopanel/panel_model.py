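"""Declarative data model of the immunophenotyping panels.

A :class:`PanelDefinition` couples three things:

* the reagent list (:class:`ChannelDef`: marker, fluorophore, detector),
* a hierarchical gate tree (:class:`GateNode`), and
* the cell-population rules (:class:`PopulationRule`) that name a path
  through that tree, optionally carrying activation markers.

Two built-in panels are provided. Panel 1 (the *lymphocyte panel*)
resolves B cells and the major T-cell subsets (cytotoxic, naive
cytotoxic, CD4 helper, regulatory, gamma/delta) and scores activation via
CD25 and CD154. Panel 2 (the *monocyte / dendritic-cell / NK panel*)
resolves CD14+ monocytes, plasmacytoid and myeloid DCs, NK and NKT cells
and scores activation via CD54 and CD69.

Panels are plain declarative data: they can be serialized to and loaded
from YAML/JSON so users can define their own panels with the same schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

SCATTER_CHANNELS = ("FSC-A", "FSC-H", "SSC-A")

GATE_KINDS = (
    "scatter-region",
    "singlet",
    "viability-exclusion",
    "threshold-positive",
    "threshold-negative",
    "threshold-low",
    "quadrant",
)

THRESHOLD_KINDS = ("threshold-positive", "threshold-negative", "threshold-low")


@dataclass(frozen=True)
class ChannelDef:
    """One reagent: an antibody (or dye) read out on one detector."""

    marker: str
    fluorophore: str
    detector: str

    @staticmethod
    def make(marker: str, fluorophore: str) -> "ChannelDef":
        """Build with the ``Marker-Fluorophore`` detector naming convention."""
        return ChannelDef(marker, fluorophore, f"{marker}-{fluorophore}")


@dataclass(frozen=True)
class GateNode:
    """One node of the hierarchical gate tree.

    ``polarity`` is "inclusive" for ordinary gates (members flow to the
    children) and "exclusive" for the viability gate, whose members (dead
    cells) are removed from all downstream gating.

    ``region`` names a scatter-region rule ("main-cells", "monocyte",
    "lymphocyte") resolved by the gating engine; ``quadrant`` selects one
    of "--", "+-", "-+", "++" for quadrant-kind nodes.
    """

    id: str
    parent: str | None
    kind: str
    channels: tuple[str, ...]
    threshold_source: str = "isotype-quantile"  # or "fixed-value"
    polarity: str = "inclusive"
    region: str | None = None
    quadrant: str | None = None


@dataclass(frozen=True)
class PopulationRule:
    """A named cell population: an ordered root-to-leaf gate path."""

    name: str
    path: tuple[str, ...]
    activation_markers: tuple[str, ...] = ()


@dataclass
class PanelDefinition:
    panel_id: int
    name: str
    channels: list[ChannelDef]
    gate_tree: dict[str, GateNode]
    populations: list[PopulationRule]
    activation_markers: tuple[str, ...] = ()

    @property
    def detectors(self) -> list[str]:
        return [c.detector for c in self.channels]

    def detector_for_marker(self, marker: str) -> str:
        for c in self.channels:
            if c.marker == marker:
                return c.detector
        raise KeyError(f"marker {marker!r} not in panel {self.panel_id}")

    @property
    def viability_detector(self) -> str:
        return self.detector_for_marker("Viability")

    @property
    def root_id(self) -> str:
        roots = [g.id for g in self.gate_tree.values() if g.parent is None]
        if len(roots) != 1:
            raise ValueError(f"panel {self.panel_id} has {len(roots)} roots")
        return roots[0]

    def threshold_gates(self) -> list[GateNode]:
        return [g for g in self.gate_tree.values() if g.kind in THRESHOLD_KINDS]

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "panel_id": self.panel_id,
            "name": self.name,
            "channels": [
                {"marker": c.marker, "fluorophore": c.fluorophore, "detector": c.detector}
                for c in self.channels
            ],
            "gates": [
                {
                    "id": g.id,
                    "parent": g.parent,
                    "kind": g.kind,
                    "channels": list(g.channels),
                    "threshold_source": g.threshold_source,
                    "polarity": g.polarity,
                    **({"region": g.region} if g.region else {}),
                    **({"quadrant": g.quadrant} if g.quadrant else {}),
                }
                for g in self.gate_tree.values()
            ],
            "populations": [
                {
                    "name": p.name,
                    "path": list(p.path),
                    "activation_markers": list(p.activation_markers),
                }
                for p in self.populations
            ],
            "activation_markers": list(self.activation_markers),
        }

    @staticmethod
    def from_dict(d: Mapping) -> "PanelDefinition":
        channels = [
            ChannelDef(c["marker"], c["fluorophore"], c["detector"]) for c in d["channels"]
        ]
        gates = {
            g["id"]: GateNode(
                id=g["id"],
                parent=g.get("parent"),
                kind=g["kind"],
                channels=tuple(g.get("channels", ())),
                threshold_source=g.get("threshold_source", "isotype-quantile"),
                polarity=g.get("polarity", "inclusive"),
                region=g.get("region"),
                quadrant=g.get("quadrant"),
            )
            for g in d["gates"]
        }
        pops = [
            PopulationRule(
                p["name"], tuple(p["path"]), tuple(p.get("activation_markers", ()))
            )
            for p in d["populations"]
        ]
        return PanelDefinition(
            panel_id=int(d["panel_id"]),
            name=d.get("name", f"Panel {d['panel_id']}"),
            channels=channels,
            gate_tree=gates,
            populations=pops,
            activation_markers=tuple(d.get("activation_markers", ())),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @staticmethod
    def load(path: str | Path) -> "PanelDefinition":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return PanelDefinition.from_dict(d)


def _chain(gates: dict[str, GateNode], *nodes: GateNode) -> None:
    for g in nodes:
        gates[g.id] = g


def build_panel1() -> PanelDefinition:
    """The lymphocyte panel: B cells and the major T-cell subsets.

    12 channels (11 antibodies plus the amine-reactive viability dye);
    activation markers CD25 (proliferation) and CD154 (co-stimulation)
    attached to B cells, cytotoxic T cells and CD4 T cells.
    """
    channels = [
        ChannelDef.make("CD8a", "FITC"),
        ChannelDef.make("CD4", "PE"),
        ChannelDef.make("CD19", "PE-Cy7"),
        ChannelDef.make("CCR4", "APC"),
        ChannelDef.make("CD45RA", "AF700"),
        ChannelDef.make("TCRgd", "APC-Fire750"),
        ChannelDef.make("CD45", "PacBlue"),
        ChannelDef.make("Viability", "ZombieAqua"),
        ChannelDef.make("CD3", "BV570"),
        ChannelDef.make("CD25", "BV650"),
        ChannelDef.make("CD154", "BV711"),
        ChannelDef.make("CD127", "BV785"),
    ]
    det = {c.marker: c.detector for c in channels}
    gates: dict[str, GateNode] = {}
    _chain(
        gates,
        GateNode("main_cells", None, "scatter-region", ("FSC-A", "SSC-A"), "fixed-value",
                 region="main-cells"),
        GateNode("singlets", "main_cells", "singlet", ("FSC-A", "FSC-H"), "fixed-value"),
        GateNode("dead", "singlets", "viability-exclusion", (det["Viability"],),
                 "fixed-value", polarity="exclusive"),
        GateNode("cd45_pos", "dead", "threshold-positive", (det["CD45"],)),
        GateNode("cd19_pos", "cd45_pos", "threshold-positive", (det["CD19"],)),
        GateNode("cd3_pos", "cd45_pos", "threshold-positive", (det["CD3"],)),
        GateNode("cd8_pos", "cd3_pos", "threshold-positive", (det["CD8a"],)),
        GateNode("cd8pos_cd4_neg", "cd8_pos", "threshold-negative", (det["CD4"],)),
        GateNode("cd45ra_pos", "cd8pos_cd4_neg", "threshold-positive", (det["CD45RA"],)),
        GateNode("cd4_pos", "cd3_pos", "threshold-positive", (det["CD4"],)),
        GateNode("cd4pos_cd8_neg", "cd4_pos", "threshold-negative", (det["CD8a"],)),
        GateNode("ccr4_pos", "cd4pos_cd8_neg", "threshold-positive", (det["CCR4"],)),
        GateNode("treg_cd25_pos", "ccr4_pos", "threshold-positive", (det["CD25"],)),
        GateNode("treg_cd127_low", "treg_cd25_pos", "threshold-low", (det["CD127"],)),
        GateNode("cd8_neg", "cd3_pos", "threshold-negative", (det["CD8a"],)),
        GateNode("dn_cd4_neg", "cd8_neg", "threshold-negative", (det["CD4"],)),
        GateNode("tcrgd_pos", "dn_cd4_neg", "threshold-positive", (det["TCRgd"],)),
    )
    trunk = ("main_cells", "singlets", "dead", "cd45_pos")
    populations = [
        PopulationRule("B cells", trunk + ("cd19_pos",), ("CD25", "CD154")),
        PopulationRule("T cells", trunk + ("cd3_pos",)),
        PopulationRule(
            "Cytotoxic T cells",
            trunk + ("cd3_pos", "cd8_pos", "cd8pos_cd4_neg"),
            ("CD25", "CD154"),
        ),
        PopulationRule(
            "Naive cytotoxic T cells",
            trunk + ("cd3_pos", "cd8_pos", "cd8pos_cd4_neg", "cd45ra_pos"),
        ),
        PopulationRule(
            "CD4 T cells",
            trunk + ("cd3_pos", "cd4_pos", "cd4pos_cd8_neg"),
            ("CD25", "CD154"),
        ),
        PopulationRule(
            "Regulatory T cells",
            trunk
            + (
                "cd3_pos",
                "cd4_pos",
                "cd4pos_cd8_neg",
                "ccr4_pos",
                "treg_cd25_pos",
                "treg_cd127_low",
            ),
        ),
        PopulationRule(
            "Gamma-delta T cells",
            trunk + ("cd3_pos", "cd8_neg", "dn_cd4_neg", "tcrgd_pos"),
        ),
    ]
    return PanelDefinition(
        panel_id=1,
        name="Lymphocyte panel",
        channels=channels,
        gate_tree=gates,
        populations=populations,
        activation_markers=("CD25", "CD154"),
    )


def build_panel2() -> PanelDefinition:
    """The monocyte / dendritic-cell / NK panel.

    11 channels. A shared debris/singlet/viability trunk splits into two
    scatter-morphology branches — monocytes (large, granular) and
    lymphocytes — before lineage gating. Activation markers CD54
    (adhesion) and CD69 (early activation) on monocytes, pDC, mDC and NK.
    """
    channels = [
        ChannelDef.make("CD56", "FITC"),
        ChannelDef.make("CD14", "PE"),
        ChannelDef.make("CD19", "PE-Cy7"),
        ChannelDef.make("CD123", "APC"),
        ChannelDef.make("CD54", "AF700"),
        ChannelDef.make("CD20", "APC-Fire750"),
        ChannelDef.make("CD45", "PacBlue"),
        ChannelDef.make("Viability", "ZombieAqua"),
        ChannelDef.make("CD3", "BV570"),
        ChannelDef.make("CD69", "BV650"),
        ChannelDef.make("CD11c", "BV785"),
    ]
    det = {c.marker: c.detector for c in channels}
    gates: dict[str, GateNode] = {}
    _chain(
        gates,
        GateNode("main_cells", None, "scatter-region", ("FSC-A", "SSC-A"), "fixed-value",
                 region="main-cells"),
        GateNode("singlets", "main_cells", "singlet", ("FSC-A", "FSC-H"), "fixed-value"),
        GateNode("dead", "singlets", "viability-exclusion", (det["Viability"],),
                 "fixed-value", polarity="exclusive"),
        GateNode("mono_scatter", "dead", "scatter-region", ("FSC-A", "SSC-A"),
                 "fixed-value", region="monocyte"),
        GateNode("lymph_scatter", "dead", "scatter-region", ("FSC-A", "SSC-A"),
                 "fixed-value", region="lymphocyte"),
        # monocyte branch
        GateNode("m_cd45_pos", "mono_scatter", "threshold-positive", (det["CD45"],)),
        GateNode("m_cd3_neg", "m_cd45_pos", "threshold-negative", (det["CD3"],)),
        GateNode("m_cd19_neg", "m_cd3_neg", "threshold-negative", (det["CD19"],)),
        GateNode("m_cd14_pos", "m_cd19_neg", "threshold-positive", (det["CD14"],)),
        # lymphocyte branch
        GateNode("l_cd45_pos", "lymph_scatter", "threshold-positive", (det["CD45"],)),
        GateNode("l_cd3_neg", "l_cd45_pos", "threshold-negative", (det["CD3"],)),
        GateNode("l_cd19_neg", "l_cd3_neg", "threshold-negative", (det["CD19"],)),
        GateNode("l_cd14_neg", "l_cd19_neg", "threshold-negative", (det["CD14"],)),
        GateNode("l_cd20_neg", "l_cd14_neg", "threshold-negative", (det["CD20"],)),
        GateNode("cd123_pos", "l_cd20_neg", "threshold-positive", (det["CD123"],)),
        GateNode("cd11c_pos", "l_cd20_neg", "threshold-positive", (det["CD11c"],)),
        GateNode("cd56_pos", "l_cd20_neg", "threshold-positive", (det["CD56"],)),
        GateNode("l_cd3_pos", "l_cd45_pos", "threshold-positive", (det["CD3"],)),
        GateNode("nkt_cd56_pos", "l_cd3_pos", "threshold-positive", (det["CD56"],)),
    )
    trunk = ("main_cells", "singlets", "dead")
    lymph = trunk + ("lymph_scatter", "l_cd45_pos", "l_cd3_neg", "l_cd19_neg",
                     "l_cd14_neg", "l_cd20_neg")
    populations = [
        PopulationRule(
            "Monocytes",
            trunk + ("mono_scatter", "m_cd45_pos", "m_cd3_neg", "m_cd19_neg", "m_cd14_pos"),
            ("CD54", "CD69"),
        ),
        PopulationRule("pDCs", lymph + ("cd123_pos",), ("CD54", "CD69")),
        PopulationRule("mDCs", lymph + ("cd11c_pos",), ("CD54", "CD69")),
        PopulationRule("NK cells", lymph + ("cd56_pos",), ("CD54", "CD69")),
        PopulationRule(
            "NK T cells",
            trunk + ("lymph_scatter", "l_cd45_pos", "l_cd3_pos", "nkt_cd56_pos"),
        ),
    ]
    return PanelDefinition(
        panel_id=2,
        name="Monocyte/DC/NK panel",
        channels=channels,
        gate_tree=gates,
        populations=populations,
        activation_markers=("CD54", "CD69"),
    )


def validate_panel(panel: PanelDefinition) -> list[str]:
    """Check all panel invariants; return one diagnostic string per violation.

    An empty list means the panel is structurally valid. Diagnostics are
    returned rather than raised so a config author sees every problem at
    once.
    """
    diags: list[str] = []
    detectors = set(panel.detectors)
    markers = {c.marker for c in panel.channels}

    pairs = [(c.marker, c.fluorophore) for c in panel.channels]
    if len(set(pairs)) != len(pairs):
        dup = sorted({p for p in pairs if pairs.count(p) > 1})
        diags.append(f"duplicate (marker, fluorophore) pairs: {dup}")
    if len(detectors) != len(panel.channels):
        diags.append("duplicate detector ids among channels")

    # gate tree structure
    roots = [g for g in panel.gate_tree.values() if g.parent is None]
    if len(roots) != 1:
        diags.append(f"gate tree must have exactly one root, found {len(roots)}")
    for g in panel.gate_tree.values():
        if g.kind not in GATE_KINDS:
            diags.append(f"gate {g.id!r}: unknown kind {g.kind!r}")
        if g.parent is not None and g.parent not in panel.gate_tree:
            diags.append(f"gate {g.id!r}: unknown parent {g.parent!r}")
        if g.kind == "quadrant" and len(g.channels) != 2:
            diags.append(f"quadrant gate {g.id!r} must reference exactly 2 channels")
        if not 1 <= len(g.channels) <= 2:
            diags.append(f"gate {g.id!r} must reference 1-2 channels")
        for ch in g.channels:
            if ch not in detectors and ch not in SCATTER_CHANNELS:
                diags.append(f"gate {g.id!r}: channel {ch!r} not a panel detector")

    # acyclicity via parent walk with cycle detection
    for g in panel.gate_tree.values():
        seen = [g.id]
        node = g
        while node.parent is not None:
            if node.parent in seen:
                diags.append(f"gate tree cycle: {' -> '.join(seen + [node.parent])}")
                break
            seen.append(node.parent)
            nxt = panel.gate_tree.get(node.parent)
            if nxt is None:
                break
            node = nxt

    n_viab = sum(1 for g in panel.gate_tree.values() if g.kind == "viability-exclusion")
    if n_viab != 1:
        diags.append(f"expected exactly one viability-exclusion gate, found {n_viab}")
    for g in panel.gate_tree.values():
        if g.kind == "viability-exclusion" and g.polarity != "exclusive":
            diags.append(f"viability gate {g.id!r} must be exclusive")

    # populations
    for pop in panel.populations:
        for gid in pop.path:
            if gid not in panel.gate_tree:
                diags.append(f"population {pop.name!r}: unknown gate id {gid!r}")
        if pop.path:
            ids_ok = all(gid in panel.gate_tree for gid in pop.path)
            if ids_ok:
                if panel.gate_tree[pop.path[0]].parent is not None:
                    diags.append(f"population {pop.name!r}: path does not start at root")
                for a, b in zip(pop.path, pop.path[1:]):
                    if panel.gate_tree[b].parent != a:
                        diags.append(
                            f"population {pop.name!r}: {b!r} is not a child of {a!r}"
                        )
        for m in pop.activation_markers:
            if m not in markers:
                diags.append(
                    f"population {pop.name!r}: activation marker {m!r} not in panel"
                )
        if pop.activation_markers and set(pop.activation_markers) != set(
            panel.activation_markers
        ):
            diags.append(
                f"population {pop.name!r}: activation markers {pop.activation_markers} "
                f"differ from panel activation markers {panel.activation_markers}"
            )
    return diags
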