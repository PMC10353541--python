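"""Synthetic PBMC cytometry cohorts with known ground truth.

The simulator draws complete experiments — donors x conditions x
replicates x stain types — for either built-in panel. Each sample is a
mixture of disjoint "truth" cell populations (B cells, T-cell subsets,
monocytes, DCs, NK, ...) with:

* two-component log-normal marker expression (negative background vs
  positive, plus an intermediate "low" component for CD127 on Tregs),
* forward/side scatter clusters for lymphocyte and monocyte morphology,
  debris and doublet events,
* an amine-reactive viability-dye signal separating live from dead cells
  (default 3:1 live:dead, the ratio used when building dye controls),
* per-donor random effects on population fractions and expression,
* condition-dependent activation shifts on the panel's activation
  markers (CD25/CD154 or CD54/CD69), and
* optional linear spectral spillover between detectors.

Every sample records per-event truth (population label, dead flag,
activation states) so downstream gating and readouts can be scored
exactly. Random substreams are derived by stable hashing of
(seed, donor, condition, replicate, stain type): adding samples to a
cohort never perturbs existing ones, and the fully-stained and isotype
samples of one (donor, condition, replicate) share the same underlying
cell draw.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cytopanel.panel_model import (
    PanelDefinition,
    THRESHOLD_KINDS,
    build_panel1,
    build_panel2,
)

SCATTER_COLUMNS = ["FSC-A", "FSC-H", "SSC-A"]

STAIN_TYPES = ("fully-stained", "isotype", "unstained")  # plus single-stain:/FMO: prefixes

CONDITIONS = (
    "Unstimulated",
    "LPS/PHA-M",
    "PMA/Ionomycin",
    "ODN2216/PHA-M",
)


# --------------------------------------------------------------------------
# metadata and event container
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleMetadata:
    """Identity of one acquired or simulated sample."""

    donor_id: str
    condition: str
    stain_type: str
    replicate_index: int = 1
    panel_id: int = 1

    def __post_init__(self):
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")
        base = self.stain_type.split(":")[0]
        if base not in ("fully-stained", "isotype", "unstained", "single-stain", "FMO"):
            raise ValueError(f"unknown stain_type {self.stain_type!r}")

    @property
    def sample_id(self) -> str:
        stain = self.stain_type.replace(":", "_").replace("/", "-")
        cond = self.condition.replace("/", "-").replace(" ", "_")
        return f"P{self.panel_id}_{self.donor_id}_{cond}_{stain}_r{self.replicate_index}"


@dataclass
class EventMatrix:
    """Events x channels for one sample.

    ``scatter`` holds FSC-A/FSC-H/SSC-A, ``fluorescence`` one column per
    detector. ``truth`` (synthetic samples only) carries the per-event
    population label, dead flag and activation states.
    """

    metadata: SampleMetadata
    scatter: pd.DataFrame
    fluorescence: pd.DataFrame
    truth: pd.DataFrame | None = None

    def __post_init__(self):
        if len(self.scatter) != len(self.fluorescence):
            raise ValueError("scatter and fluorescence blocks differ in length")
        if self.truth is not None and len(self.truth) != len(self.scatter):
            raise ValueError("truth block length mismatch")

    @property
    def n_events(self) -> int:
        return len(self.scatter)

    @property
    def detectors(self) -> list[str]:
        return list(self.fluorescence.columns)

    @property
    def truth_labels(self) -> pd.Series | None:
        return None if self.truth is None else self.truth["population"]

    def copy(self) -> "EventMatrix":
        return EventMatrix(
            self.metadata,
            self.scatter.copy(),
            self.fluorescence.copy(),
            None if self.truth is None else self.truth.copy(),
        )


# --------------------------------------------------------------------------
# simulation spec
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthPopulation:
    """One ground-truth cell population of the mixture.

    ``markers`` maps marker name -> expression state ("pos" or "low");
    markers not listed are negative (background only). ``scatter`` is
    "lymphocyte" or "monocyte".
    """

    name: str
    fraction: float
    scatter: str = "lymphocyte"
    markers: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ActivationEffect:
    """Condition effect on one activation marker in one population."""

    delta_positive_fraction: float = 0.0
    log_shift: float = 0.0  # additive shift of the positive log-location


@dataclass
class SyntheticSpec:
    """Full description of a synthetic experiment's generating process."""

    panel_id: int
    populations: list[TruthPopulation]
    # log-normal (log-location, log-scale) per expression state
    expression_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "neg": (np.log(100.0), 0.5),
            "low": (np.log(150.0), 0.4),
            "pos": (np.log(8000.0), 0.5),
        }
    )
    activation_base_fraction: float = 0.05
    # condition -> population -> marker -> ActivationEffect
    activation_effects: dict[str, dict[str, dict[str, ActivationEffect]]] = field(
        default_factory=dict
    )
    donor_effect_sd: float = 0.15
    donor_expression_sd: float = 0.10
    dead_fraction: float = 0.25
    debris_fraction: float = 0.05
    doublet_fraction: float = 0.02
    spillover: "SpilloverMatrix | None" = None
    n_events: int = 100_000
    seed: int = 0
    # scatter clusters: log-normal (log-location, log-scale) per axis
    scatter_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "lymphocyte": {"FSC-A": (np.log(60_000.0), 0.15), "SSC-A": (np.log(30_000.0), 0.25)},
            "monocyte": {"FSC-A": (np.log(130_000.0), 0.12), "SSC-A": (np.log(90_000.0), 0.20)},
            "debris": {"FSC-A": (np.log(8_000.0), 0.5), "SSC-A": (np.log(6_000.0), 0.6)},
        }
    )
    viability_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"live": (np.log(100.0), 0.5), "dead": (np.log(20_000.0), 0.4)}
    )

    @property
    def population_fractions(self) -> dict[str, float]:
        return {p.name: p.fraction for p in self.populations}

    def panel(self) -> PanelDefinition:
        return build_panel1() if self.panel_id == 1 else build_panel2()


def validate_spec(spec: SyntheticSpec) -> None:
    """Reject an invalid spec, naming the offending field."""
    if spec.n_events < 1:
        raise ValueError("n_events must be >= 1")
    fracs = list(spec.population_fractions.values())
    if any(f < 0 or f > 1 for f in fracs):
        raise ValueError("population_fractions entries must lie in [0, 1]")
    if sum(fracs) > 1 + 1e-9:
        raise ValueError("population_fractions must sum to <= 1")
    for name, frac in {
        "dead_fraction": spec.dead_fraction,
        "debris_fraction": spec.debris_fraction,
        "doublet_fraction": spec.doublet_fraction,
        "activation_base_fraction": spec.activation_base_fraction,
    }.items():
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    if spec.donor_effect_sd < 0:
        raise ValueError("donor_effect_sd must be >= 0")
    for p in spec.populations:
        if p.scatter not in ("lymphocyte", "monocyte"):
            raise ValueError(f"populations: unknown scatter class {p.scatter!r}")
        for m, state in p.markers.items():
            if state not in ("pos", "low"):
                raise ValueError(f"populations: unknown marker state {state!r}")


# -- default generating conditions -----------------------------------------


def _panel1_populations() -> list[TruthPopulation]:
    return [
        TruthPopulation("B cells", 0.10, "lymphocyte", {"CD45": "pos", "CD19": "pos"}),
        TruthPopulation(
            "Naive CD8 T", 0.06, "lymphocyte",
            {"CD45": "pos", "CD3": "pos", "CD8a": "pos", "CD45RA": "pos", "CD127": "pos"},
        ),
        TruthPopulation(
            "Memory CD8 T", 0.14, "lymphocyte",
            {"CD45": "pos", "CD3": "pos", "CD8a": "pos", "CD127": "pos"},
        ),
        TruthPopulation(
            "CD4 T conv", 0.26, "lymphocyte",
            {"CD45": "pos", "CD3": "pos", "CD4": "pos", "CD127": "pos"},
        ),
        TruthPopulation(
            "Treg", 0.04, "lymphocyte",
            {"CD45": "pos", "CD3": "pos", "CD4": "pos", "CCR4": "pos", "CD25": "pos",
             "CD127": "low"},
        ),
        TruthPopulation(
            "Gamma-delta T", 0.04, "lymphocyte",
            {"CD45": "pos", "CD3": "pos", "TCRgd": "pos"},
        ),
        TruthPopulation("Monocytes", 0.20, "monocyte", {"CD45": "pos"}),
        # remainder (0.16) becomes the implicit CD45+ "other live cells"
    ]


def _panel2_populations() -> list[TruthPopulation]:
    return [
        TruthPopulation("Monocytes", 0.20, "monocyte", {"CD45": "pos", "CD14": "pos"}),
        TruthPopulation("T cells", 0.42, "lymphocyte", {"CD45": "pos", "CD3": "pos"}),
        TruthPopulation(
            "B cells", 0.10, "lymphocyte", {"CD45": "pos", "CD19": "pos", "CD20": "pos"}
        ),
        TruthPopulation("NK", 0.10, "lymphocyte", {"CD45": "pos", "CD56": "pos"}),
        TruthPopulation(
            "NKT", 0.03, "lymphocyte", {"CD45": "pos", "CD3": "pos", "CD56": "pos"}
        ),
        TruthPopulation("pDC", 0.01, "lymphocyte", {"CD45": "pos", "CD123": "pos"}),
        TruthPopulation("mDC", 0.02, "lymphocyte", {"CD45": "pos", "CD11c": "pos"}),
        # remainder (0.12) -> implicit other
    ]


def _default_activation_effects(panel_id: int) -> dict:
    if panel_id == 1:
        lymph = ["B cells", "Naive CD8 T", "Memory CD8 T", "CD4 T conv", "Treg"]
        return {
            "LPS/PHA-M": {
                p: {"CD25": ActivationEffect(0.30, 0.3), "CD154": ActivationEffect(0.10, 0.2)}
                for p in lymph
            },
            "PMA/Ionomycin": {
                p: {"CD25": ActivationEffect(0.40, 0.5), "CD154": ActivationEffect(0.35, 0.5)}
                for p in lymph
            },
        }
    myeloid = ["Monocytes", "pDC", "mDC", "NK"]
    return {
        "ODN2216/PHA-M": {
            p: {"CD54": ActivationEffect(0.30, 0.4), "CD69": ActivationEffect(0.40, 0.4)}
            for p in myeloid
        },
    }


def default_spec(panel_id: int = 1, n_events: int = 100_000, seed: int = 0,
                 **overrides) -> SyntheticSpec:
    """Default synthetic experiment for one of the built-in panels.

    Population fractions approximate a healthy-donor PBMC composition;
    the positive-control conditions carry clearly separable activation
    shifts on the panel's activation markers. ``n_events`` defaults to
    100,000 (scaled down from the instrument's >=500,000 acquisition
    target to desk scale).
    """
    pops = _panel1_populations() if panel_id == 1 else _panel2_populations()
    spec = SyntheticSpec(
        panel_id=panel_id,
        populations=pops,
        activation_effects=_default_activation_effects(panel_id),
        n_events=n_events,
        seed=seed,
    )
    spec = replace(spec, **overrides)
    validate_spec(spec)
    return spec


# --------------------------------------------------------------------------
# deterministic substreams
# --------------------------------------------------------------------------


def _substream(seed: int, *key) -> np.random.Generator:
    """Stable per-sample RNG: hash of the key, independent of call order."""
    digest = hashlib.sha256("|".join(str(k) for k in key).encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") % (2**31) for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *words]))


# --------------------------------------------------------------------------
# core sample generator
# --------------------------------------------------------------------------


def _donor_effects(spec: SyntheticSpec, donor: str, pop_names: list[str],
                   markers: list[str]):
    rng = _substream(spec.seed, "donor", spec.panel_id, donor)
    frac_factor = np.exp(rng.normal(0.0, spec.donor_effect_sd, size=len(pop_names)))
    expr_factor = np.exp(rng.normal(0.0, spec.donor_expression_sd, size=len(markers)))
    return dict(zip(pop_names, frac_factor)), dict(zip(markers, expr_factor))


def _stained_markers(stain_type: str, panel: PanelDefinition) -> set[str]:
    """Markers whose antibody is actually present in a given stain type."""
    all_markers = {c.marker for c in panel.channels if c.marker != "Viability"}
    base, _, arg = stain_type.partition(":")
    if base == "fully-stained":
        return all_markers
    if base in ("isotype", "unstained"):
        return set()
    if base == "single-stain":
        marker = next(c.marker for c in panel.channels if c.detector == arg)
        return {marker} if marker != "Viability" else set()
    if base == "FMO":
        omitted = next(c.marker for c in panel.channels if c.detector == arg)
        return all_markers - {omitted}
    raise ValueError(f"unknown stain_type {stain_type!r}")


def _has_viability_dye(stain_type: str, panel: PanelDefinition) -> bool:
    base, _, arg = stain_type.partition(":")
    if base == "unstained":
        return False
    if base == "single-stain":
        return arg == panel.viability_detector
    if base == "FMO":
        return arg != panel.viability_detector
    return True


def simulate_sample(spec: SyntheticSpec, metadata: SampleMetadata) -> EventMatrix:
    """Draw one sample. Deterministic given (spec, metadata).

    The underlying cell draw (labels, scatter, dead flags, activation
    states) is keyed by (donor, condition, replicate) only, so the
    fully-stained sample and its matched isotype/FMO controls see the
    same cells; only the staining signal differs.
    """
    validate_spec(spec)
    panel = spec.panel()
    markers = [c.marker for c in panel.channels if c.marker != "Viability"]

    pops = list(spec.populations)
    rem = 1.0 - sum(p.fraction for p in pops)
    if rem > 1e-9:
        pops.append(TruthPopulation("Other live", rem, "lymphocyte", {"CD45": "pos"}))
    pop_names = [p.name for p in pops]
    frac_fx, expr_fx = _donor_effects(spec, metadata.donor_id, pop_names, markers)
    fracs = np.array([p.fraction * frac_fx[p.name] for p in pops])
    fracs = fracs / fracs.sum()

    cells = _substream(
        spec.seed, "cells", spec.panel_id, metadata.donor_id, metadata.condition,
        metadata.replicate_index,
    )

    n = spec.n_events
    n_debris = int(round(n * spec.debris_fraction))
    n_doublets = int(round(n * spec.doublet_fraction))
    n_singlets = n - n_debris - n_doublets
    n_cells = n_singlets + 2 * n_doublets  # doublets consume two cell draws

    pop_idx = cells.choice(len(pops), size=n_cells, p=fracs)
    is_dead = cells.random(n_cells) < spec.dead_fraction

    # scatter for cells
    fsc_a = np.empty(n_cells)
    ssc_a = np.empty(n_cells)
    for i, p in enumerate(pops):
        m = pop_idx == i
        mu_f, sd_f = spec.scatter_params[p.scatter]["FSC-A"]
        mu_s, sd_s = spec.scatter_params[p.scatter]["SSC-A"]
        fsc_a[m] = np.exp(cells.normal(mu_f, sd_f, m.sum()))
        ssc_a[m] = np.exp(cells.normal(mu_s, sd_s, m.sum()))
    fsc_h = fsc_a * np.clip(cells.normal(0.98, 0.04, n_cells), 0.5, 1.5)

    # activation states (latent; independent of stain type)
    cond_fx = spec.activation_effects.get(metadata.condition, {})
    act_state: dict[str, np.ndarray] = {}
    for marker in panel.activation_markers:
        p_pos = np.full(n_cells, spec.activation_base_fraction)
        for i, p in enumerate(pops):
            eff = cond_fx.get(p.name, {}).get(marker)
            if eff is not None:
                p_pos[pop_idx == i] = np.clip(
                    spec.activation_base_fraction + eff.delta_positive_fraction, 0, 1
                )
        act_state[marker] = cells.random(n_cells) < p_pos

    # viability dye (cell draw; shared across stains that carry the dye)
    mu_l, sd_l = spec.viability_params["live"]
    mu_d, sd_d = spec.viability_params["dead"]
    viab = np.where(
        is_dead,
        np.exp(cells.normal(mu_d, sd_d, n_cells)),
        np.exp(cells.normal(mu_l, sd_l, n_cells)),
    )

    # staining intensities (stain-type specific stream)
    stain = _substream(
        spec.seed, "stain", spec.panel_id, metadata.donor_id, metadata.condition,
        metadata.replicate_index, metadata.stain_type,
    )
    stained = _stained_markers(metadata.stain_type, panel)
    mu_neg, sd_neg = spec.expression_params["neg"]
    marker_signal = np.empty((n_cells, len(markers)))
    for j, marker in enumerate(markers):
        if marker not in stained:
            marker_signal[:, j] = np.exp(stain.normal(mu_neg, sd_neg, n_cells))
            continue
        log_mu = np.full(n_cells, mu_neg)
        log_sd = np.full(n_cells, sd_neg)
        for i, p in enumerate(pops):
            state = p.markers.get(marker)
            if state is not None:
                mu_s, sd_s = spec.expression_params[state]
                sel = pop_idx == i
                log_mu[sel] = mu_s + (np.log(expr_fx[marker]) if state == "pos" else 0.0)
                log_sd[sel] = sd_s
        if marker in act_state:
            mu_pos, sd_pos = spec.expression_params["pos"]
            shift = np.zeros(n_cells)
            for i, p in enumerate(pops):
                eff = cond_fx.get(p.name, {}).get(marker)
                if eff is not None:
                    shift[pop_idx == i] = eff.log_shift
            pos = act_state[marker]
            log_mu[pos] = mu_pos + np.log(expr_fx[marker]) + shift[pos]
            log_sd[pos] = sd_pos
        marker_signal[:, j] = np.exp(stain.normal(log_mu, log_sd))

    if not _has_viability_dye(metadata.stain_type, panel):
        viab = np.exp(stain.normal(mu_neg, sd_neg, n_cells))

    # assemble singlets / doublets / debris
    sl = slice(0, n_singlets)
    d1 = slice(n_singlets, n_singlets + n_doublets)
    d2 = slice(n_singlets + n_doublets, n_cells)

    det_cols = panel.detectors
    viab_det = panel.viability_detector
    fl_cells = pd.DataFrame(index=range(n_cells), columns=det_cols, dtype=float)
    for j, marker in enumerate(markers):
        fl_cells[panel.detector_for_marker(marker)] = marker_signal[:, j]
    fl_cells[viab_det] = viab

    fl = np.vstack(
        [
            fl_cells.values[sl],
            fl_cells.values[d1] + fl_cells.values[d2],
            np.exp(stain.normal(mu_neg, sd_neg, (n_debris, len(det_cols)))),
        ]
    )
    scatter = np.empty((n, 3))
    scatter[:n_singlets, 0] = fsc_a[sl]
    scatter[:n_singlets, 1] = fsc_h[sl]
    scatter[:n_singlets, 2] = ssc_a[sl]
    scatter[n_singlets : n_singlets + n_doublets, 0] = fsc_a[d1] + fsc_a[d2]
    scatter[n_singlets : n_singlets + n_doublets, 1] = 0.6 * (fsc_h[d1] + fsc_h[d2])
    scatter[n_singlets : n_singlets + n_doublets, 2] = ssc_a[d1] + ssc_a[d2]
    mu_f, sd_f = spec.scatter_params["debris"]["FSC-A"]
    mu_s, sd_s = spec.scatter_params["debris"]["SSC-A"]
    deb_f = np.exp(cells.normal(mu_f, sd_f, n_debris))
    scatter[n - n_debris :, 0] = deb_f
    scatter[n - n_debris :, 1] = deb_f * np.clip(cells.normal(0.98, 0.04, n_debris), 0.5, 1.5)
    scatter[n - n_debris :, 2] = np.exp(cells.normal(mu_s, sd_s, n_debris))

    labels = np.concatenate(
        [
            np.array(pop_names, dtype=object)[pop_idx[sl]],
            np.full(n_doublets, "doublet", dtype=object),
            np.full(n_debris, "debris", dtype=object),
        ]
    )
    dead = np.concatenate(
        [is_dead[sl], np.zeros(n_doublets, bool), np.zeros(n_debris, bool)]
    )
    truth = pd.DataFrame({"population": labels, "is_dead": dead})
    for marker, st in act_state.items():
        truth[f"act_{marker}"] = np.concatenate(
            [st[sl], np.zeros(n_doublets, bool), np.zeros(n_debris, bool)]
        )

    sample = EventMatrix(
        metadata,
        pd.DataFrame(scatter, columns=SCATTER_COLUMNS),
        pd.DataFrame(fl, columns=det_cols),
        truth,
    )
    if spec.spillover is not None:
        sample = apply_spillover(sample, spec.spillover)
    return sample


def simulate_cohort(
    spec: SyntheticSpec,
    n_donors: int,
    conditions: Sequence[str],
    n_replicates: int,
    stain_types: Sequence[str] = ("fully-stained", "isotype"),
) -> list[EventMatrix]:
    """Simulate a full cohort: donors x conditions x replicates x stains."""
    validate_spec(spec)
    if n_donors < 1 or n_replicates < 1:
        raise ValueError("n_donors and n_replicates must be >= 1")
    out = []
    for d in range(1, n_donors + 1):
        for cond in conditions:
            for rep in range(1, n_replicates + 1):
                for stain in stain_types:
                    md = SampleMetadata(f"D{d}", cond, stain, rep, spec.panel_id)
                    out.append(simulate_sample(spec, md))
    return out


def simulate_single_stains(
    spec: SyntheticSpec, n_events: int | None = None
) -> dict[str, EventMatrix]:
    """One single-stain control per panel detector (bead-style 50/50 pos/neg).

    Half the events carry positive signal on the stained detector, all
    other channels carry background; used to estimate spillover.
    """
    panel = spec.panel()
    n = n_events or min(spec.n_events, 25_000)
    mu_neg, sd_neg = spec.expression_params["neg"]
    mu_pos, sd_pos = spec.expression_params["pos"]
    out = {}
    for det in panel.detectors:
        rng = _substream(spec.seed, "single-stain", spec.panel_id, det)
        fl = np.exp(rng.normal(mu_neg, sd_neg, (n, len(panel.detectors))))
        j = panel.detectors.index(det)
        pos = np.zeros(n, bool)
        pos[: n // 2] = True
        fl[pos, j] = np.exp(rng.normal(mu_pos, sd_pos, pos.sum()))
        fsc = np.exp(rng.normal(*spec.scatter_params["lymphocyte"]["FSC-A"], n))
        ssc = np.exp(rng.normal(*spec.scatter_params["lymphocyte"]["SSC-A"], n))
        md = SampleMetadata("beads", "Unstimulated", f"single-stain:{det}", 1, spec.panel_id)
        em = EventMatrix(
            md,
            pd.DataFrame({"FSC-A": fsc, "FSC-H": fsc * 0.98, "SSC-A": ssc}),
            pd.DataFrame(fl, columns=panel.detectors),
        )
        if spec.spillover is not None:
            em = apply_spillover(em, spec.spillover)
        out[det] = em
    return out


def simulate_unstained(
    spec: SyntheticSpec,
    donor_id: str = "D1",
    condition: str = "Unstimulated",
    replicate_index: int = 1,
) -> EventMatrix:
    md = SampleMetadata(donor_id, condition, "unstained", replicate_index, spec.panel_id)
    return simulate_sample(spec, md)


# --------------------------------------------------------------------------
# forward models applied to existing samples
# --------------------------------------------------------------------------


def apply_spillover(sample: EventMatrix, S: "SpilloverMatrix") -> EventMatrix:
    """Forward spillover: observed = true @ S (what compensation undoes)."""
    from cytopanel.controls import SpilloverMatrix  # noqa: F401 (type only)

    if list(S.detectors) != sample.detectors:
        if set(S.detectors) != set(sample.detectors):
            raise ValueError("spillover matrix detectors do not match sample")
        S = S.reorder(sample.detectors)
    observed = sample.fluorescence.values @ S.matrix
    out = sample.copy()
    out.fluorescence = pd.DataFrame(
        observed, columns=sample.detectors, index=sample.fluorescence.index
    )
    return out


def simulate_interfering_drug(
    sample: EventMatrix,
    channel_gains: Mapping[str, float],
    concentration: float,
    seed: int = 0,
) -> EventMatrix:
    """Add intrinsic drug fluorescence to the listed detectors.

    Models a formulation whose chromophore (e.g. an anthracycline)
    fluoresces into specific detectors: each event gains
    ``gain * concentration * L`` with a per-event log-normal loading L,
    leaving scatter and unlisted channels untouched.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    out = sample.copy()
    if concentration == 0:
        return out
    rng = _substream(seed, "drug", sample.metadata.sample_id)
    loading = np.exp(rng.normal(0.0, 0.5, sample.n_events))
    for det, gain in channel_gains.items():
        if det not in out.fluorescence.columns:
            raise KeyError(f"unknown detector {det!r}")
        out.fluorescence[det] = out.fluorescence[det].values + gain * concentration * loading
    return out


# --------------------------------------------------------------------------
# dose arithmetic
# --------------------------------------------------------------------------


def final_concentration(stock: float, mrd: float) -> float:
    """In-assay concentration after dilution at the minimal required dilution."""
    if mrd < 1:
        raise ValueError("mrd must be >= 1")
    return stock / mrd


def serial_dilution_factors(fold: float, steps: int) -> list[float]:
    """Cumulative dilution factors of a serial titration: [1, fold, ..., fold**steps]."""
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    return [float(fold) ** k for k in range(steps + 1)]


# --------------------------------------------------------------------------
# ground truth helpers
# --------------------------------------------------------------------------


def truth_population_fractions(
    spec: SyntheticSpec, panel: PanelDefinition | None = None
) -> dict[str, float]:
    """Expected percent-of-live (as fractions) for each panel population.

    Evaluates each truth population's marker profile against the panel's
    gate paths: a threshold-positive gate requires the "pos" state, a
    threshold-negative or threshold-low gate requires "neg"/"low", and
    scatter-region branches require the matching morphology class.
    """
    panel = panel or spec.panel()
    pops = _with_other(spec)
    return {
        rule.name: sum(tp.fraction for tp in pops if _rule_accepts(panel, rule, tp))
        for rule in panel.populations
    }


def _with_other(spec: SyntheticSpec) -> list[TruthPopulation]:
    pops = list(spec.populations)
    rem = 1.0 - sum(p.fraction for p in pops)
    if rem > 1e-9:
        pops.append(TruthPopulation("Other live", rem, "lymphocyte", {"CD45": "pos"}))
    return pops


def _rule_accepts(panel: PanelDefinition, rule, tp: TruthPopulation) -> bool:
    """Would an (idealized) event of truth population ``tp`` satisfy ``rule``?"""
    marker_of = {c.detector: c.marker for c in panel.channels}
    for gid in rule.path:
        g = panel.gate_tree[gid]
        if g.kind == "scatter-region" and g.region in ("monocyte", "lymphocyte"):
            if tp.scatter != g.region:
                return False
        elif g.kind in THRESHOLD_KINDS:
            state = tp.markers.get(marker_of[g.channels[0]], "neg")
            if g.kind == "threshold-positive" and state != "pos":
                return False
            if g.kind in ("threshold-negative", "threshold-low") and state == "pos":
                return False
    return True


def truth_pct_of_live(
    sample: EventMatrix, spec: SyntheticSpec, panel: PanelDefinition | None = None
) -> dict[str, float]:
    """Per-sample ground-truth percent-of-live from the stored truth labels.

    The denominator is live singlet cells (debris, doublets and dead
    cells excluded); the numerator counts events whose truth population
    profile satisfies the panel rule. This is the oracle gating results
    are scored against.
    """
    if sample.truth is None:
        raise ValueError("sample carries no truth labels")
    panel = panel or spec.panel()
    labels = sample.truth["population"].values
    live = (~sample.truth["is_dead"].values) & ~np.isin(labels, ("debris", "doublet"))
    n_live = int(live.sum())
    out = {}
    for rule in panel.populations:
        accepted = {tp.name for tp in _with_other(spec) if _rule_accepts(panel, rule, tp)}
        out[rule.name] = 100.0 * np.isin(labels, list(accepted))[live].sum() / max(n_live, 1)
    return out


def truth_activation_fractions(
    spec: SyntheticSpec, condition: str
) -> dict[str, dict[str, float]]:
    """True activation-marker-positive fraction per truth population."""
    panel = spec.panel()
    cond_fx = spec.activation_effects.get(condition, {})
    out: dict[str, dict[str, float]] = {}
    for p in spec.populations:
        out[p.name] = {}
        for marker in panel.activation_markers:
            eff = cond_fx.get(p.name, {}).get(marker)
            base = spec.activation_base_fraction
            out[p.name][marker] = float(
                np.clip(base + (eff.delta_positive_fraction if eff else 0.0), 0, 1)
            )
    return out
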