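"""End-to-end orchestration: compensate, gate, derive readouts, test.

`run_pipeline` ties the stages together for one cohort of one panel:

1. compensation of every stained sample (given or estimated spillover),
2. isotype-threshold fitting, condition-matched: the isotype control of
   the same (donor, condition) sets the gates for that condition's
   stained samples,
3. gate-tree execution per fully-stained sample,
4. stimulation-index table vs the unstimulated/vehicle reference,
5. negative-control reproducibility (Pearson + complete linkage) and the
   paired-t + exhaustive sign-flip permutation analysis.

No sample is silently dropped: anything that cannot be processed lands
in the exclusion log with a reason.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cytopanel import __version__
from cytopanel.controls import SpilloverMatrix, compensate
from cytopanel.gating import (
    GateStats,
    GatingConfig,
    ThresholdSet,
    apply_gate_tree,
    fit_isotype_thresholds,
)
from cytopanel.panel_model import PanelDefinition
from cytopanel.readouts import assemble_si_tables, endpoint_values, replicate_averaged
from cytopanel.stats import (
    ControlCorrelation,
    PermutationResult,
    control_correlation,
    permutation_analysis,
)
from cytopanel.synthetic import EventMatrix

_CSV_FLOAT = "%.10g"


@dataclass
class PipelineConfig:
    """Run configuration; YAML round-trippable."""

    gating: GatingConfig = field(default_factory=GatingConfig)
    default_reference: str = "Unstimulated"
    # treatment condition -> its vehicle/reference condition
    reference_rule: dict[str, str] = field(default_factory=dict)
    permutation_strict: bool = True
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "gating": asdict(self.gating),
            "default_reference": self.default_reference,
            "reference_rule": dict(self.reference_rule),
            "permutation_strict": self.permutation_strict,
            "alpha": self.alpha,
        }

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        gating = d.get("gating", {})
        for k in ("main_cells_trim", "singlet_ratio_band"):
            if k in gating:
                gating[k] = tuple(gating[k])
        return PipelineConfig(
            gating=GatingConfig(**gating),
            default_reference=d.get("default_reference", "Unstimulated"),
            reference_rule=dict(d.get("reference_rule", {})),
            permutation_strict=bool(d.get("permutation_strict", True)),
            alpha=float(d.get("alpha", 0.05)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @staticmethod
    def load(path: str | Path) -> "PipelineConfig":
        return PipelineConfig.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    gate_stats: list[GateStats]
    si_table: pd.DataFrame
    permutation_results: list[PermutationResult]
    pooled_null: list[float]
    control_correlation: ControlCorrelation | None
    thresholds: dict[str, ThresholdSet]
    exclusions: list[dict]

    def permutation_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.permutation_results:
            rows.append(
                {
                    "treatment": r.treatment,
                    "endpoint": r.endpoint,
                    "n_pairs": r.n_pairs,
                    "included": r.included,
                    "real_t": r.real_t,
                    "real_p": r.real_p,
                    "n_permutations": len(r.permuted_ps),
                    "n_below": r.n_below,
                    "perm_p": r.perm_p,
                }
            )
        return pd.DataFrame(rows)

    def gate_stats_frame(self) -> pd.DataFrame:
        frames = []
        for gs in self.gate_stats:
            f = gs.populations.copy()
            f.insert(0, "sample_id", gs.sample_id)
            f.insert(1, "donor_id", gs.metadata.donor_id)
            f.insert(2, "condition", gs.metadata.condition)
            f.insert(3, "replicate_index", gs.metadata.replicate_index)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def run_pipeline(
    samples: list[EventMatrix],
    panel: PanelDefinition,
    config: PipelineConfig | None = None,
    spillover: SpilloverMatrix | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on an in-memory cohort.

    ``samples`` must contain, per (donor, condition, replicate), a
    fully-stained sample and (per donor and condition) at least one
    isotype control; the isotype of the matching condition sets the
    thresholds, as activated samples must be gated against activated
    isotype controls.
    """
    config = config or PipelineConfig()
    exclusions: list[dict] = []

    stained: dict[tuple, EventMatrix] = {}
    isotypes: dict[tuple, EventMatrix] = {}
    for s in samples:
        md = s.metadata
        if md.panel_id != panel.panel_id:
            exclusions.append(
                {"sample_id": md.sample_id, "reason": "panel mismatch"}
            )
            continue
        if spillover is not None and md.stain_type in ("fully-stained", "isotype"):
            s = compensate(s, spillover)
        key = (md.donor_id, md.condition, md.replicate_index)
        if md.stain_type == "fully-stained":
            stained[key] = s
        elif md.stain_type == "isotype":
            isotypes[key] = s
        else:
            exclusions.append(
                {"sample_id": md.sample_id,
                 "reason": f"stain type {md.stain_type!r} not used by this stage"}
            )

    # condition-matched isotype thresholds (replicate-matched when present)
    thresholds: dict[str, ThresholdSet] = {}
    gate_stats: list[GateStats] = []
    for key, sample in sorted(stained.items()):
        donor, condition, rep = key
        iso = isotypes.get(key)
        if iso is None:
            candidates = [
                v for (d, c, _r), v in isotypes.items() if d == donor and c == condition
            ]
            iso = candidates[0] if candidates else None
        if iso is None:
            exclusions.append(
                {"sample_id": sample.metadata.sample_id,
                 "reason": f"no condition-matched isotype control for "
                           f"({donor}, {condition})"}
            )
            continue
        ts = fit_isotype_thresholds(iso, panel, config=config.gating)
        thresholds[sample.metadata.sample_id] = ts
        gate_stats.append(apply_gate_tree(sample, panel, ts, config.gating))

    if not gate_stats:
        raise ValueError("no sample could be gated; see the exclusion log")

    si_table = assemble_si_tables(
        gate_stats,
        reference_rule=config.reference_rule,
        default_reference=config.default_reference,
    )

    # reproducibility of negative-control runs (one run = donor x replicate)
    control_corr = None
    ref_stats = [
        gs for gs in gate_stats if gs.metadata.condition == config.default_reference
    ]
    if len(ref_stats) >= 2:
        vectors = {}
        for gs in ref_stats:
            vec = list(gs.populations["pct_of_live"].values)
            vec += list(gs.quadrants["pct"].values)
            vectors[f"{gs.metadata.donor_id}_r{gs.metadata.replicate_index}"] = vec
        control_corr = control_correlation(vectors)

    # paired-t + permutation on replicate-averaged gate percentages
    avg = replicate_averaged(endpoint_values(gate_stats))
    pct = avg[avg["endpoint"].str.contains(r"\|pct_of_live|\|quad_")]
    references = set(config.reference_rule.values()) | {config.default_reference}
    conditions = sorted(pct["condition"].unique())
    tests = {}
    for treatment in (c for c in conditions if c not in references):
        ref = config.reference_rule.get(treatment, config.default_reference)
        for endpoint in sorted(pct["endpoint"].unique()):
            tr = pct[(pct["condition"] == treatment) & (pct["endpoint"] == endpoint)]
            co = pct[(pct["condition"] == ref) & (pct["endpoint"] == endpoint)]
            tests[(treatment, endpoint)] = (
                dict(zip(tr["donor"], tr["value"])),
                dict(zip(co["donor"], co["value"])),
            )
    if tests:
        perm_results, pooled = permutation_analysis(
            tests, strict=config.permutation_strict
        )
    else:
        perm_results, pooled = [], []

    result = PipelineResult(
        gate_stats=gate_stats,
        si_table=si_table,
        permutation_results=perm_results,
        pooled_null=pooled,
        control_correlation=control_corr,
        thresholds=thresholds,
        exclusions=exclusions,
    )
    if out_dir is not None:
        write_outputs(result, out_dir, config)
    return result


def write_outputs(
    result: PipelineResult, out_dir: str | Path, config: PipelineConfig
) -> None:
    """Write every stage's outputs plus a run log (config + version)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.gate_stats_frame().to_csv(
        out / "gate_stats.csv", index=False, float_format=_CSV_FLOAT
    )
    result.si_table.to_csv(out / "si_table.csv", index=False, float_format=_CSV_FLOAT)
    result.permutation_frame().to_csv(
        out / "permutation_results.csv", index=False, float_format=_CSV_FLOAT
    )
    pd.DataFrame({"permuted_p": result.pooled_null}).to_csv(
        out / "pooled_null.csv", index=False, float_format=_CSV_FLOAT
    )
    if result.control_correlation is not None:
        result.control_correlation.R.to_csv(
            out / "control_correlation.csv", float_format=_CSV_FLOAT
        )
    pd.DataFrame(result.exclusions, columns=["sample_id", "reason"]).to_csv(
        out / "exclusions.csv", index=False
    )
    thresholds = {sid: ts.to_dict() for sid, ts in result.thresholds.items()}
    (out / "thresholds.json").write_text(json.dumps(thresholds, indent=2, sort_keys=True))
    (out / "run_log.json").write_text(
        json.dumps(
            {"version": __version__, "config": config.to_dict(),
             "n_samples_gated": len(result.gate_stats),
             "n_exclusions": len(result.exclusions)},
            indent=2, sort_keys=True,
        )
    )
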