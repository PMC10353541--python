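"""Event-table and cohort manifest I/O.

Events are stored either as plain CSV (comma delimiter, "." decimal,
UTF-8; one column per channel) or as FCS 3.1. A cohort on disk is a
directory of event files plus ``manifest.csv`` (sample identity and
pairing) and, for synthetic cohorts, ``truth_fractions.csv`` with the
per-sample ground-truth population fractions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from cytopanel import fcs
from cytopanel.controls import SpilloverMatrix
from cytopanel.panel_model import PanelDefinition
from cytopanel.synthetic import (
    EventMatrix,
    SCATTER_COLUMNS,
    SampleMetadata,
    SyntheticSpec,
    truth_pct_of_live,
)

MANIFEST_COLUMNS = [
    "sample_id",
    "path",
    "donor_id",
    "condition",
    "stain_type",
    "replicate_index",
    "panel_id",
]

_CSV_FLOAT = "%.10g"


def events_to_frame(sample: EventMatrix) -> pd.DataFrame:
    return pd.concat([sample.scatter, sample.fluorescence], axis=1)


def write_events(sample: EventMatrix, path: str | Path,
                 spillover: SpilloverMatrix | None = None) -> None:
    """Write one sample's events as CSV or FCS (by file suffix)."""
    path = Path(path)
    frame = events_to_frame(sample)
    if path.suffix.lower() == ".fcs":
        extra = {}
        if spillover is not None:
            extra["$SPILLOVER"] = fcs.spillover_keyword(
                spillover.detectors, spillover.matrix
            )
        fcs.write_fcs(path, frame, extra)
    else:
        frame.to_csv(path, index=False, float_format=_CSV_FLOAT)


def read_events(
    path: str | Path,
    metadata: SampleMetadata | None = None,
    panel: PanelDefinition | None = None,
) -> tuple[EventMatrix, SpilloverMatrix | None]:
    """Read a CSV or FCS event table into an EventMatrix.

    When a panel is given, every panel detector must be present in the
    file; a missing channel raises an error naming it. An FCS
    ``$SPILLOVER`` keyword, when present, is returned alongside.
    """
    path = Path(path)
    spill = None
    if path.suffix.lower() == ".fcs":
        frame, keywords = fcs.read_fcs(path)
        if "$SPILLOVER" in keywords:
            dets, M = fcs.parse_spillover_keyword(keywords["$SPILLOVER"])
            spill = SpilloverMatrix(dets, M)
    else:
        frame = pd.read_csv(path)
    if panel is not None:
        missing = [d for d in panel.detectors if d not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing panel channels {missing}")
    scatter_cols = [c for c in SCATTER_COLUMNS if c in frame.columns]
    fl_cols = (
        panel.detectors if panel is not None
        else [c for c in frame.columns if c not in SCATTER_COLUMNS]
    )
    metadata = metadata or SampleMetadata("unknown", "Unstimulated", "fully-stained")
    em = EventMatrix(
        metadata,
        frame[scatter_cols].reset_index(drop=True),
        frame[fl_cols].reset_index(drop=True),
    )
    return em, spill


def write_cohort(
    samples: list[EventMatrix],
    outdir: str | Path,
    spec: SyntheticSpec | None = None,
    file_format: str = "csv",
) -> pd.DataFrame:
    """Write a cohort directory: event files + manifest (+ truth manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth_rows = []
    for s in samples:
        fname = f"{s.metadata.sample_id}.{file_format}"
        write_events(s, outdir / fname)
        rows.append(
            {
                "sample_id": s.metadata.sample_id,
                "path": fname,
                "donor_id": s.metadata.donor_id,
                "condition": s.metadata.condition,
                "stain_type": s.metadata.stain_type,
                "replicate_index": s.metadata.replicate_index,
                "panel_id": s.metadata.panel_id,
            }
        )
        if spec is not None and s.truth is not None:
            for pop, pct in truth_pct_of_live(s, spec).items():
                truth_rows.append(
                    {"sample_id": s.metadata.sample_id, "population": pop,
                     "true_pct_of_live": pct}
                )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    if truth_rows:
        pd.DataFrame(truth_rows).to_csv(
            outdir / "truth_fractions.csv", index=False, float_format=_CSV_FLOAT
        )
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(Path(path))
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    return manifest


def load_cohort(
    manifest_path: str | Path, panel: PanelDefinition | None = None
) -> list[EventMatrix]:
    """Load every sample named by a cohort manifest."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = read_manifest(manifest_path)
    samples = []
    for row in manifest.itertuples(index=False):
        p = base / row.path
        if not p.exists():
            raise FileNotFoundError(f"manifest entry {row.sample_id}: {p} does not exist")
        md = SampleMetadata(
            str(row.donor_id), row.condition, row.stain_type,
            int(row.replicate_index), int(row.panel_id),
        )
        em, _ = read_events(p, md, panel)
        samples.append(em)
    return samples
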