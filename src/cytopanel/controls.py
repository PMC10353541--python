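"""Control-sample computations.

Everything derived from the control taxonomy of a multicolor experiment:

* spillover estimation from single-stain controls and its inverse
  (compensation),
* stain index and optimal-dilution selection for antibody titration,
* a screen for intrinsic-fluorescence interference from test articles
  (drugs/nanoformulations) using treated vs untreated unstained cells,
* a fluorescence-minus-one (FMO) overlay diagnostic.

The spillover model is the standard linear one: ``observed = true @ S``
with ``S[i, j]`` the fraction of fluorophore *i*'s signal read in
detector *j* (unit diagonal). Compensation solves that linear system per
event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cytopanel.synthetic import EventMatrix


def robust_sd(values: np.ndarray) -> float:
    """1.4826 x median absolute deviation (consistent for a normal)."""
    values = np.asarray(values, float)
    return float(1.4826 * np.median(np.abs(values - np.median(values))))


@dataclass
class SpilloverMatrix:
    """Square fluorophore-into-detector leakage matrix, unit diagonal."""

    detectors: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        n = len(self.detectors)
        if self.matrix.shape != (n, n):
            raise ValueError("spillover matrix must be square over the detectors")

    def validate(self) -> None:
        if not np.allclose(np.diag(self.matrix), 1.0):
            raise ValueError("spillover diagonal must be 1")
        if (self.matrix < 0).any() or (self.matrix > 1).any():
            raise ValueError("spillover entries must lie in [0, 1]")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("spillover matrix is singular")

    @staticmethod
    def identity(detectors: Sequence[str]) -> "SpilloverMatrix":
        return SpilloverMatrix(list(detectors), np.eye(len(detectors)))

    def reorder(self, detectors: Sequence[str]) -> "SpilloverMatrix":
        idx = [self.detectors.index(d) for d in detectors]
        return SpilloverMatrix(list(detectors), self.matrix[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.detectors, columns=self.detectors)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.10g")

    @staticmethod
    def from_csv(path: str | Path) -> "SpilloverMatrix":
        df = pd.read_csv(path, index_col=0)
        return SpilloverMatrix(list(df.columns), df.values)


@dataclass
class TitrationCurve:
    """Stain index along a serial antibody-dilution series for one channel."""

    channel: str
    dilution_factors: list[float]
    stain_indices: list[float]

    def __post_init__(self):
        if len(self.dilution_factors) != len(self.stain_indices):
            raise ValueError("dilution_factors and stain_indices differ in length")
        d = np.asarray(self.dilution_factors, float)
        if (np.diff(d) <= 0).any():
            raise ValueError("dilution_factors must be strictly increasing")

    @property
    def optimal_dilution(self) -> float:
        return select_optimal_dilution(self)


@dataclass
class InterferenceReport:
    """Per-detector robust standardized median shift and interference flag."""

    detectors: list[str]
    scores: np.ndarray
    cutoff: float = 3.0

    @property
    def flags(self) -> np.ndarray:
        return self.scores >= self.cutoff

    def flagged_detectors(self) -> list[str]:
        return [d for d, f in zip(self.detectors, self.flags) if f]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"detector": self.detectors, "shift_score": self.scores, "flagged": self.flags}
        )


# --------------------------------------------------------------------------
# spillover estimation and compensation
# --------------------------------------------------------------------------


def estimate_spillover(
    single_stains: Mapping[str, EventMatrix],
    unstained: EventMatrix,
    split_quantile: float = 0.995,
    min_positive: int = 50,
) -> SpilloverMatrix:
    """Estimate spillover from one single-stain control per detector.

    For each stained fluorophore the events are split into positive and
    negative against the unstained background (``split_quantile`` of the
    background on the primary detector); the spillover into every other
    detector is the ratio of median shifts. Negative estimates are
    clipped to 0, the diagonal forced to 1.
    """
    detectors = unstained.detectors
    missing = [d for d in detectors if d not in single_stains]
    if missing:
        raise ValueError(f"missing single-stain controls for detectors: {missing}")
    S = np.eye(len(detectors))
    for i, det in enumerate(detectors):
        ss = single_stains[det]
        primary = ss.fluorescence[det].values
        cut = float(np.quantile(unstained.fluorescence[det].values, split_quantile))
        pos = primary > cut
        neg = ~pos
        if pos.sum() < min_positive or neg.sum() < min_positive:
            raise ValueError(
                f"no separable positive population on detector {det!r} "
                f"({int(pos.sum())} positive events)"
            )
        denom = np.median(primary[pos]) - np.median(primary[neg])
        if denom <= 0:
            raise ValueError(f"no separable positive population on detector {det!r}")
        for j, other in enumerate(detectors):
            if j == i:
                continue
            vals = ss.fluorescence[other].values
            num = np.median(vals[pos]) - np.median(vals[neg])
            S[i, j] = min(max(num / denom, 0.0), 1.0)
    return SpilloverMatrix(list(detectors), S)


def compensate(sample: EventMatrix, S: SpilloverMatrix) -> EventMatrix:
    """Undo spillover: solve ``observed = true @ S`` per event.

    Scatter channels and truth labels are untouched.
    """
    if list(S.detectors) != sample.detectors:
        if set(S.detectors) != set(sample.detectors):
            raise ValueError("spillover matrix detectors do not match sample")
        S = S.reorder(sample.detectors)
    if abs(np.linalg.det(S.matrix)) < 1e-12:
        raise np.linalg.LinAlgError("singular spillover matrix")
    true = np.linalg.solve(S.matrix.T, sample.fluorescence.values.T).T
    out = sample.copy()
    out.fluorescence = pd.DataFrame(
        true, columns=sample.detectors, index=sample.fluorescence.index
    )
    return out


# --------------------------------------------------------------------------
# titration
# --------------------------------------------------------------------------


def stain_index(
    stained: np.ndarray,
    negative: np.ndarray,
    split_quantile: float = 0.995,
    min_positive_fraction: float = 0.02,
) -> float:
    """Separation score between stained-positive and negative events.

    ``(median(positive) - median(negative)) / (2 * robust-SD(negative))``
    with robust-SD = 1.4826 x MAD. The positive component is the stained
    events above the ``split_quantile`` of the negative distribution; if
    fewer than ``min_positive_fraction`` of events land there the sample
    has no separable positive population and the whole stained sample is
    used (an unstained-like sample then scores ~0).

    Returns NaN (with a warning) when the negative spread is zero.
    """
    stained = np.asarray(stained, float)
    negative = np.asarray(negative, float)
    if stained.size == 0 or negative.size == 0:
        raise ValueError("stained and negative must be nonempty")
    rsd = robust_sd(negative)
    if rsd == 0:
        warnings.warn("zero robust-SD of the negative population; stain index undefined")
        return float("nan")
    cut = float(np.quantile(negative, split_quantile))
    pos = stained[stained > cut]
    if pos.size < min_positive_fraction * stained.size:
        pos = stained
    return float((np.median(pos) - np.median(negative)) / (2.0 * rsd))


def select_optimal_dilution(curve: TitrationCurve) -> float:
    """Dilution with the maximum stain index; ties go to the larger factor.

    A larger dilution factor means less antibody, so ties are broken
    toward reagent economy. Undefined (NaN) indices are ignored.
    """
    if len(curve.dilution_factors) < 2:
        raise ValueError("need at least 2 titration points")
    idx = np.asarray(curve.stain_indices, float)
    if np.isnan(idx).all():
        raise ValueError("all stain indices are undefined")
    best = np.nanmax(idx)
    candidates = [
        d for d, s in zip(curve.dilution_factors, idx) if not np.isnan(s) and s == best
    ]
    return float(max(candidates))


# --------------------------------------------------------------------------
# interference screen
# --------------------------------------------------------------------------


def interference_screen(
    treated_unstained: EventMatrix,
    untreated_unstained: EventMatrix,
    detectors: Sequence[str] | None = None,
    cutoff: float = 3.0,
) -> InterferenceReport:
    """Screen a test article for intrinsic-fluorescence interference.

    Compares unstained treated cells to unstained untreated cells:
    per detector, score = (median_treated - median_untreated) /
    robust-SD(untreated); detectors with score >= ``cutoff`` (default 3
    robust SDs) are flagged as unusable at that concentration.
    """
    detectors = list(detectors or untreated_unstained.detectors)
    scores = np.empty(len(detectors))
    for k, det in enumerate(detectors):
        ctrl = untreated_unstained.fluorescence[det].values
        rsd = robust_sd(ctrl)
        if rsd == 0:
            raise ValueError(f"zero robust-SD on control channel {det!r}")
        scores[k] = (
            np.median(treated_unstained.fluorescence[det].values) - np.median(ctrl)
        ) / rsd
    return InterferenceReport(detectors, scores, cutoff)


# --------------------------------------------------------------------------
# FMO overlay diagnostic
# --------------------------------------------------------------------------


def fmo_overlay_report(
    fully_stained: EventMatrix, fmo_samples: Mapping[str, EventMatrix]
) -> pd.DataFrame:
    """Per-channel overlay statistics of fully-stained vs FMO controls.

    The visual over/under-compensation check done with FMO overlays is a
    judgment call; this reports, per omitted channel, the FMO background
    quantiles and the fully-stained negative-fraction median so an
    analyst can review the compensation. It never edits the matrix.
    """
    rows = []
    for det, fmo in fmo_samples.items():
        bg = fmo.fluorescence[det].values
        full = fully_stained.fluorescence[det].values
        q995 = float(np.quantile(bg, 0.995))
        rows.append(
            {
                "detector": det,
                "fmo_median": float(np.median(bg)),
                "fmo_q995": q995,
                "full_median": float(np.median(full)),
                "full_fraction_above_fmo_q995": float((full > q995).mean()),
            }
        )
    return pd.DataFrame(rows)
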