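"""Carrier/noncarrier discrimination from Stage-1 top-% scores.

A *low* top-% (the candidate variant's H ranks near the top genome-wide) is
the carrier signal, so an individual is predicted to be a carrier when their
top-% falls *below* a threshold.  Sweeping the threshold over the observed
scores yields the ROC curve (sensitivity against 1 - specificity), its
trapezoidal area AUC, and the threshold maximizing the total probability of
a correct prediction.

The packaged reference dataset (:func:`load_reference_scores`) holds the
top-% scores of 9 known carriers and 8 noncarriers of dominant pathogenic
variants from sequenced families; on it the machinery reproduces AUC = 0.85
and the operating rule "call a candidate a true positive when its top-% is
below ~21" (sensitivity 0.889, specificity 0.750).  That rule is an estimate
from n = 17 individuals and should be treated accordingly.
"""
from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path

import numpy as np

from ._util import round_half_up

__all__ = [
    "LabeledScore",
    "ClassifyResult",
    "ROCResult",
    "classify",
    "roc_curve",
    "read_scores_tsv",
    "load_reference_scores",
    "RECOMMENDED_TOP_PCT_CUT",
    "RECOMMENDED_CUT_SENSITIVITY",
    "RECOMMENDED_CUT_SPECIFICITY",
]

#: Operating rule estimated from the packaged 17-individual reference set:
#: predict carrier when the candidate variant's top-% is smaller than this.
RECOMMENDED_TOP_PCT_CUT = 21.0
RECOMMENDED_CUT_SENSITIVITY = 0.889
RECOMMENDED_CUT_SPECIFICITY = 0.750


@dataclasses.dataclass(frozen=True)
class LabeledScore:
    """One individual's top-% score with carrier label 'C' or 'N'."""

    id: str
    top_pct: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in ("C", "N"):
            raise ValueError(f"label must be 'C' or 'N', got {self.label!r}")
        if not 0.0 < self.top_pct <= 100.0:
            raise ValueError(f"top_pct must be in (0, 100], got {self.top_pct}")


@dataclasses.dataclass(frozen=True)
class ClassifyResult:
    sensitivity: float
    specificity: float
    total_correct: float
    tp: int
    fp: int
    tn: int
    fn: int


def _split(scores: list[LabeledScore]) -> tuple[np.ndarray, np.ndarray]:
    s = np.array([x.top_pct for x in scores], dtype=float)
    y = np.array([x.label == "C" for x in scores], dtype=bool)
    if y.all() or not y.any():
        raise ValueError("need at least one carrier and one noncarrier")
    return s, y


def classify(scores: list[LabeledScore], threshold: float) -> ClassifyResult:
    """Confusion-matrix summary at one threshold (carrier iff top-% < threshold).

    A non-positive threshold degenerates to predicting everyone a
    noncarrier, which is a valid ROC endpoint.
    """
    s, y = _split(scores)
    pred = s < threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    return ClassifyResult(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        total_correct=(tp + tn) / len(s),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


@dataclasses.dataclass(frozen=True)
class ROCResult:
    """ROC points from (0,0) to (1,1), trapezoidal AUC and best operating cut.

    ``best_threshold`` is an observed top-% value; the corresponding rule is
    "predict carrier when top-% <= best_threshold" (equivalently, a strict
    cut placed just above it).
    """

    points: np.ndarray  # (k, 2) of (fpr, tpr)
    auc: float
    best_threshold: float
    best_sens: float
    best_spec: float
    best_total: float

    def to_tsv(self, path: str | Path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            fh.write("fpr\ttpr\n")
            for x, y in self.points:
                fh.write(f"{x:.6f}\t{y:.6f}\n")

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "best_threshold": self.best_threshold,
            "best_sens": self.best_sens,
            "best_spec": self.best_spec,
            "best_total": self.best_total,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=1)


def roc_curve(scores: list[LabeledScore]) -> ROCResult:
    """ROC curve over thresholds placed just above each observed score.

    Predicting carrier for ``top_pct <= v`` for each distinct observed value
    ``v`` (plus the predict-nobody endpoint) sweeps every achievable
    confusion matrix; the exact epsilon of a strict cut never changes one.
    AUC is the trapezoidal area, which on this staircase equals the
    Mann-Whitney concordance probability with half-credit for ties.  The
    best cut maximizes total correct predictions, ties resolved toward
    higher specificity, then toward the smaller cut.
    """
    s, y = _split(scores)
    n_c = int(y.sum())
    n_n = int((~y).sum())
    cuts = np.unique(s)
    pts = [(0.0, 0.0)]  # threshold below every score: nobody predicted carrier
    best = None
    for v in cuts:
        pred = s <= v
        tpr = float(np.sum(pred & y)) / n_c
        fpr = float(np.sum(pred & ~y)) / n_n
        total = (np.sum(pred & y) + np.sum(~pred & ~y)) / len(s)
        if pts[-1] != (fpr, tpr):
            pts.append((fpr, tpr))
        key = (total, 1.0 - fpr, -v)  # prefer higher specificity, then smaller cut
        if best is None or key > best[0]:
            best = (key, v, tpr, 1.0 - fpr, float(total))
    points = np.array(pts)
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    assert best is not None
    return ROCResult(
        points=points,
        auc=auc,
        best_threshold=float(best[1]),
        best_sens=best[2],
        best_spec=best[3],
        best_total=best[4],
    )


def read_scores_tsv(path: str | Path) -> list[LabeledScore]:
    """Read id/top_pct/label rows from a TSV ('#' lines are comments)."""
    out: list[LabeledScore] = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                expected = ["id", "top_pct", "label"]
                if [p.lower() for p in parts] != expected:
                    raise ValueError(f"expected columns {expected}, got {parts}")
                continue
            out.append(LabeledScore(parts[0], float(parts[1]), parts[2]))
    if not out:
        raise ValueError(f"no score rows in {path}")
    return out


def load_reference_scores() -> list[LabeledScore]:
    """The packaged 17-individual reference carrier/noncarrier score set."""
    ref = resources.files("hetscan.data").joinpath("carrier_scores.tsv")
    with resources.as_file(ref) as path:
        return read_scores_tsv(path)


def display_pct(x: float) -> float:
    """One-decimal half-up rounding used in report tables."""
    return round_half_up(x, 1)
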