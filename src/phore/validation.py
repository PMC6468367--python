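"""Pharmacophore validation: decoy-set (Güner-Henry) statistics and ROC.

The decoy-set method screens a database of D molecules containing A known
actives; the model retrieves Ht hits of which Ha are active.  Derived
statistics:

* % yield of actives      = 100 * Ha / Ht
* % ratio of actives      = 100 * Ha / A
* enrichment factor  EF   = (Ha * D) / (Ht * A)  ==  (Ha/Ht) / (A/D)
* goodness of fit    GF   = [Ha * (3A + Ht) / (4 * Ht * A)] * [1 - (Ht - Ha)/(D - A)]

The GF numerator is typeset ambiguously in the literature this implements:
with (3A + Ht) the worked example (D=720, A=24, Ht=26, Ha=23) evaluates to
0.8992, while the published table prints 0.87 — which the (3Ha + Ht)
variant reproduces exactly (0.8716 -> 0.87).  Both variants are computed and
reported (``GF_eq`` as-printed-in-the-equation, ``GF_alt`` matching the
printed table value); the discrepancy is surfaced, never silently resolved.

Display conventions match the published table: yield floored to an integer,
ratio truncated to 1 decimal, EF truncated to 2 decimals, GF rounded to 2
decimals.  Raw full-precision values are always retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .pharmacophore import PharmacophoreModel
from .screening import ScreeningLibrary, screen_library

__all__ = [
    "DecoySetCounts",
    "ValidationReport",
    "RocPoint",
    "UndefinedMetricError",
    "gh_metrics",
    "roc_curve",
    "validate_model",
]


class UndefinedMetricError(ValueError):
    """A decoy-set denominator (Ht, A, or D - A) is zero."""


@dataclass(frozen=True)
class DecoySetCounts:
    """The four confusion counts of decoy-set validation."""

    D: int  # total molecules in the database
    A: int  # known actives in the database
    Ht: int  # hits retrieved
    Ha: int  # actives among the hits

    def __post_init__(self) -> None:
        for name in ("D", "A", "Ht", "Ha"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.A > self.D:
            raise ValueError("A cannot exceed D")
        if self.Ht > self.D:
            raise ValueError("Ht cannot exceed D")
        if self.Ha > min(self.Ht, self.A):
            raise ValueError("Ha cannot exceed min(Ht, A)")


def _truncate(x: float, decimals: int) -> float:
    f = 10**decimals
    return math.floor(x * f + 1e-12) / f


@dataclass
class ValidationReport:
    counts: DecoySetCounts
    yield_pct: float
    ratio_pct: float
    EF: float
    GF_eq: float
    GF_alt: float
    FN: int
    FP: int
    auc: Optional[float] = None
    display: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "D": self.counts.D,
            "A": self.counts.A,
            "Ht": self.counts.Ht,
            "Ha": self.counts.Ha,
            "yield_pct": self.yield_pct,
            "ratio_pct": self.ratio_pct,
            "EF": self.EF,
            "GF_eq": self.GF_eq,
            "GF_alt": self.GF_alt,
            "FN": self.FN,
            "FP": self.FP,
            "auc": self.auc,
            "display": dict(self.display),
            "notes": list(self.notes),
        }
        return d


def gh_metrics(counts: DecoySetCounts) -> ValidationReport:
    """Güner-Henry decoy-set statistics with table-style display values."""
    D, A, Ht, Ha = counts.D, counts.A, counts.Ht, counts.Ha
    if Ht == 0:
        raise UndefinedMetricError("Ht = 0: yield, EF and GF denominators undefined")
    if A == 0:
        raise UndefinedMetricError("A = 0: ratio, EF and GF denominators undefined")
    if D == A:
        raise UndefinedMetricError("D = A: the GF decoy term divides by D - A = 0")
    yield_pct = 100.0 * Ha / Ht
    ratio_pct = 100.0 * Ha / A
    ef = (Ha * D) / (Ht * A)
    decoy_term = 1.0 - (Ht - Ha) / (D - A)
    gf_eq = (Ha * (3 * A + Ht) / (4.0 * Ht * A)) * decoy_term
    gf_alt = (Ha * (3 * Ha + Ht) / (4.0 * Ht * A)) * decoy_term
    display = {
        "yield_pct": int(math.floor(yield_pct + 1e-12)),
        "ratio_pct": _truncate(ratio_pct, 1),
        "EF": _truncate(ef, 2),
        "GF_eq": round(gf_eq, 2),
        "GF_alt": round(gf_alt, 2),
        "FN": A - Ha,
        "FP": Ht - Ha,
    }
    notes = []
    if display["GF_eq"] != display["GF_alt"]:
        notes.append(
            "GF numerator variants disagree at display precision: "
            f"(3A+Ht) gives {gf_eq:.4f} -> {display['GF_eq']:.2f} while "
            f"(3Ha+Ht) gives {gf_alt:.4f} -> {display['GF_alt']:.2f}; "
            "the published worked example matches the (3Ha+Ht) variant."
        )
    return ValidationReport(
        counts=counts,
        yield_pct=yield_pct,
        ratio_pct=ratio_pct,
        EF=ef,
        GF_eq=gf_eq,
        GF_alt=gf_alt,
        FN=A - Ha,
        FP=Ht - Ha,
        display=display,
        notes=notes,
    )


@dataclass(frozen=True)
class RocPoint:
    fpr: float
    tpr: float
    threshold: float


def roc_curve(
    scores: Sequence[float], labels: Sequence[bool]
) -> tuple[list[RocPoint], float]:
    """Threshold-sweep ROC curve and trapezoidal AUC.

    The trapezoidal area equals the Mann-Whitney pair statistic with ties
    counted 1/2.  Requires at least one active and one inactive.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("scores and labels differ in length")
    if y.all() or (~y).all():
        raise ValueError("ROC needs at least one active and one inactive")
    fpr, tpr, thresh = _sk_roc_curve(y.astype(int), s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    points = [RocPoint(float(f), float(t), float(th)) for f, t, th in zip(fpr, tpr, thresh)]
    return points, auc


def validate_model(
    model: PharmacophoreModel, dataset: ScreeningLibrary
) -> ValidationReport:
    """Screen a labeled library and derive the full decoy-set report plus
    ROC AUC over the fit scores."""
    if not dataset.labeled:
        raise ValueError("validation requires an activity label on every record")
    scored, hits = screen_library(model, dataset)
    counts = DecoySetCounts(
        D=len(scored.records),
        A=sum(1 for r in scored.records if r.active),
        Ht=len(hits),
        Ha=sum(1 for r in hits if r.active),
    )
    report = gh_metrics(counts)
    _, auc = roc_curve(
        [r.score or 0.0 for r in scored.records],
        [bool(r.active) for r in scored.records],
    )
    report.auc = auc
    return report


def plot_roc(points: list[RocPoint], path, auc: Optional[float] = None) -> None:
    """Save a ROC curve figure (Agg backend; no display needed)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([p.fpr for p in points], [p.tpr for p in points], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if auc is not None:
        ax.set_title(f"ROC (AUC = {auc:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
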