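"""Binary-classifier evaluation: Sn, Sp, Acc, MCC, G-mean and the
pairwise-comparison AUC.

Counts follow the imbalanced-classification convention: N+ and N- are
the class sizes, fn the positives called negative, fp the negatives
called positive.  Then

    Sn  = 1 - fn / N+
    Sp  = 1 - fp / N-
    Acc = 1 - (fn + fp) / (N+ + N-)
    MCC = [1 - (fn/N+ + fp/N-)] /
          sqrt( (1 + (fp - fn)/N+) * (1 + (fn - fp)/N-) )
    G-mean = sqrt(Sn * Sp)
    AUC = #{(i, j) : score_i+ > score_j-} / (N+ * N-)

The MCC ratio form above is algebraically identical to the standard
four-product MCC.  A "strict" variant whose numerator is
1 - (fn + fp)/(N+ + N-) — i.e. the accuracy — is also provided; it is
NOT a valid MCC (it diverges from the standard formula on most
confusion tables) and exists only for auditing against legacy reports
that printed it.

The pairwise AUC scores ties as 0 by default; ``tie_correction=True``
scores them 0.5, which recovers the conventional rank-statistic AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DISPLAY_DECIMALS = 4

METRIC_ORDER = ["sn", "sp", "acc", "mcc", "auc", "gmean"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Class sizes and the two error counts."""

    N_plus: int
    N_minus: int
    fn: int  # positives predicted negative
    fp: int  # negatives predicted positive

    def __post_init__(self) -> None:
        if not 0 <= self.fn <= self.N_plus:
            raise ValueError(f"fn={self.fn} outside 0..{self.N_plus}")
        if not 0 <= self.fp <= self.N_minus:
            raise ValueError(f"fp={self.fp} outside 0..{self.N_minus}")

    @property
    def tp(self) -> int:
        return self.N_plus - self.fn

    @property
    def tn(self) -> int:
        return self.N_minus - self.fp


@dataclass(frozen=True)
class MetricsReport:
    sn: float
    sp: float
    acc: float
    mcc: float
    gmean: float
    auc: float = math.nan
    counts: ConfusionCounts | None = None

    def as_dict(self, rounded: bool = False) -> dict[str, float]:
        d = {m: getattr(self, m) for m in METRIC_ORDER}
        if rounded:
            d = {k: round(v, DISPLAY_DECIMALS) for k, v in d.items()}
        return d

    def as_row(self) -> str:
        """One display row in the conventional column order
        (Sn, Sp, Acc, MCC, AUC, G-mean), rounded to 4 decimals."""
        return "\t".join(f"{getattr(self, m):.{DISPLAY_DECIMALS}f}" for m in METRIC_ORDER)


def confusion(labels, calls) -> ConfusionCounts:
    """Tally confusion counts from aligned binary vectors."""
    labels = np.asarray(labels)
    calls = np.asarray(calls)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != calls.shape:
        raise ValueError("labels and calls differ in length")
    pos = labels == 1
    return ConfusionCounts(
        N_plus=int(pos.sum()),
        N_minus=int((~pos).sum()),
        fn=int((pos & (calls == 0)).sum()),
        fp=int((~pos & (calls == 1)).sum()),
    )


def threshold_metrics(
    counts: ConfusionCounts, strict_mcc: bool = False
) -> tuple[float, float, float, float, float]:
    """(Sn, Sp, Acc, MCC, G-mean) from confusion counts.

    MCC is NaN when either denominator factor vanishes (a degenerate
    prediction column).  ``strict_mcc`` switches to the audit-only
    accuracy-numerator variant described in the module docstring.
    """
    Np, Nm, fn, fp = counts.N_plus, counts.N_minus, counts.fn, counts.fp
    if Np == 0 or Nm == 0:
        raise ValueError("both classes must be present")
    sn = 1.0 - fn / Np
    sp = 1.0 - fp / Nm
    acc = 1.0 - (fn + fp) / (Np + Nm)
    gmean = math.sqrt(sn * sp)
    f1 = 1.0 + (fp - fn) / Np
    f2 = 1.0 + (fn - fp) / Nm
    if f1 <= 0 or f2 <= 0 or f1 * f2 == 0:
        mcc = math.nan
    else:
        numerator = acc if strict_mcc else 1.0 - (fn / Np + fp / Nm)
        mcc = numerator / math.sqrt(f1 * f2)
    return sn, sp, acc, mcc, gmean


def auc_rank(scores_pos, scores_neg, tie_correction: bool = False) -> float:
    """Pairwise-comparison AUC.

    The fraction of (positive, negative) score pairs where the positive
    scores strictly higher; ties count 0 by default, 0.5 with
    ``tie_correction`` (the Mann-Whitney convention).
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score vectors must be non-empty")
    neg_sorted = np.sort(neg)
    wins = np.searchsorted(neg_sorted, pos, side="left").sum()
    if tie_correction:
        ties = np.searchsorted(neg_sorted, pos, side="right").sum() - wins
        wins = wins + 0.5 * ties
    return float(wins) / (pos.size * neg.size)


def evaluate(
    labels,
    scores,
    threshold: float = 0.5,
    tie_correction: bool = False,
    strict_mcc: bool = False,
) -> MetricsReport:
    """Full report from scores: threshold at `threshold` (ties to the
    positive class) for the count-based metrics, plus the pairwise AUC."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    calls = (scores >= threshold).astype(np.int64)
    counts = confusion(labels, calls)
    sn, sp, acc, mcc, gmean = threshold_metrics(counts, strict_mcc=strict_mcc)
    auc = auc_rank(scores[labels == 1], scores[labels == 0], tie_correction)
    return MetricsReport(sn=sn, sp=sp, acc=acc, mcc=mcc, gmean=gmean, auc=auc,
                         counts=counts)


def average_reports(reports: list[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of each metric across reports (full precision;
    rounding to 4 decimals happens only at display time).  Confusion
    counts, when present in every input, are summed."""
    if not reports:
        raise ValueError("need at least one report")
    means = {m: float(np.mean([getattr(r, m) for r in reports])) for m in METRIC_ORDER}
    counts = None
    if all(r.counts is not None for r in reports):
        counts = ConfusionCounts(
            N_plus=sum(r.counts.N_plus for r in reports),
            N_minus=sum(r.counts.N_minus for r in reports),
            fn=sum(r.counts.fn for r in reports),
            fp=sum(r.counts.fp for r in reports),
        )
    return MetricsReport(counts=counts, **means)
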