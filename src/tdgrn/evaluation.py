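"""Confusion counts and network-inference metrics over ordered gene pairs.

An inferred network is scored against a gold standard on the universe of
ordered (regulator, target) pairs — N^2 pairs when self-loops count, N^2-N
otherwise. From the confusion counts the usual five metrics follow:
sensitivity (TPR), fall-out (FPR), precision (PPV), accuracy (ACC) and the
F-score (harmonic mean of TPR and PPV).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import GeneMismatchError
from .network import RegulatoryNetwork

__all__ = ["ConfusionCounts", "Metrics", "confusion_counts", "compute_metrics",
           "percent_increase", "score_networks"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def universe_size(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    """Five edge-recovery metrics; ppv/f carry an undefined flag when
    nothing was predicted (reported as 0 for comparability)."""

    tpr: float
    fpr: float
    ppv: float
    acc: float
    f: float
    ppv_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "tpr": self.tpr,
            "fpr": self.fpr,
            "ppv": self.ppv,
            "acc": self.acc,
            "f": self.f,
        }


def confusion_counts(
    inferred: RegulatoryNetwork,
    gold: RegulatoryNetwork,
    include_self_loops: bool = True,
) -> ConfusionCounts:
    """Count TP/FP/FN/TN over the ordered-pair universe.

    Both networks must share the same gene universe. Weights, lags and
    regulation signs are ignored; only directed pair membership counts.
    """
    if set(inferred.gene_ids) != set(gold.gene_ids):
        raise GeneMismatchError(
            "inferred and gold networks carry different gene sets"
        )
    n = len(gold.gene_ids)
    universe = n * n if include_self_loops else n * n - n

    def keep(pairs):
        if include_self_loops:
            return set(pairs)
        return {(r, t) for r, t in pairs if r != t}

    inf = keep(inferred.pairs)
    gld = keep(gold.pairs)
    tp = len(inf & gld)
    fp = len(inf - gld)
    fn = len(gld - inf)
    tn = universe - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Derive TPR/FPR/PPV/ACC/F from confusion counts.

    Zero-denominator conventions: TPR is 0 when the gold standard is empty,
    FPR is 0 when there are no negatives, and PPV/F are 0 with the
    ``ppv_defined`` flag cleared when nothing was predicted.
    """
    if c.universe_size <= 0:
        raise ValueError("empty pair universe")
    tpr = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    fpr = c.fp / (c.fp + c.tn) if (c.fp + c.tn) else 0.0
    predicted = c.tp + c.fp
    ppv_defined = predicted > 0
    ppv = c.tp / predicted if ppv_defined else 0.0
    acc = (c.tp + c.tn) / c.universe_size
    f = 2 * tpr * ppv / (tpr + ppv) if (tpr + ppv) > 0 else 0.0
    return Metrics(tpr, fpr, ppv, acc, f, ppv_defined)


def percent_increase(a: float, b: float) -> float:
    """Relative improvement of a over baseline b, in percent: 100 (a-b)/b."""
    if b <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (a - b) / b


def score_networks(
    inferred: RegulatoryNetwork,
    gold: RegulatoryNetwork,
    include_self_loops: bool = True,
) -> tuple[ConfusionCounts, Metrics]:
    """Convenience: counts and metrics in one call."""
    c = confusion_counts(inferred, gold, include_self_loops)
    return c, compute_metrics(c)
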