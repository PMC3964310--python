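"""Threshold calibration of specificity scores against a reference list.

A reference interaction set (bait, prey gene pairs cataloged elsewhere)
stands in for ground truth: a scored pair present in the reference is
counted as a (known) true positive, an absent pair as a false positive.
Absence from a catalog is of course not evidence of non-interaction, so the
resulting rates are approximate and are labeled as such throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .saint import SaintResult

__all__ = [
    "ReferenceInteractionSet",
    "RocCurve",
    "read_reference",
    "label_results",
    "roc_like_curve",
    "recovery_report",
]


@dataclass(frozen=True)
class ReferenceInteractionSet:
    """Uppercased, de-duplicated (bait, prey) pairs from a catalog."""

    pairs: frozenset[tuple[str, str]]
    source_tag: str = ""

    @classmethod
    def from_pairs(
        cls, pairs, source_tag: str = ""
    ) -> "ReferenceInteractionSet":
        return cls(
            pairs=frozenset((b.upper(), p.upper()) for b, p in pairs),
            source_tag=source_tag,
        )

    def __contains__(self, pair: tuple[str, str]) -> bool:
        b, p = pair
        return (b.upper(), p.upper()) in self.pairs

    def preys_for(self, bait: str) -> set[str]:
        bait = bait.upper()
        return {p for b, p in self.pairs if b == bait}


def read_reference(path: str | Path, source_tag: str = "") -> ReferenceInteractionSet:
    """Read a two-column (bait, prey) TSV; '#' comments allowed."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = list(df.columns[:2])
    if len(cols) < 2:
        raise FormatError(f"reference file {path} needs two columns (bait, prey)")
    return ReferenceInteractionSet.from_pairs(
        df[cols].itertuples(index=False), source_tag=source_tag or str(path)
    )


@dataclass
class RocCurve:
    """Approximate TP/FP rates over a descending threshold grid.

    ``recovery`` is the fraction of the bait's reference pairs recovered at
    each threshold, with all reference pairs (scored or not) in the
    denominator.
    """

    thresholds: np.ndarray
    tp_rate: np.ndarray
    fp_rate: np.ndarray
    recovery: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(self.thresholds)[::-1]
        self.thresholds = np.asarray(self.thresholds, dtype=float)[order]
        self.tp_rate = np.asarray(self.tp_rate, dtype=float)[order]
        self.fp_rate = np.asarray(self.fp_rate, dtype=float)[order]
        self.recovery = np.asarray(self.recovery, dtype=float)[order]
        for name, arr in (("tp_rate", self.tp_rate), ("fp_rate", self.fp_rate)):
            finite = arr[np.isfinite(arr)]
            if np.any(np.diff(finite) < -1e-12):
                raise DataError(f"{name} not monotone as threshold decreases")

    def auc(self) -> float:
        """Area under the (fp, tp) curve, closed at (0,0) and (1,1)."""
        # rates ascend along the (descending) threshold grid
        fp = np.concatenate([[0.0], self.fp_rate, [1.0]])
        tp = np.concatenate([[0.0], self.tp_rate, [1.0]])
        return float(np.trapezoid(tp, fp))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "approx_tp_rate": self.tp_rate,
                "approx_fp_rate": self.fp_rate,
                "recovery": self.recovery,
            }
        )


def label_results(
    results: list[SaintResult], ref: ReferenceInteractionSet
) -> list[SaintResult]:
    """Mark each result as known (pair in the reference) or novel (in place)."""
    for r in results:
        r.known = (r.bait, r.prey) in ref
    return results


def roc_like_curve(
    labeled: list[SaintResult],
    ref: ReferenceInteractionSet,
    grid=None,
) -> RocCurve:
    """Approximate ROC over a threshold grid for one bait's labeled results.

    At threshold t: TP-rate = known scored pairs with score >= t over all
    known scored pairs; FP-rate likewise over novel scored pairs. Preys the
    bait never co-isolated cannot appear among the scored pairs and are
    excluded from the rates, but still count in the recovery denominator.
    """
    if not labeled:
        raise DataError("no scored results to benchmark")
    if any(r.known is None for r in labeled):
        raise DataError("results not labeled; call label_results first")
    baits = {r.bait for r in labeled}
    if len(baits) != 1:
        raise DataError(f"roc_like_curve expects one bait, got {sorted(baits)}")
    bait = baits.pop()
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    grid = np.asarray(grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise DataError("threshold grid must lie in [0,1]")
    scores = np.array([r.score for r in labeled])
    known = np.array([bool(r.known) for r in labeled])
    n_known, n_novel = int(known.sum()), int((~known).sum())
    n_ref = len(ref.preys_for(bait))
    if n_known == 0:
        warnings.warn(
            f"no known reference pairs among scored preys for {bait}; "
            "TP-rate undefined",
            stacklevel=2,
        )
    tp, fp, rec = [], [], []
    for t in grid:
        hit = scores >= t
        tp.append((hit & known).sum() / n_known if n_known else np.nan)
        fp.append((hit & ~known).sum() / n_novel if n_novel else np.nan)
        rec.append((hit & known).sum() / n_ref if n_ref else np.nan)
    return RocCurve(
        thresholds=grid,
        tp_rate=np.array(tp),
        fp_rate=np.array(fp),
        recovery=np.array(rec),
    )


def recovery_report(
    filtered: list[SaintResult], ref: ReferenceInteractionSet, bait: str
) -> float:
    """Fraction of the bait's reference pairs present among passing preys.

    Returns NaN (with a warning) when the bait has no reference pairs.
    """
    bait = bait.upper()
    ref_preys = ref.preys_for(bait)
    if not ref_preys:
        warnings.warn(f"bait {bait} absent from reference; recovery undefined",
                      stacklevel=2)
        return float("nan")
    passing = {r.prey for r in filtered if r.bait == bait and r.passes}
    return len(ref_preys & passing) / len(ref_preys)
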