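"""SAINT-style probabilistic specificity scoring from spectral counts.

Each prey observed in a bait's purification is scored against the negative
controls with a two-component Poisson mixture: counts arise either from the
background rate ``lambda_false`` (estimated from control runs) or from a
bait-specific rate ``lambda_true`` (estimated from that bait's replicates).
The posterior probability that a replicate count came from the specific
component is the per-replicate interaction probability (iProb), and the
final score for a bait–prey pair is the mean of the two highest iProbs
(or the single iProb when only one replicate exists).

Modeling is per bait: each bait is compared to the controls independently,
so heterogeneous baits (different dynamic ranges, different numbers of
co-isolated proteins) do not share a model. Exact parity with the original
SAINT implementation is not attempted; the mixture here is a fixed,
documented surrogate with the same inputs and decision rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .countmatrix import NormalizedCounts
from .errors import ConfigError, DataError

__all__ = [
    "SaintConfig",
    "SaintResult",
    "ThresholdPolicy",
    "fit_background",
    "score_replicate",
    "score_bait",
    "combine_iprobs",
    "apply_thresholds",
    "results_to_frame",
]


@dataclass(frozen=True)
class SaintConfig:
    """Mixture-model settings.

    pi_true
        Prior probability that a scored prey is a specific interactor.
    pseudocount
        Added to count sums before averaging so all-zero profiles yield a
        small positive rate.
    minfold
        Floor on lambda_true as a multiple of lambda_false (1 = no bait
        enrichment required beyond the background itself).
    min_separation
        Minimum lambda_true - lambda_false, keeping the likelihood ratio
        defined when a prey is no more abundant with the bait than in
        controls.
    """

    pi_true: float = 0.1
    pseudocount: float = 0.1
    minfold: float = 1.0
    min_separation: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 < self.pi_true < 1.0:
            raise ConfigError(f"pi_true must be in (0,1), got {self.pi_true}")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be >= 0")
        if self.min_separation <= 0:
            raise ConfigError("min_separation must be > 0")


@dataclass
class SaintResult:
    """Score for one bait–prey pair."""

    bait: str
    prey: str
    iprobs: list[float]
    score: float
    lambda_false: float = math.nan
    lambda_true: float = math.nan
    threshold: float | None = None
    passes: bool | None = None
    manual: bool = False
    known: bool | None = None  # set by the reference benchmark


@dataclass(frozen=True)
class ThresholdPolicy:
    """Per-bait score thresholds.

    ``thresholds`` maps bait -> cutoff; ``strict`` baits require score
    strictly above the cutoff (``>``) instead of ``>=``. Baits without an
    entry use ``default``. ``manual_include`` pairs are retained regardless
    of score and flagged, mirroring the rescue of well-known low-abundance
    interactors that never accumulate enough spectra to pass.
    """

    default: float = 0.75
    thresholds: dict[str, float] = field(default_factory=dict)
    strict: frozenset[str] = frozenset()
    manual_include: frozenset[tuple[str, str]] = frozenset()

    def cutoff(self, bait: str) -> tuple[float, bool]:
        bait = bait.upper()
        thr = self.thresholds.get(bait, self.default)
        return thr, bait in {b.upper() for b in self.strict}


def fit_background(
    controls: NormalizedCounts, prey: str, pseudocount: float = 0.1
) -> float:
    """Pseudocount-smoothed mean control count for one prey.

    Returns ``(sum of control counts + pseudocount) / n_control_runs``.
    """
    ctrl_runs = controls.runs_for(None)
    if not ctrl_runs:
        raise ConfigError("no control runs to fit a background rate")
    prey = prey.upper()
    cols = [r.run_id for r in ctrl_runs]
    if prey in controls.counts.index:
        total = float(controls.counts.loc[prey, cols].sum())
    else:
        total = 0.0
    return (total + pseudocount) / len(ctrl_runs)


def score_replicate(
    count: float, lambda_false: float, lambda_true: float, pi_true: float
) -> float:
    """Posterior probability that one replicate count is bait-specific.

    Bayes with Poisson masses evaluated at the count rounded to the nearest
    integer (normalization produces non-integer counts):

        iprob = pi * P(k|lt) / (pi * P(k|lt) + (1-pi) * P(k|lf))
    """
    if not (np.isfinite(count) and np.isfinite(lambda_false) and np.isfinite(lambda_true)):
        raise DataError("non-finite input to score_replicate")
    if lambda_false <= 0 or lambda_true <= 0:
        raise DataError("rates must be positive after smoothing")
    k = int(round(count))
    if lambda_true == lambda_false:
        return pi_true
    # log-space likelihood ratio for numerical stability at large counts
    log_lr = poisson.logpmf(k, lambda_false) - poisson.logpmf(k, lambda_true)
    odds = (1.0 - pi_true) / pi_true * math.exp(log_lr)
    return 1.0 / (1.0 + odds)


def combine_iprobs(iprobs: list[float]) -> float:
    """Final score: mean of the two highest iProbs (single one passes through)."""
    if not iprobs:
        raise DataError("no replicate probabilities to combine")
    top = sorted(iprobs, reverse=True)[:2]
    return float(sum(top) / len(top))


def score_bait(
    m: NormalizedCounts, bait: str, config: SaintConfig | None = None
) -> list[SaintResult]:
    """Score every prey observed in at least one of the bait's runs.

    lambda_false is the smoothed mean control count of the prey;
    lambda_true is the smoothed mean over the bait's replicates, floored at
    ``minfold * lambda_false`` and kept at least ``min_separation`` above it.
    Preys seen only in controls cannot be interactions of the bait and are
    not scored.
    """
    config = config or SaintConfig()
    bait = bait.upper()
    bait_runs = sorted(m.runs_for(bait), key=lambda r: r.replicate_index)
    if not bait_runs:
        raise ConfigError(f"no runs for bait {bait!r}")
    if not m.runs_for(None):
        raise ConfigError("no control runs present")
    cols = [r.run_id for r in bait_runs]
    bait_counts = m.counts[cols]
    observed = bait_counts.index[(bait_counts > 0).any(axis=1)]
    results: list[SaintResult] = []
    for prey in observed:
        lam_f = fit_background(m, prey, config.pseudocount)
        row = bait_counts.loc[prey]
        lam_t = (float(row.sum()) + config.pseudocount) / len(cols)
        lam_t = max(lam_t, config.minfold * lam_f, lam_f + config.min_separation)
        iprobs = [
            score_replicate(float(c), lam_f, lam_t, config.pi_true) for c in row
        ]
        results.append(
            SaintResult(
                bait=bait,
                prey=prey,
                iprobs=iprobs,
                score=combine_iprobs(iprobs),
                lambda_false=lam_f,
                lambda_true=lam_t,
            )
        )
    return results


def apply_thresholds(
    results: list[SaintResult], policy: ThresholdPolicy | None = None
) -> list[SaintResult]:
    """Set pass/fail per the bait's threshold and return the passing subset.

    All results get ``threshold`` and ``passes`` filled in (in place); the
    returned list contains only passing pairs, with manual-include pairs
    appended (``passes=True, manual=True``) even when below threshold.
    """
    policy = policy or ThresholdPolicy()
    manual = {(b.upper(), p.upper()) for b, p in policy.manual_include}
    filtered: list[SaintResult] = []
    for r in results:
        thr, strict = policy.cutoff(r.bait)
        r.threshold = thr
        r.passes = r.score > thr if strict else r.score >= thr
        if (r.bait, r.prey) in manual and not r.passes:
            r.passes = True
            r.manual = True
        if r.passes:
            filtered.append(r)
    return filtered


def results_to_frame(results: list[SaintResult]) -> pd.DataFrame:
    """Tabular view: bait, prey, iprob_1..n, score, threshold, passes, manual."""
    n_rep = max((len(r.iprobs) for r in results), default=0)
    rows = []
    for r in results:
        row: dict[str, object] = {"bait": r.bait, "prey": r.prey}
        for i in range(n_rep):
            row[f"iprob_{i + 1}"] = r.iprobs[i] if i < len(r.iprobs) else math.nan
        row.update(
            score=r.score,
            threshold=r.threshold,
            passes=r.passes,
            manual_flag=r.manual,
        )
        rows.append(row)
    return pd.DataFrame(rows)
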