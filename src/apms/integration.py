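"""Joint specificity x stability classification of bait-prey interactions.

Plotting each prey's label-free specificity score against its isotope-label
stability ratio divides an interactome into interpretable quadrants:

* ``stable`` — specific (score passes) and label-pure (ratio >= 0.80):
  bona fide complex members that do not exchange during purification.
* ``dynamic`` — specific but exchanging (ratio < 0.80): transient partners
  such as transcription factors in rapid equilibrium.
* ``rescued`` — below the specificity threshold yet stable by isotope
  ratio: real but low-abundance interactors the spectral-count filter
  misses (false-negative rescue).
* ``contaminant`` — near-zero specificity score (< 0.10) with a maximal
  ratio (= 1.0): environmental, light-only proteins (keratins, skin/ECM
  proteins) never present in the heavy pool.
* ``nonspecific`` — fails both signatures.
* ``unquantified`` — passes the specificity filter but was not detected in
  the isotope-label experiment; kept, since absence from one workflow is
  not evidence against the interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import DataError
from .idirt import StabilityRatio
from .saint import SaintResult

__all__ = [
    "ClassifyConfig",
    "StabilityProfile",
    "CATEGORIES",
    "classify",
    "join_profiles",
    "quadrant_summary",
    "profiles_to_frame",
]

CATEGORIES = (
    "stable",
    "dynamic",
    "rescued",
    "contaminant",
    "nonspecific",
    "unquantified",
)

#: Categories that denote genuine interactions (exported to networks).
INTERACTION_CATEGORIES = ("stable", "dynamic", "rescued", "unquantified")


@dataclass(frozen=True)
class ClassifyConfig:
    saint_pass: float = 0.75
    strict: bool = False
    stable_ratio: float = 0.80
    contaminant_saint: float = 0.10
    contaminant_ratio: float = 1.0
    ratio_tol: float = 1e-6


@dataclass
class StabilityProfile:
    bait: str
    prey: str
    saint_score: float | None
    idirt_ratio: float | None
    category: str | None = None


def classify(
    saint_score: float | None,
    idirt_ratio: float | None,
    cfg: ClassifyConfig | None = None,
) -> str:
    """Assign one category to a (specificity score, stability ratio) pair.

    Total over the domain: a missing score is treated as 0 (never observed
    in the label-free workflow) and a missing ratio routes to
    ``unquantified``/``nonspecific`` on the score alone. Precedence:
    contaminant, then the ratio-aware quadrants.
    """
    cfg = cfg or ClassifyConfig()
    s = 0.0 if saint_score is None or math.isnan(saint_score) else saint_score
    r = idirt_ratio
    if r is not None and math.isnan(r):
        r = None
    passes = s > cfg.saint_pass if cfg.strict else s >= cfg.saint_pass
    if r is None:
        return "unquantified" if passes else "nonspecific"
    if s < cfg.contaminant_saint and r >= cfg.contaminant_ratio - cfg.ratio_tol:
        return "contaminant"
    if not passes and r >= cfg.stable_ratio:
        return "rescued"
    if passes and r >= cfg.stable_ratio:
        return "stable"
    if passes:
        return "dynamic"
    return "nonspecific"


def join_profiles(
    saint: list[SaintResult],
    stab: list[StabilityRatio],
    bait: str | None = None,
    cfg: ClassifyConfig | None = None,
) -> list[StabilityProfile]:
    """Outer-join specificity scores and stability ratios per prey.

    A prey present on one side only keeps the other value missing. Profiles
    are classified on construction.
    """
    cfg = cfg or ClassifyConfig()
    baits = {r.bait for r in saint}
    if bait is None:
        if len(baits) > 1:
            raise DataError(f"multiple baits in SAINT results: {sorted(baits)}")
        bait = baits.pop() if baits else "UNKNOWN"
    bait = bait.upper()
    if baits and baits != {bait}:
        raise DataError(f"bait mismatch: expected {bait}, got {sorted(baits)}")
    scores = {r.prey: r.score for r in saint}
    ratios = {r.prey: r.ratio for r in stab}
    profiles = []
    for prey in sorted(set(scores) | set(ratios)):
        p = StabilityProfile(
            bait=bait,
            prey=prey,
            saint_score=scores.get(prey),
            idirt_ratio=ratios.get(prey),
        )
        p.category = classify(p.saint_score, p.idirt_ratio, cfg)
        profiles.append(p)
    return profiles


def quadrant_summary(
    profiles: Iterable[StabilityProfile],
) -> tuple[dict[str, int], dict[str, list[str]]]:
    """Counts per category plus per-quadrant prey lists (sorted by score).

    Counts sum to the number of profiles; contaminants are counted but are
    not interactions.
    """
    counts = {c: 0 for c in CATEGORIES}
    members: dict[str, list[StabilityProfile]] = {c: [] for c in CATEGORIES}
    for p in profiles:
        if p.category not in counts:
            raise DataError(f"unclassified profile {p.bait}-{p.prey}")
        counts[p.category] += 1
        members[p.category].append(p)
    lists = {
        c: [
            p.prey
            for p in sorted(
                members[c],
                key=lambda q: (-(q.saint_score or 0.0), q.prey),
            )
        ]
        for c in CATEGORIES
    }
    return counts, lists


def profiles_to_frame(profiles: Iterable[StabilityProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bait": p.bait,
                "prey": p.prey,
                "saint_score": p.saint_score,
                "idirt_ratio": p.idirt_ratio,
                "category": p.category,
            }
            for p in profiles
        ],
        columns=["bait", "prey", "saint_score", "idirt_ratio", "category"],
    )
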