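"""I-DIRT relative-stability ratios from SILAC peptide pairs.

In an I-DIRT experiment, isotopically heavy wild-type cells are mixed 1:1
with light cells expressing the tagged bait *before* lysis. A prey that
stays bound to the bait complex throughout purification keeps its light
label (light fraction -> 1.0), while a prey that exchanges between the
pools during isolation equilibrates toward the mixing ratio (light
fraction -> 0.5). The light fraction L/(L+H), taken per protein as the
median over its quantified peptides, therefore reports relative
interaction stability.

Mixing is never perfectly 1:1, so per-peptide light/heavy odds are divided
by the median protein-level odds of the *input* (whole mixed lysate)
sample before conversion to a fraction; a perfectly restored input then
yields 0.5 for a fully exchanging prey.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from statistics import median

import pandas as pd

from .errors import DataError, FormatError

__all__ = [
    "PeptidePair",
    "IdirtExperiment",
    "StabilityRatio",
    "peptide_light_fraction",
    "input_normalizer",
    "protein_stability",
    "read_peptides",
    "stability_to_frame",
]

#: Minimum quantified peptides for a protein-level ratio.
MIN_PEPTIDES = 2


@dataclass(frozen=True)
class PeptidePair:
    """One quantified SILAC peptide pair."""

    prey: str
    peptide_seq: str
    light_intensity: float
    heavy_intensity: float

    def __post_init__(self) -> None:
        if self.light_intensity < 0 or self.heavy_intensity < 0:
            raise DataError(f"negative intensity for {self.peptide_seq}")
        object.__setattr__(self, "prey", self.prey.upper())

    @property
    def quantifiable(self) -> bool:
        return self.light_intensity > 0 or self.heavy_intensity > 0


@dataclass
class IdirtExperiment:
    """Peptide pairs from one bait IP plus the mixed-lysate input sample."""

    bait: str
    pairs: list[PeptidePair]
    input_pairs: list[PeptidePair]


@dataclass(frozen=True)
class StabilityRatio:
    """Protein-level light fraction in [0,1] with its provenance."""

    prey: str
    ratio: float
    n_peptides: int
    normalizer: float


def _odds(p: PeptidePair) -> float:
    """Light/heavy odds; inf for light-only, 0 for heavy-only pairs."""
    if p.heavy_intensity == 0:
        return float("inf")
    return p.light_intensity / p.heavy_intensity


def peptide_light_fraction(p: PeptidePair, normalizer: float = 1.0) -> float:
    """Mixing-corrected light fraction of one peptide pair.

    The raw light/heavy odds are divided by the input normalizer, then
    converted back to a fraction: f = (L/H / norm) / (1 + L/H / norm).
    A light-only pair is 1.0 and a heavy-only pair 0.0 regardless of the
    normalizer.
    """
    if normalizer <= 0:
        raise DataError(f"normalizer must be positive, got {normalizer}")
    if not p.quantifiable:
        raise DataError(f"peptide {p.peptide_seq} has zero intensity in both channels")
    if p.heavy_intensity == 0:
        return 1.0
    if p.light_intensity == 0:
        return 0.0
    adj = _odds(p) / normalizer
    return adj / (1.0 + adj)


def input_normalizer(input_pairs: list[PeptidePair]) -> float:
    """Median over input proteins of their median peptide light/heavy odds.

    Only proteins with >= 2 quantifiable peptides contribute. When no input
    protein is quantifiable, normalization is disabled (returns 1.0 with a
    warning).
    """
    by_prey: dict[str, list[float]] = defaultdict(list)
    for p in input_pairs:
        if p.quantifiable:
            by_prey[p.prey].append(_odds(p))
    protein_odds = [
        median(odds) for odds in by_prey.values() if len(odds) >= MIN_PEPTIDES
    ]
    protein_odds = [o for o in protein_odds if 0 < o < float("inf")]
    if not protein_odds:
        warnings.warn(
            "no quantifiable input protein; mixing normalization disabled",
            stacklevel=2,
        )
        return 1.0
    return float(median(protein_odds))


def protein_stability(
    exp: IdirtExperiment, normalizer: float | None = None
) -> list[StabilityRatio]:
    """Median peptide light fraction per prey with >= 2 quantified peptides.

    Peptide sequences assigned to more than one prey are ambiguous and
    dropped. Preys with fewer than two quantified peptides are excluded
    (reported via warning).
    """
    if normalizer is None:
        normalizer = input_normalizer(exp.input_pairs) if exp.input_pairs else 1.0
    preys_per_seq: dict[str, set[str]] = defaultdict(set)
    for p in exp.pairs:
        preys_per_seq[p.peptide_seq].add(p.prey)
    ambiguous = {s for s, preys in preys_per_seq.items() if len(preys) > 1}
    fractions: dict[str, list[float]] = defaultdict(list)
    for p in exp.pairs:
        if p.peptide_seq in ambiguous or not p.quantifiable:
            continue
        fractions[p.prey].append(peptide_light_fraction(p, normalizer))
    results = []
    dropped = []
    for prey in fractions:
        if len(fractions[prey]) < MIN_PEPTIDES:
            dropped.append(prey)
            continue
        results.append(
            StabilityRatio(
                prey=prey,
                ratio=float(median(fractions[prey])),
                n_peptides=len(fractions[prey]),
                normalizer=normalizer,
            )
        )
    if dropped:
        warnings.warn(
            f"preys with < {MIN_PEPTIDES} quantified peptides dropped: "
            f"{sorted(dropped)}",
            stacklevel=2,
        )
    results.sort(key=lambda r: r.prey)
    return results


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

PEPTIDE_COLUMNS = [
    "prey_gene",
    "peptide_seq",
    "light_intensity",
    "heavy_intensity",
    "sample",
]


def read_peptides(path: str | Path, bait: str) -> IdirtExperiment:
    """Read a peptide TSV with columns prey_gene, peptide_seq,
    light_intensity, heavy_intensity, sample (ip | input)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PEPTIDE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"peptide table missing columns: {sorted(missing)}")
    bad = ~df["sample"].isin(["ip", "input"])
    if bad.any():
        raise FormatError(
            f"sample column must be 'ip' or 'input', got {df.loc[bad, 'sample'].unique()}"
        )

    def build(sub: pd.DataFrame) -> list[PeptidePair]:
        return [
            PeptidePair(
                prey=row.prey_gene,
                peptide_seq=row.peptide_seq,
                light_intensity=float(row.light_intensity),
                heavy_intensity=float(row.heavy_intensity),
            )
            for row in sub.itertuples(index=False)
        ]

    return IdirtExperiment(
        bait=bait.upper(),
        pairs=build(df[df["sample"] == "ip"]),
        input_pairs=build(df[df["sample"] == "input"]),
    )


def stability_to_frame(ratios: list[StabilityRatio]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "prey": r.prey,
                "idirt_ratio": r.ratio,
                "n_peptides": r.n_peptides,
                "normalizer": r.normalizer,
            }
            for r in ratios
        ],
        columns=["prey", "idirt_ratio", "n_peptides", "normalizer"],
    )
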