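"""Synthetic AP-MS data with planted ground truth.

The generator emits the statistical structure the analysis assumes, so the
whole pipeline is testable without any deposited data:

* spectral-count matrices — per-prey Poisson counts, background preys at a
  low control rate in every run, each bait's specific preys at an elevated
  rate in that bait's replicates only, a shared-complex block specific in
  several baits, and the bait protein itself dominating its own runs;
* SILAC peptide tables — per-prey exchange fraction ``f`` sets the expected
  light fraction to ``1 - f/2`` (f=1 fully exchanging -> 0.5, f=0 stable
  -> 1.0), with lognormal intensity noise, an optional global mixing
  imbalance (applied to the input sample too), and light-only contaminants;
* reference interaction lists — a coverage/noise-controlled sample of the
  planted specific pairs, standing in for an interaction catalog;
* protein-length and cellular-abundance tables for NSAF and enrichment.

Every draw is governed by the mandatory config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .benchmark import ReferenceInteractionSet
from .countmatrix import CountMatrix, Run, write_count_matrix
from .errors import ConfigError
from .idirt import IdirtExperiment, PeptidePair

__all__ = [
    "SimConfig",
    "simulate_counts",
    "simulate_peptides",
    "simulate_reference",
    "simulate_pax",
    "generate_all",
]


@dataclass(frozen=True)
class SimConfig:
    """Study design for the synthetic experiment.

    Defaults mirror the design the analysis is built for: a handful of
    baits at 3 biological replicates each against 7 control runs, 50
    specific preys per bait at a specific rate of 15 counts/run over a
    450-prey background at <= 0.5 counts/run, a 10-prey complex shared by
    the first two baits, and I-DIRT peptide pairs at 20 peptides/prey with
    lognormal intensity noise (sigma 0.2) and balanced 1:1 mixing.
    """

    seed: int
    n_baits: int = 3
    n_control_runs: int = 7
    n_replicates: int = 3
    n_background_preys: int = 450
    n_specific_per_bait: int = 50
    lambda_true: float = 15.0
    lambda_false_max: float = 0.5
    shared_complex_size: int = 10
    stable_fraction: float = 0.5  # fraction of specific preys with f=0
    peptides_per_prey: int = 20
    intensity_sigma: float = 0.2
    mixing_imbalance: float = 1.0  # light/heavy input ratio
    heavy_leakage: float = 0.0  # heavy signal bleeding into stable preys
    n_contaminants: int = 5
    n_input_proteins: int = 20
    bait_self_rate: float = 200.0
    overdispersion: float = 0.0  # Gamma-Poisson shape^-1; 0 = pure Poisson

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_baits < 1 or self.n_control_runs < 1 or self.n_replicates < 1:
            raise ConfigError("need >= 1 bait, control run, and replicate")
        if not 0 <= self.stable_fraction <= 1:
            raise ConfigError("stable_fraction must lie in [0,1]")
        if self.lambda_true < 0 or self.lambda_false_max <= 0:
            raise ConfigError("rates must be non-negative")
        if self.shared_complex_size > self.n_specific_per_bait:
            raise ConfigError("shared complex larger than the specific set")
        if self.mixing_imbalance <= 0:
            raise ConfigError("mixing_imbalance must be positive")

    @property
    def baits(self) -> list[str]:
        return [f"BAIT{i + 1}" for i in range(self.n_baits)]


def _poisson(rng: np.random.Generator, lam, size, overdispersion: float):
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        lam = rng.gamma(shape, np.asarray(lam) / shape, size=size)
        return rng.poisson(lam)
    return rng.poisson(lam, size=size)


def _truth_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["prey", "role", "baits", "exchange_f"]
    ).set_index("prey")


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a spectral-count matrix plus its ground-truth table.

    The truth table is indexed by prey with columns ``role`` (specific /
    background / contaminant / bait), ``baits`` (';'-joined baits the prey
    is specific for) and ``exchange_f`` (NaN for non-specific preys).
    """
    rng = np.random.default_rng(cfg.seed)
    baits = cfg.baits

    shared = (
        [f"CPLX{i + 1:02d}" for i in range(cfg.shared_complex_size)]
        if cfg.n_baits >= 2
        else []
    )
    shared_members = baits[:2]
    specific_for: dict[str, list[str]] = {}
    truth_rows: list[dict] = []
    for b_idx, bait in enumerate(baits):
        own_n = cfg.n_specific_per_bait - (
            len(shared) if bait in shared_members else 0
        )
        own = [f"SP{b_idx + 1}_{i + 1:03d}" for i in range(own_n)]
        specific_for[bait] = (shared if bait in shared_members else []) + own
    # exchange fractions: the shared complex is stable (f=0); of each bait's
    # own preys, the first stable_fraction are stable, the rest exchange
    exchange_f: dict[str, float] = {p: 0.0 for p in shared}
    for bait in baits:
        own = [p for p in specific_for[bait] if p not in shared]
        n_stable = int(round(cfg.stable_fraction * len(own)))
        for i, p in enumerate(own):
            exchange_f[p] = 0.0 if i < n_stable else 1.0

    background = [f"BG{i + 1:04d}" for i in range(cfg.n_background_preys)]
    contaminants = [f"CONT{i + 1:02d}" for i in range(cfg.n_contaminants)]

    all_specific = sorted({p for v in specific_for.values() for p in v})
    preys = all_specific + background + contaminants + baits
    base_rate = pd.Series(
        rng.uniform(0.02, cfg.lambda_false_max, size=len(preys)), index=preys
    )
    # contaminants shed steadily into every sample: background-level counts
    base_rate[contaminants] = rng.uniform(
        0.2, cfg.lambda_false_max, size=len(contaminants)
    )
    base_rate[baits] = 0.0  # bait genes only appear in their own runs

    runs: list[Run] = [
        Run(run_id=f"CONTROL_r{i + 1}", bait=None, replicate_index=i + 1)
        for i in range(cfg.n_control_runs)
    ]
    for bait in baits:
        runs.extend(
            Run(run_id=f"{bait}_r{i + 1}", bait=bait, replicate_index=i + 1)
            for i in range(cfg.n_replicates)
        )

    counts = pd.DataFrame(0, index=preys, columns=[r.run_id for r in runs], dtype=np.int64)
    for run in runs:
        lam = base_rate.to_numpy().copy()
        if not run.is_control:
            for p in specific_for[run.bait]:
                lam[preys.index(p)] = cfg.lambda_true
            lam[preys.index(run.bait)] = cfg.bait_self_rate
        counts[run.run_id] = _poisson(rng, lam, len(preys), cfg.overdispersion)

    lengths = rng.integers(100, 2001, size=len(preys))
    prey_table = pd.DataFrame(
        {
            "accession": [f"ACC_{p}" for p in preys],
            "length": lengths,
        },
        index=preys,
    )

    bait_of: dict[str, list[str]] = {p: [] for p in preys}
    for bait, plist in specific_for.items():
        for p in plist:
            bait_of[p].append(bait)
    for p in all_specific:
        truth_rows.append(
            {
                "prey": p,
                "role": "specific",
                "baits": ";".join(bait_of[p]),
                "exchange_f": exchange_f[p],
            }
        )
    truth_rows += [
        {"prey": p, "role": "background", "baits": "", "exchange_f": np.nan}
        for p in background
    ]
    truth_rows += [
        {"prey": p, "role": "contaminant", "baits": "", "exchange_f": np.nan}
        for p in contaminants
    ]
    truth_rows += [
        {"prey": b, "role": "bait", "baits": b, "exchange_f": np.nan}
        for b in baits
    ]
    matrix = CountMatrix(counts=counts, preys=prey_table, runs=runs)
    return matrix, _truth_frame(truth_rows)


def simulate_peptides(
    cfg: SimConfig, truth: pd.DataFrame, bait: str
) -> tuple[IdirtExperiment, pd.DataFrame]:
    """Draw SILAC peptide pairs for one bait's I-DIRT experiment.

    For a prey with exchange fraction ``f`` the expected light fraction is
    ``1 - f/2``; intensities are drawn lognormally around that expectation,
    the light channel of every peptide (input included) is multiplied by
    the mixing imbalance, and contaminants are emitted light-only. Returns
    the experiment plus a per-prey truth table of expected fractions.
    """
    bait = bait.upper()
    b_idx = cfg.baits.index(bait)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1000 + b_idx]))
    m = cfg.mixing_imbalance
    sigma = cfg.intensity_sigma

    def noisy(base: float) -> float:
        return float(base * rng.lognormal(0.0, sigma)) if base > 0 else 0.0

    pairs: list[PeptidePair] = []
    truth_rows = []
    specific = truth[
        (truth["role"] == "specific")
        & truth["baits"].str.split(";").apply(lambda bs: bait in bs)
    ]
    for prey, row in specific.iterrows():
        f = float(row["exchange_f"])
        p_light = 1.0 - f / 2.0
        heavy_share = (1.0 - p_light) + cfg.heavy_leakage
        for j in range(cfg.peptides_per_prey):
            total = rng.lognormal(np.log(1e6), 1.0)
            pairs.append(
                PeptidePair(
                    prey=prey,
                    peptide_seq=f"{prey}_PEP{j + 1}",
                    light_intensity=m * noisy(total * p_light),
                    heavy_intensity=noisy(total * heavy_share),
                )
            )
        truth_rows.append(
            {"prey": prey, "exchange_f": f, "expected_fraction": p_light}
        )
    contaminants = truth.index[truth["role"] == "contaminant"]
    for prey in contaminants:
        for j in range(cfg.peptides_per_prey):
            total = rng.lognormal(np.log(1e6), 1.0)
            pairs.append(
                PeptidePair(
                    prey=prey,
                    peptide_seq=f"{prey}_PEP{j + 1}",
                    light_intensity=m * noisy(total),
                    heavy_intensity=0.0,
                )
            )
        truth_rows.append(
            {"prey": prey, "exchange_f": np.nan, "expected_fraction": 1.0}
        )
    input_pairs: list[PeptidePair] = []
    for i in range(cfg.n_input_proteins):
        prey = f"INP{i + 1:02d}"
        for j in range(cfg.peptides_per_prey):
            total = rng.lognormal(np.log(1e6), 1.0)
            input_pairs.append(
                PeptidePair(
                    prey=prey,
                    peptide_seq=f"{prey}_PEP{j + 1}",
                    light_intensity=m * noisy(total),
                    heavy_intensity=noisy(total),
                )
            )
    exp = IdirtExperiment(bait=bait, pairs=pairs, input_pairs=input_pairs)
    return exp, pd.DataFrame(
        truth_rows, columns=["prey", "exchange_f", "expected_fraction"]
    ).set_index("prey")


def simulate_reference(
    truth: pd.DataFrame,
    coverage: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
) -> ReferenceInteractionSet:
    """Sample a reference interaction list from the planted truth.

    ``coverage`` is the fraction of true specific pairs included;
    ``noise`` adds that fraction of spurious (bait, background-prey) pairs.
    """
    rng = np.random.default_rng(seed)
    true_pairs = sorted(
        (b, p)
        for p, row in truth[truth["role"] == "specific"].iterrows()
        for b in row["baits"].split(";")
        if b
    )
    n_take = int(round(coverage * len(true_pairs)))
    idx = rng.choice(len(true_pairs), size=n_take, replace=False) if n_take else []
    chosen = [true_pairs[i] for i in sorted(idx)]
    background = truth.index[truth["role"] == "background"].tolist()
    baits = sorted(
        {b for p, row in truth.iterrows() for b in row["baits"].split(";") if b}
    )
    n_noise = int(round(noise * len(true_pairs)))
    for _ in range(n_noise):
        chosen.append(
            (baits[rng.integers(len(baits))], background[rng.integers(len(background))])
        )
    return ReferenceInteractionSet.from_pairs(chosen, source_tag="synthetic")


def simulate_pax(truth: pd.DataFrame, seed: int = 0) -> pd.Series:
    """Lognormal proteome-abundance table (ppm-like units) over all preys."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    values = rng.lognormal(np.log(50.0), 1.5, size=len(truth))
    return pd.Series(values, index=truth.index, name="pax_abundance")


def generate_all(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full fixture family to ``outdir`` and return the paths.

    Emits counts.tsv (long dialect), peptides_<BAIT>.tsv per bait,
    reference.tsv, lengths.tsv, pax.tsv and truth.tsv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    matrix, truth = simulate_counts(cfg)
    paths["counts"] = outdir / "counts.tsv"
    write_count_matrix(matrix, paths["counts"])
    for bait in cfg.baits:
        exp, _ = simulate_peptides(cfg, truth, bait)
        rows = [
            {
                "prey_gene": p.prey,
                "peptide_seq": p.peptide_seq,
                "light_intensity": p.light_intensity,
                "heavy_intensity": p.heavy_intensity,
                "sample": sample,
            }
            for sample, plist in (("ip", exp.pairs), ("input", exp.input_pairs))
            for p in plist
        ]
        path = outdir / f"peptides_{bait}.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        paths[f"peptides_{bait}"] = path
    ref = simulate_reference(truth, coverage=0.6, noise=0.1, seed=cfg.seed)
    paths["reference"] = outdir / "reference.tsv"
    pd.DataFrame(sorted(ref.pairs), columns=["bait", "prey"]).to_csv(
        paths["reference"], sep="\t", index=False
    )
    paths["lengths"] = outdir / "lengths.tsv"
    matrix.preys["length"].rename("length").rename_axis("prey").to_csv(
        paths["lengths"], sep="\t"
    )
    paths["pax"] = outdir / "pax.tsv"
    simulate_pax(truth, seed=cfg.seed).rename_axis("prey").to_csv(
        paths["pax"], sep="\t"
    )
    paths["truth"] = outdir / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t")
    return paths
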