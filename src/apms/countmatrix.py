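"""Spectral-count matrices for AP-MS experiments.

A :class:`CountMatrix` holds non-negative integer spectral counts indexed by
(prey, run), where each run is either a bait purification (annotated with the
bait gene symbol and a replicate index) or a negative control. This is the
shape of the matrix an ABACUS-style spectral-count extraction produces: one
row per prey protein (gene symbol, accession, length in amino acids) and one
column per purification.

Two tab-delimited dialects are supported:

* ``long`` — one row per (prey, run) cell with columns
  ``prey_gene, prey_accession, prey_length, run_id, bait, count``; omitted
  cells read as zero.
* ``wide`` — columns ``prey_gene, prey_accession, prey_length`` followed by
  one column per run. Run columns are named ``<BAIT>_r<k>`` (``CONTROL_r<k>``
  for control runs) so the header itself declares bait/control labels and
  replicate indices.

Lines starting with ``#`` are comments. The writer emits the long dialect.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FormatError, ValidationError

#: Sentinel bait label for negative-control runs.
CONTROL = "CONTROL"

_RUN_ID_RE = re.compile(r"^(?P<bait>.+)_r(?P<rep>\d+)$")

LONG_COLUMNS = [
    "prey_gene",
    "prey_accession",
    "prey_length",
    "run_id",
    "bait",
    "count",
]


@dataclass(frozen=True)
class Run:
    """One purification run: a bait isolation or a negative control."""

    run_id: str
    bait: str | None  # None for control runs
    replicate_index: int

    def __post_init__(self) -> None:
        if self.replicate_index < 1:
            raise ValidationError(
                f"replicate_index must be >= 1, got {self.replicate_index}"
            )
        if self.bait is not None and self.bait.upper() == CONTROL:
            object.__setattr__(self, "bait", None)

    @property
    def is_control(self) -> bool:
        return self.bait is None

    @property
    def bait_label(self) -> str:
        return CONTROL if self.bait is None else self.bait


@dataclass
class CountMatrix:
    """Validated spectral counts per (prey, run) with run/prey metadata.

    Parameters
    ----------
    counts
        Integer DataFrame, index = prey gene symbols, columns = run ids.
    preys
        DataFrame indexed by prey gene symbol with columns ``accession``
        and ``length`` (amino acids, >= 1).
    runs
        Run annotations, one per counts column.
    """

    counts: pd.DataFrame
    preys: pd.DataFrame
    runs: list[Run]

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.counts.index = [str(g).upper() for g in self.counts.index]
        self.preys = self.preys.copy()
        self.preys.index = [str(g).upper() for g in self.preys.index]
        self._validate()

    def _validate(self) -> None:
        run_ids = [r.run_id for r in self.runs]
        if len(set(run_ids)) != len(run_ids):
            raise ValidationError("duplicate run_id in run annotations")
        if list(self.counts.columns) != run_ids:
            raise ValidationError("counts columns do not match run annotations")
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate prey rows: {dupes}")
        if not self.counts.index.equals(self.preys.index):
            raise ValidationError("counts index does not match prey table")
        arr = self.counts.to_numpy()
        if arr.size:
            if np.any(arr < 0):
                raise ValidationError("negative spectral counts")
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("non-integer spectral counts")
        self.counts = self.counts.astype(np.int64)
        if len(self.preys) and (self.preys["length"] < 1).any():
            bad = self.preys.index[self.preys["length"] < 1].tolist()
            raise ValidationError(f"prey length < 1 aa: {bad}")

    # -- convenience -----------------------------------------------------

    @property
    def run_ids(self) -> list[str]:
        return [r.run_id for r in self.runs]

    @property
    def baits(self) -> list[str]:
        """Distinct bait gene symbols, in first-seen order."""
        seen: dict[str, None] = {}
        for r in self.runs:
            if not r.is_control:
                seen.setdefault(r.bait, None)
        return list(seen)

    def runs_for(self, bait: str | None) -> list[Run]:
        """Runs for one bait, or the control runs when ``bait`` is None."""
        if bait is None:
            return [r for r in self.runs if r.is_control]
        bait = bait.upper()
        return [r for r in self.runs if r.bait == bait]

    def control_runs(self) -> list[Run]:
        return self.runs_for(None)


@dataclass
class NormalizedCounts:
    """Real-valued counts after bait-group normalization.

    ``scale_factors`` maps run_id -> the multiplier applied to that run
    (1.0 for control runs and for baits not being normalized).
    """

    counts: pd.DataFrame
    preys: pd.DataFrame
    runs: list[Run]
    scale_factors: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def run_ids(self) -> list[str]:
        return [r.run_id for r in self.runs]

    def runs_for(self, bait: str | None) -> list[Run]:
        if bait is None:
            return [r for r in self.runs if r.is_control]
        bait = bait.upper()
        return [r for r in self.runs if r.bait == bait]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _parse_run_id(run_id: str, declared_bait: str | None = None) -> Run:
    m = _RUN_ID_RE.match(run_id)
    if m:
        bait = m.group("bait").upper()
        return Run(
            run_id=run_id,
            bait=None if bait == CONTROL else bait,
            replicate_index=int(m.group("rep")),
        )
    if declared_bait is None:
        raise FormatError(
            f"run column {run_id!r} does not encode a bait "
            "(expected '<BAIT>_r<k>' or 'CONTROL_r<k>')"
        )
    return Run(run_id=run_id, bait=declared_bait, replicate_index=1)


def read_count_matrix(path: str | Path, dialect: str = "long") -> CountMatrix:
    """Read a spectral-count matrix from a tab-delimited file.

    Missing (prey, run) cells read as zero; a duplicated cell is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect not in ("long", "wide"):
        raise ConfigError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # malformed TSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if dialect == "long":
        return _from_long(df)
    return _from_wide(df)


def _coerce_counts(values: pd.Series, where: str) -> pd.Series:
    num = pd.to_numeric(values, errors="coerce")
    if num.isna().any():
        raise ValidationError(f"non-numeric count in {where}")
    if (num < 0).any():
        raise ValidationError(f"negative count in {where}")
    if not np.allclose(num, np.round(num)):
        raise ValidationError(f"non-integer count in {where}")
    return num.astype(np.int64)


def _from_long(df: pd.DataFrame) -> CountMatrix:
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"long dialect missing columns: {sorted(missing)}")
    df = df.copy()
    df["prey_gene"] = df["prey_gene"].str.upper()
    df["bait"] = df["bait"].str.upper()
    df["count"] = _coerce_counts(df["count"], "long table")
    dup = df.duplicated(subset=["prey_gene", "run_id"])
    if dup.any():
        pairs = df.loc[dup, ["prey_gene", "run_id"]].itertuples(index=False)
        raise ValidationError(
            "duplicated (prey, run) cells: " + ", ".join(map(str, pairs))
        )
    # replicate index from the run-id suffix when present, else by sorted order
    runs: list[Run] = []
    run_bait = df.drop_duplicates("run_id").set_index("run_id")["bait"]
    rep_counter: dict[str, int] = {}
    for run_id in run_bait.index:
        bait = run_bait[run_id]
        bait = None if bait == CONTROL else bait
        m = _RUN_ID_RE.match(run_id)
        if m:
            rep = int(m.group("rep"))
        else:
            key = bait or CONTROL
            rep_counter[key] = rep_counter.get(key, 0) + 1
            rep = rep_counter[key]
        runs.append(Run(run_id=run_id, bait=bait, replicate_index=rep))
    preys = (
        df.drop_duplicates("prey_gene")
        .set_index("prey_gene")[["prey_accession", "prey_length"]]
        .rename(columns={"prey_accession": "accession", "prey_length": "length"})
    )
    preys = _validate_lengths(preys)
    wide = (
        df.pivot(index="prey_gene", columns="run_id", values="count")
        .reindex(index=preys.index, columns=[r.run_id for r in runs])
        .fillna(0)
        .astype(np.int64)
    )
    wide.columns.name = None
    wide.index.name = None
    return CountMatrix(counts=wide, preys=preys, runs=runs)


def _from_wide(df: pd.DataFrame) -> CountMatrix:
    meta_cols = ["prey_gene", "prey_accession", "prey_length"]
    missing = set(meta_cols) - set(df.columns)
    if missing:
        raise FormatError(f"wide dialect missing columns: {sorted(missing)}")
    run_cols = [c for c in df.columns if c not in meta_cols]
    if not run_cols:
        raise FormatError("wide dialect has no run columns")
    df = df.copy()
    df["prey_gene"] = df["prey_gene"].str.upper()
    if df["prey_gene"].duplicated().any():
        dupes = df.loc[df["prey_gene"].duplicated(), "prey_gene"].tolist()
        raise ValidationError(f"duplicated prey rows: {dupes}")
    runs = [_parse_run_id(c) for c in run_cols]
    preys = df.set_index("prey_gene")[["prey_accession", "prey_length"]].rename(
        columns={"prey_accession": "accession", "prey_length": "length"}
    )
    preys = _validate_lengths(preys)
    counts = df.set_index("prey_gene")[run_cols]
    for c in run_cols:
        counts[c] = _coerce_counts(counts[c].fillna("0"), f"column {c}")
    counts = counts.reindex(index=preys.index)
    counts.index.name = None
    return CountMatrix(counts=counts, preys=preys, runs=runs)


def _validate_lengths(preys: pd.DataFrame) -> pd.DataFrame:
    preys = preys.copy()
    length = pd.to_numeric(preys["length"], errors="coerce")
    bad = length.isna() | (length < 1)
    if bad.any():
        # silent length defaults would corrupt NSAF downstream: reject the prey
        warnings.warn(
            f"dropping preys with missing/invalid length: {preys.index[bad].tolist()}",
            stacklevel=3,
        )
        preys = preys.loc[~bad]
        length = length.loc[~bad]
    preys["length"] = length.astype(np.int64)
    return preys


def write_count_matrix(m: CountMatrix, path: str | Path) -> None:
    """Write a CountMatrix in the long dialect (cells with count 0 omitted)."""
    rows = []
    bait_by_run = {r.run_id: r.bait_label for r in m.runs}
    for run_id in m.run_ids:
        col = m.counts[run_id]
        for gene, count in col.items():
            if count == 0:
                continue
            rows.append(
                {
                    "prey_gene": gene,
                    "prey_accession": m.preys.loc[gene, "accession"],
                    "prey_length": m.preys.loc[gene, "length"],
                    "run_id": run_id,
                    "bait": bait_by_run[run_id],
                    "count": int(count),
                }
            )
    # keep preys with all-zero rows visible so a round trip is cell-identical
    seen = {r["prey_gene"] for r in rows}
    first_run = m.run_ids[0] if m.runs else None
    for gene in m.counts.index:
        if gene not in seen and first_run is not None:
            rows.append(
                {
                    "prey_gene": gene,
                    "prey_accession": m.preys.loc[gene, "accession"],
                    "prey_length": m.preys.loc[gene, "length"],
                    "run_id": first_run,
                    "bait": bait_by_run[first_run],
                    "count": 0,
                }
            )
    pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cleaning and normalization
# ---------------------------------------------------------------------------


def clean_preys(m: CountMatrix, blocklist: Iterable[str]) -> CountMatrix:
    """Remove blocklisted preys (keratins, external contaminants) by gene symbol."""
    block = {str(g).upper() for g in blocklist}
    keep = [g for g in m.counts.index if g not in block]
    return CountMatrix(
        counts=m.counts.loc[keep], preys=m.preys.loc[keep], runs=list(m.runs)
    )


def zero_bait_self_counts(
    m: CountMatrix, bait_prey_map: Mapping[str, str] | None = None
) -> CountMatrix:
    """Zero each bait's own spectral counts in its purification runs.

    The bait protein dominates its own isolation; its counts carry no
    interaction information and bias normalization, so they are set to zero.
    ``bait_prey_map`` maps bait label -> prey gene symbol; identity by default.
    """
    bait_prey_map = {
        k.upper(): v.upper() for k, v in (bait_prey_map or {}).items()
    }
    counts = m.counts.copy()
    for run in m.runs:
        if run.is_control:
            continue
        gene = bait_prey_map.get(run.bait, run.bait)
        if gene is None:
            raise ConfigError(f"bait {run.bait!r} missing from bait→prey map")
        if gene in counts.index:
            counts.loc[gene, run.run_id] = 0
    return CountMatrix(counts=counts, preys=m.preys, runs=list(m.runs))


def identity_normalized(m: CountMatrix) -> NormalizedCounts:
    """Wrap a CountMatrix as NormalizedCounts with unit scale factors.

    For runs acquired at a common sampling depth no totals correction is
    needed; scoring then operates on the raw counts.
    """
    return NormalizedCounts(
        counts=m.counts.astype(float).copy(),
        preys=m.preys.copy(),
        runs=list(m.runs),
        scale_factors=pd.Series(1.0, index=m.run_ids),
    )


def normalize_counts(m: CountMatrix, bait: str) -> NormalizedCounts:
    """Scale one bait's runs by mean control total / mean bait-run total.

    Preys with high counts in an abundant isolation would otherwise dominate
    specificity scoring; after normalization the mean total count of the
    bait's runs equals the mean total of the control runs. Control runs keep
    scale factor 1; other baits' runs are left untouched (factor 1).
    """
    bait = bait.upper()
    ctrl = m.control_runs()
    bait_runs = m.runs_for(bait)
    if not ctrl:
        raise ConfigError("no control runs present")
    if not bait_runs:
        raise ConfigError(f"no runs for bait {bait!r}")
    totals = m.counts.sum(axis=0)
    ctrl_mean = totals[[r.run_id for r in ctrl]].mean()
    bait_mean = totals[[r.run_id for r in bait_runs]].mean()
    if bait_mean == 0:
        raise DataError(f"bait {bait!r} has zero total spectral counts")
    factor = float(ctrl_mean) / float(bait_mean)
    counts = m.counts.astype(float).copy()
    factors = pd.Series(1.0, index=m.run_ids)
    for r in bait_runs:
        counts[r.run_id] = counts[r.run_id] * factor
        factors[r.run_id] = factor
    return NormalizedCounts(
        counts=counts, preys=m.preys.copy(), runs=list(m.runs), scale_factors=factors
    )
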