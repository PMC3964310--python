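"""Downstream interactome summaries.

* Hierarchical clustering of log2 spectral-count profiles under Pearson
  correlation distance (average linkage), for preys and for runs/baits.
* NSAF (normalized spectral abundance factor) and cellular-abundance
  normalized enrichment indices.
* Bait-centric network export (node/edge TSV and SIF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import DataError
from .integration import INTERACTION_CATEGORIES, StabilityProfile

__all__ = [
    "ClusterResult",
    "EnrichmentRecord",
    "log2_counts",
    "cluster_matrix",
    "linkage_to_newick",
    "nsaf",
    "enrichment_index",
    "export_network",
    "write_sif",
]


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    prey_order: list[str]
    run_order: list[str]
    prey_linkage: np.ndarray
    run_linkage: np.ndarray
    matrix: pd.DataFrame  # input matrix reordered by the two dendrograms

    def prey_newick(self) -> str:
        return linkage_to_newick(self.prey_linkage, list(self.matrix.index))

    def run_newick(self) -> str:
        return linkage_to_newick(self.run_linkage, list(self.matrix.columns))


def log2_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1); the +1 keeps zero counts finite."""
    return np.log2(counts.astype(float) + 1.0)


def _pearson_distance(x: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson r distances over rows of x.

    A zero-variance row has no defined correlation; its distance to every
    other row is set to 1 (uninformative) with a warning.
    """
    n = x.shape[0]
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance profile(s); distances set to 1",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    d = 1.0 - corr
    d[np.isnan(d)] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return squareform(d, checks=False)


def cluster_matrix(matrix: pd.DataFrame) -> ClusterResult:
    """Average-linkage trees for rows (preys) and columns (runs).

    ``matrix`` should already hold log2-transformed counts of the filtered
    preys with bait self-counts removed (see :func:`log2_counts` and the
    pipeline). Requires at least 2 rows and 2 columns.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise DataError(f"need >= 2 preys and >= 2 runs, got {matrix.shape}")
    x = matrix.to_numpy(dtype=float)
    prey_link = hierarchy.linkage(_pearson_distance(x), method="average")
    run_link = hierarchy.linkage(_pearson_distance(x.T), method="average")
    prey_order = [matrix.index[i] for i in hierarchy.leaves_list(prey_link)]
    run_order = [matrix.columns[i] for i in hierarchy.leaves_list(run_link)]
    return ClusterResult(
        prey_order=prey_order,
        run_order=run_order,
        prey_linkage=prey_link,
        run_linkage=run_link,
        matrix=matrix.loc[prey_order, run_order],
    )


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree with branch lengths."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = linkage[i - n]
        a, b = int(a), int(b)
        la = f"{node(a)}:{max(h - heights[a], 0.0):.6g}"
        lb = f"{node(b)}:{max(h - heights[b], 0.0):.6g}"
        heights[i] = h
        return f"({la},{lb})"

    root = n + len(linkage) - 1
    return node(root) + ";"


# ---------------------------------------------------------------------------
# NSAF and enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentRecord:
    prey: str
    nsaf: float
    pax_abundance: float | None
    enrichment_index: float | None


def nsaf(counts: pd.Series, lengths: pd.Series) -> pd.Series:
    """Normalized spectral abundance factor per prey.

    NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j): spectral counts scaled by
    protein length (longer proteins yield more peptides), renormalized to
    sum to one over the prey set.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()].tolist()
        raise DataError(f"missing protein length for {missing}")
    if (lengths < 1).any():
        raise DataError("protein lengths must be >= 1")
    saf = counts.astype(float) / lengths.astype(float)
    total = saf.sum()
    if total <= 0:
        raise DataError("all spectral counts are zero; NSAF undefined")
    return saf / total


def enrichment_index(
    nsaf_values: pd.Series,
    pax_abundance: pd.Series,
    reference_prey: str,
) -> list[EnrichmentRecord]:
    """NSAF over cellular abundance, scaled so the reference prey is 1.

    Dividing a prey's NSAF (its share of the isolate) by its proteome-wide
    abundance highlights proteins enriched in the isolation beyond what
    their cellular copy number predicts. Preys missing from the abundance
    table get a flagged record with no index.
    """
    reference_prey = reference_prey.upper()
    nsaf_values = nsaf_values.copy()
    nsaf_values.index = [str(i).upper() for i in nsaf_values.index]
    pax = pax_abundance.copy()
    pax.index = [str(i).upper() for i in pax.index]
    if reference_prey not in nsaf_values.index or reference_prey not in pax.index:
        raise DataError(f"reference prey {reference_prey} missing from NSAF or abundance")
    ref_raw = nsaf_values[reference_prey] / pax[reference_prey]
    if not np.isfinite(ref_raw) or ref_raw <= 0:
        raise DataError(f"reference prey {reference_prey} has non-positive index")
    records = []
    for prey, value in nsaf_values.items():
        if prey in pax.index and pax[prey] > 0:
            idx = (value / pax[prey]) / ref_raw
            records.append(EnrichmentRecord(prey, float(value), float(pax[prey]), float(idx)))
        else:
            records.append(EnrichmentRecord(prey, float(value), None, None))
    return records


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------


def export_network(
    profiles: Iterable[StabilityProfile],
    mean_counts: Mapping[tuple[str, str], float] | None = None,
    known_pairs: Iterable[tuple[str, str]] | None = None,
    annotations: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build node/edge tables for a bait-centric interaction network.

    Only interaction categories (stable/dynamic/rescued/unquantified) become
    edges; contaminant and nonspecific preys are excluded. Edge weight is
    log2(mean spectral count + 1) when counts are supplied.
    """
    mean_counts = dict(mean_counts or {})
    known = {(b.upper(), p.upper()) for b, p in (known_pairs or [])}
    annotations = {k.upper(): v for k, v in (annotations or {}).items()}
    g = nx.Graph()
    for p in profiles:
        if p.category not in INTERACTION_CATEGORIES:
            continue
        g.add_node(p.bait, role="bait")
        if p.prey not in g:
            g.add_node(p.prey, role="prey")
        count = mean_counts.get((p.bait, p.prey))
        weight = float(np.log2(count + 1.0)) if count is not None else np.nan
        g.add_edge(
            p.bait,
            p.prey,
            weight=weight,
            category=p.category,
            known=(p.bait, p.prey) in known,
        )
    nodes = pd.DataFrame(
        [
            {
                "gene": n,
                "role": data["role"],
                "process": annotations.get(n, ""),
            }
            for n, data in sorted(g.nodes(data=True))
        ],
        columns=["gene", "role", "process"],
    )
    edges = pd.DataFrame(
        [
            {
                "bait": a if g.nodes[a]["role"] == "bait" else b,
                "prey": b if g.nodes[a]["role"] == "bait" else a,
                "weight": data["weight"],
                "category": data["category"],
                "known": data["known"],
            }
            for a, b, data in g.edges(data=True)
        ],
        columns=["bait", "prey", "weight", "category", "known"],
    ).sort_values(["bait", "prey"], ignore_index=True)
    return nodes, edges


def write_sif(edges: pd.DataFrame, path: str | Path) -> None:
    """Write edges in simple interaction format: bait <tab> pp <tab> prey."""
    with open(path, "w", encoding="utf-8") as fh:
        for row in edges.itertuples(index=False):
            fh.write(f"{row.bait}\tpp\t{row.prey}\n")
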