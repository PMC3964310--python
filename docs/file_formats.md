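# File formats

All files are tab-delimited UTF-8 text; lines starting with `#` are
comments. Gene symbols are matched case-insensitively and written
uppercased. The `CONTROL` bait label marks negative-control runs.

## Spectral-count matrix

**Long dialect** (the writer's output): one row per non-zero
(prey, run) cell.

| column | type | notes |
|---|---|---|
| prey_gene | text | official gene symbol |
| prey_accession | text | protein accession |
| prey_length | int ≥ 1 | amino acids; preys without a valid length are rejected |
| run_id | text | unique per run; `<BAIT>_r<k>` convention recommended |
| bait | text | bait gene symbol, or `CONTROL` |
| count | int ≥ 0 | spectral count; omitted cells read as 0 |

A duplicated (prey_gene, run_id) pair is an error. The replicate index is
parsed from a `_r<k>` run-id suffix when present, otherwise assigned by
sorted run-id order within each bait.

**Wide dialect**: columns `prey_gene`, `prey_accession`, `prey_length`,
then one column per run named `<BAIT>_r<k>` (`CONTROL_r<k>` for controls),
so the header itself declares run ids, bait/control labels, and replicate
indices. One row per prey; empty cells read as 0.

## SILAC peptide table

| column | type | notes |
|---|---|---|
| prey_gene | text | |
| peptide_seq | text | peptides mapping to >1 prey are dropped as ambiguous |
| light_intensity | real ≥ 0 | |
| heavy_intensity | real ≥ 0 | not both zero |
| sample | `ip` \| `input` | IP vs mixed-lysate input (mixing normalizer) |

## Reference interaction list

Two columns, `bait` and `prey`; duplicates collapse.

## Length and abundance tables

`lengths.tsv`: `prey`, `length` (aa). `pax.tsv`: `prey`,
`pax_abundance` (ppm-like positive reals).

## Outputs

* `saint_results.tsv` / `saint_filtered.tsv`: bait, prey, iprob_1..n,
  score, threshold, passes, manual_flag.
* `stability_<BAIT>.tsv`: prey, idirt_ratio, n_peptides, normalizer.
* `profiles.tsv`: bait, prey, saint_score, idirt_ratio, category.
* `roc_<BAIT>.tsv`: threshold, approx_tp_rate, approx_fp_rate, recovery.
* `enrichment_<BAIT>.tsv`: prey, nsaf, pax_abundance, enrichment_index.
* `cluster_matrix.tsv` plus `prey_dendrogram.nwk` / `run_dendrogram.nwk`
  (Newick with branch lengths).
* `network_nodes.tsv` / `network_edges.tsv` / `network.sif`.
* `manifest.json`: seed, config hash, per-stage output digests.
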