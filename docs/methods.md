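# Methods

## Scope and data model

The package analyses two complementary AP-MS readouts for the same baits:

* a **spectral-count matrix**: non-negative integer counts per
  (prey, run), where runs are bait purifications (2–3 biological
  replicates per bait) or negative controls (typically 7); preys carry a
  gene symbol, accession, and protein length in amino acids;
* **SILAC peptide tables** from I-DIRT experiments: per peptide, a light
  and a heavy intensity, plus the same for a mixed-lysate *input* sample.

Gene symbols are matched case-insensitively and stored uppercased, because
reference interaction lists mix capitalization conventions. Preys without
a valid protein length are rejected at read time (with a warning) rather
than defaulted, since a silent length default would corrupt NSAF values
downstream.

## Count preprocessing

Blocklisted preys (keratins, known environmental contaminants) are removed
first. The bait's own counts in its own purifications are then set to
zero: the bait dominates its isolation, carries no interaction
information, and would bias both normalization and clustering. Run totals
used anywhere afterwards are computed on this cleaned, bait-zeroed matrix.

`normalize_counts` rescales one bait's runs by
(mean control run total) / (mean bait run total), leaving controls
untouched, so that mean totals agree between the two groups (asserted to
1e-9 in tests). This is a correction for differential *acquisition depth*.
It is deliberately **optional** in the scoring path (`saint.normalize` in
the pipeline config, default off): when bait runs contain more total
counts because they contain genuine interactors — which is exactly the
situation the synthetic generator produces, where all runs are drawn at a
common per-prey rate scale — a totals-ratio correction shrinks the
specific signal itself (for the default simulation, by a factor of ≈6,
which measurably costs sensitivity). For real data in which runs were
acquired at visibly different depths, enable it.

## Specificity model

Scoring is a fixed, documented surrogate for mixture-model interaction
scoring, run **per bait** against the shared controls so that baits with
very different interactome sizes do not share parameters:

* background rate per prey: λ_F = (Σ control counts + c) / n_controls;
* specific rate per prey: λ_T = (Σ bait-replicate counts + c) / n_reps,
  floored at `minfold`·λ_F (default 1) and kept at least 1e-6 above λ_F;
* per-replicate probability: Bayes posterior of the specific component
  under Poisson likelihoods evaluated at the count rounded to the nearest
  integer (normalization can produce non-integers), with prior π;
* pair score: mean of the two highest replicate probabilities (the single
  probability when only one replicate exists).

Defaults: π = 0.1, pseudocount c = 0.1. Both are exposed in configuration.
The posterior is computed in log space; for counts up to several hundred
it matches an exact factorial-based computation to better than 1e-12
(tested). iProb is non-decreasing in the count whenever λ_T > λ_F.

Two consequences of this surrogate are worth knowing. First, a prey whose
bait counts match the controls scores ≈ π, not 0; the "very low score"
contaminant signature therefore sits near the π = 0.1 default, and a
light-only contaminant whose bait counts fluctuate slightly above its
control mean can score just above 0.1 and be reported *rescued* rather
than *contaminant* (its ratio of 1.0 still flags it as label-pure). Second,
λ_T is estimated from the same counts it scores, so scores are slightly
anti-conservative for preys observed once at a moderate count; the
two-highest-replicate rule damps this.

Thresholding is per bait: score ≥ t (or > t for baits configured strict),
with defaults 0.75 and stricter settings intended for baits with large,
promiscuous interactomes. A manual-include list preserves well-established
partners whose low abundance keeps them below any count-based threshold;
these are flagged `manual` in all outputs.

## Reference benchmarking

A reference set of (bait, prey) pairs approximates ground truth. At each
threshold of a descending grid, the TP rate is computed over *scored*
known pairs, the FP rate over scored novel pairs, and recovery over **all**
reference pairs of the bait (so preys never observed with the bait count
against recovery but not against the rates). Absence from a catalog is not
evidence of non-interaction, so outputs label these rates approximate.
Curve monotonicity is asserted on construction; the area under the
(FP, TP) curve closes the polygon at (0,0) and (1,1).

## Stability ratios

Raw per-peptide light/heavy odds are divided by the input normalizer — the
median over input proteins (≥2 peptides each) of their median peptide
odds — and then converted to a fraction, f = odds/(1+odds). Odds-space
correction is the only order in which restoring an imbalanced input to
1:1 makes a fully exchanging prey read 0.5. A light-only peptide is 1.0
and a heavy-only peptide 0.0 regardless of the normalizer. Protein ratios
are the median over ≥2 quantified peptides; peptide sequences assigned to
more than one prey are dropped as ambiguous. Doubling every light
intensity (IP and input together) leaves all ratios unchanged to 1e-9.

Ratios are reported as *light* fractions. With light-labeled bait-expressing
cells, a stable interaction is label-pure light, so stability → 1.0; the
orientation is fixed by that requirement.

## Quadrant classification

Defaults: specificity threshold as configured per bait (0.75), stable/
dynamic boundary at ratio 0.80, contaminant signature score < 0.10 with
ratio ≥ 1.0 − 1e-6 (exact 1.0 up to floating point). Precedence:
contaminant first, then rescued (fails specificity, ratio ≥ 0.80), then
stable / dynamic (passes, ratio ≥ / < 0.80), else nonspecific. A prey
passing specificity but absent from the I-DIRT experiment is kept as
*unquantified* — absence from one workflow is not evidence against the
interaction. A prey quantified by I-DIRT but never observed label-free is
classified with score 0, so light-only contaminants unseen in the
label-free workflow still land in the contaminant quadrant. The function
is total: every (score, ratio) pair, missing values included, maps to
exactly one category (tested exhaustively on a 0.05 grid).

## Clustering, NSAF, networks

Clustering operates on log2(x+1)-transformed counts (the +1 keeps zeros
finite) of specificity-passing preys with bait self-counts removed, under
distance d = 1 − Pearson r with average linkage, separately for prey rows
and run columns. A zero-variance profile has no defined correlation; its
distance to everything is set to 1 with a warning. Dendrograms are
emitted as Newick with branch lengths; tie-breaking follows scipy's
deterministic input-order convention, so trees are reproducible.

NSAF_i = (SpC_i/L_i) / Σ_j (SpC_j/L_j) over the analyzed prey set (sums
to 1 by construction; asserted to 1e-9). The enrichment index divides
NSAF by a cellular-abundance value (PAX-style, ppm) and rescales so a
chosen reference protein is exactly 1; preys missing from the abundance
table get a flagged record with no index. Per-prey counts for NSAF and
edge weights are means over the bait's replicate runs.

Network export emits node/edge TSVs and SIF. Only stable, dynamic,
rescued, and unquantified categories become edges; edge weight is
log2(mean count + 1) and edges carry the known/novel flag when a
reference list is available.

## Synthetic data

The generator draws the study design the analysis assumes: by default 3
baits × 3 replicates against 7 controls; 450 background preys with
per-prey background rates uniform on (0.02, 0.5] counts/run in every run;
50 specific preys per bait at λ_T = 15 counts/run in their bait's runs
(background rate elsewhere), including a 10-prey complex shared by the
first two baits; the bait protein itself at rate 200 in its own runs; and
5 light-only contaminants at background-level counts in all runs. Counts
are Poisson (a Gamma–Poisson overdispersion option exists for robustness
experiments only). Protein lengths are uniform on 100–2000 aa and
abundances lognormal — arbitrary but realistic scales for enrichment
arithmetic.

For I-DIRT, a prey with exchange fraction f has expected light fraction
1 − f/2 (f = 1 fully exchanging → 0.5; f = 0 stable → 1.0, with heavy
intensity exactly zero unless a leakage parameter is set). Peptide
intensities are lognormal around these expectations (σ = 0.2 per channel
by default, 20 peptides/prey); a global mixing-imbalance parameter
multiplies the light channel of every peptide including the input sample,
which is what the input normalizer must undo. Half of each bait's own
specific preys are stable (f = 0), half fully exchanging (f = 1), and the
shared complex is stable.

What the generator does **not** emulate: compositional competition for
MS/MS sampling (run totals are not fixed, which is why depth
normalization is off by default on synthetic data), peptide-level
identification errors, protein inference ambiguity beyond simple shared
peptides, label incorporation below 100 %, and arginine-to-proline
conversion. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to those
upstream artifacts.

## Pipeline and reproducibility

All stages run from one YAML config with a mandatory integer seed that
governs every random draw. Each stage records SHA-256 digests of its
outputs in `manifest.json`; rerunning with the same config and seed
reproduces digests exactly (tested), resuming skips stages whose outputs
are intact, and a digest mismatch aborts with a dependency error instead
of silently overwriting. Exit codes: 0 ok, 2 configuration error, 3 data
error.

Problem sizes used in the shipped tests and in `scripts/acceptance.py` —
the default 3-bait matrix (≈600 preys × 16 runs) and I-DIRT experiments
of 50–100 peptide-pair preys — were chosen as the smallest designs at
which the stochastic properties (recovery rates, median-ratio
convergence) are stable across seeds.

## Known limitations

* No numeric parity with any released SAINT implementation is attempted;
  thresholds tuned for real SAINT scores may need recalibration for the
  surrogate.
* The contaminant/rescued boundary interacts with the prior π (see above).
* The ROC-like rates inherit the incompleteness of whatever reference
  catalog is supplied.
* Statistical testing of enrichment indices (beyond the point estimates)
  and term-enrichment analysis are out of scope; exports are designed to
  feed standard network and enrichment tools.
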