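# Methods

## The problem

Perturbation-expression screens treat cultured cells with bioactive
compounds and record genome-wide expression fold changes
(treatment/control) per *instance*. Instances are produced in experimental
*batches*, and cells sharing a culture run resemble each other more than
biology warrants: the batch effect can dominate the drug effect, so naive
profile similarity connects co-batched compounds rather than
co-pharmacology. dtibridge removes the batch component using compounds
assayed in more than one batch, scores compound–compound similarity on the
adjusted profiles, and turns similarity into target-level predictions.

All input fold changes are linear ratios (> 0); every internal computation
is on log₂ scale. Log base is a presentation choice only — any fixed base
yields identical adjusted ratios and identical ranks.

## Bridge-based batch adjustment

Model: for gene g and instance i of compound c in batch b,

    log₂ E(g, i) = drug(c, g) + offset(b, g) + ε.

Under this additive-in-log model, if batches A and B share n bridge
instance pairs (same compound, different batch), the per-gene mean of
paired log differences

    Δ(g) = (1/n) Σᵢ [log₂ E(A,i,g) − log₂ E(B,i,g)]

is an unbiased estimate of offset(A,g) − offset(B,g), and multiplying every
instance of B by 2^Δ(g) moves the whole batch onto A's scale exactly (up to
the noise term). All cross-batch instance pairs of every shared compound
are used, each weighted equally.

Merge procedure:

* **Seed component.** Among batches with at least `big_batch_min` (default
  30) instances, the connected component (in the bridge graph) with the
  most instances is merged first, largest batch first, each next seed batch
  chosen among those already bridged to the current component (largest
  first, then most bridge pairs, then batch id). If no batch is big enough,
  the single largest batch seeds and a warning is logged.
* **Absorption.** Remaining batches are absorbed one at a time: the batch
  with the most bridge pairs to the *current* merged component wins; ties
  break by batch size, then id. Δ is always re-estimated against the
  current, already-adjusted component — never precomputed pairwise — so
  each absorbed batch lands directly on the seed scale.
* **Unbridgeable batches** (no bridge path to the seed component) are
  excluded from the plan and reported, never silently passed through.

Consequences, all tested: bridge-pair mean log differences are exactly
zeroed across every merge edge; within-batch ratios between instances are
untouched (the adjustment is a per-batch gene-wise rescaling); instances of
the already-merged component never move again; with zero noise the
adjustment recovers drug profiles exactly.

A structural caveat: after adjustment every instance carries the seed
component's offset. This common component inflates all pairwise
similarities uniformly; it cannot be removed by bridging (it is the scale
the data are expressed on) and does not affect the *ranking* of compounds
within a screen, but it compresses the dynamic range of the similarity
score. The same is true of the original procedure on real data.

## Profiles, signatures, and the BAES score

Per compound, the profile is the mean of log₂ fold changes over all of its
instances, pooled across batches, cell lines and doses (each instance
weighted equally; an arithmetic-mean-of-ratios mode exists behind a flag).
Genes are ranked by descending profile value, ties broken lexicographically
by gene id for determinism. The signature is the top s and bottom s genes
(s = 250 by default, clamped to ⌊n/2⌋ so the tag sets never overlap).

The enrichment of a tag set in another compound's ranked list uses the
two-sided Kolmogorov–Smirnov statistic of the original connectivity-map
score: with sorted tag positions V(1) < … < V(t) among n genes,

    a = max_j ( j/t − V(j)/n ),   b = max_j ( V(j)/n − (j−1)/t ),
    KS = a  if a ≥ b  else −b.

The tie a = b (measure zero in continuous data, reachable in small exact
cases) resolves toward +a; the float comparison carries a 1e-12 guard so
exact-rational ties are not flipped by rounding. The directed score of
signature S against ranking R is KS_up − KS_down, set to 0 when KS_up and
KS_down share a sign (a signature whose halves disagree about the query's
direction carries no evidence). BAES for a pair is the mean of the two
directed scores, hence symmetric, with |BAES| ≤ 2. No per-query rescaling
of directed scores is applied by default (the instance-set rescaling of the
original connectivity map is a display convention).

The all-pairs computation is vectorised per query compound over an (m × s)
tag-position array; 120 compounds × 2000 genes score in under a second.

## LOI, LOOCV and enrichment statistics

For target T with N benchmark ligands, LOI(C, T) is the mean BAES between C
and the benchmarks, excluding C itself when it is a benchmark (so
benchmarks are scored against N−1, background compounds against N). This
is the naive guilt-by-association model: no fitting, no weights.

Evaluation per target (requires ≥ `min_ligands`, default 5):

* **AUC** by the Mann–Whitney rank statistic, P(LOI⁺ > LOI⁻) + ½P(tie).
* **95% CI** by stratified percentile bootstrap, 2000 replicates by
  default, positives and negatives resampled within their own stratum (no
  replicate can lose a class); reproducible from an integer seed.
* **Threshold** at 90% specificity: the ⌈0.9·n_neg⌉-th smallest negative
  LOI; a compound is called positive iff LOI is strictly above it. This
  order-statistic rule guarantees at least the requested specificity and is
  deterministic under ties (conservative: ties collapse below).
* **Enrichment**: OR = (TP/FN)/(FP/TN), with 0 when TP = 0 and +∞ when a
  zero FN or FP makes it unbounded; significance by a one-sided (greater)
  Fisher exact test, i.e. the hypergeometric tail P(X ≥ TP). On the
  canonical 9-positive / 1300-negative table (6, 3; 130, 1170) this yields
  OR = 18 and p = 7.31×10⁻⁵.
* **Well characterized** = (CI lower bound > 0.5) and (Fisher p < 0.05).

Negatives are *all* non-benchmark compounds; unknown true ligands
contaminate the negative set by design, which biases AUC and enrichment
downward. No multiple-testing correction is applied across targets (raw
p-values are the contract). LOOCV recomputes only LOI per fold; BAES is
pairwise and unaffected by held-out labels.

## The TTI screen

For an ordered pair (family T1, model T2) of ligand-disjoint targets: score
every compound's LOI against T2 (T2's benchmarks leave-self-out), set the
threshold from T2's negatives, then Fisher-test whether T1's ligands fall
above it more often than the rest of the universe (minus T2's own ligands,
which are known positives, not discoveries). Pairs sharing a ligand are
masked, never tested. The matrix is asymmetric — the family and model roles
differ. A Benjamini–Hochberg column is appended to matrix output purely as
a reading convenience; it is not part of the screen's contract.

## The synthetic-data generator

`SimConfig` defaults define the study conditions: 2000 genes, 10 batches
(three large, expected ≳ 30 instances, so the big-batch seed path is
exercised), 120 compounds of which 48 are ligands of 6 targets (8 each),
disjoint 40-gene target modules with signed effects (half up, half down,
magnitude `effect_size` = 1 log₂ unit), batch offsets N(0, 1) per
(batch, gene) — batch effects comparable to drug effects, the pathology the
method exists for — and residual noise sd 0.3. Each compound is assayed
once in a home batch and, with probability 0.5, once more in another batch
(the bridges; roughly 1.5 instances/compound).

Beyond its target modules, every compound perturbs a broad idiosyncratic
gene set: 20% of genes receive a compound-specific N(0, effect_size)
effect. This density matters: with near-empty profiles, rankings among the
unperturbed genes are decided by tie-breaking and by the batch offsets
shared across compounds, and signature tags become artifacts rather than
biology. Real drug signatures are dense; 20% keeps profiles individual
while leaving modules detectable.

Planted off-target (TTI) structure adds the model target's full module
(`tti_scale` = 1.0 — the planted family genuinely binds the second target;
weaker binding can be dialled down) to every ligand of the family target.
No TTI pairs are planted by default.

The generator is additive in log space — exactly the family under which
bridging is correct; a multiplicative-in-log misspecification mode (off by
default) exists to probe robustness, and under it zero-noise adjustment is
no longer exact.

What the generator does *not* emulate: probe-level noise models,
dose–response structure, cell-line-specific effects, correlated gene–gene
noise, and realistic annotation incompleteness. Passing tests therefore
demonstrate the pipeline's correctness and its statistical behaviour under
the stated generative model, not performance on real screens.

## Problem sizes and determinism

The test suite and the acceptance script run the full default screen
(2000 × ~180) in about a second per seed; aggregate studies use 20
independent seeds, which keeps the scrambled-label null mean AUC within
±0.05 of 0.5 at ~120 target evaluations. Every stochastic routine takes an
explicit integer seed (numpy `default_rng`); identical config + seed gives
byte-identical TSV/JSON artifacts.

## Known limitations

* The seed-component offset remains in all adjusted profiles (see above);
  similarity values are therefore comparable within a screen, not across
  screens.
* Per-target performance varies substantially across simulation seeds —
  some targets' modules land on genes where batch offsets blur the
  signature — mirroring the observation that real targets are very
  unequally characterized by expression screens.
* The TTI screen's power is limited by the model target's own LOOCV
  quality; families planted onto weakly-characterized model targets are
  not reliably detected.
* Fisher's exact test is conservative on small above-threshold slates
  (~11 slots at 120 compounds), so null screens show fewer than 5% of
  cells at p < 0.05.
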