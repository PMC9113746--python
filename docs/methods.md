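# Methods and design notes

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would otherwise have to
reverse-engineer. No empirical claim here goes beyond what the test suite
and `scripts/acceptance.py` themselves compute.

## Expression model and units

All analyses operate on TPM (transcripts per million), a within-sample
relative scale: every valid column sums to 10⁶ within a relative tolerance
of 10⁻⁶, and this invariant is enforced at container construction. Raw
counts are accepted only as input to `to_tpm` (counts/length rates,
column-normalized), since upstream quantification is out of scope. Absent
values are schema errors, never zeros — an expression table with holes is
evidence of a broken upstream join, not of non-expression.

Ratios are everywhere stabilized with a pseudocount ε = 0.01 TPM. Marker
genes routinely have true zeros in non-focal compartments; ε keeps a
100-TPM/0-TPM contrast at a ratio of ~10⁴ (comfortably past any fold
threshold) while shifting ratios of well-expressed genes by < 1%.

## Whole-body deconvolution ("the mixture identity")

Model: the whole-body profile is a convex-weight mixture of the dissected
parts' profiles, `Σ_c X_c(g)·w_c ≈ X_wb(g)`, with `Σ_c w_c = 1` when the
parts tile the body. The estimator solves this per marker gene — for a
gene exclusive to part `c` the identity collapses to
`ŵ = X_wb(g)/X_c(g)` — and averages the per-marker estimates per part with
equal weight. Assumptions:

* markers are genuinely exclusive (enforced by the census's ≥ 50-fold
  criterion against **every** other part individually, not against their
  maximum aggregate only — the strictest reading);
* thresholds apply to replicate-mean TPM per compartment, the values an
  atlas figure displays, rather than per-replicate minima;
* per-marker estimates are equally weighted ("averaged"), with the spread
  reported as a standard deviation; an expression-weighted mean is not the
  default because it would let a single very high marker dominate.

Fractions are never renormalized to sum to 1: a shortfall is information
(dissection losses, excised sections), so `sum_check` reports the raw
total and merely flags totals outside [90%, 110%].

Validation regresses log10(prediction + 1) on log10(observation + 1) over
genes observed at ≥ 1 TPM. TPM is heavy-tailed over ~5 orders of
magnitude; a linear-scale fit would be a fit to the top twenty genes.
Outliers are shed one at a time while the largest absolute externally
studentized residual exceeds 4, capped at 5 removals — conservative,
deterministic, and on atlas-like data it removes at most a single gross
point. Which variable is the response is itself a convention; prediction
is taken as the response so that residuals measure prediction failure.

The estimator agrees with a non-negative least-squares fit over the full
gene set to 10⁻⁶ on noiseless mixtures (tested against
`scipy.optimize.nnls` as an independent oracle); NNLS is deliberately not
the implementation path because the marker-ratio form is interpretable
per gene and robust to non-markers.

## Marker census

A marker of compartment `c` is a gene with mean TPM ≥ `min_tpm` (default
5) in `c` and `(X_c+ε)/(X_d+ε) ≥ min_fold` (default 50) for every other
compartment `d`. Because `min_fold` > 1, no gene can qualify in two
compartments; the census asserts this. Output is sorted by focal TPM
descending (ties by gene id) for deterministic reports.

## Investment, yield, output

* **Investment**: cell = Σ of the category's genes' TPM in that
  compartment/condition. Genes listed in a category but absent from the
  matrix are counted as zero and reported. Genes in several categories
  count in each (curated lists legitimately overlap; the overlap is
  flagged so double counting is visible).
* **Percent-of-max** is taken across compartments within a category (the
  compartment with the highest investment scores 100), and likewise for
  single genes. An all-zero vector is returned unscaled with a flag; a
  vector whose maximum is below 1 TPM is suppressed to zeros with a
  `low_expression` flag rather than scaled — a percent-of-max display of
  sub-1-TPM noise would imply patterning the data cannot support.
* **Yield** [ng RNA per organ] = concentration [ng/µl] × suspension
  volume [µl] / organs pooled, averaged over replicates.
* **Output** = investment × yield per compartment; shares are each
  compartment's percentage of a category's total output and sum to 100 by
  construction (an all-zero category is given equal shares and is visible
  as zero output).
* **Over-representation** is a flat, one-sided hypergeometric upper tail
  per category with Benjamini–Hochberg adjustment across categories —
  over-representation only, mirroring how classic-Fisher gene-set tests
  are used. No ontology graph traversal is attempted.

## Blood-meal waves

Pipeline: (1) censor genes whose maximum replicate-mean TPM across the
compared timepoints is below 2; (2) transform to log10(TPM+1); (3) z-score
each gene across timepoints with the n−1 standard deviation (zero-variance
rows dropped with a warning); (4) agglomerative clustering, Euclidean
metric, Ward linkage, cut at k = 6; (5) label each cluster centroid from
its deviations from the t0 baseline: the larger |deviation| of the 6 h and
24 h timepoints sets induced vs repressed by sign; sustained deviation
(|z₆ − z₂₄| < 0.5 with both excursions on the same side of baseline) is
*intermediate*, otherwise the extremum timepoint decides *rapid* (6 h)
vs *delayed* (24 h).

k defaults to 6 — three induced plus three repressed waves. The 0.5
z-unit sustained-wave tolerance is a package decision and configurable.

Two defaults deserve justification because the classic heatmap-tool recipe
(raw-scale row z-scores, complete linkage) was tried first and rejected:

* **log before z.** On the raw TPM scale a cohort's z profile is dominated
  by the multiplicative noise of its highest-amplitude timepoint, and TPM
  renormalization (columns must sum to 10⁶) compresses the repressed
  templates toward a common "down at 6 and 24 h" shape. In simulation at
  realistic noise this blurs cohorts into each other regardless of
  linkage. The log10(x+1) transform symmetrizes induction and repression
  and stabilizes the variance; cohort recovery on templated courses rises
  from ~0.74 to ~0.999 (see `tests/test_acceptance.py`).
* **Ward linkage.** Complete linkage is brittle to single noisy profiles
  (it merges on worst-case distances); Ward's minimum-variance criterion
  recovers the compact, similar-sized cohorts this design expects. Both
  choices are arguments, not hard-coded: `wave_pipeline(...,
  log_expression=False, linkage="complete")` restores the classic recipe,
  and the raw `z = (x − µ)/s` contract of `zscore_profiles` is unchanged.

Note the 6 h label is nominal: early post-meal collections in this kind of
time course are often 4–6 h windows; templates use the nominal hour.

## Differential-expression gate

A deliberate stand-in for count-model testing (which requires raw counts
and dispersion estimation, both out of scope here): per gene, Welch's
two-sample t on log2(TPM+1) across replicates, Benjamini–Hochberg step-up
across all tested genes. Fold-changes for gating are computed on
replicate-mean TPM with the shared ε; `filter_regulated` applies the
conventional padj < 0.05 plus ≥ 2-fold gate, yielding disjoint up/down
sets. Genes with zero variance in both groups get p = 1 when means agree
(and p = 0 in the degenerate unequal-mean limit). Externally computed
adjusted p-values (e.g. from a count model run elsewhere) can be swapped
in via `DEResult.with_padj`.

Known limitation: with 3 replicates per group the Welch–Satterthwaite
degrees of freedom can fall to 2, which floors attainable p-values near
`2·sf(t, 2) ≈ 1/t²` no matter how large the effect. When true positives
are very rare this floor caps BH-adjusted sensitivity; designs feeding
this gate should carry ≥ 4 replicates per group or a substantial
responding fraction. The generators' defaults reflect this (below).

## Cross-species censorship

One-to-one pairs are taken from the ortholog table's `1-to-1` relation
rows (uniqueness of each gene on both sides is enforced at validation).
Both profiles are subset to the pairs and rescaled to sum 10⁶, and
species B is regressed on species A in log10(x+1) space (linear mode
available — see below). The censorship loop: among pairs significant in
the between-species Welch/BH test (padj < 0.05, computed once on the
renormalized 1-to-1 subset), censor the pair with the largest
|log10(a+1) − log10(b+1)| **on the current renormalization** (ties broken
by pair id), rescale the survivors, refit, and record; stop at
`max_steps` or when candidates run out. Disparity is recomputed each step
because each removal changes the scale of everything else; ranking by a
frozen initial score would mis-order later steps. The trajectory is
deterministic given its inputs.

Correlation space: log10(x+1) by default, because ortholog expression
spans orders of magnitude. The linear mode exists because the two spaces
answer different questions — a handful of extremely expressed, disparate
genes can leave a log-space R² nearly untouched (five residuals among
thousands of points) while devastating the linear-space fit, which is
exactly the "few genes mask the correlation" phenomenon the censorship
procedure targets. The property tests assert the depressed-then-restored
behaviour on the linear scale and the near-identity recovery on the log
scale.

## Synthetic generators: what they emulate, and what they do not

All generators share one noise model — gene-wise multiplicative
log-normal noise on TPM, `column = mean × exp(N(0, noise_sd_log²))`,
renormalized to 10⁶ — and are pure functions of (parameters, seed).
Negative-binomial count noise is not simulated: every downstream
computation here consumes TPM, and a simple Poisson-free multiplicative
model keeps planted truths exact at zero noise.

* **Atlas** (`generate_atlas`): per-compartment log10 mean expression is a
  shared baseline N(1, √(1−0.3²)) plus an independent compartment effect
  N(0, 0.3), so each compartment's marginal is the intended
  log-normal(log10 mean 1, sd 1) while compartments share the
  housekeeping backbone real tissues share. The decomposition matters:
  fully independent profiles would, by chance alone, hand tens of genes a
  ≥ 50-fold lead over five competitors in a 20,000-gene genome, which no
  real atlas census shows. Markers are planted at 10^U(2,3) TPM in their
  compartment and exactly 0 elsewhere; the whole-body mean is the
  weight-mixed sum of compartment means (weights Dirichlet(α = 2) unless
  supplied), with noise applied **after** mixing so the mixture identity
  is exact at zero noise. Defaults: 20,000 genes, 6 compartments, 12
  markers each, noise_sd_log 0.2, 3 replicates.
* **Time course** (`generate_time_course`): TPM multipliers per template
  over 0/6/24/48 h — rapid-induced (1, 6, 1, 1), intermediate-induced
  (1, 4, 4, 1), delayed-induced (1, 1, 6, 1), and their reciprocal
  repressed counterparts; remaining genes flat. Baselines 10^N(1.3, 0.4)
  TPM keep templated genes clear of the 2-TPM censor. Because each column
  is renormalized to TPM, observed fold-changes equal the template
  multipliers only up to a per-column scale (recorded multipliers in the
  truth object let tests back it out) — the same compositional distortion
  real TPM time courses carry.
* **Two species** (`generate_two_species`): non-signature orthologs share
  identical mean expression across species; signature pairs are planted
  among the highest-expressed genes (10^U(4.5, 5.0) TPM, several percent
  of the transcriptome each, as real species-signature genes are) in one
  species, alternating sides, a 10^2 deficit in the other. Defaults: 2,000
  orthologs, 5 signature pairs, noise_sd_log 0.1, and **4 replicates** —
  the between-species gate must clear BH with only five true positives,
  which the 3-replicate Welch floor (above) cannot do.
* **Two groups** (`generate_two_group`): shared mean profile, first `n_de`
  randomly chosen genes multiplied by 2^log2fc in group B before
  renormalization. The calibration tests use 5,000 genes with 5 + 5
  replicates for the null rate, and a 10%-responding design
  (500 planted, 3 + 3 replicates, noise 0.1) for sensitivity — a
  responding fraction in line with a strong physiological stimulus.

What passing these tests shows — and what it does not: recovery is
demonstrated under multiplicative log-normal noise with exactly planted,
perfectly exclusive structure. Real data add batch effects, isoform
aggregation artifacts, imperfect marker exclusivity (lowly contaminating
expression in other parts biases marker ratios upward), compositional
coupling between co-regulated genes, and count-level sampling noise for
low-TPM genes; none of these are simulated, so the tests certify the
correctness of the computations, not the field error of the estimates.

## Numerical conventions

* TSV is the interchange dialect: tab-separated, UTF-8, `#` comments, a
  leading `gene_id` column for matrices. Reports sort rows by primary key
  (unless rank order is the payload), render floats to six significant
  digits, and are byte-identical across reruns; JSON reports embed the
  run config and seed.
* BH adjustment is `statsmodels`' step-up, verified exactly against a
  literal step-up oracle for all short p-vectors in tests.
* Hierarchical clustering is `scipy.cluster.hierarchy`, verified against
  a naive Lance–Williams agglomeration oracle on small inputs for
  complete, average and Ward linkage.
* Validation-fit boundary cases: a perfect fit breaks out of outlier
  removal immediately (studentized residuals are undefined at zero
  residual variance); `sum_check` bounds carry a 10⁻⁹ tolerance so exact
  boundary totals pass despite float summation error.
* Ties everywhere break lexicographically by gene/pair id, making every
  ranked output deterministic.

## Known limitations

* The deconvolution ignores marker non-exclusivity; contaminating
  expression of a "marker" elsewhere inflates its whole-body ratio. The
  per-marker spread (`sd` column) is the first diagnostic to check.
* The differential gate is a TPM-space stand-in, not a count model; see
  its limitation note above.
* Wave labels are assigned per cluster, so a cluster that genuinely mixes
  cohorts mislabels its minority; inspect centroids when cohort sizes
  look unbalanced.
* The censorship procedure assumes the between-species test covers every
  pair; pairs with missing expression are errors, not silently dropped.
* Cross-species analysis is strictly two-species; multi-species
  generalization, ortholog inference itself, and any count-level
  preprocessing are out of scope.
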