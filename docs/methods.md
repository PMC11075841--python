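# Methods

`idr-evosig` implements an end-to-end evolutionary analysis of
intrinsically disordered regions (IDRs): aligned per-species disorder-score
traces are converted into disorder/order regions, each region's sequence
divergence is quantified with amino-acid and indel substitution models
against a scaled reference tree, 82 molecular features are computed per
species segment, and each (region, feature) trait is tested for
conservation by comparing Brownian-motion (BM) and stationary
Ornstein-Uhlenbeck (OU) fits. The per-feature log likelihood ratios form a
region's "evolutionary signature", which feeds clustering and GO
enrichment. This note records the models, the defaults that matter, and
the design decisions that were genuinely open.

## Region calling

Disorder scores (one trace per species, aligned to the MSA, values in
[0, 1]) are averaged per column with tree-derived sequence weights: the
weights are the normalized row sums of the inverse BM covariance of the
tree (the Gaussian-process derivation of tree-based weighting), so clusters
of closely related species share weight instead of dominating the average.
When species are missing from an alignment the remaining weights are
renormalized by default; recomputing them from a re-pruned tree is
available (`mode="reprune"`) and differs only when pruning changes the
covariance structure appreciably. A species contributes to a column only
where it has a scored, non-gap residue inside its own first-to-last
non-gap span and outside the optional missing-data mask; columns with no
contributor are filled by linear interpolation (flat at the ends).

Regions come from a dual cutoff: columns with average score strictly above
0.6 form the high mask, strictly above 0.4 the low mask ("exceeds" is read
as strict). The low mask is binary-dilated once with a centered size-3
structuring element (one column each side, clipped at the bounds), which
merges true runs separated by one or two columns. Seeds are maximal high
runs of at least 10 columns; each seed expands left and right through the
dilated low mask; overlapping expansions merge. Order regions are the
exact complement, so regions partition every alignment. Coordinates are
0-based half-open column intervals everywhere.

Filtering: segments with non-standard residues, segments overlapping the
missing mask, and segments with fewer than 30 non-gap residues are
dropped; a region is kept if the survivors satisfy the diversity criteria
(defaults: ≥ 20 segments, and ≥ 2 represented clade groups when a clade
list is configured — the clade list is a placeholder left configurable
because no machine-readable canonical set exists). All filter counts are
logged per alignment.

## Substitution and indel rates

A reversible substitution model is parameterized by stationary frequencies
π and a symmetric zero-diagonal exchangeability matrix S, with rates
r_ij = s_ij·π_j and the generator normalized to mean rate 1 so branch
lengths are expected substitutions per column. Likelihoods use
Felsenstein pruning with per-pattern compression and per-node rescaling;
rate heterogeneity uses a median-discretized gamma mixture, optionally
with an invariant class (the overall category mean is kept at 1). Full ML
fitting (`fit_reversible_model`) optimizes S (log scale, one entry fixed),
π (softmax), a single branch scale of the supplied topology, and the gamma
shape with L-BFGS-B and random restarts; it is alphabet-generic and is
exercised on small alphabets, where it is cross-checked against exhaustive
enumeration over internal states. Per-alignment rate estimation in the
pipeline keeps exchangeabilities uniform with empirical frequencies and
optimizes only scale, gamma shape, and invariant proportion: the
downstream quantities (branch scale and posterior-mean column rates) do
not require a free exchangeability matrix, and optimizing the 189
exchangeabilities of a 20-state model with numerical gradients per
alignment is not worth its cost.

Alignments are partitioned into disorder/order column sets; a partition
must contain ≥ 20 sequences with ≥ 30 non-gap symbols, failing partitions
are consolidated into the passing one, and alignments failing both are
skipped. The fitted tree is restricted to a scaled copy of the reference
species tree pruned to the alignment's species. A column's reported rate
is its posterior-mean category rate times the fitted-to-reference
tree-length ratio, and a region's amino-acid rate is the mean over its
columns.

Indels are coded as binary characters: every maximal gap run with a unique
(start, stop) becomes a character; a sequence is coded 1 if it has exactly
that run or the run lies strictly inside one of its longer runs (nesting).
A two-state reversible model with free stationary frequency and a branch
scale is fit with a conditional likelihood that corrects for the
unobservable all-absent pattern (excluding all-present as well is
available behind a flag). One gamma category is added per five characters
up to four; with fewer than five characters all rates are set to zero
(such fits overfit badly). Each character's normalized rate is split half
onto its start column and half onto its stop−1 column; a region's indel
rate is the mean over its columns.

## Features

The 82-entry registry is a declarative TSV (name, kind, spec): 20
single-residue and 6 class composition fractions (the polar class
[QNSTCH] excludes glycine), 21 homo/di-class repeat counts, 11
physicochemical and patterning statistics, and 24 short-linear-motif
regex counts (DOC/LIG/MOD classes). Motif and repeat counts are raw
counts, never length-normalized. Charge conventions: D/E = −1, K/R = +1,
histidine neutral. SCD is (1/N)·Σ_{i<j} q_i q_j √(j−i); kappa and omega
are blob-based patterning statistics (overlapping windows of 5 and 6,
squared deviation of blob charge asymmetry from the global value,
normalized by the maximally segregated arrangement of the same
composition, undefined for short or charge-free segments); Wootton-
Federhen complexity is the per-residue base-20 log multinomial
coefficient; the isoelectric point solves Henderson-Hasselbalch net
charge = 0 by bisection with the EMBOSS pKa table; hydropathy is the
Kyte-Doolittle mean, PPII propensity the Elam/Hilser mean; region length
enters as N^0.598, the excluded-volume radius-of-gyration scaling, since
features are z-scored downstream and only relative scale matters.
Undefined values are NaN, never silently zero.

## Trait models and the conservation test

For a trait x observed at the tips, BM gives x ~ MVN(μ1, σ²C) with C the
shared-path-length matrix; the ML estimates are closed-form (GLS mean,
quadratic form over n). The unbiased mean-of-squared-contrasts rate
(Felsenstein's recursion, polytomies resolved with zero-length edges) is
used for rate-only analyses; it equals the GLS REML estimator exactly.
The stationary OU model gives x ~ MVN(μ1, (σ²/2α)·e^{−α d}) — the root is
a draw from the stationary distribution, which keeps (μ, σ², α)
identifiable. (The obvious alternative of writing the covariance as an
exponential *growing* with distance is not a valid covariance function;
the stationary form is the one consistent with the identifiability
requirement.) For fixed α the mean and scale profile out analytically, so
the fit is a 1-D search over log₁₀ α in [−4, 4]: a 0.25-step grid scan
with cached Cholesky factors followed by bounded scalar refinement. Fits
at the α bounds are flagged; zero-variance traits are flagged degenerate
and excluded from testing rather than assigned LLR 0.

The test statistic is LLR = loglik_OU − loglik_BM in nats. Critical
values are calibrated empirically: BM traits are simulated at 13 rates
(10⁻³..10³, half-log steps, 100 replicates each, exact MVN draws), both
models are fit, and the pooled LLR quantiles give the criticals; pooling
is justified because the null LLR distribution is invariant to the true
rate (asserted by KS tests across rate strata). Significance is strict
(llr > critical).

A structural property worth stating: under this parameterization, jointly
rescaling σ² at fixed α rescales the whole OU covariance, and the BM
alternative also has a free scale, so the LLR distribution — and the
distribution of σ̂²/σ² — depends only on α relative to the tree's depth,
never on the α/σ² ratio per se. Ratio-banded summaries of power and bias
are therefore grid artifacts: they hold in pooled form because different
ratio bands weight absolute α differently. The replication experiments
(`idr_evosig.experiments`) make this explicit: the type II error is ~1
for α ≪ 1/depth regardless of σ², and 0 in the strong-selection interior
(α = 10², any σ² with ratio ≥ 2); the OU rate is overestimated (pooled
median) in the 1 < log₁₀(α/σ²) < 3 band and underestimated above 3 on the
study grids.

The reference tree for these experiments is the spec of the synthetic
module itself: a 33-tip pure-birth tree rescaled to mean root-to-tip
depth 0.5, the substitutions-per-site scale of a genus-level protein
phylogram. The depth matters because α has units of inverse branch
length; at a very different tree scale the same α grid lands in different
identifiability regimes.

Score-feature association uses pooled independent contrasts: standard
Pearson r (not through the origin) with a sign-randomization permutation
null (contrast signs are arbitrary), p = (1 + #{|r_perm| ≥ |r_obs|}) /
(1 + n_perm).

## Signatures, clustering, enrichment

Parameter matrices are z-scored per feature (population SD, NaN
preserved, zero-variance columns become missing with a warning) before
PCA; PCA is a centered SVD with the largest-magnitude loading of each
component made positive, and missing entries must be imputed (the
pipeline imputes 0 after z-scoring). Signatures are clustered with UPGMA
on correlation distance (1 − Pearson r between signature vectors;
constant vectors get distance 1 with a warning). Missing LLRs are imputed
as 0 for the distance computation only. Because raw LLR vectors are
non-negative, their pairwise correlations share a common positive offset
that lets average linkage chain unrelated regions through any tight
cluster; `standardize=True` z-scores each feature's LLRs first and makes
block recovery robust (the planted-block experiment recovers ARI 1.0
standardized versus ~0.1 raw). The pipeline default stays raw to match
the plain correlation-distance definition; flat clusters come from a
distance threshold or a requested count, and a manual node list is the
intended path for curated cluster sets.

The shuffle null permutes each feature's LLR column independently across
regions, preserving every marginal while destroying the between-feature
dependence; significance counts exclude missing tests from numerators and
denominators.

Enrichment propagates GAF annotations up the ontology along is_a and
part_of edges after dropping NOT/disallowed qualifiers (allowed: enables,
contributes_to, involved_in, located_in, part_of, is_active_in),
non-experimental evidence (allowed: experimental codes, TAS, IC), and
terms absent from the OBO graph. Tests are exact upper-tail
hypergeometric probabilities with regions as the sampling unit, skipping
terms with fewer than two regions in the cluster; cluster analyses apply
Benjamini-Hochberg within cluster, while the disorder-score (upper-decile
of score rates, ties included) analysis is deliberately uncorrected —
both behaviors are fixed defaults of their entry points.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
not protein realism. Trees are pure-birth with exponential waiting times.
Sequences evolve under a uniform-exchangeability reversible model with
configurable site-rate categories; indels are a deletion-only process in
fixed alignment coordinates (Poisson events per branch, geometric run
lengths, applied to the whole subtree), which is sufficient to exercise
the gap-run coder including its nesting rule but does not create
insertion columns. Score traces are logistic(gain · windowed
hydrophilicity + bias + species offset + noise) with the species offsets
drawn from a stationary OU process on the tree, so scores correlate with
composition and diverge with tree distance; defaults (gain 3, bias 0,
offset SD 0.5, noise SD 0.1, window 11) put typical traces astride the
0.4/0.6 cutoffs so both region classes occur. Trait matrices are exact
MVN draws from the BM or stationary-OU tip distribution with the mean
fixed at μ (0 in all simulation studies, since both likelihoods are
shift-invariant). Bundles write their generating parameters beside the
data.

What passing tests on these fixtures does not show: robustness to
alignment error, to non-stationary composition, to insertion-driven
column creation, or to disorder-score artifacts of any particular
predictor — the score generator is a test harness, not a predictor.

## Numerical choices and problem sizes

Multiplicative parameters are optimized in log space; exchangeabilities
are bounded below at 1e-6 via their log bounds; likelihood evaluations
that fail numerically return a large penalty during optimization.
Discrete-gamma categories use the median method. The replication
experiments run at: criticals from 13 × 100 pooled null fits; type I
self-consistency on 1000 fresh simulations (a batch comparable to the
calibration pool, so the ±3-SE check is not dominated by the Monte-Carlo
error of the estimated 99th-percentile critical); power at 200
replicates per cell; bias surfaces at 500 replicates per cell; planted
recovery with 200 regions × 82 features (20 regions carry an 8-feature
planted block at α/σ² = 100). These sizes keep the whole suite and the
acceptance script in the minutes range on one CPU while leaving
Monte-Carlo error well below the asserted margins.

## Known limitations

Continuous Gaussian models are applied to integer-valued features (counts,
net charge) exactly as in the source analyses; mean-reverting count
models would need different machinery. The per-alignment substitution
fits fix exchangeabilities (see above). FreeRate mixtures are replaced by
invariant + discrete gamma. The diversity-criteria clade list and the
motif registry entries reconstructed from canonical consensus patterns
are documented approximations. GO results depend entirely on the supplied
OBO/GAF releases.
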