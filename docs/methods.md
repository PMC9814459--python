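# Methods

This note records the statistical models, the numerical choices inside
the samplers, what the synthetic-data generators do and do not emulate,
and the design decisions taken where more than one defensible option
existed.

## Decontamination cascade

The OTU filtering pipeline runs five stages in a fixed order: (1) remove
OTUs with total reads < `min_read_count` (default 10) or sequence length
< `min_length_bp` (default 80 bp); (2) remove OTUs with insert length ≥
`max_insert_bp_exclusive` (default 200 bp; longer inserts are off-target,
typically microbial, amplicons); (3) remove OTUs assigned to listed
contaminant taxa (default: cow, human, house mouse, pig, chicken — taxa
routinely found in reagents and labs); (4) negative-control thresholding;
(5) remove OTUs whose residual total is < `min_otu_total` (default 20).

Stage 4 links each true sample to its negative controls three ways: field
negatives by site (and visit when both record one), extraction negatives
by extraction batch, PCR negatives by PCR batch. For each OTU the
threshold *t* is the maximum count of that OTU across the sample's linked
negatives. Two readings of "remove the counts that appeared in the
negatives" are implemented:

* **subtract** (default): the sample count is reduced by *t*, floored at
  zero — the stricter reading, guaranteeing that any contamination the
  negatives witnessed is fully deducted;
* **threshold**: counts ≤ *t* are zeroed, larger counts kept whole — the
  milder "detection threshold" reading.

Whether the final abundance floor applies to an OTU's total (default) or
per cell is likewise a config switch (`low_abundance_scope`), since both
interpretations are common. The stages do not commute (the abundance
floor is meant to act on post-threshold residuals), so the pipeline order
is fixed and the audit records reads in/out and a removal reason per
stage; the suite asserts exact read conservation, elementwise
monotonicity and idempotence of the full cascade.

## Community occupancy model

Hierarchical Dorazio–Royle-type model for K species × I trees × repeat
events, with a collection-method covariate (roller = 1, soil = 0) in the
detection submodel; species-level parameters u_k (logit-occupancy), α_k
(logit soil detection) and β_k (roller effect) are drawn from Normal
community hyper-distributions. Hyperpriors are μ ~ Normal(0, 10²) and
σ ~ Uniform(0, 10) — the conventional operationalization of
"non-informative" for community models; both constants are arguments.
Missing events (e.g. soil visits never extracted) contribute no
likelihood term, which assumes missingness is ignorable given the design.
Species never detected anywhere carry no information without data
augmentation (out of scope: the model describes detected species, not
total richness) and are dropped with a warning.

**Sampler.** Metropolis-within-Gibbs:

* z_ik from its exact Bernoulli full conditional, forced to 1 where the
  species was observed at the tree; the conditional logit is
  u_k + Σ_events log(1 − p_ijk).
* u_k, α_k, β_k by per-species random-walk Metropolis on the logit scale.
  Proposal scales start at 0.5 and adapt every 50 burn-in iterations by a
  factor exp(rate − 0.3), targeting the 20–40% acceptance band, clipped
  to [1e-3, 50]; adaptation freezes at the end of burn-in so the kept
  chain is a valid Markov chain.
* μ hyperparameters by conjugate Normal draws; σ hyperparameters by
  random-walk Metropolis on log σ (with the Jacobian term), rejected
  above the Uniform upper bound.

The per-(species, tree) detection log-likelihood is cached between
updates — it does not depend on z, so z updates leave it valid — cutting
the dominant array work per iteration roughly in half. Chains are seeded
as `default_rng([seed, chain])`, making runs exactly reproducible.
Defaults follow the survey protocol (3 × 30,000, burn 10,000, thin 10);
the calibration tests use a reduced 3 × 6,000 / burn 2,000 / thin 4
protocol, which already yields split r-hat < 1.1 for all hyperparameters
at survey size (20 species, 21 trees).

**Diagnostics.** Split-chain Gelman–Rubin PSRF (each chain halved before
the between/within comparison) — stricter than the unsplit classic and
the current standard; constant chains return NaN rather than a spurious
1. The implementation is cross-checked against an independent reference
implementation in the tests.

**Oracle.** `exact_posterior_oracle` computes the posterior over a
weighted discrete grid of (ψ, p_soil, p_roller) by summing the likelihood
over all 2^(K·I) occupancy configurations (limits: 2 species, 4 trees, 4
events/tree). `CommunityGrid.from_logit_normal` builds the grid from
Gauss–Hermite nodes of the same logit-Normal priors the sampler uses
(41 nodes per dimension by default), so with fixed hyperparameters both
routes target the identical posterior; the suite requires agreement of
posterior means within 3 Monte-Carlo standard errors (autocorrelation-
adjusted via effective sample size).

## Multimethod occupancy model

Single-species, three-layer model: tree occupancy ψ, per-sample eDNA
availability θ (logit-linear in collection method) and conditional
detection p_m (logit-linear in molecular method), with both molecular
methods scored on every sample; qPCR technical replicates are collapsed
to one binary outcome per sample (any-positive rule). ψ gets a
Uniform(0,1) prior and conjugate Beta updates given z.

The four logit coefficients get Normal(0, 1.75²) priors by default. This
is a deliberate choice: a Normal(0, 10²) logit prior is *not* vague on
the probability scale — it is U-shaped with most of its mass near 0 and
1 — and because availability is identified only weakly (through the joint
qPCR × metabarcoding detection pattern), that prior drags θ toward 1 and
biases the conditional detection probabilities down by ~0.1 at realistic
sizes. Normal(0, 1.75²) induces an approximately uniform prior on each
probability, the standard weakly-informative choice in occupancy
modelling; the sd is an argument for users who want the diffuse version.

z and a have exact Bernoulli full conditionals (a forced to 1 where any
method detected; z forced to 1 where any sample is available); the
coefficients use the same adaptive random-walk scheme as the community
model. The enumeration oracle (`exact_multimethod_posterior`) sums over
every (z, a) configuration on a quadrature grid — Gauss–Legendre in ψ,
Gauss–Hermite in the coefficients — on instances up to 3 trees × 3
samples.

**Planning.** The per-visit detection rate for a method pair is θ·p_m,
formed per posterior draw. `cumulative_detection(p, n) = 1 − (1 − p)^n`
(computed via expm1/log1p for accuracy near the extremes) and
`visits_for_confidence` returns the smallest n reaching a target, with an
explicit minimality check guarding against floating-point edge cases.
The qPCR:metabarcoding ratio is formed per draw and then summarized —
the posterior mean of a ratio exceeds the ratio of posterior means when
the denominator is uncertain, and the per-draw version is the honest
posterior functional.

## Synthetic-data generators

All three generators draw from one `numpy` Generator in a fixed,
fully-vectorized field order, so outputs are invariant to iteration order
and byte-identical under a repeated seed; every latent draw is recorded
in a `SimulationTruth`, from which each observed datum is reconstructible.

* **Community generator** defaults: 16 species, 21 trees, 3 roller + 3
  soil events — the survey's scale. Hyper-means put median occupancy at
  0.5 (μ_ψ = 0, σ_ψ = 1), baseline soil per-event detection near 0.2
  (μ_α = −1.4, σ_α = 1) and a positive roller effect of one logit unit
  (μ_β = 1, σ_β = 0.5), matching the qualitative roller advantage the
  method comparison is about. Missing events are represented explicitly
  as design rows with no observation, mirroring soil subsampling, not
  imputed as zeros.
* **Multimethod generator** defaults: ψ = 0.7, θ_roller = 0.7,
  θ_soil = 0.4, p_qpcr = 0.49, p_metabarcoding = 0.15, soil fraction
  35/94 — the single-species comparison's working values, with the
  conditional detection pair at the fitted point estimates.
* **OTU generator** defaults: 16 species × 94 samples with 46 negatives
  (10 field, 12 extraction, 24 PCR), species present in a sample with
  probability 0.5, negative-binomial signal (mean 2000 reads, dispersion
  0.5 — metabarcoding counts are strongly overdispersed) and independent
  Poisson(5) contamination leaking into any column at rate 0.02.

What the generators do **not** emulate: sequencing error and chimeras
(upstream of the tabular entry point), index hopping, correlated
contamination within a PCR plate, spatial/temporal correlation between
repeat visits (detections are independent given z, as in the model), and
taxonomic mis-assignment. Passing tests therefore demonstrate that the
estimators recover the truth *of the assumed data-generating process*;
real surveys can violate these assumptions, most plausibly through
visit-to-visit correlation of eDNA deposits and batch-correlated
contamination.

## Fixtures

The packaged species table transcribes the two-site survey list: 25
scored species (clade, arboreal flag, per-site documentation and
roller/soil detection percentages) plus three excluded species (two
removed for contamination concerns, one because the mammal 12S primer set
does not amplify bears). Detection-coverage arithmetic follows the
source's convention: all 25 scored species count as expected and
available, so 16 detected gives 64% coverage. Four detected species were
absent from the externally compiled roster; a separate
`in_compiled_list` flag records this, and the fixture makes no attempt to
reconcile roster totals that cannot be recovered from the table itself.
The sampling-design fixture fixes the per-site margins (roller: 9 trees
× 3 visits plus 10 × 3 + 2 × 1; soil: 16 samples at 6 trees and 19 at 8)
and chooses one concrete allocation consistent with them: 59 roller + 35
soil = 94 events.

## Species accumulation and composition

Accumulation curves are permutation-based (default 1,000 seeded
permutations of tree order; exact enumeration available up to 8 trees):
for each ordering, distinct detected species are accumulated using only
the first *v* visits per tree and method, and the mean ± SD across
orderings is reported — so the SD reflects ordering uncertainty, and the
curve's endpoint equals the total distinct species detected exactly. The
"both" curve is defined on trees sampled by both collection methods, with
detections pooled. Composition summaries count detected species by
collection method × arboreal guild; a detected species without a guild
label is a hard error naming the species.

## Problem sizes used in the checks

The automated checks run the samplers at reduced but representative
sizes, chosen to keep the full suite under ten minutes: oracle-agreement
instances of 1–2 species/trees with 3 × 5,000 kept draws; calibration at
the survey's own size (20 species × 21 trees, 50 replicates, 3 × 6,000
iterations) requiring ≥ 80% nominal-95% interval coverage of μ_β; and
single-dataset recovery of the conditional detection probabilities at 200
trees × 3 samples within ±0.05. At that last size the data themselves
carry ~±0.05 of sampling noise for p_qpcr (availability is identified
only through joint detections), so the tolerance is at the edge of what a
single dataset supports — a point worth remembering when applying the
model to surveys of comparable size.

## Known limitations

* No data augmentation: total species richness is not estimated, and
  never-detected species are excluded rather than modelled.
* Single community: site is not a covariate in either model.
* No continuous eDNA-concentration modelling; availability is binary.
* The negative-control linkage assumes the sample metadata's batch
  columns are complete; unlinked samples are passed through with a
  warning and a zero threshold.
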