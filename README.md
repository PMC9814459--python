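# treedna

Occupancy modelling and decontamination tools for **terrestrial eDNA
metabarcoding surveys of mammal communities**, built around two collection
methods — rolling a damp paint roller over tree bark ("roller" sampling)
and sampling the soil beneath the canopy — and two molecular detection
methods (community metabarcoding and single-species qPCR).

It is written for ecologists who have an OTU read table from a
metabarcoding run (plus its field/extraction/PCR negative controls) and
want to go from raw counts to defensible statements about which species
are present, how detectable they are with each method, and how much
sampling a future survey needs.

## What it does

1. **Decontamination** (`run_filter_pipeline`) — the post-assignment
   filtering cascade for OTU tables: drop OTUs with < 10 total reads or
   sequences < 80 bp, drop insert lengths ≥ 200 bp (off-target microbial
   amplicons), remove known contaminant taxa (*Bos taurus*, *Homo
   sapiens*, *Mus musculus*, *Sus scrofa*, *Gallus gallus* by default),
   subtract per-OTU negative-control thresholds from every linked sample,
   then drop OTUs with < 20 residual reads. Every stage is audited with
   exact read conservation.

2. **Community occupancy model** (`fit_community_model`) — a hierarchical
   multi-species model separating true presence from imperfect detection.
   For species *k* at tree *i*, event *j*:

   ```
   z_ik ~ Bernoulli(ψ_k),   y_ijk ~ Bernoulli(z_ik · p_ijk)
   logit(ψ_k) = u_k ~ Normal(μ_ψ, σ_ψ²)
   logit(p_ijk) = α_k + β_k·x_ij,  x_ij = 1 for roller, 0 for soil
   α_k ~ Normal(μ_α, σ_α²),  β_k ~ Normal(μ_β, σ_β²)
   ```

   Fitted by Metropolis-within-Gibbs MCMC (default 3 chains × 30,000
   iterations, 10,000 burn-in, thin 10) with split-chain Gelman–Rubin
   diagnostics (r-hat < 1.1). A positive slope β_k means the species is
   easier to detect from bark than from soil.

3. **Multimethod occupancy model** (`fit_multimethod_model`) — a
   single-species model with an eDNA-availability layer θ between tree
   occupancy ψ and method-specific conditional detection p_m, identified
   by scoring every sample with both qPCR and metabarcoding:

   ```
   z_i ~ Bern(ψ),  a_is ~ Bern(z_i·θ_is),  y_ism ~ Bern(a_is·p_m)
   logit(θ_is) = γ0 + γ1·roller_is,   logit(p_m) = δ0 + δ1·qpcr_m
   ```

4. **Survey planning** — the cumulative probability of at least one
   detection in *n* visits, `1 − (1 − p)^n`, its inverse
   (`visits_for_confidence`), and posterior planning curves using the
   per-visit rate θ·p_m.

5. **Summaries** — permutation-based species accumulation curves,
   composition/coverage counts by collection method and arboreal guild,
   and an in-package split-chain r-hat.

6. **Synthetic data with ground truth** (`simulate_community`,
   `simulate_multimethod`, `simulate_otu_table`) — generators that mirror
   the hierarchical structure above and record every latent draw, so the
   whole pipeline is testable end to end. A packaged fixture transcribes
   the two-site New Jersey woodland survey's species detection table and
   sampling design (21 trees, 59 roller + 35 soil = 94 analyzed events).

Both MCMC samplers ship with independent exact-enumeration oracles
(`exact_posterior_oracle`, `exact_multimethod_posterior`) that integrate
the posterior over a weighted parameter grid and every latent
configuration on tiny instances — the test suite checks the samplers
against them to within Monte-Carlo error.

## Worked example

```python
import treedna as td

cfg = td.MultimethodSimConfig(n_trees=200, seed=1)   # ψ=0.7, θ_roller=0.7,
history, _ = td.simulate_multimethod(cfg)            # p_qpcr=0.49, p_meta=0.15
post = td.fit_multimethod_model(
    history, td.McmcSettings(n_chains=3, n_iter=6000, n_burn=2000, thin=4, seed=1))
print(post.summary().round(2))
```

```
                 mean    lo    hi
psi              0.71  0.64  0.78
theta_roller     0.75  0.54  0.97
theta_soil       0.39  0.25  0.60
p_qpcr           0.51  0.38  0.66
p_metabarcoding  0.15  0.10  0.21
```

The model recovers the generating values: qPCR detects available eDNA
about 3.5× as often as metabarcoding
(`td.detection_rate_ratio(post)` → 3.52, 95% CI [2.55, 4.88]), and the
fitted per-visit rates θ_roller·p_m translate into survey effort: 7
roller visits to an occupied tree for 95% confidence with qPCR versus 26
with metabarcoding (`td.visits_for_confidence`).

The `examples/` directory holds one short script per capability
(decontamination, community model, multimethod model + planning,
composition + accumulation); each prints the numbers above with a line of
interpretation.

A thin CLI wraps the same functions:

```bash
treedna filter --otu-table otu.tsv --meta meta.tsv --out filtered.tsv --audit audit.json
treedna plan --p 0.21 --target 0.95        # -> 13
treedna summarize                          # packaged survey-table counts
```

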