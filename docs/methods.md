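# Methods

`sparsetc` simulates the population-improvement component of a maize-style
hybrid breeding program — two heterotic pools improved by reciprocal
recurrent genomic selection on general combining ability (GCA) — in order to
compare early-stage testcross designs: a conventional single tester versus
*sparse testcrossing*, in which the candidate lines are partitioned at random
over k testers so that each line is phenotyped once but related lines meet
different testers.

## Genome and founder population

Founders are 80 heterozygous diploid genotypes over 10 chromosomes, each
2 × 10⁸ bp and 200 cM (a uniform map, 1 cM = 1 Mb). Linkage disequilibrium is
generated with the msprime coalescent (constant effective population size
Ne = 100, per-bp mutation rate 1.25 × 10⁻⁸, binary mutation model,
recombination rate derived as genetic/physical length = 10⁻⁸ per bp). Only
segregating biallelic sites are stored, with genetic-map positions; this
yields roughly 5,000–6,000 segregating sites per chromosome at full scale.
The founder backend is pluggable (`register_founder_backend`) so a different
demography or a forward-time burn-in can be substituted; all downstream code
sees only a `HaplotypePopulation`.

Per chromosome, 500 QTN (trait loci) and 500 SNP (marker array) are drawn
uniformly without replacement from the segregating sites, disjointly. The
prediction models only ever see the SNP; all ground-truth quantities use the
QTN. After assignment the remaining neutral sites are dropped; because the
genetic map positions of the kept loci are preserved, meiosis and all
genetics at the kept loci are unchanged.

## Trait model

A single quantitative trait with directional dominance. Per QTN i: additive
effect aᵢ ~ N(0, 1) (signed), dominance degree δᵢ ~ N(μ_δ, 0.2) independent
of aᵢ and untruncated, dominance effect dᵢ = δᵢ·|aᵢ|. Genotype aa scores
−aᵢ, Aa scores dᵢ, AA scores +aᵢ; genetic values sum over QTN. Scenarios are
μ_δ ∈ {0.1, 0.5, 0.9} (low/medium/high dominance), giving overdominance
(δ > 1) at 2%, 13% and 41% of loci respectively (exact normal-CDF values).

Effects are rescaled once so the additive genetic variance in the founder
population equals σ²_A = 20. The default basis is the genic variance
Σᵢ 2pᵢqᵢαᵢ² with average effects αᵢ = aᵢ + dᵢ(qᵢ − pᵢ) at founder
frequencies; an empirical basis (variance of founder breeding values) is
available via `scaling="empirical"`. Both a and d scale linearly with a, so
one closed-form factor is exact. The SCA/GCA variance ratios are invariant
to this choice.

## Breeding operations

* **Founder inbreeding** — one haplotype per chromosome is chosen at random
  and doubled; the 80 inbreds are split at random into a female and a male
  pool of 40.
* **Pool formation** — per pool, three generations of: 60 bi-parental
  crosses sampled from the half diallel of the 40 parents (uniform without
  replacement, plans rejected until every parent is used), 20 doubled
  haploids (DH) per cross (1,200 lines), and 40 lines chosen at random as
  the next parents. No trait-based selection (pure drift).
* **Meiosis** — crossover counts per chromosome are Poisson with mean equal
  to the map length in Morgans (2.0 for 200 cM), positions uniform on the
  genetic map, no interference, no obligate chiasma; the starting haplotype
  is random. A DH line is one gamete of an F1, doubled.
* **Testcrosses** — inbred × inbred, so the hybrid genotype is determined
  (one allele from each parent; no meiosis needed).
* **Phenotypes** — hybrid genetic value plus i.i.d. N(0, σ²_e) error. σ²_e
  is calibrated once at cycle 1 so that broad-sense heritability is
  H² = 0.3 over the 40 × 40 = 1,600 possible parent hybrids
  (σ²_e = σ²_G (1 − H²)/H², σ²_G enumerated exactly), then frozen for all
  15 cycles.

## Testcross designs

A k-tester sparse design draws k testers uniformly from the *current*
opposite-pool lines and partitions the n candidate lines into k equal
uniform-random subsets (named designs: k ∈ {1, 2, 3, 4, 5, 10, 20, 50, 100,
600, 1200} at n = 1,200). Every design phenotypes exactly n testcrosses per
pool per cycle — the equal-resources premise of the comparison. A
family-stratified allocator (round-robin within families, load-rebalanced)
is available behind a flag for sensitivity analysis; the default follows the
unconstrained random partition. The incomplete-factorial comparator pairs
the two pools by a uniform random bijection (1,200 hybrids, every line of
both pools used exactly once) and predicts both pools from one joint fit.

## Genomic prediction

**Testcross model** (single tester): y = 1μ + Zα + e with line dosages
coded 0/2 and i.i.d. marker effects. Variance components are estimated by
exact single-component REML on the spectrum of the marker covariance ZZᵀ
(one-dimensional profile restricted likelihood, optimized on ln γ with a
grid start and bounded refinement); marker BLUPs are recovered in
observation space, identical to the m × m ridge system.

**Pool-specific additive + dominance model** (k ≥ 2): y = 1μ + Z₁a₁ + Z₂a₂
+ W1μ_d + Wd* + e, with 0/1-coded line and tester genotypes, W marking
heterozygous hybrid loci (equal to Z₁ ≠ Z₂ for inbred parents, asserted),
the heterozygosity count W1 as a fixed covariate whose coefficient is the
mean dominance effect μ_d, and three independent marker-effect variances.
Estimation is REML in observation space on the three kernels Z₁Z₁ᵀ, Z₂Z₂ᵀ,
WWᵀ: damped average-information updates with per-component EM fallback
(EM updates are non-negative by construction), a trust region of at most a
five-fold change per iteration, and convergence when the applied update is
below 0.3% of each component's natural scale (phenotypic variance divided by
the kernel's mean diagonal). The scale-aware damping matters scientifically:
in late breeding cycles the heterozygosity structure of the testcrosses is
nearly constant, the restricted likelihood becomes almost flat in the
dominance variance, and an undamped Newton-type optimizer wanders to extreme
values that amplify noise in the dominance BLUPs; the damped scheme leaves
weakly identified components near their equal-split starting values, the
behavior of the EM solvers traditionally used for this model class. Start
values split half the phenotypic variance equally across the three genetic
components; the cap is 200 iterations (typical fits converge in 5–50) and a
non-converged fit returns the last iterate flagged. A constant
heterozygosity covariate is dropped (μ_d = 0); with a single tester the
tester effects a₂ collapse to 0 automatically because the projection
annihilates constant columns.

GCA allele effects combine the estimates with the *opposite* pool's current
allele frequencies, α̂₁ = ½[â₁ + d̂(q₂ − p₂)] with d̂ = d* + μ_d (and
symmetrically for pool 2); frequencies come from all current-cycle lines of
the pool, not from the testers or parents (config-selectable). Line GCA is
the dosage-weighted sum of allele effects; the 40 top-ranked lines are
selected as parents, ties broken by ascending line index.

The baseline accuracy program fits the testcross model to each line's mean
phenotype over three common testers.

## Ground-truth metrics

True GCA of a line is the mean genetic value of its hybrids with every
opposite-pool line, computed exactly by per-locus marginalisation over
partner frequencies (equal to brute-force enumeration). The full-factorial
hybrid mean is exact from pool frequencies. Hybrid genetic variance is
enumerated exactly whenever the factorial has ≤ 2 × 10⁶ pairs (the full
1,200 × 1,200 factorial is a single matrix product; the dominance cross term
is computed in float32, a < 10⁻⁶ relative error on these sums), with uniform
Monte-Carlo pair sampling beyond (default 100,000 pairs, chunked to bound
memory). SCA variance is var_hybrid − var_gca_f − var_gca_m floored at 0,
which is exactly 0 under pure additivity. The reported SCA/GCA ratio divides
by the summed GCA variances by default; a "pooled-lines" convention
(variance of the concatenated line-GCA values of both pools, about half the
summed value) is available for sensitivity. Pool divergence is tracked by
Nei's minimum distance (mean squared frequency difference over QTN
polymorphic in the union of the pools), mid-parent heterosis Σ dᵢ(Δpᵢ)²
(the classical hybrid-minus-midparent deviation for parental populations at
Hardy–Weinberg proportions — for fully inbred parental pools the identity
holds against HWE population means, not per-se line means), and fractions of
QTN fixed for the same or for opposite alleles. A VanRaden genomic
relationship matrix with eigenvalue variance fractions supports
population-structure summaries.

## Protocols, seeding, scale

The **gain protocol** runs the full 15-cycle program separately per design
and measures the full-factorial hybrid mean relative to the initial pools.
The **accuracy protocol** runs one baseline trajectory (three common
testers) and applies all configured designs to the same lines at evaluation
cycles (default 1, 2, 3, 5, 10, 15) with freshly drawn testers; evaluations
never feed back into selection. Genomic accuracy is the Pearson correlation
of predicted with true GCA; phenotypic accuracy correlates the single
testcross phenotype with true GCA.

All randomness derives from one root seed through named child streams
(numpy `SeedSequence` spawn keys): founder genome, locus assignment, trait
and pool formation depend only on (seed, replicate), so all designs of a
replicate share identical initial pools; breeding streams additionally key
on design and cycle. Outputs are bit-identical across reruns.

Two scale profiles ship with the package. The **full profile** is the complete
program scale (1,200 lines per pool from 60 crosses × 20 DH, 5,000 QTN, 5,000
SNP). The **desk profile** (400 lines from 40 crosses × 10 DH, 1,000 QTN,
1,000 SNP, same genome map) reproduces the qualitative behavior in minutes
and is used for the long 15-cycle experiments in the test suite and the
gain comparisons in `scripts/acceptance.py`; cycle-1 accuracy comparisons
in the acceptance script run at the full profile because the sparse-design
advantage grows with population size and marker density (at 400 lines the
relative accuracy gain of 10 testers over one is roughly half the full-scale
value, and tester loads drop from 120 to 40 crosses per tester). The
variance-ratio computations use 2,000 QTN. A **mini profile** exists for
smoke tests only.

## What the generator does and does not emulate

The simulation captures LD buildup in a small founder population, family
structure from repeated half-diallel crossing, drift and selection-driven
pool divergence, directional dominance and overdominance, and the
confounding of GCA with tester-specific SCA in single-tester testing. It
does **not** model epistasis, epigenetics, genotype-by-environment
interaction, multi-allelic loci, new mutation after the founder stage,
sequence-level realism, or seed-production logistics; heterotic pools share
one set of loci with identical effects. Passing tests therefore demonstrate
internal consistency of the model and the reproducibility of the study's
simulated comparisons, not predictions for any real breeding program.

## Known limitations

* The founder demography is a constant-Ne coalescent; the allele-frequency
  spectrum of a realistic maize demography (bottlenecks, ancestral
  expansion) would shift absolute variance levels, though scale-free ratios
  are only mildly affected.
* The cycle-1 SCA/GCA ratio progression across dominance scenarios is
  structurally bounded by the trait model: with independent loci the ratio
  is 4vB/(A + vC) in v = E[δ²], concave in v, so the high:low ratio cannot
  exceed E[δ²]-ratios (~4.8) under any GCA-variance convention. The
  simulated values (≈ 0.06 / 0.15 / 0.29 summed; ≈ 0.12 / 0.29 / 0.58
  pooled-lines) reflect this.
* REML components that are weakly identified in late cycles are effectively
  regularized toward their starting values by the damped optimizer; this is
  deliberate (see above) but means late-cycle variance-component estimates
  should not be over-interpreted.
* Reduced-scale runs compress differences between designs; sign and ordering
  of design effects are stable, point magnitudes are not.
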