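# Methods

This note records the models implemented, the assumptions behind them, the
numerical choices that matter, and what the synthetic-data tests do and do
not establish.

## Data model

All statistics operate on a polarized haploid SNP matrix: samples × sites
with calls in {0 = ancestral, 1 = derived, missing}. Polarization assumes
the ancestral allele is the one matching an outgroup-aligned reference
(`AA` tag or REF in VCF input). Sites whose annotated ancestral allele
matches neither observed allele are **dropped, not folded** — folding them
would corrupt the unfolded SFS — and multi-allelic sites are dropped
likewise (counts logged). Missingness is a first-class third state and
never enters allele counts. Positions are 1-based within a locus; loci are
treated as unlinked, sites within a locus as fully linked.

The locus-presence filter discards loci with non-missing calls in fewer
than a given fraction of samples (default use: 0.8), mirroring standard
RAD-assembly practice; presence is per locus, not per site, because RAD
dropout is allele/locus-wise.

## Diversity statistics

π and D<sub>xy</sub> are average pairwise differences per comparable site;
each pair's denominator counts only sites called in both members
(pairwise-complete), plus the invariant-site total when an alignment length
is supplied — otherwise values are per-variant-site and should only be
compared within a dataset. F<sub>ST</sub> is Hudson's
1 − mean(π_A, π_B)/D<sub>xy</sub>, reported unclipped (it is negative in
expectation noise for undifferentiated groups, and undefined when
D<sub>xy</sub> = 0). Jackknife SDs use the delete-one formula
sqrt((n−1)/n · Σ(θ̂₍ᵢ₎ − θ̄)²). Group comparisons use one-way ANOVA on the
leave-one-out estimate sets and pairwise Student's t-tests with Bonferroni
(not Holm) adjustment.

Wright's haploid island-model conversion Nem = ½(1/F<sub>ST</sub> − 1)
assumes migrants are drawn from the metapopulation-wide pool. In a
**finite** d-deme symmetric model a migrant necessarily comes from one of
the other d−1 demes, which inflates effective migration by d/(d−1); the
`island_model` constructor therefore sets the per-pair backward rate to
Nem/(Ne·d) so that equilibrium Hudson F<sub>ST</sub> equals Wright's
1/(1 + 2Nem) for any d. Without this correction a two-deme world at
Nem = 4.5 equilibrates at F<sub>ST</sub> ≈ 0.053 instead of 0.1.

## ABBA/BABA statistics

Pattern sums use population allele frequencies (not pseudo-haploid draws):
ABBA = Σ(1−p₁)p₂p₃(1−p₄), BABA = Σp₁(1−p₂)p₃(1−p₄),
BBAA = Σp₁p₂(1−p₃)(1−p₄). D = (ABBA−BABA)/(ABBA+BABA); significance from a
delete-one-block jackknife over 20 contiguous site blocks by default
(configurable). Because loci are unlinked, contiguous blocks are a
conservative convenience rather than a linkage necessity. The jackknife
Z-calibration is trustworthy only when discordant-site counts are dense
(tens of ABBA+BABA sites); with a handful of informative sites the
delete-block ratio is heavy-tailed and Z is not normal — the test suite's
calibration world is chosen accordingly.

The f4-ratio uses the P3-substitution denominator
α̂ = Σ(p₁−p₂)(p₃−p₄) / Σ(p₁−p₃)(p₃−p₄) (an f-hom-style approximation; no
P3 subpopulation split is available), flagged in result metadata. The
denominator contains p₃², whose plug-in estimate is biased upward by
Het(p₃)/n₃; when per-site call counts are available the unbiased
p₃(n₃p₃−1)/(n₃−1) is substituted, which is what makes α recoverable to
±0.03 at realistic sample sizes. For a **pulse** admixture of fraction α
from P3 into P2 the estimand equals α; for continuous migration windows
there is no single "α", only a monotone relationship.

## Demographic models and simulator

A model is a species tree of haploid populations with present-day sizes,
divergence events (backward lineage relocation), piecewise-constant size
changes, forward-time migration windows (source → dest at per-lineage,
per-generation rate m on [t_start, t_end)), and pulse admixture events.
Times are generations before present; nothing is calendar-calibrated, and
with SNP-only data all estimates are interpretable primarily as relative
values tied to the assumed mutation rate (default 2.8 × 10⁻⁸ per site per
generation).

The simulator is a continuous-time structured coalescent: k lineages in a
deme of size Ne coalesce at total rate k(k−1)/(2Ne); backward migration
reverses the forward arrows (a dedicated test pins the convention with an
asymmetric two-population model). The expected SFS accumulates each
branch's length into the cell indexed by its descendant counts per sampled
population, normalized over polymorphic cells; by branch-length/mutation
duality this is the expected SNP spectrum under infinite sites. Sampled
spectra and synthetic genotypes place Poisson(μ·L·total length) mutations
on one genealogy per locus. Replicate r of seed s uses substream mix(s, r),
so results are chunking-independent and exactly reproducible. The event
loop is numba-compiled; cross-checked against msprime's branch-mode allele
frequency spectrum on a three-population windowed-migration model (max
cell discrepancy ~5 × 10⁻⁴ at 1.5 × 10⁵/2 × 10⁴ replicates) and against
closed forms (1/i law, 2NeΣ1/i tree length, island-model F<sub>ST</sub>).

The model zoo implements the standard gene-flow families for
the (REC,(ENA,EUR)) topology: strict isolation, full migration (all eight
gene-flow events), current-populations-only (six), the eight leave-one-out
variants, the three-event "model 10", and early/secondary-contact timing
variants of the ancestral REC↔FLEX events ("early": window starting at the
species split with a free stop time; "secondary contact": a free contact
time after an isolation period, flowing until the next divergence; both
parameterized by a window fraction so any parameter draw yields a valid
tree). Beyond the named families, `make_model` builds any event subset.

## Composite likelihood and optimization

log₁₀CL = Σ obs_i log₁₀ max(exp_i, 1/(10·n_sims)) over polymorphic cells;
the floor guards cells unobserved among finite simulations, and
monomorphic corners are excluded (SNP-only data). Because proportions are
invariant to jointly rescaling all sizes and times, a fit on SNP-only data
cannot identify absolute scale; when the observed SFS knows its locus
count, a Poisson term for the total polymorphic-site count
(λ = n_loci·μ·L·E[total branch length]) is added, identifying scale through
the fixed mutation rate — the same role sequence length plays in
simulation-based SFS likelihood tools. Observed masses may be fractional
(projection output).

Optimization mirrors cycle-based conditional maximization: per run, a
log-uniform start within bounds, then cycles visiting one parameter at a
time, evaluated on a shrinking five-point symmetric pattern on the log₁₀
scale (initial span a quarter of the parameter's log-range, decaying to
0.05 decades). All evaluations within a cycle share one simulation seed
(common random numbers) — without CRN, Monte Carlo noise at desk-scale
n_sims defeats any 1-D search. Runs are compared at a final common-seed
evaluation. For high-dimensional families, `fit_model(init=...)` supports
hierarchical warm starts (half the runs jittered from a nested simpler
model's estimates); at desk-scale budgets purely random starts routinely
leave 10+-parameter models below the likelihood of their own nested
submodels. Model ranking uses AIC = 2k − 2 ln(10)·log₁₀CL on a second-step
evaluation: one high-count expected SFS at the fixed estimates against the
one-SNP-per-locus spectrum. Defaults follow the full-scale protocol
(100 runs × 50,000 sims × 40 cycles; 10⁷ evaluation sims; bootstrap
100 × 10); tests use desk-scale settings (~10 × 5,000 × 10; 10⁵) and say so.

Parametric bootstrap: resimulate observed spectra at the best estimates
(one genealogy per locus), refit each with short runs, take 2.5%/97.5%
percentiles. CIs are percentile intervals of a **composite** likelihood —
approximately, not exactly, 95%; they are honest about ridges (e.g. the
divergence-time/migration-rate trade-off in IM models, where the
likelihood is nearly flat along T·m contours).

## Synthetic data: what a green test establishes

The generator emulates the post-assembly product: ~10³–10⁴ unlinked 90 bp
loci, polarized biallelic SNPs (ancestral = 0 exactly), whole-locus
per-sample dropout (the pattern the 80% presence filter targets), three
focal populations plus a deep outgroup. The default preset's sizes follow
a plausible ordering for a recently diverged amphi-Atlantic species
pair (REC 6000 > ENA 3000 > EUR 1000, bottlenecked ENA+EUR ancestor,
splits at 2000/8000 generations, outgroup at 40,000, secondary contact at
5000) — round values chosen once. Not emulated: sequencing error, paralog collapse, reference
bias, depth variation, within-locus recombination. A green end-to-end test
therefore establishes correctness of the statistics and inference on
idealized RAD-like data, not robustness to assembly artifacts.

## Known limitations

* Composite likelihood ignores linkage between SNPs of a locus during
  fitting (by design — the two-step protocol evaluates on thinned data).
* The ECM-style search with desk-scale simulation counts can stall on
  plateaus for ≥13-parameter families; the full-scale defaults exist for
  real analyses.
* f4-ratio assumes the outgroup is unadmixed and P3 is the donor's sister;
  the P3-substitution denominator underestimates α if the true donor
  diverged long before P3.
* Genotype simulation supports ≤64 sampled haploids (bitmask encoding);
  SFS simulation has no such limit.
* The Z calibration of the block jackknife degrades for datasets with
  fewer than ~20 discordant sites; results there should be treated as
  qualitative.
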