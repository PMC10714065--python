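# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `mtcohort`, and what the synthetic-data tests do and
do not establish about real data.

## Data model and deletion rule

An alignment is a rectangular matrix over {A, C, G, T, gap, IUPAC
ambiguity}; only A/C/G/T count as called bases. All statistics and
haplotype definitions use **complete deletion**: any column with a
non-called state in any analysed sequence is excluded. This matches the
behaviour of the classic DnaSP-style workflow this package mirrors and
makes per-group statistics depend only on that group's sequences (a
column unusable in one cohort may be usable in another). Pairwise
deletion is available for site classification only. Reported positions
are 1-based.

Site categories: a usable column with ≥2 alleles is *segregating*; it is
*parsimony-informative* when ≥2 alleles are each carried by ≥2 sequences,
otherwise a *singleton* column (all its minor alleles are carried by
exactly one sequence each — this extends the biallelic definition to
multi-allelic columns and keeps S = singletons + informative exactly).

Haplotypes are equivalence classes of identity over usable columns,
numbered by first occurrence. The divergent-haplotype filter flags any
haplotype whose minimum pairwise difference to *every* other haplotype of
a comparison set is ≥ `min_steps` (default 10); such haplotypes (likely
vagrants from an unsampled population) can be excluded before diversity
and demographic analyses.

## Statistics

* `Hd` uses Nei's n/(n−1) bias correction.
* π and θ_W are computed per usable site and reported in percent.
* Tajima's `D` uses the 1989 constants applied to (S, mean pairwise
  differences); multi-allelic columns count once in S and allele-wise in
  the pairwise differences. `D` is undefined (NaN, with a warning) when
  S = 0.
* Achaz's `Y` is implemented in its folded (no outgroup) form: singleton
  columns are removed, and the two theta estimators — a pairwise-difference
  type and a Watterson type restricted to minor-allele classes
  2…n−2 — are contrasted and normalised by the exact variance
  α·θ̂ + β·θ̂², with α and β assembled from the neutral-coalescent
  covariances of the site-frequency spectrum (Fu's σ coefficients) and
  θ̂, θ̂² estimated unbiasedly from the non-singleton segregating-site
  count. The σ implementation is verified in the tests against two exact
  algebraic identities: Σσ_ij equals the quadratic coefficient of Var(S),
  and the π-weighted quadratic form equals Tajima's b₂ constant. `Y` needs
  n ≥ 4 and at least one non-singleton segregating site.
* Hudson's F_ST = 1 − H_w/H_b with H_w the unweighted mean of the two
  within-cohort mean pairwise differences. φ_ST is the two-group AMOVA
  variance decomposition treating nucleotide differences as squared
  distances. Both are undefined when the denominator vanishes
  (monomorphic data). Note the finite-sample property that F_ST of two
  identical groups is ≈ −1/(n−1), not exactly 0.
* Permutation tests shuffle labels preserving group sizes and use the
  add-one estimator p = (1 + #{perm ≥ obs})/(n_perm + 1); ties count as
  extreme (conservative). With near-monomorphic data the statistic is
  heavily tied and p-values concentrate near 1 — the uniformity property
  holds only where the statistic is quasi-continuous.

## Rarefaction

Sampling is **with replacement**, k from k_min to min(n, 50), default
5000 resamples per k; the mean and SE (SD/√valid) are reported per k.
Draws on which a statistic is undefined are dropped and counted, never
imputed. k_min is 2 for H/Hd/π/θ_W and 3 for D; Y starts at k = 4 (below
that every draw's folded spectrum is all singletons, so the whole column
would be empty). Because resampling is with replacement, the curve at
k = n sits *below* the full-sample statistic (coupon-collector effect),
and comparing groups of unequal n at matched k slightly favours the
larger group; both effects are inherent to the stated procedure and are
reproduced exactly by the enumeration oracles in the tests. Two curves
are compared per k by flagging disjoint mean ± SE intervals.

All statistics for one group are computed from the same draws via
precomputed one-hot allele and haplotype indicators, which makes the
5000-resample default cheap; curves are bit-reproducible given the seed.

## Serial coalescent simulator

Haploid bookkeeping throughout: N_e is the effective number of
mtDNA-transmitting females; with j active lineages in an epoch of size
N_e the coalescence rate is j(j−1)/(2N_e) per generation, so E[T₂] = N_e.
Samples enter the genealogy at their sampling times (generations before
present); epoch boundaries and pending sampling events truncate the
exponential waiting time, which is redrawn (memorylessness). Mutations
are finite-sites: Poisson(μ·L·branch length) hits per branch, uniform
site choice, transition bias κ (a hit is a transition with probability
κ/(κ+2)); recurrent hits are allowed. The root sequence is uniform
random (configurable composition; the statistics used are
composition-insensitive). Defaults: κ = 10 (typical mammalian mtDNA
coding bias), locus L = 4175 bp, cohorts of 52 (time 0) and 19 (time 2
generations) matching the study design of ~25 years ≈ 2.5 generations at
a 10-year generation time.

Correctness is established two ways: closed-form moments (E[T₂],
E[total length] = 2N_e·a_n, E[S] = θ·a_n, E[π] = θ with θ = 2N_e μL) at
Monte-Carlo precision, and two-sample Kolmogorov–Smirnov agreement of
the distribution of S with msprime on matched isochronous and serial
models.

### The `iberia_like` preset

One panmictic population, cohorts as above, demographic history of the
shape best supported for the Iberian population: expansion to N_mid = 5000 at 2000 generations
BP (from N_anc = 500), collapse to N_e = 20 at 3 generations BP,
μ = 1e-7/site/generation, κ = 10. Chosen once by a pilot calibration so
that (i) mean π across histories is ≈ 0.04% per site — within a factor
two of the observed Iberian value of 0.05% (per-history π varies several-fold: one mtDNA
locus is one genealogy), and (ii) the younger cohort shows the observed
key signature, fewer haplotypes at matched sample size despite being the
larger cohort (direction holds in ~80% of histories; the directional
test therefore averages over replicates). The collapse must reach a very
small N_e to be visible over ≤3 generations — a 10-fold drop to
N_e in the hundreds leaves no detectable cohort contrast. What the
preset does **not** emulate: migration, selection, rate heterogeneity
across sites, sequencing error, and the multi-population context of the
real data; passing tests show the pipeline's internal consistency under
the stated model, not the field accuracy of the biological conclusions.

## Scenarios and priors

Six single-population scenarios (constant large; constant small; old
≥150-generation expansion; old decline; recent ≤3-generation decline;
old expansion then recent ≥10-fold decline). Default priors — package
defaults declared once and echoed into every table manifest:
log-uniform N_e ∈ [100, 20000] (large:
[2000, 20000]; small: [100, 2000]), uniform T_old ∈ [150, 2000] and
T_rec ∈ [1, 3] generations, log-uniform change factors ∈ [10, 100],
log-uniform μ ∈ [1e-8, 1e-7]. Draws are rejection-sampled against the
scenario constraints, with an error if acceptance falls below 0.1%.

The summary vector has 30 entries: per cohort (old, new, pooled) S, H,
Hd, π, θ_W, D, mean pairwise differences, singleton count; between
cohorts Hudson F_ST, φ_ST, mean between-cohort differences, shared and
private haplotype counts. Undefined entries are NaN sentinels, median-
imputed from the training columns identically for simulated and observed
vectors. The manifest is written with every table.

## ABC-RF

LDA (k−1 axes) is fitted on the training set only and appended to both
training rows and the observed vector; a singular within-class
covariance falls back to shrinkage LDA with a warning. The classifier is
a 1000-tree random forest (scikit-learn defaults otherwise); votes for
the observed vector are per-tree hard votes. Prior error, confusion
matrix and type II errors come from out-of-bag predictions. The
posterior probability of the selected scenario is a regression forest on
the indicator "out-of-bag prediction correct", evaluated at the observed
point, with ranger-style regression defaults (features per split = p/3,
minimum node size 5) — the conventions of the reference ABC-RF
implementation, and an order of magnitude faster than fully-grown
regression trees at identical estimates. Evaluating this regression
forest at a *training* point is unreliable (trees memorise their in-bag
rows); it is only ever evaluated at the held-out observed vector.
Replicate analyses re-train the forest with derived seeds on the shared
training table (forest-only variance); full re-simulation is available
by rebuilding the table with a new seed.

### Scenario discriminability under the default priors

With the default substitute priors the six scenarios overlap strongly:
at 2000 simulations per scenario and 1000 trees the out-of-bag prior
error is ≈ 0.60 (worst confusions: recent-decline scenarios vs constant
sizes — a ≤3-generation decline is invisible in mtDNA unless the
post-decline N_e is tiny relative to the sample size; and old expansion
vs constant). This is a property of the prior ranges, not of the forest:
under a sharply separated alternative prior set (`TIGHT_PRIORS`:
non-overlapping constant-size ranges, narrower mid-range, fixed μ) the
error drops to ≈ 0.43, and in the fully separable two-scenario case the
tests show < 5% error. Published analyses of this design that report
~10% prior error therefore imply far tighter, data-informed priors than
the defaults declared here; the acceptance script reports both numbers
so the sensitivity is visible in every run.

## Numerical conventions

Seeds: every pipeline stage derives a 31-bit seed from
SHA-256(master, stage label); all results are bit-reproducible from the
master seed. Quantiles in the goodness-of-fit envelope are empirical
order statistics with linear interpolation; a statistic is an outlier
when the observed value leaves the central 1−α interval (α = 0.05), and
a constant simulated column is an outlier only if the observed value
differs from the constant. Zero-variance columns are dropped (with a
warning) before PCA/LDA projections; statistics are median-imputed and
standardised on the training set.

## Problem sizes

Defaults follow the study design (10,000 simulations per scenario, 1000
trees, 10 replicates, 5000 resamples). The test suite and the acceptance
script run a 2000-per-scenario tier with 1000 trees and 3–5 replicates,
chosen as the package's smoke-scale configuration; at these sizes the
out-of-bag diagnostics are stable to well under a percentage point, so
conclusions do not change at the full scale.

## Known limitations

Single non-recombining locus only; no migration or selection; folded Y
only unless an outgroup polarisation is added by the caller; Hudson
F_ST's small-sample bias is not corrected; the GOF envelope uses the
prior predictive (the training set), not a posterior predictive
re-simulation; the posterior-probability regression forest inherits the
classifier's feature space and is only as calibrated as the out-of-bag
record allows.
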