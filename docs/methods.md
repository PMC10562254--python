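# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of `hybridsel`.

## Synthetic populations

The generator produces the four population layers of a hybrid-breeding
study, each with stored ground truth.

**Founder panels.** Two subpopulations of fully homozygous inbred lines
(defaults: 19 indica-like, 23 japonica-like accessions). A Bernoulli
draw with probability `diff_fraction` marks each marker as
subspecies-differentiated; at differentiated markers the two panels
carry opposite major alleles, each at within-panel frequency `purity`
(default 0.95, so the ≥17/19 and ≥21/23 panel-majority rules are
exercised non-trivially rather than passed by construction). At
undifferentiated markers both panels share one major-allele frequency
drawn uniformly from [0.5, 0.95]. Truth stored per marker: the
differentiation flag and both panel major alleles.

**Crosses.** `make_f1` derives the F1 of two inbreds deterministically
(heterozygous exactly at parent-discordant sites; missing propagates;
a heterozygous parent is an error). `simulate_f2` selfs an F1 under the
Haldane model: crossovers per chromosome are Poisson with mean L/100
Morgans, positions uniform on the cM map, no interference. The model was
chosen because it is standard and analytically checkable — the
recombinant fraction between markers δ cM apart is (1 − e^(−δ/50))/2,
which the tests verify. An optional symmetric genotyping-error rate
flips calls uniformly to the other two classes; the default is
error-free, since the bin-genotyping error structure of real low-coverage
F2 data is not modelled here.

**Cohorts.** Two cohort builders sit on top: `simulate_multicross_f2`
(several independent biparental F2 families — realistic family LD) and
`simulate_hybrid_cohort` (each individual the F1 of two independently
drawn gametes, i.e. a panmictic cohort in Hardy–Weinberg proportions
with free recombination between markers — the analogue of a diverse
hybrid-cultivar collection). Variance-component recovery is evaluated on
the panmictic cohort: in a single- or multi-family F2, long-range family
LD lets out-region flanking markers absorb part of a candidate region's
variance, biasing regional PVE downward (we measured ≈0.22 recovered for
a planted 0.30 on multicross F2 versus ≈0.29 on the panmictic cohort);
the mixed model in question is designed for association cohorts, which
the panmictic cohort mirrors.

**Phenotypes.** g_i = Σⱼ aⱼ·x_ij + dⱼ·z_ij with x the −1/0/1 coding and
z the heterozygosity indicator. The residual SD is calibrated on the
simulated cohort itself so that Var(g)/Var(y) equals the requested h²
exactly in the empirical sense — robust to LD among the causal loci,
at the price that the *population* h² differs from the target by
sampling error only. h² = 0 produces pure unit-variance noise; h² = 1
with zero genetic variance is an error.

**Seeding.** One master seed; every stage derives an independent child
generator via `SeedSequence(master, spawn_key=crc32(stage))`, so stages
are reproducible in isolation and insensitive to call order.

## Introgression scanning

Window calls use a fixed hit count (≥120 of a 199-SNP window), not a
fraction: missing labels count toward neither state, which is
conservative near gaps. Since 2 × 120 > 199, no single window can pass
both states, but runs of passing windows of the two states can overlap
near boundaries; the merge rule is per-state union of passing windows →
maximal runs, with any overlap assigned SNP-by-SNP to the state covered
by more windows, ties to the heterozygous state. Segment coordinates are
reported half-open in panel-SNP index space plus the bp positions of the
terminal SNPs — the bp extent never extrapolates beyond observed SNPs.
All thresholds (window 199, hits 120, panel majorities 17/21) are
parameters with these defaults.

Panel criteria count missing panel genotypes in neither the numerator
nor the modal count (the effective denominator shrinks with
missingness); the major allele is taken over observed allele copies, and
an exact 50/50 tie disqualifies the marker.

## Dominance analysis

Genotype-class effects default to plain class means over non-missing
pairs. A mixed-model association fit could supply adjusted effects
instead; the d/a formulas operate on class effects regardless of the
estimator, and class means keep the estimator transparent and exactly
testable on simulated data. The degree is d/a for higher-favorable and
−d/a for lower-favorable traits; for window-favorable traits (e.g.
amylose content with an optimal interval) the sign convention is not
standardized, and this package uses +d/a. Category boundaries (additive
within ±0.1 of 0, complete within ±0.1 of 1, partial between,
overdominant above, negative below) are configurable; the defaults
reproduce the conventional verbal labels for degrees such as 0.15
(modest), 0.4 (partial), 1.24 (overdominant). Loci where either
homozygote class holds fewer than 5 observations are flagged invalid
(outlier-prone class means), and a = 0 yields a NaN degree rather than
an exception.

Top-signal selection clumps greedily by ascending p-value with a 1 Mb
exclusion radius — the same 1 Mb convention used for candidate regions —
because "one representative per signal" needs a definition and
physical-distance clumping is the simplest auditable one.

Better-parent heterosis is reported in both absolute (F1 − better
parent, direction-aware) and relative form; the boolean indicator uses
the absolute form, since a formula-level convention is not standardized.

## REML

Variance components are estimated by average-information REML on the
phenotypic covariance V = Σ σ²ᵢKᵢ + σ²ₑI with explicit dense algebra
(the package targets hundreds to a few thousand individuals). Each
iteration proposes a Newton step on the AI matrix; any step that leaves
the non-negative orthant falls back to the fixed-point update
σ²ᵢ ← σ²ᵢ·(y′PKᵢPy)/tr(PKᵢ), which is non-negative by construction, and
steps that decrease the restricted likelihood are halved (up to 8
times). Convergence: |Δ logL| < 1e−6·(1+|logL|), max 200 iterations;
non-convergence is flagged, never silent. Components are floored at
1e−8·Var(y) during iteration and reported as exactly 0 at the boundary.
Kernels with numerically zero trace (e.g. a dominance kernel on a fully
inbred cohort) are pinned at 0 and excluded, which makes the fit
identical to omitting the kernel — the tested equivalence between "σ²_d
fixed at zero" and the additive-only model. A kernel whose smallest
eigenvalue is negative from rounding is repaired with the minimal
diagonal jitter (at least 1e−6).

## Relationship matrices and GBLUP

W centers the −1/0/1 coding by its column mean (equivalently dosage −
2p); H centers the 0/1 heterozygosity coding by its expectation 2pq.
Both A and D share the denominator 2Σ pⱼ(1−pⱼ) by default; the classical
dominance normalization Σ(2pⱼqⱼ)² is available via
`dominance_denominator="classical"` (the two differ by a scalar, which
REML absorbs into σ²_d). Monomorphic markers are dropped with a warning;
missing genotypes are imputed at their expectation per marker (they
contribute 0 after centering). Allele frequencies always come from the
training cohort; candidate blocks are centered with training
frequencies, which makes relationship-based candidate prediction
u_c = G_ct(G_tt + λI)⁻¹u_t and marker-effect back-solving
algebraically identical up to the ridge λ (default 1e−6; the two routes
agree to ~1e−12 on full-rank problems, and a candidate equal to a
training individual reproduces that individual's GEBV to about the
ridge magnitude).

The reported h² scales kernel variances by the mean kernel diagonal
(σ²_a·mean diag A, etc.), i.e. the average individual-level genetic
variance, so it is comparable to the empirical Var(g)/Var(y) the
simulator calibrates. The default model is additive-only; the dominance
kernel is a switch, reflecting that adding dominance does not
automatically improve hybrid prediction accuracy and costs
identifiability at small n.

Cross-validation is sixfold with three independently shuffled
iterations by default; accuracy is the Pearson correlation between
predicted genetic value and observed phenotype per held-out fold,
averaged over folds and iterations. Folds with constant held-out
phenotypes are skipped and logged.

## Selection index and sterility screen

Percentile traits are scored against the candidate set's own empirical
GEBV quantiles with right-closed bins (a value exactly at the 80th
percentile scores in the 60–80% bin); whether the original protocol
ranked against candidates or the training cohort is ambiguous, and the
candidate set is the self-contained choice. Range traits score 40 inside
/ 20 outside fixed optimal intervals (heading date 80–90 d, plant height
115–125 cm, grain shape 3.0–3.4), so the index of seven traits is
bounded in [60, 280] and ≥80 flags a high-scoring combination — note the
bound makes the flag informative only together with the percentile
scores. Sterility screening flags a combination when its derived F1 is
homozygous for the sterility-causing allele at any listed locus whose
seed-production system (wild-abortive vs two-line) matches the female's
cytoplasm; a missing F1 genotype at a screened locus yields an
undetermined flag rather than a pass.

Parents entering combination enumeration may carry up to 2% residual
heterozygosity; residual heterozygous sites are treated as missing in
the derived F1, and anything above the tolerance is an error.

## Problem sizes used in tests

The shipped test-suite and acceptance-script sizes are chosen as the
smallest scales at which the statistical claims are stable: dominance
recovery at n = 3,000 (20 replicates), GBLUP heritability at n = 1,000,
m = 500 (10 replicates), regional PVE at n = 500 (20 replicates, 4
kernels), scanner-oracle equivalence on 100 random tracks of up to 5,000
labels, and the full 367 × 159 factorial for combination counting.

## Limitations

* The generator draws marker positions on a uniform genetic/physical
  map (250 kb/cM) and founder allele frequencies independently per
  marker; real LD decay, recombination hotspots and ascertainment are
  not emulated, so passing tests demonstrate correctness of the
  estimators under the stated models, not robustness to real-data LD
  structure.
* Association scans are out of scope: p-value tables are inputs.
* The REML solver is dense; cohorts beyond ~5,000 individuals need a
  sparse or low-rank reformulation.
* Genotype data paths assume biallelic SNPs; multiallelic records are
  skipped at parse time.
* The purity verification (pure japonica → 100% japonica-lineage
  windows) holds at `purity=1.0`; at 0.95 a pure sample still scans as
  its own subspecies, but window coverage near chromosome ends depends
  on the local density of discordant calls.
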