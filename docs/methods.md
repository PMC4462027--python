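# Methods

This note documents the statistical models the package implements, the
defaults and why, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer should know about.

## Data model

Genotypes are single-allele calls per (accession, locus): the panels
this package targets are pure lines genotyped from one plant, so a cell
is an allele size in base pairs, a *null allele* (the marker amplified
no band) or *missing*. The two non-size states are deliberately
distinct: null alleles are a real genotype class — they are excluded
from frequency-based statistics (diversity, distance, structure, LD,
F_ST) but define the baseline class in allele mining and enter the
marker factor in the association scan — while missing cells are
excluded everywhere. Heterozygous input is rejected rather than
collapsed.

Rare-allele filtering removes alleles at frequency ≤ 0.05 (the
threshold is inclusive: "5% or less"), computed per locus over scored
calls; carriers of a removed allele become missing and loci left with
fewer than two alleles are dropped. A single pass suffices: removing a
rare allele can only raise the surviving alleles' frequencies, so the
filter is idempotent. It is applied before LD and association scans
only; diversity statistics are computed on the unfiltered matrix, where
the rare-allele share is itself a quantity of interest.

## Diversity

Gene diversity `D = 1 − Σ pᵢ²` and Botstein's
`PIC = 1 − Σ pᵢ² − Σᵢ<ⱼ 2 pᵢ² pⱼ²` are plug-in estimators with no
small-sample correction by default, matching the desktop software
conventional in SSR studies; the `n/(n−1)` correction is available by
flag. Informativeness classes are PIC > 0.5 (high),
0.25 < PIC ≤ 0.5 (moderate), PIC ≤ 0.25 (slight); boundary ties fall to
the lower class. The rare-allele proportion is a plain allele-count
fraction (rare alleles / all alleles), not weighted by locus.

## Structure

Nei's 1972 standard distance `−ln(J_xy/√(J_x J_y))` is the default
(J's averaged across loci), with the bounded D_A variant selectable;
for single-allele inbred profiles both reduce to functions of the
shared-allele match fraction, which is how the accession-level matrix
is computed. Zero identity is capped at a configurable maximum
(default 10) instead of returning infinity. Neighbour joining is
delegated to scikit-bio with negative branch lengths clamped to zero;
the tests verify exact recovery of additive matrices for 4–8 taxa.

The model-based structure stage fits the admixture likelihood
`Πᵢₗ Σₖ q_ik f_kl,a` by EM with multiple random restarts (default five
runs, the usual practice), keeping the best run. The log-likelihood is
monotone non-decreasing across iterations (asserted in tests) and Q
rows renormalize each step. This is a maximum-likelihood stand-in for
the Bayesian MCMC sampler normally used on such panels; an external Q
matrix can be imported and used downstream unchanged.

K selection records the mean final log-likelihood over runs per K — the
quantity structure scans conventionally report — but, because the
maximized likelihood never decreases with K, the default *selection*
applies an AIC-type penalty of one unit per free parameter
(`n·(K−1)` ancestry parameters plus `K·Σ(Aₗ−1)` frequency parameters).
The expected chance gain of an extra cluster is about half a unit per
added parameter, so the penalty accepts a K only when its clusters
explain real structure; on strongly diverged simulations it recovers
the generating K and on panmictic data it returns the smallest K. A
BIC penalty was considered and rejected: with hundreds of frequency
parameters per cluster it over-penalizes and misses true clusters at
realistic panel sizes. Raw log-likelihood and BIC remain available.
Subpopulation assignment is strict: an accession is labelled only when
max Q exceeds the threshold (default 0.9), otherwise admixed.

## Differentiation

F_ST is Weir–Cockerham θ adapted to haploid-coded inbreds: per locus
and allele, a one-way ANOVA of the allele indicator gives among- and
within-subpopulation mean squares, `σ²_a = (MSA − MSW)/n_c`,
`σ²_w = MSW`; θ is the ratio of components summed over alleles (per
locus) and over loci (multi-locus, a ratio of sums). Pairwise F_ST
restricts to each subpopulation pair. Reported values are clamped to
[0, 1]; raw ratios are retained. Subpopulations with fewer than two
scored calls at a locus drop that locus from the comparison.

AMOVA partitions squared allele-identity distances (count of shared
scored loci with different alleles) among vs within subpopulations via
the standard sums-of-squares identities; significance comes from
permuting accession labels (φ_ST as the test statistic, +1-corrected
P). Negative among-components are floored at zero for the percentage
report.

The allele-size trend statistic z-scores each locus's sizes over scored
accessions, averages per accession over contributing loci
(zero-variance loci contribute nothing), and compares groups to a
reference subpopulation by Welch's t-test, signed as
(comparison − reference). Only magnitude and P are meaningful for
comparison with published tables, whose signs are not internally
consistent.

## Linkage disequilibrium

Inbred accessions are phased haploids, so two-locus haplotype counts
come straight from the matrix. Multiallelic D′ is the
frequency-weighted mean of |D′ᵢⱼ| over allele pairs with the usual
D_max normalization; degenerate pairs (margin 0 or D_max 0) contribute
nothing; the statistic is invariant to allele relabeling and locus
exchange, and lies in [0, 1]. Per-pair significance permutes one
locus's calls across accessions (+1-corrected P; below 100 permutations
a warning notes the coarse resolution). The census counts total,
significant (P < 0.05) and intrachromosomal-significant pairs.

Decay is summarized by OLS of D′ on ln(distance cM) over syntenic
pairs, `y = b ln x + c`, excluding zero distances. Published work fits
this curve but never states the decay criterion; here the decay
distance is where the fitted curve crosses a background baseline,
`x* = exp((baseline − c)/b)`, with the baseline defaulting to the 95th
percentile of interchromosomal D′ (a standard background level) and
configurable to a constant. The solve is refused (with an explanatory
status, not an exception) when b ≥ 0 or the baseline exceeds the
intercept.

## Association

Kinship is the Loiselle estimator over shared scored loci, including
the small-sample `p(1−p)/(n−1)` correction term, with negative
estimates truncated to zero after estimation — the convention of the
software lineage this pipeline follows. Truncation leaves the matrix
mildly indefinite; the scan therefore projects it once onto the nearest
PSD matrix (negative eigenvalues clamped), which also guarantees every
principal submatrix used for markers with missing calls is PSD.

The mixed model per trait × environment is `y = Xβ + u + e` with
`Var(u) = σ²_g·2K` (the doubled-kinship convention) and
`Var(e) = σ²_e·I`; y is the accession mean over replicates (replicate-
level data feed only heritability); X holds an intercept and the first
K−1 ancestry columns. Variance components are estimated by REML on the
spectrum of 2K: the restricted likelihood is profiled over
δ = σ²_e/σ²_g, located on a log-spaced grid and refined by bounded
Brent. The tests verify agreement with a dense independent grid search
to 1e-4 in log-likelihood, ratio invariance under phenotype scaling,
and collapse to OLS when K = 0. Components are then held fixed while
each marker — coded as an allele-class factor with the null allele a
class of its own, classes under 3 carriers pooled into "other", the
null class (else the largest) as reference — is F-tested by GLS on the
whitened scale ("population parameters previously determined"); exact
per-marker REML is intentionally not the default, being ~50× slower
for marginal gain at these panel sizes. PVE is the marker term's
whitened sum of squares over the whitened corrected total (the model-R²
alternative is not implemented; the SS fraction is documented and
monotone in the F statistic). BH-FDR is applied within trait ×
environment. Under a 1,000-marker null the scan's type-I rate at
P < 0.05 sits inside the binomial 95% band (slightly conservative, as
expected from class pooling and multi-df F tests).

Broad-sense heritability uses the replicate-level one-way ANOVA:
`σ²_e = MS_error`, `σ²_g = (MS_accession − MS_error)/n` floored at
zero, `H²_B = σ²_g/(σ²_g + σ²_e/n)` in percent; unbalanced replication
substitutes the harmonic-mean replicate count.

## Allele mining and cross design

The effect of allele i at a significant marker is the mean phenotype of
its carriers minus the null-allele carriers' mean (accession means
pooled over replicates and environments by default); with no phenotyped
null carriers the locus-wide mean substitutes, and the substitution is
logged. Effects are translation-equivariant by construction. In a
structured panel this naive contrast absorbs subpopulation-composition
differences between carrier groups; at the 150-accession recovery scale
its replicate standard deviation is roughly 0.4 mm for a planted
1.45 mm effect — the estimator is reported as defined, confounding and
all, because it is the field's convention for SSR panels.

Elite alleles are those with strictly positive effect. The typical
carrier is the phenotypically most extreme carrier in the effect's
direction, ties broken to the lexicographically smaller accession id.
Cross design scores every unordered parent pair lexicographically by
(number of associated markers covered by at least one carried elite
allele, sum of the best carried effect per marker) — the two criteria
breeders state for pyramiding, in that order; both raw quantities and
the full allele union are reported so users can re-rank. Deterministic
tie-breaks make the ranking invariant to input order.

## Synthetic data

The generator emulates the statistical structure of a multi-
subpopulation inbred SSR panel. Per locus, ancestral frequencies come
from a symmetric Dirichlet (α = 0.5); subpopulation frequencies from a
Dirichlet centred on the ancestral vector with concentration
(1−F)/F — the Balding–Nichols model — and each accession draws one
allele from its subpopulation. A dedicated null-allele class (default
frequency 0.03) and missing cells (0.02) are injected. Defaults mirror
the study conditions: 532 accessions in 6 subpopulations with relative
sizes (94, 54, 147, 65, 69, 45), divergence F = 0.3, 258 loci on 12
chromosomes with uniform cM positions, four yearly environments × two
replicates, trait scales GL ≈ 8.1 mm, GW ≈ 3.2 mm, GT ≈ 2.2 mm,
TGW ≈ 24.8 g, polygenic sd ≈ 12% of the trait mean and replicate error
≈ 2.5% (putting H²_B in the mid-to-high 90s at n = 2). The drawn
allele-class count (Poisson mean 12 + 2, capped at 25) was set once so
the *realized* spectrum of a full draw lands at gene diversity ≈ 0.73
and PIC ≈ 0.69 with ≈ 40% rare alleles.

Phenotypes are grand mean + planted QTL allelic effects (null allele =
baseline 0) + a polygenic value + a year effect + replicate noise. The
polygenic value is the sum over loci of small per-allele random
effects, so its covariance across accessions tracks realized allele
sharing — kinship-correlated by construction rather than by a
multivariate-normal shortcut. Truth tables (labels, one-hot Q,
generating frequencies, planted effects, genetic values) are kept for
recovery tests. `pick_qtl_marker` selects the marker/allele closest to
frequency 1/2 — the standard detectable-QTL condition; planting on a
near-fixed marker can leave the locus monomorphic after rare-allele
filtering.

What the generator does *not* emulate: stepwise mutation or any
sequence-level process (frequencies are drawn, not evolved), admixed
ancestry (true Q is one-hot; admixture arises only statistically),
linkage between loci (map positions are decorative for LD decay — no
genetic linkage is simulated, so realized D′ between syntenic markers
carries no distance trend), genotype-by-environment interaction, and
the empirical panel's exact allele-count spectrum (realized ≈ 8.4
alleles/locus vs the observed 10.46 — the Dirichlet family cannot match
allele count, diversity, PIC and rare-share simultaneously; the
diversity statistics were prioritized). Passing tests therefore
demonstrate estimator correctness and calibration under the stated
frequency model, not robustness to mutation-model misspecification or
to real LD structure.

## Problem sizes and numerics

Test-suite simulations use 50–150 accessions × 20–60 loci with 60–500
permutations; recovery suites use 12 seeded replicates; the acceptance
script runs the full 532 × 258 panel for diversity/differentiation/EM
plus a 1,000-marker null scan — sizes chosen so the whole suite runs in
well under a minute each while keeping binomial confidence bands tight
enough to be meaningful. Numerical guards: EM frequency and Q floors at
1e-9 with per-step renormalization; a 1e-6 ridge on 2K before
eigendecomposition; REML grid bounds 10⁻⁸–10⁸ on δ; D′ capped at 1;
permutation P values +1-corrected. All randomness flows from explicit
integer seeds (numpy `default_rng`); identical seeds give byte-identical
outputs.
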