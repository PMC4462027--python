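# ssrpop

SSR (microsatellite) population genetics and marker–trait association for
inbred crop panels, built around the analysis chain used in grain-trait
association studies of rice (*Oryza sativa*): several hundred pure-line
accessions genotyped at a few hundred multiallelic SSR loci, phenotyped
for grain length, width, thickness and 1,000-grain weight over multiple
years.

The package is for quantitative/population geneticists who want that
whole chain as tested, reusable code rather than a pile of
single-purpose desktop programs:

* **Diversity** — per-locus allele frequencies, Nei gene diversity
  `D = 1 − Σ pᵢ²`, Botstein polymorphism information content
  `PIC = 1 − Σ pᵢ² − Σᵢ<ⱼ 2 pᵢ² pⱼ²`, informativeness classes.
* **Structure** — Nei genetic distance (1972 standard and bounded D_A)
  with a neighbour-joining dendrogram; a multi-restart EM fit of the
  admixture likelihood `P(data) = Πᵢₗ Σₖ q_ik f_kl,a(i,l)` over ancestry
  proportions Q and cluster frequencies F; K selection over a range;
  strict `maxQ > 0.9` non-admixed assignment. STRUCTURE-style Q matrices
  can be imported instead.
* **Differentiation** — Weir–Cockerham θ (haploid-coded inbreds), per
  locus, multi-locus and pairwise; AMOVA on allele-identity distances
  with a permutation test; the standardized individual allele-size
  profile and Welch t trend tests for directional SSR evolution.
* **Linkage disequilibrium** — multiallelic
  `D′ = Σᵢⱼ pᵢ qⱼ |D′ᵢⱼ|` with permutation P per marker pair, the
  intra/inter-chromosomal census, the decay curve `y = b ln x + c`
  fitted by OLS and the decay distance `x* = exp((baseline − c)/b)`.
* **Association** — Loiselle kinship (negatives truncated to zero); the
  Q+K mixed linear model `y = Xβ + u + e`, `Var(u) = σ²_g·2K`,
  `Var(e) = σ²_e·I`, with REML variance components estimated once per
  trait×environment by spectral decomposition and every marker F-tested
  as an allele-class factor (the non-amplified "null allele" is its own
  class); Benjamini–Hochberg FDR; PVE; broad-sense heritability
  `H²_B = σ²_g / (σ²_g + σ²_e/n)` from replicate-level ANOVA.
* **Allele mining** — allele phenotypic effects against the null-allele
  baseline, elite alleles (strictly positive effect), typical carriers,
  and cross-design ranking of parent pairs by (elite-marker coverage,
  expected pyramided effect).
* **Synthetic data** — a Balding–Nichols-style generator reproducing the
  panel's statistical structure (diverged subpopulations, multiallelic
  spectra with rare alleles, null alleles, planted QTLs, polygenic
  background, year effects, replicate error), so every stage is testable
  end to end with no external data.

## Worked example

```python
from ssrpop import synthetic_data as sd, structure, association, \
    differentiation, diversity
from ssrpop.core_data import filter_rare_alleles
from ssrpop.allele_mining import allele_effects, elite_alleles

cfg = sd.SimConfig(n_accessions=150, n_subpops=3, subpop_proportions=None,
                   n_loci=60, divergence_F=0.3, seed=11)
g, marker_map, truth = sd.simulate_genotypes(cfg)
marker, allele = sd.pick_qtl_marker(g)
sd.plant_qtl(truth, g, marker, "GL", 1.45, allele=allele)
phen = sd.simulate_phenotypes(g, truth, cfg, traits=("GL",))

summary = diversity.diversity_summary(diversity.locus_diversity_table(g))
gf, _ = filter_rare_alleles(g)                  # drop alleles at freq <= 5%
qm = structure.admixture_em(gf, K=3, runs=5, seed=11)
assign = structure.assign_subpopulations(qm, threshold=0.9)
fst = differentiation.fst(g, truth.labels, pairwise=False)
kin = association.kinship_matrix(gf)
scan = association.mlm_scan(gf, phen, truth.q, kin,
                            traits=["GL"], environments=["2010"])
top = scan.sort_values("p_value").iloc[0]
best = elite_alleles(allele_effects(g, phen, {"GL": [marker]})).iloc[0]
h2 = association.broad_sense_heritability(phen, "GL", "2010")
```

Output (printed from the objects above):

```
mean gene diversity D = 0.6755, mean PIC = 0.6330
non-admixed accessions (maxQ > 0.9): 145 of 150
multi-locus Weir-Cockerham F_ST = 0.311
top association for GL: SSR0028 (planted QTL: SSR0028), P = 1.67e-10, q = 1.00e-08, PVE = 0.31
largest allelic effect at SSR0028: 266 bp, +1.60 mm over the null-allele baseline (planted +1.45)
broad-sense heritability of GL in 2010: 98.0%
```

Reading: the panel is strongly structured (F_ST ≈ 0.31, nearly all
accessions confidently assigned), the Q+K scan puts the planted
grain-length QTL at the top with a genome-wide significant q value, the
allele's phenotypic effect against the null-allele baseline recovers the
planted +1.45 mm within sampling noise, and replicate-level heritability
is in the high 90s (%) as expected for grain dimensions.

## Command line

The same stages run from a shell, chained or individually, with all
randomness flowing from one seed:

```sh
ssrpop --seed 7 --out-dir run1 pipeline          # simulate → … → mine
ssrpop --config my.yaml --seed 7 --out-dir run2 simulate
```

Each stage writes tab-separated tables (plus a newick tree and a JSON
run manifest) into the output directory; every table starts with a
comment line recording the stage and seed.

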