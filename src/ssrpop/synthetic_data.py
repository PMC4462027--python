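"""Synthetic SSR panel generator.

Emulates the statistical structure of a multi-subpopulation inbred rice
panel: several hundred accessions drawn from diverged subpopulations
(Balding-Nichols frequency model), a few hundred multiallelic SSR loci
scattered over 12 chromosomes, a planted null-allele class, missing
data, designated QTL markers with additive allelic effects, a polygenic
background built from per-allele random effects (hence correlated
through realized kinship), year (environment) effects, and replicate
measurement error.

Defaults mirror a 532-accession, 258-locus, 6-subpopulation panel with
subpopulation divergence around F = 0.3, roughly ten alleles per locus
with a sizeable rare-allele fraction, four yearly environments and two
replicates; trait scales follow typical grain dimensions (GL ~8 mm,
GW ~3.2 mm, GT ~2.2 mm, TGW ~25 g).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ssrpop.core_data import (
    MISSING,
    NULL_ALLELE,
    DataError,
    GenotypeMatrix,
    validate_marker_map,
    validate_phenotypes,
)

#: (trait, grand mean, QTL-free genetic sd) defaults for the four grain traits
TRAIT_MEANS = {"GL": 8.1, "GW": 3.2, "GT": 2.2, "TGW": 24.8}


@dataclass
class QTLSpec:
    """A designated marker with additive allelic effects on one trait.

    ``effects`` maps allele index (0-based within the locus, in allele-size
    order) to an additive effect in trait units; the null allele and any
    allele not listed have effect 0 (the null class is the baseline).
    """

    marker: str
    trait: str
    effects: dict[int, float]


@dataclass
class SimConfig:
    n_accessions: int = 532
    n_subpops: int = 6
    subpop_proportions: tuple[float, ...] | None = (94, 54, 147, 65, 69, 45)
    divergence_F: float = 0.3
    n_loci: int = 258
    # drawn allele classes per locus; set so the *realized* spectrum of a
    # 532-accession draw lands at the observed panel conditions (about
    # 8-10 segregating alleles per locus, gene diversity ~0.73, PIC ~0.70,
    # a bit under 40% rare alleles)
    mean_alleles: float = 12.0
    max_alleles: int = 25
    dirichlet_alpha: float = 0.5
    null_allele_freq: float = 0.03
    missing_rate: float = 0.02
    n_chromosomes: int = 12
    chrom_length_cM: float = 180.0
    qtls: list[QTLSpec] = field(default_factory=list)
    polygenic_sd: dict[str, float] | None = None  # trait -> genetic sd
    year_effect_sd: float = 0.02  # as a fraction of the trait mean
    replicate_error_sd: dict[str, float] | None = None  # trait -> error sd
    environments: tuple[str, ...] = ("2010", "2011", "2012", "2013")
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.divergence_F < 1.0:
            raise DataError("divergence_F must lie in (0, 1)")
        for name in ("null_allele_freq", "missing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise DataError(f"{name} must lie in [0, 1]")
        if self.mean_alleles < 2:
            raise DataError("mean_alleles must be >= 2")
        if self.polygenic_sd is None:
            # default: trait sd at roughly the panel-level spread seen in
            # grain-trait panels (~12% of the mean), before QTL effects
            self.polygenic_sd = {t: 0.12 * m for t, m in TRAIT_MEANS.items()}
        if self.replicate_error_sd is None:
            # small plot-to-plot error -> broad-sense heritability in the
            # mid-90s (%) at two replicates
            self.replicate_error_sd = {t: 0.025 * m for t, m in TRAIT_MEANS.items()}


@dataclass
class SimTruth:
    labels: pd.Series  # accession -> POP<k>
    q: pd.DataFrame  # one-hot ancestry
    subpop_freqs: list[np.ndarray]  # per locus (n_subpops, n_alleles+null)
    allele_sizes: list[np.ndarray]  # per locus, sizes of the non-null classes
    qtl_effects: pd.DataFrame  # trait, marker, allele (bp), effect
    genetic_values: pd.DataFrame | None = None  # accession x trait


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Draw genotypes, a marker map and the generating truth.

    Ancestral frequencies per locus come from a symmetric Dirichlet;
    subpopulation frequencies from a Dirichlet centred on the ancestral
    vector with concentration (1 - F)/F (Balding-Nichols); each inbred
    accession draws a single allele per locus from its subpopulation.
    A dedicated null-allele class and missing cells are injected at the
    configured rates.
    """
    rng = np.random.default_rng(cfg.seed)
    n, L = cfg.n_accessions, cfg.n_loci
    props = np.asarray(
        cfg.subpop_proportions
        if cfg.subpop_proportions is not None
        else np.ones(cfg.n_subpops),
        dtype=float,
    )
    if props.size != cfg.n_subpops:
        raise DataError("subpop_proportions length must equal n_subpops")
    props = props / props.sum()
    labels_idx = rng.choice(cfg.n_subpops, size=n, p=props)
    accessions = [f"ACC{i + 1:04d}" for i in range(n)]
    loci = [f"SSR{j + 1:04d}" for j in range(L)]

    calls = np.empty((n, L), dtype=np.int64)
    subpop_freqs = []
    allele_sizes = []
    conc = (1.0 - cfg.divergence_F) / cfg.divergence_F
    for j in range(L):
        A = int(np.clip(rng.poisson(cfg.mean_alleles - 2) + 2, 2, cfg.max_alleles))
        anc = rng.dirichlet(np.full(A, cfg.dirichlet_alpha))
        # append the null class at its configured frequency
        anc = np.concatenate([anc * (1.0 - cfg.null_allele_freq),
                              [cfg.null_allele_freq]])
        pf = np.vstack([
            rng.dirichlet(np.maximum(anc * conc, 1e-6))
            for _ in range(cfg.n_subpops)
        ])
        subpop_freqs.append(pf)
        motif = int(rng.integers(2, 6))
        base = int(rng.integers(80, 300))
        sizes = base + motif * np.arange(A)
        allele_sizes.append(sizes)
        draws = np.array([
            rng.choice(A + 1, p=pf[k]) for k in labels_idx
        ])
        col = np.where(draws == A, NULL_ALLELE, sizes[np.minimum(draws, A - 1)])
        calls[:, j] = col
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING

    chroms = rng.integers(1, cfg.n_chromosomes + 1, size=L)
    positions = rng.uniform(0.0, cfg.chrom_length_cM, size=L)
    marker_map = validate_marker_map(pd.DataFrame({
        "marker": loci, "chromosome": chroms, "position_cM": positions,
    }))

    labels = pd.Series([f"POP{k + 1}" for k in labels_idx], index=accessions,
                       name="subpopulation")
    q = pd.DataFrame(np.eye(cfg.n_subpops)[labels_idx], index=accessions,
                     columns=[f"q{k + 1}" for k in range(cfg.n_subpops)])
    qtl_rows = []
    for spec in cfg.qtls:
        if spec.marker not in loci:
            raise DataError(f"QTL marker {spec.marker!r} not simulated")
        sizes = allele_sizes[loci.index(spec.marker)]
        for ai, eff in spec.effects.items():
            if ai >= len(sizes):
                raise DataError(
                    f"QTL allele index {ai} out of range at {spec.marker!r} "
                    f"({len(sizes)} alleles)"
                )
            qtl_rows.append({"trait": spec.trait, "marker": spec.marker,
                             "allele": int(sizes[ai]), "effect": float(eff)})
    truth = SimTruth(
        labels=labels, q=q, subpop_freqs=subpop_freqs,
        allele_sizes=allele_sizes,
        qtl_effects=pd.DataFrame(qtl_rows,
                                 columns=["trait", "marker", "allele", "effect"]),
    )
    return GenotypeMatrix(accessions, loci, calls), marker_map, truth


def simulate_phenotypes(
    g: GenotypeMatrix, truth: SimTruth, cfg: SimConfig,
    traits: tuple[str, ...] = ("GL", "GW", "GT", "TGW"),
) -> pd.DataFrame:
    """Phenotype table: grand mean + QTL allelic effects + polygenic value
    + year effect + replicate noise, per accession x environment x replicate.

    The polygenic value of an accession is the sum over loci of small
    per-allele random effects, so its covariance across accessions tracks
    realized allele sharing (kinship).  Truth genetic values are stored on
    ``truth.genetic_values`` for recovery tests.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = g.n_accessions
    effect_lookup: dict[str, dict[tuple[str, int], float]] = {}
    for _, row in truth.qtl_effects.iterrows():
        effect_lookup.setdefault(row["trait"], {})[
            (row["marker"], int(row["allele"]))
        ] = float(row["effect"])

    genetic = {}
    for trait in traits:
        base = np.full(n, TRAIT_MEANS.get(trait, 10.0))
        # polygenic: per-allele effects spread over all loci
        sd = cfg.polygenic_sd[trait]
        poly = np.zeros(n)
        per_locus_sd = sd / np.sqrt(max(g.n_loci, 1))
        for j in range(g.n_loci):
            col = g.calls[:, j]
            alleles = np.unique(col[col > 0])
            if alleles.size < 2:
                continue
            effs = rng.normal(0.0, per_locus_sd, size=alleles.size)
            lut = dict(zip(alleles, effs))
            poly += np.array([lut.get(a, 0.0) for a in col])
        qtl = np.zeros(n)
        for (marker, allele), eff in effect_lookup.get(trait, {}).items():
            col = g.locus_calls(marker)
            qtl += np.where(col == allele, eff, 0.0)
        genetic[trait] = base + poly + qtl
    truth.genetic_values = pd.DataFrame(genetic, index=g.accessions)

    rows = []
    for trait in traits:
        err_sd = cfg.replicate_error_sd[trait]
        for env in cfg.environments:
            year = rng.normal(0.0, cfg.year_effect_sd * TRAIT_MEANS.get(trait, 10.0))
            for rep in range(1, cfg.n_replicates + 1):
                noise = rng.normal(0.0, err_sd, size=n)
                vals = genetic[trait] + year + noise
                vals = np.maximum(vals, 1e-3)  # traits are physical sizes > 0
                for acc, v in zip(g.accessions, vals):
                    rows.append({"accession": acc, "environment": env,
                                 "replicate": rep, "trait": trait,
                                 "value": float(v)})
    return validate_phenotypes(pd.DataFrame(rows))


def default_qtls(loci: list[str]) -> list[QTLSpec]:
    """A small default QTL panel: one major and one minor locus per trait,
    with effect sizes on the scale reported for grain-trait SSR panels
    (e.g. a ~1.4 mm grain-length effect at the strongest locus).  Effects
    sit on the first two allele classes, which every locus has."""
    picks = {
        "GL": [(10, {0: 1.45, 1: 0.5}), (40, {1: 0.3})],
        "GW": [(70, {0: 0.35}), (100, {1: 0.15})],
        "GT": [(130, {0: 0.14})],
        "TGW": [(160, {0: 0.67}), (200, {1: 0.3})],
    }
    out = []
    for trait, specs in picks.items():
        for pos, effects in specs:
            if pos < len(loci):
                out.append(QTLSpec(marker=loci[pos], trait=trait, effects=effects))
    return out


def pick_qtl_marker(g: GenotypeMatrix) -> tuple[str, int]:
    """Choose the (marker, allele bp) whose allele frequency is closest
    to 1/2 panel-wide: the locus with the most segregating variance,
    guaranteed to survive rare-allele filtering."""
    best = None
    for j, marker in enumerate(g.loci):
        col = g.calls[:, j]
        scored = col[col > 0]
        if scored.size == 0:
            continue
        alleles, counts = np.unique(scored, return_counts=True)
        freqs = counts / scored.size
        i = int(np.argmin(np.abs(freqs - 0.5)))
        gap = abs(freqs[i] - 0.5)
        if best is None or gap < best[0]:
            best = (gap, marker, int(alleles[i]))
    if best is None:
        raise DataError("no scored loci to place a QTL on")
    return best[1], best[2]


def plant_qtl(
    truth: SimTruth,
    g: GenotypeMatrix,
    marker: str,
    trait: str,
    effect: float,
    allele: int | None = None,
    policy: str = "common",
) -> int:
    """Register a QTL effect on a realized allele after genotype simulation.

    When ``allele`` (bp) is omitted it is chosen by ``policy``: the most
    common scored allele (``"common"``, guaranteeing a well-populated
    carrier class) or the allele with frequency closest to 1/2
    (``"balanced"``, maximizing segregating variance -- the standard
    condition for power studies).  Must be called before
    :func:`simulate_phenotypes`.  Returns the allele size.
    """
    col = g.locus_calls(marker)
    scored = col[col > 0]
    if scored.size == 0:
        raise DataError(f"marker {marker!r} has no scored calls")
    if allele is None:
        alleles, counts = np.unique(scored, return_counts=True)
        freqs = counts / scored.size
        if policy == "balanced":
            allele = int(alleles[np.argmin(np.abs(freqs - 0.5))])
        elif policy == "common":
            allele = int(alleles[np.argmax(counts)])
        else:
            raise DataError(f"unknown allele policy {policy!r}")
    row = pd.DataFrame([
        {"trait": trait, "marker": marker, "allele": int(allele),
         "effect": float(effect)}
    ])
    if truth.qtl_effects.empty:
        truth.qtl_effects = row
    else:
        truth.qtl_effects = pd.concat([truth.qtl_effects, row], ignore_index=True)
    return int(allele)
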