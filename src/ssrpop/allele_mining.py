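"""Elite-allele mining and optimal cross design.

At each trait-associated marker the phenotypic effect of allele i is the
mean trait value of its carriers minus the mean of the null-allele
(non-amplified) carriers at the same marker -- the null class is the
natural baseline because it carries no amplified product.  Alleles with
strictly positive effects are elite; the typical carrier of an elite
allele is its phenotypically most extreme carrier.  Cross design ranks
parent pairs lexicographically by (number of associated markers covered
by at least one elite allele, sum of the best per-marker effects), the
two criteria breeders state for pyramiding.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ssrpop.core_data import (
    MISSING,
    NULL_ALLELE,
    DataError,
    GenotypeMatrix,
    accession_means,
)

logger = logging.getLogger(__name__)


def allele_effects(
    g: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    markers_by_trait: dict[str, list[str]],
    environment: str | None = None,
) -> pd.DataFrame:
    """Phenotypic effect of every allele at the significant markers.

    The phenotype is the per-accession mean over replicates and (by
    default) environments.  Effect ``a_i`` = mean phenotype of allele-i
    carriers minus the null-allele carriers' mean; when a marker has no
    phenotyped null carriers the locus-wide carrier mean is the baseline
    instead (logged).  Alleles with no phenotyped carriers are omitted.
    """
    rows = []
    for trait, markers in markers_by_trait.items():
        y = accession_means(phenotypes, trait, environment)
        for marker in markers:
            if marker not in g.loci:
                raise DataError(f"marker {marker!r} absent from genotypes")
            calls = pd.Series(g.locus_calls(marker), index=g.accessions)
            calls = calls[calls.index.isin(y.index)]
            calls = calls[calls != MISSING]
            null_carriers = calls.index[calls == NULL_ALLELE]
            if len(null_carriers) > 0:
                baseline = float(y.loc[null_carriers].mean())
                baseline_kind = "null_allele"
            else:
                baseline = float(y.loc[calls.index].mean())
                baseline_kind = "locus_mean"
                logger.info("marker %s has no phenotyped null carriers; "
                            "locus-wide mean used as baseline", marker)
            for allele in sorted(set(calls.unique()) - {NULL_ALLELE}):
                carriers = calls.index[calls == allele]
                if len(carriers) == 0:
                    logger.info("allele %s-%d has no phenotyped carriers; omitted",
                                marker, allele)
                    continue
                vals = y.loc[carriers]
                rows.append({
                    "trait": trait, "marker": marker, "allele": int(allele),
                    "effect": float(vals.mean() - baseline),
                    "carriers": int(len(carriers)),
                    "baseline": baseline_kind,
                })
    return pd.DataFrame(
        rows, columns=["trait", "marker", "allele", "effect", "carriers", "baseline"]
    )


def elite_alleles(effects: pd.DataFrame) -> pd.DataFrame:
    """Alleles with strictly positive effect, sorted by effect descending."""
    out = effects[effects["effect"] > 0].copy()
    return out.sort_values(["trait", "effect"], ascending=[True, False]).reset_index(drop=True)


def typical_carriers(
    elites: pd.DataFrame,
    g: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    environment: str | None = None,
) -> pd.DataFrame:
    """Attach each elite allele's typical carrier: the carrier with the
    most extreme trait value in the effect's direction (ties break to the
    lexicographically smaller accession id)."""
    out = elites.copy()
    carriers_col = []
    for _, row in out.iterrows():
        y = accession_means(phenotypes, row["trait"], environment)
        calls = pd.Series(g.locus_calls(row["marker"]), index=g.accessions)
        carriers = [a for a in calls.index[calls == row["allele"]] if a in y.index]
        if not carriers:
            carriers_col.append(None)
            continue
        vals = y.loc[carriers]
        best = vals.max() if row["effect"] >= 0 else vals.min()
        winner = sorted(vals.index[vals == best])[0]
        carriers_col.append(winner)
    out["typical_carrier"] = carriers_col
    return out


@dataclass
class CrossPlan:
    trait: str
    parent1: str
    parent2: str
    coverage: int  # markers covered by >= 1 elite allele
    n_elite: int  # distinct elite alleles in the union
    expected_sum: float  # sum of best per-marker effects
    alleles: list[tuple[str, int]] = field(default_factory=list)
    rank: int = 0


def design_crosses(
    elites: pd.DataFrame,
    g: GenotypeMatrix,
    trait: str,
    top_n: int = 5,
) -> list[CrossPlan]:
    """Rank unordered parent pairs for pyramiding a trait's elite alleles.

    Each parent carries at most one allele per marker; both parents'
    elite alleles at a marker are substitutable alternatives, so a marker
    counts once toward coverage and contributes its best carried effect
    to the expected sum.  Pairs are ranked by (coverage, expected sum)
    descending with accession-id tie-breaks, making the output invariant
    to input ordering.
    """
    sub = elites[elites["trait"] == trait]
    if sub.empty:
        return []
    effect_of = {(r["marker"], r["allele"]): r["effect"] for _, r in sub.iterrows()}
    markers = sorted(sub["marker"].unique())
    # per accession: {marker: (allele, effect)} for carried elite alleles
    carried: dict[str, dict[str, tuple[int, float]]] = {}
    for marker in markers:
        calls = pd.Series(g.locus_calls(marker), index=g.accessions)
        for acc, allele in calls.items():
            eff = effect_of.get((marker, allele))
            if eff is not None:
                carried.setdefault(acc, {})[marker] = (int(allele), eff)
    parents = sorted(carried)
    if len(parents) < 2:
        logger.info("fewer than 2 elite-allele carriers for %s; no crosses", trait)
        return []
    plans = []
    for p1, p2 in itertools.combinations(parents, 2):
        union: dict[tuple[str, int], float] = {}
        best_per_marker: dict[str, float] = {}
        for parent in (p1, p2):
            for marker, (allele, eff) in carried[parent].items():
                union[(marker, allele)] = eff
                if marker not in best_per_marker or eff > best_per_marker[marker]:
                    best_per_marker[marker] = eff
        plans.append(CrossPlan(
            trait=trait, parent1=p1, parent2=p2,
            coverage=len(best_per_marker),
            n_elite=len(union),
            expected_sum=float(sum(best_per_marker.values())),
            alleles=sorted(union),
        ))
    plans.sort(key=lambda c: (-c.coverage, -c.expected_sum, c.parent1, c.parent2))
    for i, plan in enumerate(plans[:top_n], start=1):
        plan.rank = i
    return plans[:top_n]


def cross_plan_table(plans: list[CrossPlan]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "trait": p.trait, "rank": p.rank,
            "parent1": p.parent1, "parent2": p.parent2,
            "coverage": p.coverage, "n_elite": p.n_elite,
            "expected_sum": p.expected_sum,
            "alleles": ";".join(f"{m}-{a}" for m, a in p.alleles),
        }
        for p in plans
    ])
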