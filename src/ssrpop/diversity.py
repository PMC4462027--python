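"""Per-locus allele frequencies, Nei gene diversity and PIC.

Gene diversity (expected heterozygosity) at a locus with allele
frequencies p_i is ``D = 1 - sum(p_i^2)``.  Polymorphism information
content follows Botstein:

    PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2

Both are computed from scored calls only; null-allele and missing cells
never enter the denominators.  No small-sample (n/(n-1)) correction is
applied by default, matching the plain plug-in estimators standard SSR
software reports; pass ``unbiased=True`` for the corrected variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ssrpop.core_data import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class AlleleFrequencies:
    """Allele frequency spectra per locus, over scored calls only."""

    freqs: dict[str, pd.Series]  # locus -> Series(allele -> frequency)
    n_scored: dict[str, int]  # locus -> number of scored calls


def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencies:
    """Per-locus allele frequencies over non-missing, non-null calls.

    Loci with zero scored calls are excluded with a warning.
    """
    freqs: dict[str, pd.Series] = {}
    n_scored: dict[str, int] = {}
    for j, locus in enumerate(g.loci):
        col = g.calls[:, j]
        scored = col[col > 0]
        if scored.size == 0:
            logger.warning("locus %s has no scored calls; excluded", locus)
            continue
        alleles, counts = np.unique(scored, return_counts=True)
        freqs[locus] = pd.Series(counts / scored.size, index=alleles, dtype=float)
        n_scored[locus] = int(scored.size)
    return AlleleFrequencies(freqs=freqs, n_scored=n_scored)


def gene_diversity(p: np.ndarray | pd.Series, unbiased: bool = False, n: int | None = None) -> float:
    """Nei gene diversity ``1 - sum(p^2)`` for one locus."""
    p = np.asarray(p, dtype=float)
    d = 1.0 - float(np.sum(p**2))
    if unbiased:
        if n is None or n < 2:
            raise ValueError("unbiased estimator needs the sample size n >= 2")
        d *= n / (n - 1)
    return d


def pic(p: np.ndarray | pd.Series) -> float:
    """Botstein polymorphism information content for one locus."""
    p = np.asarray(p, dtype=float)
    sq = p**2
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    cross = float(np.sum(sq)) ** 2 - float(np.sum(sq**2))
    return 1.0 - float(np.sum(sq)) - cross


def locus_diversity_table(
    g: GenotypeMatrix,
    rare_threshold: float = 0.05,
    marker_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-locus summary: allele count, gene diversity, PIC, rare-allele
    count at the given frequency rule (alleles at frequency < threshold).

    Mirrors the usual per-marker supplementary table: locus, chromosome,
    alleles, diversity, PIC.
    """
    af = allele_frequencies(g)
    rows = []
    for locus, p in af.freqs.items():
        rows.append(
            {
                "locus": locus,
                "alleles": int(p.size),
                "diversity": gene_diversity(p),
                "PIC": pic(p),
                "rare_alleles": int((p < rare_threshold).sum()),
                "n_scored": af.n_scored[locus],
            }
        )
    df = pd.DataFrame(rows)
    if marker_map is not None:
        df = df.merge(
            marker_map[["marker", "chromosome", "position_cM"]],
            left_on="locus", right_on="marker", how="left",
        ).drop(columns="marker")
    return df


def diversity_summary(table: pd.DataFrame) -> dict:
    """Panel-level informativeness summary.

    Markers are classed as highly (PIC > 0.5), moderately
    (0.25 < PIC <= 0.5) or slightly (PIC <= 0.25) informative; ties at a
    boundary fall to the lower class.  Percentages are of all loci.
    """
    if table.empty:
        raise ValueError("diversity table is empty")
    n = len(table)
    high = int((table["PIC"] > 0.5).sum())
    moderate = int(((table["PIC"] > 0.25) & (table["PIC"] <= 0.5)).sum())
    slight = n - high - moderate
    total_alleles = int(table["alleles"].sum())
    rare = int(table["rare_alleles"].sum())
    return {
        "n_loci": n,
        "total_alleles": total_alleles,
        "mean_alleles_per_locus": total_alleles / n,
        "mean_diversity": float(table["diversity"].mean()),
        "mean_PIC": float(table["PIC"].mean()),
        "n_high_PIC": high,
        "n_moderate_PIC": moderate,
        "n_slight_PIC": slight,
        "pct_high_PIC": 100.0 * high / n,
        "pct_moderate_PIC": 100.0 * moderate / n,
        "pct_slight_PIC": 100.0 * slight / n,
        "rare_allele_count": rare,
        "rare_allele_proportion": rare / total_alleles,
    }
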