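"""Multiallelic linkage disequilibrium (D') and its decay with map distance.

Inbred accessions are treated as phased haploids, so two-locus haplotype
frequencies are read directly off the genotype matrix.  For loci with
alleles i and j at frequencies p_i, q_j and haplotype frequency x_ij,

    D_ij   = x_ij - p_i q_j
    D'_ij  = D_ij / D_max,ij
    D'     = sum_ij p_i q_j |D'_ij|        (Hedrick's multiallelic D')

with D_max,ij the usual bound min(p_i q_j, (1-p_i)(1-q_j)) for negative
D_ij and min(p_i (1-q_j), (1-p_i) q_j) for positive.  Significance per
pair comes from permuting one locus's calls across accessions.  Decay
along a chromosome is summarized by ordinary least squares of D' on
ln(distance in cM), y = b ln x + c, and the decay distance is where the
fitted curve falls to a background baseline: x* = exp((baseline - c)/b).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ssrpop.core_data import DataError, GenotypeMatrix

logger = logging.getLogger(__name__)


def dprime_from_counts(joint: np.ndarray) -> float:
    """Multiallelic D' from a 2-D table of joint haplotype counts."""
    joint = np.asarray(joint, dtype=float)
    n = joint.sum()
    if n < 2:
        raise DataError("need at least 2 haplotypes")
    x = joint / n
    p = x.sum(axis=1)
    q = x.sum(axis=0)
    dp = 0.0
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            if p[i] == 0 or q[j] == 0:
                continue
            d = x[i, j] - p[i] * q[j]
            if d < 0:
                dmax = min(p[i] * q[j], (1 - p[i]) * (1 - q[j]))
            else:
                dmax = min(p[i] * (1 - q[j]), (1 - p[i]) * q[j])
            if dmax <= 0:
                continue
            dp += p[i] * q[j] * abs(d) / dmax
    return float(min(dp, 1.0))


def _joint_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    joint = np.zeros((ua.size, ub.size))
    np.add.at(joint, (ia, ib), 1.0)
    return joint


def dprime(g: GenotypeMatrix, locus1: str, locus2: str) -> float:
    """Multiallelic D' between two loci over shared scored accessions."""
    a = g.locus_calls(locus1)
    b = g.locus_calls(locus2)
    ok = (a > 0) & (b > 0)
    if ok.sum() < 2:
        raise DataError(
            f"fewer than 2 shared scored accessions for {locus1}/{locus2}"
        )
    return dprime_from_counts(_joint_counts(a[ok], b[ok]))


@dataclass
class LDCensus:
    total_pairs: int
    tested_pairs: int
    significant_pairs: int
    significant_intra: int

    @property
    def intra_share_of_significant(self) -> float:
        if self.significant_pairs == 0:
            return float("nan")
        return self.significant_intra / self.significant_pairs


def marker_pairs(loci: list[str]) -> list[tuple[str, str]]:
    """All unordered marker pairs (C(n, 2) of them)."""
    return list(itertools.combinations(loci, 2))


def ld_scan(
    g: GenotypeMatrix,
    marker_map: pd.DataFrame | None = None,
    permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, LDCensus]:
    """D' and permutation P for every unordered marker pair.

    The permutation null shuffles one locus's calls across accessions;
    P = (1 + #{D'_perm >= D'_obs}) / (1 + permutations).  The census
    reports total pairs, significant pairs at ``alpha`` and how many of
    the significant pairs are intrachromosomal.  Genetic distance (cM)
    is attached for syntenic pairs when a map is given.
    """
    if permutations < 100:
        logger.warning("only %d permutations; P resolution is coarse", permutations)
    pos = {}
    chrom = {}
    if marker_map is not None:
        for _, row in marker_map.iterrows():
            pos[row["marker"]] = float(row["position_cM"])
            chrom[row["marker"]] = int(row["chromosome"])
    rng = np.random.default_rng(seed)
    rows = []
    for l1, l2 in marker_pairs(g.loci):
        a = g.locus_calls(l1)
        b = g.locus_calls(l2)
        ok = (a > 0) & (b > 0)
        same_chr = chrom.get(l1) is not None and chrom.get(l1) == chrom.get(l2)
        dist = abs(pos[l1] - pos[l2]) if same_chr else np.nan
        if ok.sum() < 2:
            logger.info("pair %s/%s skipped (<2 shared scored accessions)", l1, l2)
            rows.append({"marker1": l1, "marker2": l2, "same_chromosome": same_chr,
                         "distance_cM": dist, "Dprime": np.nan, "p_value": np.nan})
            continue
        av, bv = a[ok], b[ok]
        obs = dprime_from_counts(_joint_counts(av, bv))
        hits = 0
        for _ in range(permutations):
            perm = rng.permutation(bv)
            if dprime_from_counts(_joint_counts(av, perm)) >= obs - 1e-12:
                hits += 1
        p = (hits + 1) / (permutations + 1)
        rows.append({"marker1": l1, "marker2": l2, "same_chromosome": same_chr,
                     "distance_cM": dist, "Dprime": obs, "p_value": p})
    table = pd.DataFrame(rows)
    tested = table["Dprime"].notna()
    sig = tested & (table["p_value"] < alpha)
    census = LDCensus(
        total_pairs=len(table),
        tested_pairs=int(tested.sum()),
        significant_pairs=int(sig.sum()),
        significant_intra=int((sig & table["same_chromosome"]).sum()),
    )
    return table, census


@dataclass
class DecayFit:
    b: float
    c: float
    r_squared: float
    n_pairs: int
    baseline: float | None = None
    decay_distance_cM: float | None = None
    status: str = "ok"


def fit_decay(pairs: pd.DataFrame) -> DecayFit:
    """OLS fit of D' on ln(distance) over syntenic pairs: y = b ln x + c.

    Pairs at distance 0 are excluded (ln undefined); needs >= 3 pairs with
    distinct positive distances.
    """
    sub = pairs.dropna(subset=["Dprime", "distance_cM"])
    sub = sub[sub["distance_cM"] > 0]
    dropped = len(pairs) - len(sub)
    if dropped:
        logger.info("%d pair(s) excluded from decay fit (distance 0 or missing)",
                    dropped)
    if len(sub) < 3 or sub["distance_cM"].nunique() < 2:
        raise DataError("decay fit needs >= 3 syntenic pairs with distinct distances")
    x = np.log(sub["distance_cM"].to_numpy(dtype=float))
    y = sub["Dprime"].to_numpy(dtype=float)
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    b, c = float(coef[0]), float(coef[1])
    resid = y - (b * x + c)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DecayFit(b=b, c=c, r_squared=r2, n_pairs=len(sub))


def decay_distance(fit: DecayFit, baseline: float) -> DecayFit:
    """Solve b ln x + c = baseline for the decay distance x* (cM).

    Defined only for a decaying curve (b < 0) that starts above the
    baseline (c > baseline); otherwise the fit is returned with an
    explanatory status and no distance.
    """
    out = DecayFit(**{**fit.__dict__})
    out.baseline = baseline
    if fit.b >= 0:
        out.status = "undefined: non-negative slope"
        return out
    if baseline > fit.c:
        out.status = "undefined: baseline above intercept"
        return out
    out.decay_distance_cM = float(np.exp((baseline - fit.c) / fit.b))
    out.status = "ok"
    return out


def background_baseline(pairs: pd.DataFrame, quantile: float = 0.95) -> float:
    """Background D' level: the given quantile of interchromosomal D'."""
    inter = pairs.loc[~pairs["same_chromosome"].astype(bool), "Dprime"].dropna()
    if inter.empty:
        raise DataError("no interchromosomal pairs to set a baseline")
    return float(np.quantile(inter.to_numpy(), quantile))
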