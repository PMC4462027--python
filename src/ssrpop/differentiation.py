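"""Genetic differentiation among subpopulations.

F_ST uses the Weir-Cockerham variance-component estimator adapted to
haploid-coded inbred lines: at each locus and allele the indicator
variable is partitioned by one-way ANOVA into among- and
within-subpopulation components, and theta is the ratio of summed
components (summing over alleles for a per-locus estimate and over loci
for the multi-locus estimate).  AMOVA partitions allele-identity
(0/1 mismatch) distances among vs within subpopulations with a
label-permutation test, and the allele-size module implements the
standardized individual allele-size comparison used to test directional
SSR evolution across geographic groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ssrpop.core_data import DataError, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST (haploid coding)
# ---------------------------------------------------------------------------

@dataclass
class DifferentiationResult:
    per_locus: pd.DataFrame  # locus, theta (raw), theta_clamped
    multi_locus: float  # ratio-of-sums estimate, raw
    pairwise: pd.DataFrame  # symmetric subpop x subpop matrix (clamped)

    @property
    def multi_locus_clamped(self) -> float:
        return float(np.clip(self.multi_locus, 0.0, 1.0))


def _locus_components(col: np.ndarray, groups: list[np.ndarray]) -> tuple[float, float]:
    """Among/within variance components at one locus, summed over alleles.

    ``groups`` are index arrays per subpopulation; only scored calls are
    used and subpopulations with fewer than two scored calls are excluded
    for this locus.
    """
    samples = []
    for idx in groups:
        vals = col[idx]
        vals = vals[vals > 0]
        if vals.size >= 2:
            samples.append(vals)
    r = len(samples)
    if r < 2:
        return np.nan, np.nan
    sizes = np.array([s.size for s in samples], dtype=float)
    N = sizes.sum()
    nc = (N - (sizes**2).sum() / N) / (r - 1)
    alleles = np.unique(np.concatenate(samples))
    sig_a = sig_w = 0.0
    for a in alleles:
        p_i = np.array([(s == a).mean() for s in samples])
        p_bar = float((sizes * p_i).sum() / N)
        msa = float((sizes * (p_i - p_bar) ** 2).sum()) / (r - 1)
        msw = float((sizes * p_i * (1.0 - p_i)).sum()) / (N - r)
        sig_a += (msa - msw) / nc
        sig_w += msw
    return sig_a, sig_w


def fst(
    g: GenotypeMatrix, assignment: pd.Series, pairwise: bool = True
) -> DifferentiationResult:
    """Weir-Cockerham theta per locus, multi-locus (ratio of summed
    components) and pairwise between subpopulations.

    ``assignment`` maps accession id -> subpopulation label; accessions
    labelled admixed (or absent) are excluded.  Reported per-locus and
    pairwise estimates are clamped to [0, 1]; the raw ratio is retained.
    """
    assignment = assignment.reindex(g.accessions)
    pops = sorted(p for p in assignment.dropna().unique() if p != "ADMIXED")
    if len(pops) < 2:
        raise DataError("need at least 2 subpopulations")
    groups = {p: np.flatnonzero((assignment == p).to_numpy()) for p in pops}

    def _scan(pop_subset: list[str]) -> tuple[pd.DataFrame, float]:
        rows = []
        tot_a = tot_aw = 0.0
        for j, locus in enumerate(g.loci):
            sa, sw = _locus_components(g.calls[:, j], [groups[p] for p in pop_subset])
            if np.isnan(sa):
                logger.debug("locus %s skipped (insufficient calls)", locus)
                continue
            denom = sa + sw
            theta = sa / denom if denom > 0 else 0.0
            rows.append({"locus": locus, "theta_raw": theta,
                         "theta": float(np.clip(theta, 0.0, 1.0))})
            tot_a += sa
            tot_aw += denom
        multi = tot_a / tot_aw if tot_aw > 0 else 0.0
        return pd.DataFrame(rows), multi

    per_locus, multi = _scan(pops)
    pw = pd.DataFrame(np.nan, index=pops, columns=pops)
    if pairwise:
        for i, p1 in enumerate(pops):
            for p2 in pops[i + 1:]:
                _, m = _scan([p1, p2])
                v = float(np.clip(m, 0.0, 1.0))
                pw.loc[p1, p2] = pw.loc[p2, p1] = v
    return DifferentiationResult(per_locus=per_locus, multi_locus=multi, pairwise=pw)


def pairwise_mean(pairwise: pd.DataFrame) -> float:
    """Mean of the off-diagonal pairwise F_ST values (each pair once)."""
    vals = pairwise.to_numpy(dtype=float)
    iu = np.triu_indices_from(vals, k=1)
    v = vals[iu]
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise DataError("pairwise matrix holds no values")
    return float(v.mean())


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    sigma_among: float
    sigma_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float
    permutations: int


def _mismatch_sq(g: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    """Squared distance = count of shared scored loci with different alleles."""
    calls = g.calls[idx]
    n = calls.shape[0]
    d2 = np.zeros((n, n))
    for j in range(calls.shape[1]):
        col = calls[:, j]
        ok = col > 0
        both = np.outer(ok, ok)
        diff = col[:, None] != col[None, :]
        d2 += both & diff
    return d2


def _amova_components(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    N = d2.shape[0]
    groups = [np.flatnonzero(labels == p) for p in np.unique(labels)]
    r = len(groups)
    ss_total = d2[np.triu_indices(N, k=1)].sum() / N
    ss_within = 0.0
    for idx in groups:
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among = r - 1
    df_within = N - r
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    sizes = np.array([len(i) for i in groups], dtype=float)
    n0 = (N - (sizes**2).sum() / N) / df_among
    sigma_within = ms_within
    sigma_among = (ms_among - ms_within) / n0
    denom = sigma_among + sigma_within
    phi = sigma_among / denom if denom > 0 else 0.0
    return sigma_among, sigma_within, phi


def amova(
    g: GenotypeMatrix,
    assignment: pd.Series,
    permutations: int = 1000,
    seed: int = 0,
) -> AmovaResult:
    """Two-level AMOVA (among vs within subpopulations).

    Distances are allele-identity mismatch counts over shared scored loci.
    Significance of the among-subpopulation component comes from permuting
    accession labels; P is the fraction of permuted phi_ST >= observed
    (with the +1 correction).
    """
    if permutations < 1:
        raise DataError("permutations must be >= 1")
    assignment = assignment.reindex(g.accessions)
    keep = assignment.notna() & (assignment != "ADMIXED")
    idx = np.flatnonzero(keep.to_numpy())
    labels = assignment.to_numpy()[idx]
    if len(np.unique(labels)) < 2:
        raise DataError("need at least 2 subpopulations")
    d2 = _mismatch_sq(g, idx)
    sa, sw, phi = _amova_components(d2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(labels)
        _, _, phi_p = _amova_components(d2, perm)
        if phi_p >= phi - 1e-12:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    sa_rep = max(sa, 0.0)
    total = sa_rep + sw
    pct_among = 100.0 * sa_rep / total if total > 0 else 0.0
    return AmovaResult(
        sigma_among=sa, sigma_within=sw,
        pct_among=pct_among, pct_within=100.0 - pct_among,
        phi_st=phi, p_value=p, permutations=permutations,
    )


# ---------------------------------------------------------------------------
# Standardized individual allele size and the directional trend test
# ---------------------------------------------------------------------------

@dataclass
class AlleleSizeProfile:
    scores: pd.Series  # accession -> mean standardized allele size
    by_subpop: pd.DataFrame  # subpopulation, mean, se, n


def standardized_allele_size(
    g: GenotypeMatrix, assignment: pd.Series | None = None
) -> AlleleSizeProfile:
    """Mean standardized (z-scored) allele size per accession.

    Each locus's allele sizes are z-scored over scored accessions;
    monomorphic / zero-variance loci contribute nothing.  An accession's
    score is the mean z over its contributing loci; subpopulation
    summaries (mean, standard error, n) are attached when an assignment
    is given.
    """
    n = g.n_accessions
    zsum = np.zeros(n)
    zcnt = np.zeros(n)
    for j in range(g.n_loci):
        col = g.calls[:, j].astype(float)
        ok = col > 0
        vals = col[ok]
        if vals.size < 2 or np.ptp(vals) == 0:
            logger.debug("locus %s monomorphic/zero variance; excluded", g.loci[j])
            continue
        mu = vals.mean()
        sd = vals.std(ddof=0)
        z = (col - mu) / sd
        zsum[ok] += z[ok]
        zcnt[ok] += 1
    has = zcnt > 0
    if not has.all():
        logger.warning("%d accession(s) with no contributing loci excluded",
                       int((~has).sum()))
    scores = pd.Series(zsum[has] / zcnt[has],
                       index=[a for a, h in zip(g.accessions, has) if h],
                       name="std_allele_size")
    rows = []
    if assignment is not None:
        assignment = assignment.reindex(scores.index)
        for pop in sorted(p for p in assignment.dropna().unique() if p != "ADMIXED"):
            vals = scores[assignment == pop]
            rows.append({
                "subpopulation": pop,
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
                "n": int(len(vals)),
            })
    return AlleleSizeProfile(scores=scores, by_subpop=pd.DataFrame(rows))


def allele_size_trend_test(
    profile: AlleleSizeProfile,
    assignment: pd.Series,
    reference: str,
) -> pd.DataFrame:
    """Welch two-sample t-tests of each subpopulation's individual
    standardized allele sizes against a reference subpopulation.

    The t statistic is signed as (comparison - reference)."""
    assignment = assignment.reindex(profile.scores.index)
    ref_vals = profile.scores[assignment == reference]
    if len(ref_vals) < 2:
        raise DataError(f"reference group {reference!r} needs n >= 2")
    rows = []
    for pop in sorted(p for p in assignment.dropna().unique()
                      if p not in ("ADMIXED", reference)):
        vals = profile.scores[assignment == pop]
        if len(vals) < 2:
            raise DataError(f"group {pop!r} needs n >= 2")
        t, p = stats.ttest_ind(vals, ref_vals, equal_var=False)
        rows.append({"comparison": f"{pop} vs {reference}",
                     "t": float(t), "p_value": float(p)})
    return pd.DataFrame(rows)
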