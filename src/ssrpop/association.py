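"""Q+K mixed-linear-model association mapping and broad-sense heritability.

The marker scan fits, per trait and environment,

    y = X beta + u + e,   Var(u) = sigma_g^2 * 2K,   Var(e) = sigma_e^2 * I

where X holds an intercept, the first K-1 ancestry (Q) columns and the
marker's allele-class dummies, and K is the Loiselle kinship matrix
(negatives truncated to zero).  Variance components are estimated once
per trait x environment by REML under the no-marker null model -- the
spectral decomposition of 2K reduces the restricted likelihood to a 1-D
optimization over the variance ratio -- and are then held fixed while
each marker term is F-tested by generalized least squares (the
"population parameters previously determined" scheme).  P values are
corrected by Benjamini-Hochberg within trait x environment.

Broad-sense heritability uses the replicate-level one-way ANOVA:
sigma_e^2 = MS_error, sigma_g^2 = (MS_accession - MS_error)/n and
H^2_B = sigma_g^2 / (sigma_g^2 + sigma_e^2/n), reported in percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from ssrpop.core_data import (
    MISSING,
    NULL_ALLELE,
    DataError,
    GenotypeMatrix,
    accession_means,
)
from ssrpop.structure import QMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Loiselle kinship
# ---------------------------------------------------------------------------

def kinship_matrix(g: GenotypeMatrix, truncate: bool = True) -> pd.DataFrame:
    """Loiselle pairwise kinship over shared scored loci.

    For haploid-coded inbreds the per-locus contribution for accessions
    i, j is ``sum_a (x_ia - p_a)(x_ja - p_a) + sum_a p_a(1-p_a)/(n_l-1)``
    (the second term is the small-sample bias correction), normalized by
    the summed ``p_a (1 - p_a)`` of the loci the pair shares.  Negative
    estimates are truncated to zero after estimation.
    """
    if g.n_accessions < 2:
        raise DataError("kinship needs at least 2 accessions")
    n = g.n_accessions
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for j in range(g.n_loci):
        col = g.calls[:, j]
        ok = col > 0
        n_l = int(ok.sum())
        if n_l < 2:
            continue
        alleles = np.unique(col[ok])
        if alleles.size < 2:
            continue
        X = (col[:, None] == alleles[None, :]).astype(float)
        p = X[ok].mean(axis=0)
        het = float((p * (1 - p)).sum())
        if het <= 0:
            continue
        C = np.where(ok[:, None], X - p, 0.0)
        both = np.outer(ok, ok)
        num += (C @ C.T + het / (n_l - 1)) * both
        den += het * both
    with np.errstate(invalid="ignore", divide="ignore"):
        kin = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    if (den == 0).any():
        logger.warning("some accession pairs share no informative loci; kinship 0")
    if truncate:
        kin = np.maximum(kin, 0.0)
    kin = (kin + kin.T) / 2.0
    return pd.DataFrame(kin, index=g.accessions, columns=g.accessions)


# ---------------------------------------------------------------------------
# REML variance components (spectral / EMMA-style)
# ---------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    beta: np.ndarray
    sigma_g2: float
    sigma_e2: float
    delta: float  # sigma_e2 / sigma_g2
    reml_loglik: float
    eigvals: np.ndarray | None = None
    eigvecs: np.ndarray | None = None


def _reml_loglik(delta: float, S: np.ndarray, yt: np.ndarray, Xt: np.ndarray,
                 logdet_xtx: float) -> tuple[float, float]:
    n, p = Xt.shape
    w = 1.0 / (S + delta)
    XtW = Xt * w[:, None]
    A = Xt.T @ XtW
    beta = np.linalg.solve(A, XtW.T @ yt)
    r = yt - Xt @ beta
    R = float((r * w * r).sum())
    df = n - p
    sign, logdet_a = np.linalg.slogdet(A)
    ll = 0.5 * (
        df * np.log(df / (2 * np.pi)) - df - df * np.log(max(R, 1e-300))
        - float(np.log(S + delta).sum()) - logdet_a + logdet_xtx
    )
    return ll, R


def reml_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    ridge: float = 1e-6,
    n_grid: int = 80,
) -> MixedModelFit:
    """REML fit of the polygenic model with covariance ``sigma_g^2 2K``.

    The restricted likelihood is profiled over delta = sigma_e^2/sigma_g^2
    on the spectrum of ``2K + ridge*I``; a log-spaced grid locates the
    basin and Brent refines the optimum.  A (near-)zero K collapses the
    fit to ordinary least squares with sigma_g^2 = 0.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    p = X.shape[1]
    if n < p + 2:
        raise DataError(f"need n >= rank(X) + 2; n={n}, p={p}")
    if np.ptp(y) == 0:
        raise DataError("phenotype has zero variance")
    M = 2.0 * np.asarray(K, dtype=float)
    if np.abs(M).max() < 1e-10:
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        sig_e = float(r @ r) / (n - p)
        return MixedModelFit(beta=beta, sigma_g2=0.0, sigma_e2=sig_e,
                             delta=np.inf, reml_loglik=np.nan)
    M = M + ridge * np.eye(n)
    S, U = np.linalg.eigh(M)
    # zero-truncated kinship is mildly indefinite; project small negative
    # eigenvalues to zero, but refuse a grossly non-PSD matrix
    if S.min() < -0.1 * max(S.max(), 1.0):
        raise DataError("kinship matrix not PSD even after ridge")
    if S.min() < 0:
        logger.debug("clamping %d negative eigenvalue(s) (min %.3g)",
                     int((S < 0).sum()), float(S.min()))
    S = np.maximum(S, 1e-12)
    yt = U.T @ y
    Xt = U.T @ X
    _, logdet_xtx = np.linalg.slogdet(X.T @ X)
    log_deltas = np.linspace(-8, 8, n_grid)
    lls = [
        _reml_loglik(10.0**ld, S, yt, Xt, logdet_xtx)[0] for ld in log_deltas
    ]
    i = int(np.argmax(lls))
    lo = log_deltas[max(i - 1, 0)]
    hi = log_deltas[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda ld: -_reml_loglik(10.0**ld, S, yt, Xt, logdet_xtx)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    ld_opt = float(res.x)
    ll, R = _reml_loglik(10.0**ld_opt, S, yt, Xt, logdet_xtx)
    delta = 10.0**ld_opt
    sigma_g2 = R / (n - p)
    sigma_e2 = delta * sigma_g2
    w = 1.0 / (S + delta)
    XtW = Xt * w[:, None]
    beta = np.linalg.solve(Xt.T @ XtW, XtW.T @ yt)
    return MixedModelFit(beta=beta, sigma_g2=float(sigma_g2),
                         sigma_e2=float(sigma_e2), delta=delta,
                         reml_loglik=float(ll), eigvals=S, eigvecs=U)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("P values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Marker scan
# ---------------------------------------------------------------------------

OTHER_CLASS = -2  # pooled small allele classes


def psd_project(K: np.ndarray) -> np.ndarray:
    """Nearest PSD projection (negative eigenvalues clamped to zero).

    Zero-truncating negative kinship estimates leaves the matrix mildly
    indefinite; projecting once keeps every principal submatrix PSD, so
    per-marker GLS with missing genotypes stays well conditioned.
    """
    S, U = np.linalg.eigh(np.asarray(K, dtype=float))
    if S.min() >= 0:
        return np.asarray(K, dtype=float)
    return (U * np.maximum(S, 0.0)) @ U.T


def _allele_classes(calls: np.ndarray, min_class: int = 3) -> np.ndarray:
    """Map calls to allele-class codes, pooling classes with fewer than
    ``min_class`` carriers into a single 'other' class.  The null allele
    is a class of its own (pooled like any other if too small).  Missing
    stays :data:`MISSING`."""
    out = calls.copy()
    scored = calls != MISSING
    classes, counts = np.unique(calls[scored], return_counts=True)
    small = classes[counts < min_class]
    if small.size:
        logger.debug("pooling %d small allele class(es)", small.size)
        out[np.isin(calls, small)] = OTHER_CLASS
    return out


def _whiten(y, X, S, U, delta):
    w = 1.0 / np.sqrt(S + delta)
    return (U.T @ y) * w, (U.T @ X) * w[:, None]


def _gls_rss(zy: np.ndarray, zX: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(zX, zy, rcond=None)
    r = zy - zX @ beta
    return float(r @ r)


def mlm_scan(
    g: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    qm: QMatrix | pd.DataFrame | None,
    kinship: pd.DataFrame,
    traits: list[str] | None = None,
    environments: list[str] | None = None,
    min_class: int = 3,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Q+K mixed-model scan of every marker against every trait and
    environment.

    Genotypes should already be rare-allele filtered.  Markers are coded
    as allele-class factors (the null allele is a class); classes with
    fewer than ``min_class`` carriers are pooled.  Returns a long table
    with P, BH-adjusted q (within trait x environment) and PVE (marker
    sum of squares over corrected total, both on the whitened scale).
    """
    if traits is None:
        traits = sorted(phenotypes["trait"].unique())
    if environments is None:
        environments = sorted(phenotypes["environment"].unique())
    if isinstance(qm, QMatrix):
        qdf = qm.to_frame()
    elif qm is None:
        qdf = None
    else:
        qdf = qm
    rows = []
    for trait in traits:
        for env in environments:
            try:
                y_all = accession_means(phenotypes, trait, env)
            except DataError:
                continue
            acc = [a for a in g.accessions
                   if a in y_all.index and a in kinship.index
                   and (qdf is None or a in qdf.index)]
            if len(acc) < 10:
                logger.warning("trait %s env %s: only %d accessions; skipped",
                               trait, env, len(acc))
                continue
            y = y_all.loc[acc].to_numpy(dtype=float)
            Km = psd_project(kinship.loc[acc, acc].to_numpy(dtype=float))
            X0 = [np.ones((len(acc), 1))]
            if qdf is not None and qdf.shape[1] > 1:
                X0.append(qdf.loc[acc].to_numpy(dtype=float)[:, :-1])
            X0 = np.hstack(X0)
            null_fit = reml_variance_components(y, X0, Km)
            S, U, delta = null_fit.eigvals, null_fit.eigvecs, null_fit.delta
            if S is None:  # K == 0 path: identity whitening
                S = np.zeros(len(acc))
                U = np.eye(len(acc))
                delta = 1.0
            zy, zX0 = _whiten(y, X0, S, U, delta)
            z1 = _whiten(y, np.ones((len(acc), 1)), S, U, delta)[1]
            tss = _gls_rss(zy, z1)
            rss0_full = _gls_rss(zy, zX0)
            gi = [g.accessions.index(a) for a in acc]
            for j, marker in enumerate(g.loci):
                calls = g.calls[gi, j]
                cls = _allele_classes(calls, min_class)
                ok = cls != MISSING
                levels = np.unique(cls[ok])
                if levels.size < 2:
                    continue
                # reference class: null allele if present, else largest class
                if NULL_ALLELE in levels:
                    ref = NULL_ALLELE
                else:
                    counts = [(cls[ok] == l).sum() for l in levels]
                    ref = levels[int(np.argmax(counts))]
                dummies = np.column_stack([
                    (cls == l).astype(float) for l in levels if l != ref
                ])
                if ok.all():
                    zD = _whiten(y, dummies, S, U, delta)[1]
                    rss0 = rss0_full
                    rss1 = _gls_rss(zy, np.hstack([zX0, zD]))
                    tss_m = tss
                    n_eff = len(acc)
                else:
                    idx = np.flatnonzero(ok)
                    Vsub = (2.0 * Km + 1e-6 * np.eye(len(acc)))[np.ix_(idx, idx)]
                    Vsub = Vsub + delta * np.eye(len(idx))
                    Ss, Us = np.linalg.eigh(Vsub)
                    ws = 1.0 / np.sqrt(np.maximum(Ss, 1e-10))
                    zy_s = (Us.T @ y[idx]) * ws
                    zX0_s = (Us.T @ X0[idx]) * ws[:, None]
                    zD_s = (Us.T @ dummies[idx]) * ws[:, None]
                    z1_s = (Us.T @ np.ones((len(idx), 1))) * ws[:, None]
                    rss0 = _gls_rss(zy_s, zX0_s)
                    rss1 = _gls_rss(zy_s, np.hstack([zX0_s, zD_s]))
                    tss_m = _gls_rss(zy_s, z1_s)
                    n_eff = len(idx)
                q_df = dummies.shape[1]
                p_full = X0.shape[1] + q_df
                df_res = n_eff - p_full
                if df_res < 1 or rss1 < 0:
                    continue
                ms_marker = max(rss0 - rss1, 0.0) / q_df
                ms_res = rss1 / df_res
                if ms_res <= 0:
                    p_val = 0.0
                else:
                    F = ms_marker / ms_res
                    p_val = float(stats.f.sf(F, q_df, df_res))
                pve = max(rss0 - rss1, 0.0) / tss_m if tss_m > 0 else 0.0
                rows.append({
                    "trait": trait, "environment": env, "marker": marker,
                    "n": n_eff, "n_classes": int(levels.size),
                    "p_value": p_val, "PVE": float(min(pve, 1.0)),
                })
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["q_value"] = np.nan
    for (trait, env), idx in result.groupby(["trait", "environment"]).groups.items():
        result.loc[idx, "q_value"] = bh_adjust(result.loc[idx, "p_value"].to_numpy())
    result["significant"] = result["q_value"] < fdr_level
    return result.reset_index(drop=True)


def significant_markers(result: pd.DataFrame, fdr_level: float = 0.05) -> dict[str, list[str]]:
    """Markers significant (BH q below the level) in at least one
    environment, per trait."""
    out: dict[str, list[str]] = {}
    for trait, sub in result.groupby("trait"):
        sig = sub.loc[sub["q_value"] < fdr_level, "marker"].unique().tolist()
        out[trait] = sorted(sig)
    return out


# ---------------------------------------------------------------------------
# Broad-sense heritability
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityResult:
    trait: str
    environment: str
    sigma_g2: float
    sigma_e2: float
    n_replicates: float
    h2_percent: float


def broad_sense_heritability(
    phenotypes: pd.DataFrame, trait: str, environment: str
) -> HeritabilityResult:
    """H^2_B from replicate-level one-way ANOVA over accessions.

    ``sigma_e^2 = MS_error``; ``sigma_g^2 = (MS_accession - MS_error)/n``
    clamped at zero; ``H^2_B = sigma_g^2/(sigma_g^2 + sigma_e^2/n)`` in
    percent.  Unbalanced replication uses the harmonic-mean replicate
    count.
    """
    sub = phenotypes[(phenotypes["trait"] == trait)
                     & (phenotypes["environment"] == str(environment))]
    if sub.empty:
        raise DataError(f"no records for trait {trait!r} in {environment!r}")
    counts = sub.groupby("accession")["value"].count()
    if (counts < 2).any():
        raise DataError("every accession needs >= 2 replicates")
    if counts.nunique() > 1:
        n_rep = float(len(counts) / (1.0 / counts).sum())
        logger.info("unbalanced replication; harmonic mean n = %.3f", n_rep)
    else:
        n_rep = float(counts.iloc[0])
    grand = sub["value"].mean()
    means = sub.groupby("accession")["value"].mean()
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(((sub["value"] - sub["accession"].map(means)) ** 2).sum())
    df_between = len(counts) - 1
    df_within = len(sub) - len(counts)
    if df_between < 1 or df_within < 1:
        raise DataError("insufficient degrees of freedom for ANOVA")
    ms_g = ss_between / df_between
    ms_e = ss_within / df_within
    sigma_e2 = ms_e
    sigma_g2 = max((ms_g - ms_e) / n_rep, 0.0)
    denom = sigma_g2 + sigma_e2 / n_rep
    h2 = 100.0 * sigma_g2 / denom if denom > 0 else 0.0
    return HeritabilityResult(trait=trait, environment=str(environment),
                              sigma_g2=sigma_g2, sigma_e2=sigma_e2,
                              n_replicates=n_rep, h2_percent=h2)
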