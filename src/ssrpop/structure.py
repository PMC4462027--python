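"""Population structure: Nei distances, NJ dendrogram, admixture EM.

The model-based structure stage fits the standard admixture likelihood

    P(genotypes) = prod_{i,l} sum_k q_ik f_{k,l,a(i,l)}

for inbred (single-allele) genotypes by multi-restart EM, maximizing the
log-likelihood over per-accession ancestry proportions Q and
per-cluster allele frequencies F.  This is the maximum-likelihood
counterpart of the Bayesian sampler usually run on such panels; an
externally computed Q matrix can be imported instead and fed to the
downstream stages unchanged.

Accessions are declared members of a subpopulation only when their
largest ancestry proportion is strictly above the assignment threshold
(default 0.9); everything else is labelled admixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from ssrpop.core_data import DataError, GenotypeMatrix

logger = logging.getLogger(__name__)

ADMIXED = "ADMIXED"


# ---------------------------------------------------------------------------
# Nei genetic distance and neighbour-joining
# ---------------------------------------------------------------------------

def nei_distance(
    profile_x: dict[str, pd.Series],
    profile_y: dict[str, pd.Series],
    method: str = "nei72",
    max_distance: float = 10.0,
) -> float:
    """Nei genetic distance between two allele-frequency profiles.

    ``method="nei72"`` is Nei's (1972) standard distance
    ``-ln(J_xy / sqrt(J_x J_y))`` with the J's averaged across shared loci;
    ``method="da"`` is the bounded D_A variant ``1 - mean_l sum_a sqrt(x y)``.
    Under Nei-1972 a zero shared identity is capped at ``max_distance``.
    """
    shared = sorted(set(profile_x) & set(profile_y))
    if not shared:
        raise DataError("profiles share no loci")
    jxy = jx = jy = 0.0
    da_acc = 0.0
    for locus in shared:
        x = profile_x[locus]
        y = profile_y[locus]
        alleles = x.index.union(y.index)
        xv = x.reindex(alleles, fill_value=0.0).to_numpy()
        yv = y.reindex(alleles, fill_value=0.0).to_numpy()
        jxy += float(xv @ yv)
        jx += float(xv @ xv)
        jy += float(yv @ yv)
        da_acc += float(np.sqrt(xv * yv).sum())
    L = len(shared)
    if method == "da":
        return 1.0 - da_acc / L
    if method != "nei72":
        raise ValueError(f"unknown method {method!r}")
    identity = (jxy / L) / np.sqrt((jx / L) * (jy / L))
    if identity <= 0:
        logger.warning("zero shared identity; distance capped at %g", max_distance)
        return max_distance
    return float(min(-np.log(identity), max_distance))


def nei_distance_matrix(
    g: GenotypeMatrix, method: str = "nei72", max_distance: float = 10.0
) -> pd.DataFrame:
    """Pairwise Nei distance between accessions.

    For single-allele inbred profiles both Nei-1972 identity and the D_A
    overlap reduce to the fraction of shared scored loci carrying the same
    allele, so the matrix is computed from match counts directly.
    """
    n = g.n_accessions
    matches = np.zeros((n, n))
    shared = np.zeros((n, n))
    for j in range(g.n_loci):
        col = g.calls[:, j]
        ok = col > 0
        pair_ok = np.outer(ok, ok)
        shared += pair_ok
        same = col[:, None] == col[None, :]
        matches += pair_ok & same
    with np.errstate(invalid="ignore", divide="ignore"):
        identity = np.where(shared > 0, matches / np.maximum(shared, 1), np.nan)
    if np.isnan(identity).any():
        logger.warning("some accession pairs share no scored loci")
        identity = np.nan_to_num(identity, nan=0.0)
    if method == "da":
        d = 1.0 - identity
    else:
        with np.errstate(divide="ignore"):
            d = np.where(identity > 0, -np.log(identity), max_distance)
        d = np.minimum(d, max_distance)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=g.accessions, columns=g.accessions)


def nj_tree(distances: pd.DataFrame):
    """Neighbour-joining tree (Saitou-Nei) from a symmetric distance matrix.

    Negative branch lengths produced by the agglomeration are clamped to
    zero.  Returns an unrooted ``skbio.TreeNode``.
    """
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-9):
        raise DataError("distance matrix must be square and symmetric")
    if d.shape[0] < 3:
        raise DataError("neighbour joining needs at least 3 taxa")
    dm = _SkbioDM(d, [str(i) for i in distances.index])
    return _skbio_nj(dm, neg_as_zero=True)


def write_newick(tree, path: str | Path) -> None:
    Path(path).write_text(str(tree))


# ---------------------------------------------------------------------------
# Admixture EM
# ---------------------------------------------------------------------------

@dataclass
class QMatrix:
    """Admixture proportions for each accession over K clusters."""

    accessions: list[str]
    q: np.ndarray  # (n, K), rows sum to 1
    K: int
    loglik: float
    cluster_freqs: list[np.ndarray] = field(default_factory=list)  # per locus (K, A)
    loglik_path: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = [f"q{k + 1}" for k in range(self.K)]
        return pd.DataFrame(self.q, index=self.accessions, columns=cols)


def _encode(g: GenotypeMatrix) -> tuple[np.ndarray, list[np.ndarray]]:
    """Integer-encode scored calls per locus; -1 marks unscored cells."""
    obs = np.full((g.n_accessions, g.n_loci), -1, dtype=np.int64)
    allele_lists = []
    for j in range(g.n_loci):
        col = g.calls[:, j]
        scored = col > 0
        alleles = np.unique(col[scored])
        allele_lists.append(alleles)
        idx = np.searchsorted(alleles, col[scored])
        obs[scored, j] = idx
    return obs, allele_lists


def _em_once(
    obs: np.ndarray,
    allele_lists: list[np.ndarray],
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    n, L = obs.shape
    floor = 1e-9
    q = rng.dirichlet(np.ones(K), size=n)
    freqs = []
    for j in range(L):
        A = len(allele_lists[j])
        counts = np.bincount(obs[obs[:, j] >= 0, j], minlength=A).astype(float) + 1.0
        base = counts / counts.sum()
        f = base[None, :] * np.exp(rng.normal(0.0, 0.3, size=(K, A)))
        freqs.append(f / f.sum(axis=1, keepdims=True))
    path = []
    prev = -np.inf
    for _ in range(max_iter):
        q_acc = np.zeros_like(q)
        n_obs_per_acc = np.zeros(n)
        ll = 0.0
        new_freqs = []
        for j in range(L):
            idx = obs[:, j]
            mask = idx >= 0
            if not mask.any():
                new_freqs.append(freqs[j])
                continue
            fa = freqs[j][:, idx[mask]].T  # (n_m, K)
            joint = q[mask] * fa
            s = joint.sum(axis=1)
            ll += float(np.log(np.maximum(s, floor)).sum())
            r = joint / np.maximum(s, floor)[:, None]
            q_acc[mask] += r
            n_obs_per_acc[mask] += 1
            A = len(allele_lists[j])
            f_new = np.zeros((A, K))
            np.add.at(f_new, idx[mask], r)
            f_new = f_new.T + floor
            new_freqs.append(f_new / f_new.sum(axis=1, keepdims=True))
        path.append(ll)
        freqs = new_freqs
        ok = n_obs_per_acc > 0
        q[ok] = q_acc[ok] / n_obs_per_acc[ok, None]
        q = np.maximum(q, floor)
        q /= q.sum(axis=1, keepdims=True)
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
    return q, freqs, np.asarray(path)


def admixture_em(
    g: GenotypeMatrix,
    K: int,
    runs: int = 5,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> QMatrix:
    """Fit the admixture model at a given K by multi-restart EM.

    The best of ``runs`` random restarts (by final log-likelihood) is
    returned; the per-iteration log-likelihood path of the winning run is
    kept so monotonicity can be audited.  Restart count defaults to five
    independent runs, the usual practice for such panels.
    """
    if K < 1:
        raise DataError("K must be >= 1")
    if K > g.n_accessions:
        raise DataError(f"K={K} exceeds accession count {g.n_accessions}")
    obs, allele_lists = _encode(g)
    n = g.n_accessions
    if K == 1:
        q = np.ones((n, 1))
        ll = 0.0
        freqs = []
        for j, alleles in enumerate(allele_lists):
            idx = obs[:, j]
            mask = idx >= 0
            counts = np.bincount(idx[mask], minlength=len(alleles)).astype(float)
            p = counts / max(counts.sum(), 1.0)
            freqs.append(p[None, :])
            ll += float(np.log(np.maximum(p[idx[mask]], 1e-300)).sum())
        return QMatrix(list(g.accessions), q, 1, ll, freqs, np.array([ll]))
    if all(len(a) <= 1 for a in allele_lists):
        logger.warning("all loci monomorphic; admixture likelihood is flat")
        q = np.full((n, K), 1.0 / K)
        return QMatrix(list(g.accessions), q, K, 0.0, [], np.array([0.0]))
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, runs)):
        q, freqs, path = _em_once(obs, allele_lists, K, rng, max_iter, tol)
        if best is None or path[-1] > best[2][-1]:
            best = (q, freqs, path)
    q, freqs, path = best
    return QMatrix(list(g.accessions), q, K, float(path[-1]), freqs, path)


def _n_parameters(g: GenotypeMatrix, K: int) -> int:
    _, allele_lists = _encode(g)
    freq_params = K * sum(max(len(a) - 1, 0) for a in allele_lists)
    return g.n_accessions * (K - 1) + freq_params


def select_k(
    g: GenotypeMatrix,
    k_range=range(2, 11),
    runs: int = 5,
    seed: int = 0,
    criterion: str = "aic",
    max_iter: int = 300,
) -> tuple[int, pd.DataFrame]:
    """Scan K over a range and pick the supported number of clusters.

    For each K, ``runs`` independent EM fits are made and the mean final
    log-likelihood over runs is recorded (the quantity structure scans
    conventionally report).  Because the maximized likelihood never
    decreases with K, the default selection applies an AIC-type penalty
    of one unit per free parameter -- about twice the expected chance
    gain of an extra cluster, so a K is only accepted when its clusters
    explain real structure (``criterion="bic"`` and raw ``"loglik"`` are
    also available); ties break toward the smaller K.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise DataError("empty K range")
    if ks[0] < 1 or ks[-1] > g.n_accessions:
        raise DataError(f"K range must lie in [1, {g.n_accessions}]")
    n_obs = int((g.calls > 0).sum())
    rows = []
    for k in ks:
        lls = []
        for r in range(max(1, runs)):
            fit = admixture_em(g, k, runs=1, seed=seed + 1000 * k + r, max_iter=max_iter)
            lls.append(fit.loglik)
        mean_ll = float(np.mean(lls))
        p = _n_parameters(g, k)
        if criterion == "bic":
            score = mean_ll - 0.5 * p * np.log(max(n_obs, 2))
        elif criterion == "aic":
            score = mean_ll - p
        elif criterion == "loglik":
            score = mean_ll
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        rows.append({"K": k, "mean_loglik": mean_ll, "n_params": p, "score": score})
    table = pd.DataFrame(rows)
    best = table.loc[table["score"].idxmax(), "score"]
    chosen = int(table.loc[table["score"] >= best - 1e-9, "K"].min())
    return chosen, table


def assign_subpopulations(qm: QMatrix, threshold: float = 0.9) -> pd.Series:
    """Label each accession POP<k> when max(Q) is strictly above the
    threshold, else :data:`ADMIXED`."""
    labels = []
    for row in qm.q:
        k = int(np.argmax(row))
        labels.append(f"POP{k + 1}" if row[k] > threshold else ADMIXED)
    return pd.Series(labels, index=qm.accessions, name="subpopulation")


# ---------------------------------------------------------------------------
# Q matrix I/O
# ---------------------------------------------------------------------------

def write_q_matrix(qm: QMatrix, path: str | Path) -> None:
    df = qm.to_frame()
    df.index.name = "accession"
    df.to_csv(path, sep="\t")


def read_q_matrix(path: str | Path) -> QMatrix:
    """Read a Q matrix from a delimited table (accession, q1..qK).

    Tolerant of extra leading columns as produced by structure programs:
    the trailing block of numeric columns whose rows sum to ~1 is taken as
    the ancestry proportions.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    num = df.select_dtypes(include=[np.number])
    qcols = [c for c in num.columns if num[c].between(-1e-9, 1 + 1e-9).all()]
    if not qcols:
        raise DataError(f"no ancestry-proportion columns found in {path}")
    q = df[qcols].to_numpy(dtype=float)
    sums = q.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise DataError("ancestry rows do not sum to 1")
    acc = df.iloc[:, 0].astype(str).tolist()
    return QMatrix(acc, q / sums[:, None], q.shape[1], float("nan"))
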