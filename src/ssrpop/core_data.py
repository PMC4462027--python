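"""Data model and I/O for SSR genotype, map and phenotype tables.

Genotype calls are stored as a dense integer matrix (accession x locus).
Each cell is one of

* a positive integer -- the allele size in base pairs (inbred lines carry a
  single allele per locus),
* :data:`NULL_ALLELE` (0) -- the marker amplified no band; a real genotype
  state that serves as the baseline class in allele mining but is excluded
  from frequency-based statistics,
* :data:`MISSING` (-1) -- no data; excluded everywhere.

Heterozygous dialects are rejected outright: the data model is for pure
lines genotyped from a single plant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a cell with no data.
MISSING: int = -1
#: Sentinel for the non-amplified ("null") allele.
NULL_ALLELE: int = 0

#: Default text tokens for the two non-size states.
DEFAULT_MISSING_TOKEN = "-"
DEFAULT_NULL_TOKEN = "N"

TRAITS = ("GL", "GW", "GT", "TGW")


class DataError(ValueError):
    """Raised on any validation failure in input tables."""


@dataclass
class AnalysisConfig:
    """Pipeline-wide thresholds and the master random seed.

    rare_allele_threshold
        Alleles at frequency <= this value (inclusive) are removed before
        LD and association scans.  Default 0.05 ("5% or less").
    q_threshold
        An accession is assigned to a subpopulation only when its largest
        admixture proportion is strictly above this value.
    fdr_level
        Benjamini-Hochberg false-discovery-rate level for declaring
        marker-trait associations significant.
    permutations
        Number of label permutations for LD and AMOVA significance.
    """

    rare_allele_threshold: float = 0.05
    q_threshold: float = 0.9
    fdr_level: float = 0.05
    permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rare_allele_threshold", "q_threshold", "fdr_level"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise DataError(f"{name} must lie in (0, 1); got {v}")
        if self.permutations < 1:
            raise DataError("permutations must be >= 1")


@dataclass
class GenotypeMatrix:
    """Accession x locus matrix of single-allele SSR calls.

    ``calls[i, j]`` is the allele size (bp) of accession ``accessions[i]``
    at locus ``loci[j]``, or one of the sentinels :data:`MISSING` /
    :data:`NULL_ALLELE`.
    """

    accessions: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, m = self.calls.shape
        if n != len(self.accessions) or m != len(self.loci):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.loci)} loci"
            )
        for label, ids in (("accession", self.accessions), ("locus", self.loci)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise DataError(f"duplicate {label} identifiers: {dupes}")
        bad = (self.calls < MISSING).any()
        if bad:
            raise DataError("allele sizes must be positive integers")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_calls(self, locus: str) -> np.ndarray:
        return self.calls[:, self.loci.index(locus)]

    def scored_mask(self) -> np.ndarray:
        """Boolean mask of cells carrying an actual allele size."""
        return self.calls > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.accessions, columns=self.loci)

    def subset(
        self,
        accessions: Iterable[str] | None = None,
        loci: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        acc = list(accessions) if accessions is not None else self.accessions
        loc = list(loci) if loci is not None else self.loci
        ai = [self.accessions.index(a) for a in acc]
        li = [self.loci.index(l) for l in loc]
        return GenotypeMatrix(acc, loc, self.calls[np.ix_(ai, li)])


def write_genotype_table(
    g: GenotypeMatrix,
    path: str | Path,
    sep: str = "\t",
    missing_token: str = DEFAULT_MISSING_TOKEN,
    null_token: str = DEFAULT_NULL_TOKEN,
) -> None:
    """Write a genotype matrix as delimited text (header = marker ids)."""
    df = g.to_frame().astype(object)
    df = df.where(df != MISSING, missing_token)
    df = df.where(df != NULL_ALLELE, null_token)
    df.index.name = "accession"
    df.to_csv(path, sep=sep)


def read_genotype_table(
    path: str | Path,
    sep: str | None = None,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    null_token: str = DEFAULT_NULL_TOKEN,
) -> GenotypeMatrix:
    """Read a delimited genotype table (first column accession ids,
    header row marker ids) into a validated :class:`GenotypeMatrix`.

    Any cell token other than the configured missing/null codes must be a
    positive integer allele size; offending cells are named in the error.
    """
    # pandas mangles duplicate header names, so check the raw header first
    with open(path) as fh:
        header = ""
        for line in fh:
            if line.strip() and not line.startswith("#"):
                header = line.rstrip("\n")
                break
    hdr_sep = sep if sep is not None else ("\t" if "\t" in header else ",")
    raw_cols = [c.strip() for c in header.split(hdr_sep)][1:]
    dup_loci = pd.Index(raw_cols)[pd.Index(raw_cols).duplicated()].unique().tolist()
    if dup_loci:
        raise DataError(f"duplicate marker column(s) in {path}: {dup_loci}")
    df = pd.read_csv(path, sep=sep, engine="python", index_col=0, dtype=str, comment="#")
    loci = [str(c) for c in df.columns]
    accessions = [str(a) for a in df.index]
    dup_acc = pd.Index(accessions)[pd.Index(accessions).duplicated()].unique().tolist()
    if dup_acc:
        raise DataError(f"duplicate accession row(s) in {path}: {dup_acc}")

    calls = np.empty(df.shape, dtype=np.int64)
    n_missing = n_null = 0
    for j, locus in enumerate(loci):
        col = df.iloc[:, j].astype(str).str.strip()
        for i, tok in enumerate(col):
            if tok == missing_token or tok.lower() in ("nan", ""):
                calls[i, j] = MISSING
                n_missing += 1
            elif tok == null_token:
                calls[i, j] = NULL_ALLELE
                n_null += 1
            else:
                try:
                    size = int(float(tok))
                except ValueError:
                    raise DataError(
                        f"non-numeric allele token {tok!r} at accession "
                        f"{accessions[i]!r}, marker {locus!r}"
                    ) from None
                if size <= 0:
                    raise DataError(
                        f"allele size must be positive at accession "
                        f"{accessions[i]!r}, marker {locus!r}: {tok!r}"
                    )
                calls[i, j] = size
    logger.info(
        "read %d accessions x %d loci (%d missing, %d null-allele cells)",
        len(accessions), len(loci), n_missing, n_null,
    )
    return GenotypeMatrix(accessions, loci, calls)


def read_marker_map(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a marker map with columns marker, chromosome, position_cM.

    Returns a DataFrame sorted by (chromosome, position).  Chromosomes must
    lie in 1..12 (the rice karyotype) and positions must be finite and >= 0.
    """
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    required = {"marker", "chromosome", "position_cM"}
    if not required.issubset(df.columns):
        raise DataError(
            f"marker map needs columns {sorted(required)}; got {list(df.columns)}"
        )
    return validate_marker_map(df)


def validate_marker_map(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["marker"] = df["marker"].astype(str)
    dupes = df["marker"][df["marker"].duplicated()].unique().tolist()
    if dupes:
        raise DataError(f"duplicate markers in map: {dupes}")
    df["chromosome"] = df["chromosome"].astype(int)
    if not df["chromosome"].between(1, 12).all():
        bad = df.loc[~df["chromosome"].between(1, 12), "marker"].tolist()
        raise DataError(f"chromosome outside 1-12 for markers: {bad}")
    df["position_cM"] = df["position_cM"].astype(float)
    if not np.isfinite(df["position_cM"]).all() or (df["position_cM"] < 0).any():
        bad = df.loc[
            ~np.isfinite(df["position_cM"]) | (df["position_cM"] < 0), "marker"
        ].tolist()
        raise DataError(f"position must be finite and >= 0 for markers: {bad}")
    return df.sort_values(["chromosome", "position_cM"]).reset_index(drop=True)


def read_phenotype_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a long-format phenotype table.

    Columns: accession, environment, replicate, trait, value.  Trait values
    must be strictly positive (grain dimensions in mm, grain weight in g).
    """
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    required = {"accession", "environment", "replicate", "trait", "value"}
    if not required.issubset(df.columns):
        raise DataError(
            f"phenotype table needs columns {sorted(required)}; got {list(df.columns)}"
        )
    return validate_phenotypes(df)


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["accession"] = df["accession"].astype(str)
    df["environment"] = df["environment"].astype(str)
    df["value"] = df["value"].astype(float)
    if (df["value"] <= 0).any():
        bad = df.loc[df["value"] <= 0].iloc[0]
        raise DataError(
            f"non-positive trait value for accession {bad['accession']!r}, "
            f"trait {bad['trait']!r}: {bad['value']}"
        )
    key = ["accession", "environment", "replicate", "trait"]
    dup = df.duplicated(subset=key)
    if dup.any():
        bad = df.loc[dup, key].iloc[0].tolist()
        raise DataError(f"duplicate phenotype record: {bad}")
    return df.reset_index(drop=True)


def accession_means(
    phenotypes: pd.DataFrame,
    trait: str,
    environment: str | None = None,
) -> pd.Series:
    """Per-accession trait mean over replicates (and environments if
    ``environment`` is None), the phenotype used in association scans."""
    sub = phenotypes[phenotypes["trait"] == trait]
    if environment is not None:
        sub = sub[sub["environment"] == str(environment)]
    if sub.empty:
        raise DataError(f"no phenotype records for trait {trait!r}")
    return sub.groupby("accession")["value"].mean()


@dataclass
class RareAlleleReport:
    """Record of one rare-allele filtering pass."""

    threshold: float
    removed: pd.DataFrame = field(default_factory=pd.DataFrame)
    dropped_loci: list[str] = field(default_factory=list)


def filter_rare_alleles(
    g: GenotypeMatrix, threshold: float = 0.05
) -> tuple[GenotypeMatrix, RareAlleleReport]:
    """Remove alleles at frequency <= ``threshold`` (inclusive).

    Frequencies are computed per locus over scored calls only (null-allele
    and missing cells excluded from the denominator).  Calls carrying a
    removed allele become :data:`MISSING`; loci left with fewer than two
    surviving alleles are dropped entirely.  The filter is applied before
    LD and association scans; diversity statistics use the raw matrix.
    """
    if not 0.0 < threshold < 1.0:
        raise DataError(f"threshold must lie in (0, 1); got {threshold}")
    calls = g.calls.copy()
    removed_rows = []
    keep_loci = []
    for j, locus in enumerate(g.loci):
        col = calls[:, j]
        scored = col[col > 0]
        if scored.size == 0:
            logger.warning("locus %s has no scored calls; dropped", locus)
            continue
        alleles, counts = np.unique(scored, return_counts=True)
        freqs = counts / scored.size
        rare = freqs <= threshold
        for a, f in zip(alleles[rare], freqs[rare]):
            removed_rows.append({"locus": locus, "allele": int(a), "frequency": float(f)})
            col[col == a] = MISSING
        surviving = np.unique(col[col > 0])
        if surviving.size < 2:
            logger.warning(
                "locus %s left with %d allele(s) after rare-allele removal; dropped",
                locus, surviving.size,
            )
            continue
        keep_loci.append(j)
    report = RareAlleleReport(
        threshold=threshold,
        removed=pd.DataFrame(removed_rows, columns=["locus", "allele", "frequency"]),
        dropped_loci=[l for j, l in enumerate(g.loci) if j not in set(keep_loci)],
    )
    out = GenotypeMatrix(
        list(g.accessions), [g.loci[j] for j in keep_loci], calls[:, keep_loci]
    )
    return out, report
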