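"""Genomic relationship machinery for single-step evaluation.

Builds the VanRaden genomic relationship matrix

    G = Z D Z' / (2 * sum_i d_i p_i (1 - p_i)),

with ``Z`` the gene-content matrix centered by twice the base-population
allele frequencies ``p``, and ``D`` a diagonal matrix of per-SNP weights
(all ones in unweighted ssGBLUP).  Base frequencies are estimated by
generalized least squares on gene content using the pedigree relationships
among genotyped animals (Gengler's gene-content approach in its limiting
GLS form), so that ``G`` and ``A22`` refer to the same base population and
no further compatibility tuning is required.  The single-step matrix enters
the mixed model through

    H^-1 = A^-1 + [[0, 0], [0, G^-1 - A22^-1]]

on the genotyped block.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

MISSING = np.nan

# Allele-frequency clamp used when estimating base frequencies: avoids zero
# heterozygosity terms in the G denominator for (nearly) fixed SNPs.
CLAMP_LO = 0.01
CLAMP_HI = 0.99


class GenomicError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Animals x SNPs gene contents with a physical map.

    ``X`` holds counted-allele dosages in {0, 1, 2} with ``nan`` for missing.
    The map is kept sorted by (chromosome, position).
    """

    animal_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.X.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise GenomicError("genotype matrix shape does not match labels")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(self.snp_ids))):
            self.X = self.X[:, order]
            self.snp_ids = [self.snp_ids[i] for i in order]
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset_animals(self, animals: Sequence[str]) -> "GenotypeMatrix":
        idx = {a: i for i, a in enumerate(self.animal_ids)}
        missing = [a for a in animals if a not in idx]
        if missing:
            raise GenomicError(f"animals without genotypes: {missing[:10]}")
        rows = [idx[a] for a in animals]
        return replace(self, animal_ids=list(animals), X=self.X[rows])


# ---------------------------------------------------------------- file I/O

def read_plink_raw(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a PLINK ``--recode A`` (.raw) table.

    Returns (dosage matrix with nan missing, animal ids from IID, SNP column
    names with the ``_allele`` suffix stripped).
    """
    df = pd.read_csv(path, sep=r"\s+")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    snp_cols = [c for c in df.columns if c not in meta]
    ids = df["IID"].astype(str).tolist()
    X = df[snp_cols].to_numpy(dtype=float)
    names = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    return X, ids, names


def read_fixed_width(path) -> tuple[np.ndarray, list[str]]:
    """Read the compact dialect: ``animal-id<ws>012512...`` (5 = missing)."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            animal, geno = line.split(None, 1)
            ids.append(animal)
            arr = np.frombuffer(geno.strip().encode(), dtype=np.uint8) - ord("0")
            rows.append(arr.astype(float))
    X = np.vstack(rows)
    X[X == 5] = MISSING
    return X, ids


def read_snp_map(path) -> pd.DataFrame:
    """SNP map CSV with columns snp, chrom, pos."""
    m = pd.read_csv(path)
    required = {"snp", "chrom", "pos"}
    if not required.issubset(m.columns):
        raise GenomicError(f"SNP map must have columns {sorted(required)}")
    return m


def load_genotypes(geno_path, map_path, dialect: str = "plink_raw") -> GenotypeMatrix:
    if dialect == "plink_raw":
        X, ids, names = read_plink_raw(geno_path)
    elif dialect == "fixed_width":
        X, ids = read_fixed_width(geno_path)
        names = None
    else:
        raise GenomicError(f"unknown genotype dialect: {dialect}")
    m = read_snp_map(map_path).set_index("snp")
    if names is None:
        names = m.index.tolist()
        if X.shape[1] != len(names):
            raise GenomicError("genotype columns do not match SNP map length")
    m = m.loc[names]
    return GenotypeMatrix(
        animal_ids=ids,
        snp_ids=names,
        chrom=m["chrom"].to_numpy(),
        pos=m["pos"].to_numpy(),
        X=X,
    )


# ------------------------------------------------------------------ QC

def qc_filter(
    g: GenotypeMatrix, call_rate_min: float = 0.90, maf_min: float = 0.01
) -> tuple[GenotypeMatrix, dict]:
    """Drop SNPs failing call rate or minor-allele frequency.

    Monomorphic SNPs (including those fixed among the called animals) are
    always removed.  The report counts SNPs removed by each criterion, with
    removal attributed in the order call rate -> monomorphic/MAF.
    """
    X = g.X
    n = g.n_animals
    called = np.sum(~np.isnan(X), axis=0)
    call_rate = called / n
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(X, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    low_call = call_rate < call_rate_min
    mono = (~low_call) & ((maf <= 0.0) | np.isnan(maf))
    low_maf = (~low_call) & (~mono) & (maf < maf_min)
    keep = ~(low_call | mono | low_maf)
    if not np.any(keep):
        raise GenomicError("no SNPs survive quality control")
    report = {
        "n_input": g.n_snps,
        "removed_call_rate": int(low_call.sum()),
        "removed_monomorphic": int(mono.sum()),
        "removed_maf": int(low_maf.sum()),
        "n_retained": int(keep.sum()),
    }
    kept_idx = np.flatnonzero(keep)
    out = GenotypeMatrix(
        animal_ids=list(g.animal_ids),
        snp_ids=[g.snp_ids[i] for i in kept_idx],
        chrom=g.chrom[kept_idx],
        pos=g.pos[kept_idx],
        X=X[:, kept_idx],
    )
    return out, report


# --------------------------------------------------- base allele frequencies

def estimate_base_frequencies(
    g: GenotypeMatrix,
    A22_inv: np.ndarray,
    clamp_lo: float = CLAMP_LO,
    clamp_hi: float = CLAMP_HI,
) -> np.ndarray:
    """Base-population allele frequencies by GLS on gene content.

    For SNP ``j`` with gene-content column ``m_j`` observed on animals ``o``,

        2 * p_j = (1' A22[o,o]^-1 m_j) / (1' A22[o,o]^-1 1),

    the generalized-least-squares mean of gene content under covariance
    proportional to the pedigree relationships among genotyped animals.
    This is the limiting (variance-ratio -> 0) form of Gengler's
    gene-content BLUP for the fixed mean.  Missing entries are excluded via
    the corresponding sub-block of ``A22``.  Estimates are clamped to
    ``[clamp_lo, clamp_hi]``.
    """
    n = g.n_animals
    if A22_inv.shape != (n, n):
        raise GenomicError("A22_inv does not match number of genotyped animals")
    X = g.X
    ones = np.ones(n)
    w_full = A22_inv @ ones  # 1' A22^-1 per animal, complete-data case
    denom_full = float(ones @ w_full)
    if not np.isfinite(denom_full) or abs(denom_full) < 1e-12:
        raise GenomicError(
            "A22 appears singular; add a small jitter to its diagonal"
        )
    p = np.empty(g.n_snps)
    missing_any = np.isnan(X).any(axis=0)
    complete = ~missing_any
    if complete.any():
        p[complete] = (w_full @ np.nan_to_num(X[:, complete])) / (2.0 * denom_full)
    if missing_any.any():
        A22 = np.linalg.inv(A22_inv)
        # Group SNPs by missingness pattern so each observed sub-block of A22
        # is factorized once.
        patterns: dict[bytes, list[int]] = {}
        isnan = np.isnan(X)
        for j in np.flatnonzero(missing_any):
            patterns.setdefault(isnan[:, j].tobytes(), []).append(j)
        for key, js in patterns.items():
            obs = ~np.frombuffer(key, dtype=bool)
            sub = A22[np.ix_(obs, obs)]
            cf = sla.cho_factor(sub)
            w = sla.cho_solve(cf, np.ones(obs.sum()))
            denom = float(w.sum())
            p[js] = (w @ X[np.ix_(obs, np.array(js))]) / (2.0 * denom)
    return np.clip(p, clamp_lo, clamp_hi)


# ------------------------------------------------------------------ G and H

def center_genotypes(g: GenotypeMatrix, p: np.ndarray) -> np.ndarray:
    """``Z = M - 2p`` with missing gene contents imputed to ``2p`` (zero)."""
    Z = g.X - 2.0 * p[None, :]
    Z[np.isnan(Z)] = 0.0
    return Z


def build_G(
    g: GenotypeMatrix,
    p: np.ndarray,
    d: np.ndarray | None = None,
) -> np.ndarray:
    """VanRaden genomic relationship matrix with optional SNP weights.

    ``G = Z diag(d) Z' / (2 sum_i d_i p_i (1-p_i))``.  The weighted
    denominator keeps the trace scale of ``G`` stable as weights change
    across weighted-ssGBLUP iterations.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (g.n_snps,):
        raise GenomicError("allele frequency vector does not match SNP count")
    if d is None:
        d = np.ones(g.n_snps)
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise GenomicError("SNP weights must be strictly positive")
    if np.isnan(g.X).all(axis=0).any():
        raise GenomicError("all-missing SNP present; run qc_filter first")
    Z = center_genotypes(g, p)
    denom = 2.0 * float(np.sum(d * p * (1.0 - p)))
    if denom <= 0:
        raise GenomicError("zero heterozygosity denominator")
    return (Z * d[None, :]) @ Z.T / denom


def build_G_lambda(p: np.ndarray, d: np.ndarray | None = None) -> float:
    """The variance-ratio constant ``lambda = 1 / (2 sum d_i p_i (1-p_i))``.

    This is the scalar that maps the weighted gene-content cross-products
    onto ``G``; it is also the shrinkage constant used when backsolving
    GEBV into SNP effects.
    """
    if d is None:
        d = np.ones_like(p)
    return 1.0 / (2.0 * float(np.sum(d * p * (1.0 - p))))


def blend_G(G0: np.ndarray, A22: np.ndarray, tau: float = 0.05) -> np.ndarray:
    """``G = (1 - tau) G0 + tau A22`` — numerical invertibility safeguard."""
    if not (0.0 <= tau < 1.0):
        raise GenomicError(f"tau must be in [0, 1), got {tau}")
    if tau == 0.0:
        return G0
    if G0.shape != A22.shape:
        raise GenomicError("G and A22 dimensions differ")
    return (1.0 - tau) * G0 + tau * A22


def build_H_inverse(
    A_inv: sp.spmatrix,
    G_inv: np.ndarray,
    A22_inv: np.ndarray,
    genotyped_index: np.ndarray,
) -> sp.csc_matrix:
    """Single-step ``H^-1``: ``A^-1`` plus ``G^-1 - A22^-1`` on the genotyped block."""
    n = A_inv.shape[0]
    genotyped_index = np.asarray(genotyped_index, dtype=np.int64)
    ng = len(genotyped_index)
    if ng == 0:
        return sp.csc_matrix(A_inv)
    if G_inv.shape != (ng, ng) or A22_inv.shape != (ng, ng):
        raise GenomicError("G_inv / A22_inv do not match genotyped index length")
    delta = G_inv - A22_inv
    rows = np.repeat(genotyped_index, ng)
    cols = np.tile(genotyped_index, ng)
    corr = sp.coo_matrix((delta.ravel(), (rows, cols)), shape=(n, n))
    return (sp.csc_matrix(A_inv) + corr.tocsc())
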