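"""Single-step GWAS by backsolving GEBV, and weighted ssGBLUP iteration.

GEBVs of genotyped animals are mapped onto SNP effects through

    a_hat = lambda * D Z' G^-1 u_hat,

with ``lambda = 1 / (2 sum_i d_i p_i (1 - p_i))`` — the shrinkage constant
implied by the construction of ``G`` so that ``Z D Z' lambda = G`` and the
backsolve is the exact inverse map (checked numerically when no blending is
applied).  Per-SNP sampling variances follow the prediction-error route:

    Var(a_hat) = lambda^2 D Z' G^-1 Cov(u_hat_g) G^-1 Z D,

with ``Cov(u_hat_g) = sigma2_u G - C^uu`` (the genotyped block of the
inverse mixed-model coefficient matrix), giving two-sided normal p-values.
Nonlinear-A SNP weights ``d_i = CT^(|a_i|/sd(a) - 2)`` feed iterated
weighted ssGBLUP; iteration 1 is always the unweighted run.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import genomic, mixed_model as mm


class GwasError(ValueError):
    pass


def backsolve_snp_effects(
    u_hat_genotyped: np.ndarray,
    G_inv: np.ndarray,
    Z_centered: np.ndarray,
    d: np.ndarray | None = None,
    lam: float | None = None,
) -> np.ndarray:
    """SNP effects ``a_hat = lam * D Z' G^-1 u_hat`` (one trait at a time)."""
    u = np.asarray(u_hat_genotyped, dtype=float)
    ng, nsnp = Z_centered.shape
    if u.shape != (ng,) or G_inv.shape != (ng, ng):
        raise GwasError("dimension mismatch between u_hat, G_inv and Z")
    if d is None:
        d = np.ones(nsnp)
    if lam is None:
        raise GwasError("lambda (variance-ratio constant) is required")
    return lam * d * (Z_centered.T @ (G_inv @ u))


def snp_effect_variances(
    G_inv: np.ndarray,
    Z_centered: np.ndarray,
    cov_u_g: np.ndarray,
    d: np.ndarray | None = None,
    lam: float | None = None,
) -> np.ndarray:
    """Diagonal of ``lam^2 D Z' G^-1 Cov(u_g) G^-1 Z D``."""
    nsnp = Z_centered.shape[1]
    if d is None:
        d = np.ones(nsnp)
    B = G_inv @ Z_centered  # ng x nsnp
    var = lam**2 * d**2 * np.einsum("ij,ik,kj->j", B, cov_u_g, B)
    return var


def snp_pvalues(effects: np.ndarray, var_of_effects: np.ndarray) -> pd.DataFrame:
    """Two-sided normal p-values (and -log10 p) per SNP.

    Non-positive variances arising from numerical error are clipped to
    machine epsilon with a warning.
    """
    a = np.asarray(effects, dtype=float)
    v = np.asarray(var_of_effects, dtype=float)
    if np.any(v <= 0):
        warnings.warn(
            f"{int(np.sum(v <= 0))} non-positive SNP-effect variances clipped",
            RuntimeWarning,
        )
        v = np.maximum(v, np.finfo(float).eps)
    sd = np.sqrt(v)
    z = np.where(sd > 0, a / sd, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {"effect": a, "sd": sd, "z": z, "p": p, "neglog10p": -np.log10(p)}
    )


def bonferroni_threshold(n_snp: int, alpha: float = 0.05) -> float:
    """Family-wise -log10 significance cutoff ``-log10(alpha / n_snp)``."""
    if n_snp < 1:
        raise GwasError("n_snp must be >= 1")
    if not (0 < alpha < 1):
        raise GwasError("alpha must be in (0, 1)")
    return float(-np.log10(alpha / n_snp))


def window_variance(
    effects: np.ndarray,
    Z_centered: np.ndarray,
    chrom: np.ndarray,
    total_genetic_variance: float,
    window_size: int = 20,
) -> pd.DataFrame:
    """Percent additive variance per sliding window of adjacent SNPs.

    SNPs must already be ordered by (chromosome, position).  Within each
    chromosome, every window of ``window_size`` adjacent SNPs (step 1)
    contributes ``var_animals(sum_i z_i a_i) / sigma2_u * 100``.  A
    chromosome shorter than the window yields a single truncated window
    with a warning.
    """
    if total_genetic_variance <= 0:
        raise GwasError("total genetic variance must be positive")
    a = np.asarray(effects, dtype=float)
    rows = []
    for c in pd.unique(pd.Series(chrom)):
        sel = np.flatnonzero(np.asarray(chrom) == c)
        contrib = Z_centered[:, sel] * a[sel][None, :]
        csum = np.cumsum(contrib, axis=1)
        k = len(sel)
        if k < window_size:
            warnings.warn(
                f"chromosome {c} has {k} SNPs < window size {window_size}; "
                "using one truncated window",
                RuntimeWarning,
            )
            starts = [0]
            width = k
        else:
            starts = range(k - window_size + 1)
            width = window_size
        for s in starts:
            e = s + width
            g = csum[:, e - 1] - (csum[:, s - 1] if s > 0 else 0.0)
            pct = float(np.var(g, ddof=1) / total_genetic_variance * 100.0)
            rows.append(
                {"chrom": c, "first_snp": int(sel[s]), "last_snp": int(sel[e - 1]),
                 "pct_variance": pct}
            )
    return pd.DataFrame(rows)


def nonlinearA_weights(
    effects: np.ndarray, CT: float, cap: float = 5.0
) -> np.ndarray:
    """Nonlinear-A SNP weights ``d_i = CT^(min(|a_i|/sd(a), cap) - 2)``.

    With all effects equal (sd = 0) every weight is 1.  ``CT`` must exceed 1
    (CT = 1 would be the unweighted model).
    """
    if CT <= 1.0:
        raise GwasError(f"CT must be > 1, got {CT}")
    a = np.abs(np.asarray(effects, dtype=float))
    sd = float(np.std(np.asarray(effects, dtype=float), ddof=0))
    if sd <= 1e-12 * max(1.0, a.max(initial=0.0)):
        return np.ones_like(a)
    expo = np.minimum(a / sd, cap) - 2.0
    return CT**expo


@dataclass
class WssgblupIteration:
    iteration: int
    weights: np.ndarray
    effects: dict            # trait -> SNP effect vector
    solutions: "mm.Solutions"
    validation: object | None = None


def wssgblup_iterate(
    spec: "mm.ModelSpec",
    data: pd.DataFrame,
    ped,
    A_inv,
    A22: np.ndarray,
    A22_inv: np.ndarray,
    genotyped_index: np.ndarray,
    geno: "genomic.GenotypeMatrix",
    p: np.ndarray,
    vc: "mm.VarianceComponents",
    weight_trait: str,
    CT: float = 1.125,
    n_iter: int = 5,
    tau: float = 0.05,
    validation_hook=None,
    cap: float = 5.0,
) -> list[WssgblupIteration]:
    """Iterated weighted ssGBLUP with nonlinear-A weights.

    Iteration 1 runs with ``D = I`` (unweighted ssGBLUP); each subsequent
    iteration backsolves the genotyped animals' GEBVs of ``weight_trait``
    into SNP effects, derives nonlinear-A weights, renormalizes them to
    mean 1, rebuilds ``G`` and ``H^-1`` and re-solves the two-trait model.
    Variance components are held fixed across iterations.  An optional
    ``validation_hook(solutions)`` is evaluated and stored per iteration;
    iteration stops early (with the partial trace) if it returns NaN
    accuracy.
    """
    if weight_trait not in spec.traits:
        raise GwasError(f"unknown trait: {weight_trait}")
    nsnp = geno.n_snps
    d = np.ones(nsnp)
    out: list[WssgblupIteration] = []
    gen_ids = [ped.ids[i] for i in genotyped_index]
    for it in range(1, n_iter + 1):
        G0 = genomic.build_G(geno, p, d)
        G = genomic.blend_G(G0, A22, tau)
        G_inv = np.linalg.inv(G)
        H_inv = genomic.build_H_inverse(A_inv, G_inv, A22_inv, genotyped_index)
        system = mm.build_mme(spec, data, H_inv, vc, ped)
        sol = mm.solve_mme(system)
        lam = genomic.build_G_lambda(p, d)
        Z = genomic.center_genotypes(geno, p)
        effects = {}
        for t in spec.traits:
            u_g = sol.u.loc[gen_ids, t].to_numpy()
            effects[t] = backsolve_snp_effects(u_g, G_inv, Z, d, lam)
        rep = validation_hook(sol) if validation_hook is not None else None
        out.append(
            WssgblupIteration(iteration=it, weights=d.copy(), effects=effects,
                              solutions=sol, validation=rep)
        )
        if rep is not None and hasattr(rep, "accuracy") and np.isnan(rep.accuracy):
            warnings.warn("validation accuracy NaN; stopping weight iteration",
                          RuntimeWarning)
            break
        d_new = nonlinearA_weights(effects[weight_trait], CT, cap=cap)
        d = d_new / d_new.mean()
    return out
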