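"""Two-trait animal model with a full-sib family effect.

The model for trait ``t`` is

    y_t = X b_t + Z1 u_t + Z2 f_t + e_t,

with ``u`` the additive genetic effect (covariance ``Su (x) K`` where ``K``
is the pedigree relationship matrix ``A`` or the single-step matrix ``H``),
``f`` a common full-sib family (environmental) effect with covariance
``Sf (x) I``, and residual covariance ``Se`` acting within animal across the
two traits; animals recorded for a single trait contribute only that trait's
residual variance.

Two computational routes are provided:

* Henderson's mixed model equations, assembled sparse and solved by a direct
  factorization (or optionally conjugate gradients) -> BLUE fixed effects,
  (G)EBV and family-effect BLUPs, plus inverse-coefficient blocks on demand.
* AI-REML for the (co)variance components, working in the phenotypic
  covariance parameterisation: the records' covariance matrix ``V`` is dense
  at the scales this package targets (a few thousand records), so the
  average-information matrix, exact trace terms, and the REML log-likelihood
  come from one dense Cholesky per iteration.  An expectation-maximization
  step is used as fallback whenever an AI update leaves the parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .pedigree import Pedigree


class ModelError(ValueError):
    pass


# ------------------------------------------------------------- model spec

@dataclass
class TraitModel:
    """Fixed-effect terms for one trait.

    ``factors`` may contain interaction terms written ``"a:b"``; the first
    factor is coded with a dummy per level (absorbing the intercept), later
    factors drop their first level.  If there are no factors an explicit
    intercept is added.
    """

    covariates: list[str] = field(default_factory=list)
    factors: list[str] = field(default_factory=list)


@dataclass
class ModelSpec:
    traits: list[str]
    models: dict[str, TraitModel]
    animal_col: str = "animal"
    family_col: str = "family"

    def __post_init__(self) -> None:
        if len(self.traits) > 2:
            raise ModelError("at most two traits are supported")
        for t in self.traits:
            if t not in self.models:
                raise ModelError(f"no model given for trait {t}")


def fy_bw_default() -> ModelSpec:
    """The fillet-yield / body-weight model used throughout this package.

    FY: harvest age covariate, line, and harvest-year x slaughter-group
    interaction.  BW: age covariate, line, and hatch year.
    """
    return ModelSpec(
        traits=["fy", "bw"],
        models={
            "fy": TraitModel(
                covariates=["harvest_age"],
                factors=["line", "harvest_year:harvest_group"],
            ),
            "bw": TraitModel(covariates=["age"], factors=["line", "hatch_year"]),
        },
    )


def _factor_column(data: pd.DataFrame, term: str) -> pd.Series:
    parts = term.split(":")
    for c in parts:
        if c not in data.columns:
            raise ModelError(f"factor column missing from data: {c}")
    col = data[parts[0]].astype(str)
    for c in parts[1:]:
        col = col + "\x1f" + data[c].astype(str)
    return col


def build_design(data: pd.DataFrame, tm: TraitModel) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix with drop-first rank constraints."""
    blocks: list[np.ndarray] = []
    names: list[str] = []
    if not tm.factors:
        blocks.append(np.ones((len(data), 1)))
        names.append("intercept")
    for k, term in enumerate(tm.factors):
        col = _factor_column(data, term)
        levels = sorted(col.unique())
        use = levels if k == 0 else levels[1:]
        for lev in use:
            blocks.append((col == lev).to_numpy(dtype=float)[:, None])
            names.append(f"{term}={lev.replace(chr(31), ':')}")
    for cov in tm.covariates:
        if cov not in data.columns:
            raise ModelError(f"covariate column missing from data: {cov}")
        v = data[cov].to_numpy(dtype=float)
        blocks.append((v - np.nanmean(v))[:, None])
        names.append(cov)
    return np.hstack(blocks), names


# ------------------------------------------------------- variance components

@dataclass
class VarianceComponents:
    """2x2 additive (Su), family (Sf) and residual (Se) covariance matrices."""

    Su: np.ndarray
    Sf: np.ndarray
    Se: np.ndarray
    se: dict | None = None          # per-matrix SE arrays, if estimated
    param_cov: np.ndarray | None = None
    param_names: list[str] | None = None
    converged: bool | None = None
    n_iter: int | None = None
    loglik: float | None = None

    def __post_init__(self) -> None:
        self.Su = np.atleast_2d(np.asarray(self.Su, dtype=float))
        self.Sf = np.atleast_2d(np.asarray(self.Sf, dtype=float))
        self.Se = np.atleast_2d(np.asarray(self.Se, dtype=float))

    def validate(self, strict: bool = True) -> None:
        for name, m in (("Su", self.Su), ("Sf", self.Sf), ("Se", self.Se)):
            if not np.allclose(m, m.T):
                raise ModelError(f"{name} is not symmetric")
            w = np.linalg.eigvalsh(m)
            if strict and name == "Se" and w.min() <= 0:
                raise ModelError("Se must be positive definite")
            if w.min() < -1e-8 * max(1.0, abs(w).max()):
                raise ModelError(f"{name} is not positive semi-definite")


@dataclass
class GeneticParameters:
    h2: dict
    f2: dict
    r_g: float
    se: dict | None = None


def compute_genetic_parameters(vc: VarianceComponents, traits: Sequence[str] = ("fy", "bw")) -> GeneticParameters:
    """Heritabilities, family-variance fractions and the genetic correlation.

    ``h2_t = Su_tt / (Su_tt + Sf_tt + Se_tt)``; ``f2_t = Sf_tt / sigma2_p,t``;
    ``r_g = Su_12 / sqrt(Su_11 Su_22)``.  SEs by the delta method from the
    inverse average-information matrix when available.
    """
    nt = vc.Su.shape[0]
    traits = list(traits)[:nt]

    def stats(Su, Sf, Se):
        tot = np.diag(Su) + np.diag(Sf) + np.diag(Se)
        if np.any(tot <= 0):
            raise ModelError("zero total variance for a trait")
        h2 = np.diag(Su) / tot
        f2 = np.diag(Sf) / tot
        if nt == 2:
            denom = np.sqrt(Su[0, 0] * Su[1, 1])
            rg = Su[0, 1] / denom if denom > 0 else 0.0
        else:
            rg = np.nan
        return np.concatenate([h2, f2, [rg]])

    base = stats(vc.Su, vc.Sf, vc.Se)
    h2 = {t: float(base[i]) for i, t in enumerate(traits)}
    f2 = {t: float(base[nt + i]) for i, t in enumerate(traits)}
    rg = float(base[2 * nt])

    se = None
    if vc.param_cov is not None and vc.param_names is not None:
        # numerical delta method over the free parameters
        theta0 = _pack(vc.Su, vc.Sf, vc.Se, vc.param_names)
        J = np.zeros((len(base), len(theta0)))
        for k in range(len(theta0)):
            h = max(1e-6, 1e-6 * abs(theta0[k]))
            for sgn in (+1, -1):
                th = theta0.copy()
                th[k] += sgn * h
                # overlay the perturbed free entries on the full matrices
                Su, Sf, Se = vc.Su.copy(), vc.Sf.copy(), vc.Se.copy()
                for val, n in zip(th, vc.param_names):
                    m = {"u": Su, "f": Sf, "e": Se}[n[1]]
                    m[int(n[3]), int(n[4])] = m[int(n[4]), int(n[3])] = val
                J[:, k] += sgn * stats(Su, Sf, Se) / (2 * h)
        var = np.einsum("ij,jk,ik->i", J, vc.param_cov, J)
        sd = np.sqrt(np.maximum(var, 0.0))
        se = {
            "h2": {t: float(sd[i]) for i, t in enumerate(traits)},
            "f2": {t: float(sd[nt + i]) for i, t in enumerate(traits)},
            "r_g": float(sd[2 * nt]),
        }
    return GeneticParameters(h2=h2, f2=f2, r_g=rg, se=se)


# parameter packing: free parameters of the three covariance matrices
def _param_names(
    nt: int, free_cov: Sequence[str], fixed: Sequence[str] = ()
) -> list[str]:
    names = []
    for comp in ("u", "f", "e"):
        if comp in fixed:
            continue
        for i in range(nt):
            for j in range(i, nt):
                if i != j and comp not in free_cov:
                    continue
                names.append(f"S{comp}_{i}{j}")
    return names


def _pack(Su, Sf, Se, names) -> np.ndarray:
    mats = {"u": Su, "f": Sf, "e": Se}
    return np.array([mats[n[1]][int(n[3]), int(n[4])] for n in names])


def _unpack(theta, names, nt) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mats = {c: np.zeros((nt, nt)) for c in "ufe"}
    for val, n in zip(theta, names):
        c, i, j = n[1], int(n[3]), int(n[4])
        mats[c][i, j] = val
        mats[c][j, i] = val
    return mats["u"], mats["f"], mats["e"]


# --------------------------------------------------------------- MME route

@dataclass
class MMESystem:
    C: sp.csc_matrix
    rhs: np.ndarray
    spec: ModelSpec
    ped: Pedigree
    fixed_names: dict
    family_levels: list[str]
    slices: dict            # name -> slice into the unknown vector
    data_index: pd.DataFrame  # animal/family bookkeeping for the records


def _record_frame(spec: ModelSpec, data: pd.DataFrame, ped: Pedigree) -> pd.DataFrame:
    if spec.animal_col not in data.columns or spec.family_col not in data.columns:
        raise ModelError(
            f"data must have '{spec.animal_col}' and '{spec.family_col}' columns"
        )
    df = data.copy()
    df[spec.animal_col] = df[spec.animal_col].astype(str)
    df["_animal_idx"] = ped.index_of(df[spec.animal_col])
    fams = sorted(df[spec.family_col].astype(str).unique())
    fam_idx = {f: i for i, f in enumerate(fams)}
    df["_family_idx"] = df[spec.family_col].astype(str).map(fam_idx)
    df.attrs["family_levels"] = fams
    return df


def build_mme(
    spec: ModelSpec,
    data: pd.DataFrame,
    K_inv: sp.spmatrix,
    vc: VarianceComponents,
    ped: Pedigree,
) -> MMESystem:
    """Assemble the two-trait mixed model equations.

    ``K_inv`` is ``A^-1`` (PBLUP) or ``H^-1`` (ssGBLUP) over the full
    pedigree.  The coefficient matrix carries ``Su^-1 (x) K_inv`` for the
    additive effects and ``Sf^-1 (x) I`` for the family effects; residuals
    are absorbed per record pattern (single- or both-trait records).
    """
    vc.validate()
    nt = len(spec.traits)
    df = _record_frame(spec, data, ped)
    fams = df.attrs["family_levels"]
    n, nf, nd = len(ped), len(fams), len(df)

    # fixed-effect designs per trait, built from the rows where the trait is
    # observed (levels seen only in unrecorded rows would give empty
    # equations) and scattered back to full-length row blocks
    designs, names = {}, {}
    for t in spec.traits:
        if t not in df.columns:
            raise ModelError(f"trait column missing from data: {t}")
        obs_t = df[t].notna().to_numpy()
        if not obs_t.any():
            # recordless trait: no fixed effects, equations carry only priors
            designs[t], names[t] = np.zeros((nd, 0)), []
            continue
        X_sub, names[t] = build_design(df[obs_t], spec.models[t])
        X_full = np.zeros((nd, X_sub.shape[1]))
        X_full[obs_t] = X_sub
        designs[t] = X_full
    p = {t: designs[t].shape[1] for t in spec.traits}

    # unknown layout: b_t blocks, then u_t blocks, then f_t blocks
    slices: dict = {}
    off = 0
    for t in spec.traits:
        slices[f"b_{t}"] = slice(off, off + p[t])
        off += p[t]
    for t in spec.traits:
        slices[f"u_{t}"] = slice(off, off + n)
        off += n
    for t in spec.traits:
        slices[f"f_{t}"] = slice(off, off + nf)
        off += nf
    N = off

    # per-trait observation indicator and sparse W_t
    obs = np.column_stack(
        [df[t].notna().to_numpy() if t in df.columns else np.zeros(nd, bool) for t in spec.traits]
    )
    y = np.column_stack(
        [
            np.nan_to_num(df[t].to_numpy(dtype=float)) if t in df.columns else np.zeros(nd)
            for t in spec.traits
        ]
    )

    Se = vc.Se[:nt, :nt]
    # residual weights per record row and trait pair
    Wgt = np.zeros((nd, nt, nt))
    if nt == 1:
        Wgt[obs[:, 0], 0, 0] = 1.0 / Se[0, 0]
    else:
        both = obs[:, 0] & obs[:, 1]
        only = [obs[:, t] & ~obs[:, 1 - t] for t in range(2)]
        if both.any():
            Wgt[both] = np.linalg.inv(Se)
        for t in range(2):
            Wgt[only[t], t, t] = 1.0 / Se[t, t]

    W = []
    rows = np.arange(nd)
    for ti, t in enumerate(spec.traits):
        Xb = sp.csr_matrix(designs[t])
        Zu = sp.csr_matrix(
            (np.ones(nd), (rows, df["_animal_idx"].to_numpy())), shape=(nd, n)
        )
        Zf = sp.csr_matrix(
            (np.ones(nd), (rows, df["_family_idx"].to_numpy())), shape=(nd, nf)
        )
        blocks = []
        for tt in spec.traits:
            blocks.append(Xb if tt == t else sp.csr_matrix((nd, p[tt])))
        for tt in spec.traits:
            blocks.append(Zu if tt == t else sp.csr_matrix((nd, n)))
        for tt in spec.traits:
            blocks.append(Zf if tt == t else sp.csr_matrix((nd, nf)))
        W.append(sp.hstack(blocks, format="csr"))

    C = sp.csc_matrix((N, N))
    rhs = np.zeros(N)
    for a in range(nt):
        for b in range(nt):
            D = sp.diags(Wgt[:, a, b])
            C = C + W[a].T @ D @ W[b]
            rhs += W[a].T @ (Wgt[:, a, b] * y[:, b])

    if np.linalg.det(vc.Sf[:nt, :nt]) <= 0 or np.linalg.det(vc.Su[:nt, :nt]) <= 0:
        raise ModelError("Su and Sf must be positive definite to assemble the MME")
    Su_inv = np.linalg.inv(vc.Su[:nt, :nt])
    Sf_inv = np.linalg.inv(vc.Sf[:nt, :nt])
    Kc = sp.csc_matrix(K_inv)
    # prior precision: zero for fixed effects, Su^-1 (x) K^-1 for the
    # (contiguous, trait-major) u blocks, Sf^-1 (x) I for the f blocks
    p_total = sum(p.values())
    prior = sp.block_diag(
        [
            sp.csc_matrix((p_total, p_total)),
            sp.kron(Su_inv, Kc, format="csc"),
            sp.kron(Sf_inv, sp.identity(nf, format="csc"), format="csc"),
        ],
        format="csc",
    )
    C = C + prior

    return MMESystem(
        C=sp.csc_matrix(C),
        rhs=rhs,
        spec=spec,
        ped=ped,
        fixed_names=names,
        family_levels=fams,
        slices=slices,
        data_index=df[[spec.animal_col, spec.family_col, "_animal_idx", "_family_idx"]],
    )


@dataclass
class Solutions:
    b: dict                 # trait -> pd.Series of fixed-effect estimates
    u: pd.DataFrame         # animals x traits (G)EBV
    f: pd.DataFrame         # families x traits
    _lu: object = None
    _slices: dict | None = None

    def inverse_block(self, rows: np.ndarray) -> np.ndarray:
        """Selected columns/rows of the inverse coefficient matrix.

        ``rows`` are absolute indices into the unknown vector; returns the
        dense symmetric block ``C^-1[rows, rows]``.
        """
        if self._lu is None:
            raise ModelError("system was solved iteratively; no factor retained")
        E = np.zeros((self._lu.shape[0], len(rows)))
        E[rows, np.arange(len(rows))] = 1.0
        X = self._lu.solve(E)
        return X[rows]


def solve_mme(system: MMESystem, method: str = "direct", tol: float = 1e-10,
              maxiter: int = 20000) -> Solutions:
    """Solve the assembled equations.

    ``direct`` (default) factorizes the sparse symmetric system with LU and
    retains the factor so inverse-coefficient blocks can be extracted later;
    ``cg`` runs conjugate gradients with a Jacobi preconditioner.
    """
    C, rhs = system.C, system.rhs
    lu = None
    if method == "direct":
        lu = spla.splu(C)
        x = lu.solve(rhs)
    elif method == "cg":
        M = sp.diags(1.0 / C.diagonal())
        x, info = spla.cg(C, rhs, rtol=tol, maxiter=maxiter, M=M)
        if info != 0:
            res = float(np.linalg.norm(C @ x - rhs))
            raise ModelError(f"conjugate gradients did not converge (residual {res:.3e})")
    else:
        raise ModelError(f"unknown solver method: {method}")

    spec = system.spec
    b = {
        t: pd.Series(x[system.slices[f"b_{t}"]], index=system.fixed_names[t])
        for t in spec.traits
    }
    u = pd.DataFrame(
        {t: x[system.slices[f"u_{t}"]] for t in spec.traits}, index=system.ped.ids
    )
    f = pd.DataFrame(
        {t: x[system.slices[f"f_{t}"]] for t in spec.traits},
        index=system.family_levels,
    )
    return Solutions(b=b, u=u, f=f, _lu=lu, _slices=system.slices)


def adjust_phenotypes(
    data: pd.DataFrame, sol: Solutions, spec: ModelSpec
) -> pd.DataFrame:
    """``y* = y - X b - Z2 f``: phenotypes stripped of fixed and family effects.

    Returns a frame indexed like ``data`` with one adjusted column per trait
    (NaN where the trait was not recorded).
    """
    out = pd.DataFrame(index=data.index)
    out[spec.animal_col] = data[spec.animal_col].astype(str)
    fam = data[spec.family_col].astype(str)
    for t in spec.traits:
        yt = data[t].to_numpy(dtype=float)
        obs = ~np.isnan(yt)
        sub = data[obs]
        X, names = build_design(sub, spec.models[t])
        bt = sol.b[t]
        if list(bt.index) != names:
            missing = [n for n in names if n not in bt.index]
            if missing:
                raise ModelError(f"unestimated fixed-effect levels for {t}: {missing}")
            bt = bt[names]
        fixed = X @ bt.to_numpy()
        fam_eff = sol.f[t].reindex(fam[obs]).to_numpy()
        if np.isnan(fam_eff).any():
            bad = sorted(set(fam[obs][np.isnan(fam_eff)]))[:5]
            raise ModelError(
                f"records reference family levels without estimates for {t}: {bad}"
            )
        vals = np.full(len(data), np.nan)
        vals[obs] = yt[obs] - fixed - fam_eff
        out[t] = vals
    return out


# ------------------------------------------------------------- AI-REML

def _component_blocks(spec, df):
    """Per-trait record arrays (animal index, family index, value, row)."""
    recs = []
    for ti, t in enumerate(spec.traits):
        m = df[df[t].notna()]
        recs.append(
            (
                m["_animal_idx"].to_numpy(),
                m["_family_idx"].to_numpy(),
                m[t].to_numpy(dtype=float),
                m.index.to_numpy(),
            )
        )
    return recs


def estimate_vc_aireml(
    spec: ModelSpec,
    data: pd.DataFrame,
    K_inv: sp.spmatrix,
    start: VarianceComponents,
    ped: Pedigree,
    max_iter: int = 200,
    tol: float = 1e-8,
    free_cov: Sequence[str] = ("u", "f", "e"),
    fix_components: Sequence[str] = (),
    verbose: bool = False,
) -> tuple[VarianceComponents, list[dict]]:
    """AI-REML estimates of ``Su, Sf, Se`` with an EM fallback.

    Works on the dense covariance matrix of the observed records,

        V = Su[t,t'] A[a,a'] + Sf[t,t'] 1(fam=fam') + Se[t,t'] 1(animal=animal'),

    whose Cholesky factor per iteration yields the REML log-likelihood, the
    exact trace terms of the score, and the average-information matrix from
    nine working variates.  Off-diagonal family/residual covariances can be
    fixed at zero by omitting ``"f"`` / ``"e"`` from ``free_cov``.

    Convergence: relative parameter change < ``tol``.  Returns the estimates
    (with SEs from the inverse AI matrix) and a per-iteration trace.
    """
    start.validate()
    nt = len(spec.traits)
    df = _record_frame(spec, data, ped)

    # relationship sub-matrix among recorded animals (from sparse K^-1)
    rec_animals = np.unique(df["_animal_idx"].to_numpy())
    lu = spla.splu(sp.csc_matrix(K_inv))
    E = np.zeros((len(ped), len(rec_animals)))
    E[rec_animals, np.arange(len(rec_animals))] = 1.0
    K_cols = lu.solve(E)
    K_sub = K_cols[rec_animals]
    remap = np.full(len(ped), -1)
    remap[rec_animals] = np.arange(len(rec_animals))

    recs = _component_blocks(spec, df)
    anim = np.concatenate([remap[r[0]] for r in recs])
    fam = np.concatenate([r[1] for r in recs])
    yv = np.concatenate([r[2] for r in recs])
    trait = np.concatenate(
        [np.full(len(r[0]), ti) for ti, r in enumerate(recs)]
    )
    n_rec = len(yv)

    # standardize each trait to unit phenotypic variance: keeps the AI
    # geometry well conditioned when trait scales differ by orders of
    # magnitude; everything is transformed back at the end
    scale = np.array([np.std(r[2], ddof=1) for r in recs])
    scale[scale == 0] = 1.0
    yv = yv / scale[trait]
    blocks = []
    o = 0
    for r in recs:
        blocks.append(slice(o, o + len(r[0])))
        o += len(r[0])

    nf = int(fam.max()) + 1 if len(fam) else 0
    n_anim_lvl = len(ped)

    # fixed-effect design, block diagonal over traits
    Xb = []
    for ti, t in enumerate(spec.traits):
        sub = df[df[t].notna()]
        Xt, _ = build_design(sub, spec.models[t])
        Xb.append(Xt)
    X = sla.block_diag(*Xb)
    # guard against rank deficiency in the fixed part
    qx, rx, px = sla.qr(X, mode="economic", pivoting=True)
    rank = int(np.sum(np.abs(np.diag(rx)) > 1e-9 * abs(rx[0, 0])))
    if rank < X.shape[1]:
        X = X[:, np.sort(px[:rank])]
    p_fix = X.shape[1]

    K_bb = {}  # K blocks between trait record sets
    for a in range(nt):
        for b in range(nt):
            K_bb[a, b] = K_sub[np.ix_(anim[blocks[a]], anim[blocks[b]])]
    famEq = {}
    animEq = {}
    for a in range(nt):
        for b in range(nt):
            famEq[a, b] = (fam[blocks[a]][:, None] == fam[blocks[b]][None, :])
            animEq[a, b] = (anim[blocks[a]][:, None] == anim[blocks[b]][None, :])

    names = _param_names(nt, free_cov, fix_components)
    D = np.outer(scale, scale)  # parameter scale transform per (i, j) pair
    start_scaled = {
        "u": start.Su[:nt, :nt] / D,
        "f": start.Sf[:nt, :nt] / D,
        "e": start.Se[:nt, :nt] / D,
    }
    theta = _pack(start_scaled["u"], start_scaled["f"], start_scaled["e"], names)
    pairs = [(n[1], int(n[3]), int(n[4])) for n in names]
    npar = len(names)

    def unpack_full(th):
        """Free parameters from ``th``; fixed components from the start values."""
        Su, Sf, Se = _unpack(th, names, nt)
        mats = {"u": Su, "f": Sf, "e": Se}
        for c in fix_components:
            mats[c] = start_scaled[c]
        return mats["u"], mats["f"], mats["e"]

    floor = 1e-10

    def build_V(Su, Sf, Se):
        V = np.empty((n_rec, n_rec))
        S = {"u": Su, "f": Sf, "e": Se}
        for a in range(nt):
            for b in range(nt):
                blk = Su[a, b] * K_bb[a, b]
                blk = blk + Sf[a, b] * famEq[a, b]
                if Se[a, b] != 0.0:
                    blk = blk + Se[a, b] * animEq[a, b]
                V[blocks[a], blocks[b]] = blk
        return V

    def project(S):
        w, U = np.linalg.eigh(S)
        return U @ np.diag(np.maximum(w, floor)) @ U.T

    def _factor(theta_vec):
        Su, Sf, Se = unpack_full(theta_vec)
        V = build_V(Su, Sf, Se)
        cf = sla.cho_factor(V, lower=True, check_finite=False)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        W = sla.cho_solve(cf, X, check_finite=False)       # V^-1 X
        XtViX = X.T @ W
        cfx = sla.cho_factor(XtViX)
        logdetX = 2.0 * float(np.sum(np.log(np.diag(cfx[0]))))
        Viy = sla.cho_solve(cf, yv, check_finite=False)
        Xy = W.T @ yv
        beta = sla.cho_solve(cfx, Xy)
        yPy = float(yv @ Viy - Xy @ beta)
        ll = -0.5 * (logdetV + logdetX + yPy)
        return ll, cf, cfx, W, Viy, Xy

    def loglik_only(theta_vec):
        """Restricted log-likelihood via Cholesky solves (no dense inverse)."""
        f = _factor(theta_vec)
        return f[0], f

    def _P_from_factor(f):
        """Projection matrix P and Py from a retained factorization."""
        _, cf, cfx, W, Viy, Xy = f
        Vi, info = sla.lapack.dpotri(cf[0], lower=True)
        if info != 0:
            raise np.linalg.LinAlgError("dpotri failed")
        Vi = np.tril(Vi) + np.tril(Vi, -1).T
        P = Vi - W @ sla.cho_solve(cfx, W.T)
        Py = Viy - W @ sla.cho_solve(cfx, Xy)
        return P, Py

    def reml_quantities(theta_vec):
        ll, f = loglik_only(theta_vec)
        P, Py = _P_from_factor(f)
        return ll, P, Py

    def score_ai_em(theta_vec, P, q):
        """Score vector, AI matrix, and raw (Q,T) pair tables per component."""
        # family / animal aggregations of q per trait
        s_fam = np.zeros((nt, nf))
        v_anim = np.zeros((nt, n_anim_lvl))
        for a in range(nt):
            np.add.at(s_fam[a], fam[blocks[a]], q[blocks[a]])
            np.add.at(v_anim[a], anim[blocks[a]], q[blocks[a]])

        def qQq(comp, a, b):
            if comp == "u":
                return float(q[blocks[a]] @ (K_bb[a, b] @ q[blocks[b]]))
            if comp == "f":
                return float(s_fam[a] @ s_fam[b])
            return float(v_anim[a] @ v_anim[b])

        def trP(comp, a, b):
            Pab = P[blocks[a], blocks[b]]
            if comp == "u":
                return float(np.sum(Pab * K_bb[a, b]))
            if comp == "f":
                return float(np.sum(Pab * famEq[a, b]))
            return float(np.sum(Pab * animEq[a, b]))

        score = np.zeros(npar)
        G = np.zeros((n_rec, npar))
        Q = {c: np.zeros((nt, nt)) for c in "ufe"}
        T = {c: np.zeros((nt, nt)) for c in "ufe"}
        for c in "ufe":
            for a in range(nt):
                for b in range(a, nt):
                    Q[c][a, b] = Q[c][b, a] = qQq(c, a, b)
                    T[c][a, b] = T[c][b, a] = trP(c, a, b)
        for k, (c, a, b) in enumerate(pairs):
            mult = 1.0 if a == b else 2.0
            score[k] = -0.5 * (mult * T[c][a, b] - mult * Q[c][a, b])
            # working variate dV_k @ q
            if c == "u":
                G[blocks[a], k] += K_bb[a, b] @ q[blocks[b]]
                if a != b:
                    G[blocks[b], k] += K_bb[b, a] @ q[blocks[a]]
            elif c == "f":
                G[blocks[a], k] += s_fam[b][fam[blocks[a]]]
                if a != b:
                    G[blocks[b], k] += s_fam[a][fam[blocks[b]]]
            else:
                G[blocks[a], k] += v_anim[b][anim[blocks[a]]]
                if a != b:
                    G[blocks[b], k] += v_anim[a][anim[blocks[b]]]
        AI = 0.5 * (G.T @ (P @ G))
        return score, AI, Q, T

    def em_step(theta_vec, Q, T):
        Su, Sf, Se = unpack_full(theta_vec)
        q_lvl = {"u": float(n_anim_lvl), "f": float(max(nf, 1))}
        new = {}
        for c, S in (("u", Su), ("f", Sf)):
            new[c] = S + (S @ (Q[c] - T[c]) @ S) / q_lvl[c]
        # residual: per-pair record counts
        n_pair = np.zeros((nt, nt))
        for a in range(nt):
            for b in range(nt):
                n_pair[a, b] = max(float(np.sum(animEq[a, b])), 1.0)
        new["e"] = Se + (Se @ (Q["e"] - T["e"]) @ Se) / n_pair
        new["e"] = 0.5 * (new["e"] + new["e"].T)
        th = theta.copy()
        for k, (c, a, b) in enumerate(pairs):
            th[k] = new[c][a, b]
        return th

    is_diag = np.array([a == b for (_, a, b) in pairs])
    boundary_eps = 1e-7  # on the standardized (unit phenotypic variance) scale

    def repair(th):
        """Clip correlations to +-0.999 and eigen-project each matrix PSD."""
        Su, Sf, Se = unpack_full(th)
        out = []
        for S in (Su, Sf, Se):
            S = S.copy()
            for a in range(nt):
                S[a, a] = max(S[a, a], floor)
            for a in range(nt):
                for b in range(a + 1, nt):
                    lim = 0.999 * np.sqrt(S[a, a] * S[b, b])
                    S[a, b] = S[b, a] = np.clip(S[a, b], -lim, lim)
            out.append(project(S))
        return _pack(out[0], out[1], out[2], names)

    def optimize(theta):
      trace: list[dict] = []
      ll, P, q = reml_quantities(theta)
      converged = False
      it = 0
      prev_step = None
      lm = 0.1  # Levenberg-Marquardt damping on the AI matrix, adapted per step
      for it in range(1, max_iter + 1):
            score, AI, Q, T = score_ai_em(theta, P, q)
            # active set: variances pinned at the boundary with an outward score
            # are frozen so they cannot corrupt the step direction
            free = ~(is_diag & (theta <= boundary_eps) & (score < 0.0))
            dAI = np.maximum(np.diag(AI)[free], 1e-12)

            def try_candidate(th):
                th = repair(th)
                try:
                    ll_new, f = loglik_only(th)
                except np.linalg.LinAlgError:
                    return None
                if ll_new > ll - 1e-9 * max(1.0, abs(ll)):
                    return th, ll_new, f
                return None

            accepted = None
            if it <= 2:
                # EM warmup: stabilizes wild starting values cheaply
                got = try_candidate(em_step(theta, Q, T))
                if got:
                    accepted = ("em",) + got
            if accepted is None:
                # damped AI: the likelihood is often non-concave along weakly
                # identified directions, where an undamped AI step overshoots;
                # the damping shrinks toward a scaled-gradient step and adapts
                for attempt in range(9):
                    delta = np.zeros(npar)
                    try:
                        delta[free] = np.linalg.solve(
                            AI[np.ix_(free, free)] + lm * np.diag(dAI), score[free]
                        )
                    except np.linalg.LinAlgError:
                        delta[free] = score[free] / dAI
                    # no variance may shrink more than 10x in one step
                    capm = is_diag & (theta + delta < theta / 10.0)
                    delta[capm] = theta[capm] / 10.0 - theta[capm]
                    got = try_candidate(theta + delta)
                    if got:
                        accepted = (f"ai(lm={lm:.1e})", ) + got
                        lm = max(lm / 5.0, 1e-9)
                        break
                    lm *= 10.0
            if accepted is None:
                # last resort: a plain EM step
                got = try_candidate(em_step(theta, Q, T))
                if got:
                    accepted = ("em",) + got
            if accepted is None:
                # nothing improves the likelihood: numerical stationarity
                converged = True
                break
            kind, th_new, ll_new, fac = accepted

            # Aitken extrapolation: pure AI tail steps shrink geometrically, so
            # when two consecutive steps are aligned and contracting, jump to
            # the summed geometric series and keep the jump if it helps
            step_now = th_new - theta
            if kind.startswith("ai") and prev_step is not None:
                n_now = np.linalg.norm(step_now)
                n_prev = np.linalg.norm(prev_step)
                if n_prev > 0 and n_now > 0:
                    r = n_now / n_prev
                    cosang = float(step_now @ prev_step) / (n_now * n_prev)
                    if 0.1 < r < 0.97 and cosang > 0.9:
                        got = try_candidate(th_new + step_now * r / (1.0 - r))
                        if got and got[1] > ll_new:
                            th_acc, ll_acc, f_acc = got
                            kind += "+aitken"
                            th_new, ll_new, fac = th_acc, ll_acc, f_acc
                            step_now = th_new - theta
            prev_step = step_now

            rel = np.max(np.abs(th_new - theta) / (np.abs(theta) + 1e-8 * np.max(np.abs(theta))))
            trace.append({"iter": it, "loglik": ll_new, "step": kind, "rel_change": rel})
            if verbose:
                print(f"  it {it:3d} [{kind}] logL={ll_new:.6f} rel={rel:.2e}")
            theta = th_new
            small_gain = (ll_new - ll) < 1e-9 * max(1.0, abs(ll))
            ll = ll_new
            P, q = _P_from_factor(fac)
            if rel < tol or (it > 3 and small_gain and rel < 1e-6):
                converged = True
                break

      return theta, ll, P, q, converged, it, trace

    theta, ll, P, q, converged, it, trace = optimize(theta)

    def pinned(th):
        Su_, Sf_, Se_ = unpack_full(th)
        for S in (Su_, Sf_, Se_):
            for a in range(nt):
                for b in range(a + 1, nt):
                    denom = np.sqrt(max(S[a, a] * S[b, b], 1e-300))
                    if abs(S[a, b]) / denom >= 0.985:
                        return True
        return False

    # a correlation pinned at its clip limit (or non-convergence) marks a
    # suspect boundary mode; retry from a neutral split of the (unit)
    # phenotypic variance and keep the higher-likelihood solution
    if pinned(theta) or not converged:
        theta2 = _pack(0.4 * np.eye(nt), 0.1 * np.eye(nt), 0.5 * np.eye(nt), names)
        try:
            theta_b, ll_b, P_b, q_b, conv_b, it_b, trace_b = optimize(theta2)
            better = ll_b > ll + 1e-6 * max(1.0, abs(ll))
            if better or (not converged and conv_b and ll_b >= ll - 1e-6 * max(1.0, abs(ll))):
                theta, ll, P, q, converged, it = theta_b, ll_b, P_b, q_b, conv_b, it_b
                trace = trace + [dict(t, restart=True) for t in trace_b]
        except np.linalg.LinAlgError:
            pass

    Su, Sf, Se = unpack_full(theta)
    score, AI, _, _ = score_ai_em(theta, P, q)
    # undo the per-trait standardization
    par_scale = np.array([D[a, b] for (_, a, b) in pairs])
    Su, Sf, Se = Su * D, Sf * D, Se * D
    try:
        pcov = np.linalg.inv(AI) * np.outer(par_scale, par_scale)
        sds = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    except np.linalg.LinAlgError:
        pcov, sds = None, np.full(npar, np.nan)
    se = {"Su": np.zeros((nt, nt)), "Sf": np.zeros((nt, nt)), "Se": np.zeros((nt, nt))}
    key = {"u": "Su", "f": "Sf", "e": "Se"}
    for k, (c, a, b) in enumerate(pairs):
        se[key[c]][a, b] = se[key[c]][b, a] = sds[k]
    vc = VarianceComponents(
        Su=Su, Sf=Sf, Se=Se, se=se, param_cov=pcov, param_names=names,
        converged=converged, n_iter=it, loglik=ll,
    )
    return vc, trace
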