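"""Run configuration and end-to-end orchestration.

A :class:`RunConfig` (usually loaded from YAML) names the input files and
the analysis settings; the ``run_*`` functions chain the library modules
into the standard evaluations:

* ``run_simulate`` — write a synthetic dataset bundle (+ truth table);
* ``run_evaluate`` — PBLUP or (weighted) ssGBLUP solutions, with optional
  AI-REML variance components first;
* ``run_validate`` — whole/partial runs and the three validation schemes;
* ``run_gwas`` — backsolved SNP effects, p-values and window variances;
* ``run_wssgblup`` — iterated weighted ssGBLUP with per-iteration
  validation.

Every run writes a manifest (config hash, seed, library versions) next to
its outputs so results can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import genomic, gwas, mixed_model as mm, pedigree as pedmod, validation as val
from .simulate import SimConfig, SelectionConfig, default_variance_components, run_breeding_program

log = logging.getLogger("ssgblup")


class ConfigError(ValueError):
    pass


_KNOWN_KEYS = {
    "pedigree", "phenotypes", "genotypes", "snp_map", "genotype_dialect",
    "mode", "seed", "out_dir", "reml", "tau", "call_rate_min", "maf_min",
    "vc", "validation", "gwas", "simulate", "traits",
}


@dataclass
class RunConfig:
    seed: int
    out_dir: str = "results"
    pedigree: str | None = None
    phenotypes: str | None = None
    genotypes: str | None = None
    snp_map: str | None = None
    genotype_dialect: str = "plink_raw"
    mode: str = "pblup"               # pblup | ssgblup | wssgblup
    reml: bool = True
    tau: float = 0.05
    call_rate_min: float = 0.90
    maf_min: float = 0.01
    vc: dict | None = None            # start / fixed values, per-matrix lists
    validation: dict = field(default_factory=lambda: {"year_cut": None, "family_dedup": True})
    gwas: dict = field(default_factory=lambda: {"window_size": 20, "alpha": 0.05,
                                                "ct": 1.125, "n_iter": 5})
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "seed" not in raw:
            raise ConfigError("config must set a seed")
        return cls(**{k: v for k, v in raw.items() if k != "traits"})

    def require(self, *names: str) -> None:
        for n in names:
            v = getattr(self, n)
            if v is None:
                raise ConfigError(f"mode '{self.mode}' requires config key '{n}'")
            if n in ("pedigree", "phenotypes", "genotypes", "snp_map") and not Path(v).exists():
                raise ConfigError(f"file not found for '{n}': {v}")

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(cfg: RunConfig, out: Path, stage: str) -> None:
    import scipy

    manifest = {
        "stage": stage,
        "config_sha256": cfg.digest(),
        "seed": cfg.seed,
        "versions": {
            "ssgblup": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    out.mkdir(parents=True, exist_ok=True)
    with open(out / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _vc_from_config(cfg: RunConfig) -> mm.VarianceComponents:
    if cfg.vc is None:
        return default_variance_components()
    d = cfg.vc
    return mm.VarianceComponents(
        Su=np.array(d["Su"], dtype=float),
        Sf=np.array(d["Sf"], dtype=float),
        Se=np.array(d["Se"], dtype=float),
    )


def _sim_config(cfg: RunConfig) -> SimConfig:
    kw = dict(cfg.simulate)
    sel = kw.pop("selection", None)
    vc = kw.pop("vc", None)
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(kw) - known
    if unknown:
        raise ConfigError(f"unknown simulate key(s): {sorted(unknown)}")
    sim = SimConfig(seed=cfg.seed, **kw)
    if sel is not None:
        sim.selection = SelectionConfig(**sel)
    if vc is not None or cfg.vc is not None:
        sim.vc = _vc_from_config(cfg) if vc is None else mm.VarianceComponents(
            Su=np.array(vc["Su"], float), Sf=np.array(vc["Sf"], float),
            Se=np.array(vc["Se"], float))
    return sim


# ------------------------------------------------------------------ stages

def run_simulate(cfg: RunConfig) -> dict:
    sim = _sim_config(cfg)
    out = Path(cfg.out_dir)
    result = run_breeding_program(sim)
    paths = result.write_bundle(out)
    log.info("simulated %d animals, %d genotyped, mean dF/gen %.4f",
             len(result.pedigree), result.genotypes.n_animals,
             result.realized_delta_f)
    _write_manifest(cfg, out, "simulate")
    return {str(k): str(v) for k, v in paths.items()}


def _load_inputs(cfg: RunConfig):
    cfg.require("pedigree", "phenotypes")
    ped = pedmod.read_pedigree_csv(cfg.pedigree)
    data = pd.read_csv(cfg.phenotypes)
    spec = mm.fy_bw_default()
    missing = [t for t in spec.traits if t not in data.columns]
    if missing:
        raise ConfigError(f"phenotype file lacks trait column(s): {missing}")
    return ped, data, spec


def _genomic_stack(cfg: RunConfig, ped: pedmod.Pedigree, weights: np.ndarray | None = None):
    """QC'd genotypes plus all single-step matrices for the current config."""
    cfg.require("genotypes", "snp_map")
    g = genomic.load_genotypes(cfg.genotypes, cfg.snp_map, cfg.genotype_dialect)
    g, qc_report = genomic.qc_filter(g, cfg.call_rate_min, cfg.maf_min)
    log.info("QC: %s", qc_report)
    A22, A22_inv, gen_idx = pedmod.genotyped_blocks(ped, g.animal_ids)
    p = genomic.estimate_base_frequencies(g, A22_inv)
    G0 = genomic.build_G(g, p, weights)
    G = genomic.blend_G(G0, A22, cfg.tau)
    G_inv = np.linalg.inv(G)
    A_inv = pedmod.build_A_inverse(ped)
    H_inv = genomic.build_H_inverse(A_inv, G_inv, A22_inv, gen_idx)
    cond = np.linalg.cond(G)
    if cond > 1e10:
        log.warning("G is ill-conditioned (cond %.2e); consider larger tau", cond)
    return {
        "geno": g, "qc": qc_report, "A22": A22, "A22_inv": A22_inv,
        "gen_idx": gen_idx, "p": p, "G": G, "G_inv": G_inv, "A_inv": A_inv,
        "H_inv": H_inv,
    }


def _fit(cfg: RunConfig, ped, data, spec, vc):
    if cfg.mode == "pblup":
        K_inv = pedmod.build_A_inverse(ped)
        stack = None
    elif cfg.mode in ("ssgblup", "wssgblup"):
        stack = _genomic_stack(cfg, ped)
        K_inv = stack["H_inv"]
    else:
        raise ConfigError(f"unknown mode: {cfg.mode}")
    system = mm.build_mme(spec, data, K_inv, vc, ped)
    sol = mm.solve_mme(system)
    return sol, system, stack


def run_evaluate(cfg: RunConfig) -> dict:
    ped, data, spec = _load_inputs(cfg)
    vc = _vc_from_config(cfg)
    trace = []
    if cfg.reml:
        A_inv = pedmod.build_A_inverse(ped)
        vc, trace = mm.estimate_vc_aireml(spec, data, A_inv, vc, ped)
        if not vc.converged:
            raise ConfigError("AI-REML did not converge; inspect the trace")
    sol, system, _ = _fit(cfg, ped, data, spec, vc)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in spec.traits:
        for name, est in sol.b[t].items():
            rows.append(("fixed", name, t, est))
        for a, est in sol.u[t].items():
            rows.append(("animal", a, t, est))
        for fam, est in sol.f[t].items():
            rows.append(("family", fam, t, est))
    pd.DataFrame(rows, columns=["effect", "level", "trait", "estimate"]).to_csv(
        out / "solutions.tsv", sep="\t", index=False
    )
    params = mm.compute_genetic_parameters(vc, spec.traits)
    report = {
        "mode": cfg.mode,
        "converged": vc.converged,
        "h2": params.h2,
        "f2": params.f2,
        "r_g": params.r_g,
        "se": params.se,
        "Su": vc.Su.tolist(),
        "Sf": vc.Sf.tolist(),
        "Se": vc.Se.tolist(),
        "n_reml_iterations": len(trace),
    }
    with open(out / "parameters.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    _write_manifest(cfg, out, "evaluate")
    return report


def _partial_data(data: pd.DataFrame, spec, year_cut: int) -> pd.DataFrame:
    """Remove phenotypes (not animals) for hatch years >= the cut."""
    part = data.copy()
    drop = part["hatch_year"] >= year_cut
    for t in spec.traits:
        part.loc[drop, t] = np.nan
    return part


def run_validate(cfg: RunConfig) -> pd.DataFrame:
    ped, data, spec = _load_inputs(cfg)
    year_cut = cfg.validation.get("year_cut")
    if year_cut is None:
        raise ConfigError("validation.year_cut is required")
    vc = _vc_from_config(cfg)
    if cfg.reml:
        A_inv = pedmod.build_A_inverse(ped)
        vc, _ = mm.estimate_vc_aireml(spec, data, A_inv, vc, ped)

    sol_w, system_w, _ = _fit(cfg, ped, data, spec, vc)
    part = _partial_data(data, spec, year_cut)
    if part[spec.traits].notna().sum().sum() == data[spec.traits].notna().sum().sum():
        raise ConfigError(f"year_cut {year_cut} removes no phenotypes")
    sol_p, _, _ = _fit(cfg, ped, part, spec, vc)

    # whole-data PBLUP adjusted phenotypes as the benchmark
    A_inv = pedmod.build_A_inverse(ped)
    system_pb = mm.build_mme(spec, data, A_inv, vc, ped)
    sol_pb = mm.solve_mme(system_pb)
    y_star = mm.adjust_phenotypes(data, sol_pb, spec)

    params = mm.compute_genetic_parameters(vc, spec.traits)
    valmask = data["hatch_year"] >= year_cut
    reports: list[val.ValidationReport] = []
    for t in spec.traits:
        sel = valmask & data[t].notna()
        animals = data.loc[sel, "animal"].astype(str)
        if sel.sum() < 3:
            continue
        ys = y_star.loc[sel, t].to_numpy()
        up = sol_p.u.loc[animals, t].to_numpy()
        uw = sol_w.u.loc[animals, t].to_numpy()
        rep = val.forward_validation_adjusted(ys, up, params.h2[t])
        rep.method = f"adjusted-{t}"
        reports.append(rep)
        fbar = float(np.mean(ped.f[ped.index_of(animals)]))
        rep = val.lr_validation(uw, up, fbar, vc.Su[spec.traits.index(t), spec.traits.index(t)])
        rep.method = f"LR-{t}"
        reports.append(rep)
    # mid-parent validation for the first trait on the validation cohort
    t0 = spec.traits[0]
    sel = valmask & data[t0].notna()
    if sel.sum() >= 3:
        prog = pd.DataFrame(
            {"animal": data.loc[sel, "animal"].astype(str),
             "phenotype": data.loc[sel, t0].astype(float)}
        )
        try:
            rep = val.midparent_validation(sol_p.u[t0], ped, prog, mode="raw")
            rep.method = f"midparent-raw-{t0}"
            reports.append(rep)
            prog_adj = prog.assign(phenotype=y_star.loc[sel, t0].to_numpy())
            rep = val.midparent_validation(sol_p.u[t0], ped, prog_adj, mode="adjusted")
            rep.method = f"midparent-adjusted-{t0}"
            reports.append(rep)
        except val.ValidationError as exc:
            log.warning("mid-parent validation skipped: %s", exc)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = pd.concat([r.as_frame() for r in reports], ignore_index=True)
    table.to_csv(out / "validation.tsv", sep="\t", index=False)
    _write_manifest(cfg, out, "validate")
    return table


def run_gwas(cfg: RunConfig) -> dict:
    if cfg.mode == "pblup":
        raise ConfigError("GWAS requires a genomic mode")
    ped, data, spec = _load_inputs(cfg)
    vc = _vc_from_config(cfg)
    if cfg.reml:
        A_inv = pedmod.build_A_inverse(ped)
        vc, _ = mm.estimate_vc_aireml(spec, data, A_inv, vc, ped)
    sol, system, stack = _fit(cfg, ped, data, spec, vc)
    g = stack["geno"]
    Z = genomic.center_genotypes(g, stack["p"])
    lam = genomic.build_G_lambda(stack["p"])
    gen_ids = [ped.ids[i] for i in stack["gen_idx"]]
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = {}
    for ti, t in enumerate(spec.traits):
        u_g = sol.u.loc[gen_ids, t].to_numpy()
        a_hat = gwas.backsolve_snp_effects(u_g, stack["G_inv"], Z, None, lam)
        # genotyped block of the inverse coefficient matrix for this trait
        sl = system.slices[f"u_{t}"]
        rows = np.asarray(stack["gen_idx"]) + sl.start
        Cuu = sol.inverse_block(rows)
        cov_u = vc.Su[ti, ti] * stack["G"] - Cuu
        var_a = gwas.snp_effect_variances(stack["G_inv"], Z, cov_u, None, lam)
        table = gwas.snp_pvalues(a_hat, var_a)
        table.insert(0, "snp", g.snp_ids)
        table.insert(1, "chrom", g.chrom)
        table.insert(2, "pos", g.pos)
        table["weight"] = 1.0
        wins = gwas.window_variance(
            a_hat, Z, g.chrom, vc.Su[ti, ti], cfg.gwas.get("window_size", 20)
        )
        table.to_csv(out / f"gwas_{t}.tsv", sep="\t", index=False)
        wins.to_csv(out / f"windows_{t}.tsv", sep="\t", index=False)
        results[t] = {
            "n_snp": g.n_snps,
            "bonferroni": gwas.bonferroni_threshold(g.n_snps, cfg.gwas.get("alpha", 0.05)),
            "n_significant": int((table["neglog10p"] > gwas.bonferroni_threshold(
                g.n_snps, cfg.gwas.get("alpha", 0.05))).sum()),
            "max_window_pct": float(wins["pct_variance"].max()),
        }
    _write_manifest(cfg, out, "gwas")
    return results


def run_wssgblup(cfg: RunConfig) -> pd.DataFrame:
    ped, data, spec = _load_inputs(cfg)
    vc = _vc_from_config(cfg)
    if cfg.reml:
        A_inv = pedmod.build_A_inverse(ped)
        vc, _ = mm.estimate_vc_aireml(spec, data, A_inv, vc, ped)
    stack = _genomic_stack(cfg, ped)
    year_cut = cfg.validation.get("year_cut")
    hook = None
    if year_cut is not None:
        A_inv = stack["A_inv"]
        system_pb = mm.build_mme(spec, data, A_inv, vc, ped)
        y_star = mm.adjust_phenotypes(data, mm.solve_mme(system_pb), spec)
        params = mm.compute_genetic_parameters(vc, spec.traits)
        t0 = spec.traits[0]
        valmask = (data["hatch_year"] >= year_cut) & data[t0].notna()
        animals = data.loc[valmask, "animal"].astype(str)
        ys = y_star.loc[valmask, t0].to_numpy()

        def hook(sol):
            return val.forward_validation_adjusted(
                ys, sol.u.loc[animals, t0].to_numpy(), params.h2[t0]
            )

    iters = gwas.wssgblup_iterate(
        spec, data, ped, stack["A_inv"], stack["A22"], stack["A22_inv"],
        stack["gen_idx"], stack["geno"], stack["p"], vc,
        weight_trait=spec.traits[0], CT=cfg.gwas.get("ct", 1.125),
        n_iter=cfg.gwas.get("n_iter", 5), tau=cfg.tau, validation_hook=hook,
    )
    rows = []
    for it in iters:
        row = {"iteration": it.iteration, "mean_weight": float(it.weights.mean()),
               "max_weight": float(it.weights.max())}
        if it.validation is not None:
            row.update(accuracy=it.validation.accuracy, b0=it.validation.b0,
                       b1=it.validation.b1)
        rows.append(row)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(rows)
    table.to_csv(out / "wssgblup.tsv", sep="\t", index=False)
    _write_manifest(cfg, out, "wssgblup")
    return table
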