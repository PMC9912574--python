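"""Seeded simulator of a multi-generation fish breeding program.

Emulates (at configurable scale) a full-sib family design of the kind run
for fillet yield and body weight in rainbow trout: discrete generations of
full-sib families, body weight recorded on essentially all grown fish, the
fillet-yield trait recorded lethally on ~5 fish per family chosen by a
rank-skipping rule on body weight, divergent high/low lines with selection
on family-mean EBVs, mate allocation constrained to keep inbreeding
accumulation at or below a per-generation limit, and a genotyped subset of
a few fish per family plus the parents.

Genetics: founders are drawn in linkage equilibrium at frequencies uniform
on a configurable range; alleles drop through the pedigree with Haldane
(Poisson) recombination on each chromosome.  True breeding values come from
a few hundred biallelic QTL (withheld from the marker panel) whose
bivariate effects are rescaled exactly so the realized founder TBV
(co)variance matches the target additive covariance — making
parameter-recovery checks sharp.  Family and residual effects are drawn
from the target family and residual covariance matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic import GenotypeMatrix
from .mixed_model import VarianceComponents, ModelSpec, build_mme, solve_mme, fy_bw_default
from .pedigree import UNKNOWN, Pedigree, build_A, build_A_inverse, renumber_pedigree


class SimulationError(ValueError):
    pass


# Default generating (co)variances for the two traits (FY in %^2, BW in g^2):
# additive 1.99 / 17648 with genetic correlation 0.24, family 0.24 / 5679,
# residual 2.60 / 29913.  Family and residual cross-trait correlations are
# not separately reported for this design; 0.3 is used as a realistic
# default for a part-whole trait pair and is freely re-estimated by REML.
def _cov2(v1: float, v2: float, r: float) -> np.ndarray:
    c = r * np.sqrt(v1 * v2)
    return np.array([[v1, c], [c, v2]])


def default_variance_components(r_g: float = 0.24) -> VarianceComponents:
    return VarianceComponents(
        Su=_cov2(1.99, 17648.0, r_g),
        Sf=_cov2(0.24, 5679.0, 0.3),
        Se=_cov2(2.60, 29913.0, 0.3),
    )


@dataclass
class SelectionConfig:
    trait: str = "fy"
    direction: str = "up"        # up | down | random
    proportion: float = 0.5      # fraction of families contributing parents
    on: str = "family_ebv"       # family_ebv | phenotype


@dataclass
class SimConfig:
    seed: int
    n_generations: int = 3
    families_per_generation: int = 60
    offspring_per_family: int = 15
    n_chromosomes: int = 10
    snps_per_chromosome: int = 100
    map_length_morgans: float = 1.0
    n_qtl: int = 300
    founder_freq_range: tuple = (0.1, 0.9)
    founder_ld: bool = True      # coalescent founders (ancestral LD) vs LE
    founder_ne: int = 50         # effective size of the founder coalescent
    vc: VarianceComponents = field(default_factory=default_variance_components)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    low_line_fraction: float = 0.2
    inbreeding_limit_per_gen: float = 0.01
    fy_sampled_per_family: int = 5
    genotyped_per_family: int = 5
    # fixed-effect layers (units of the trait scales)
    trait_means: tuple = (50.9, 1043.0)
    year_effect_sd: tuple = (1.0, 70.0)
    group_effect_sd: tuple = (0.4, 0.0)     # harvest group applies to FY only
    line_effect: tuple = (0.3, 20.0)        # environmental H-vs-L offset
    age_mean: float = 400.0
    age_sd: float = 10.0
    harvest_age_offset: float = 45.0
    age_slope: tuple = (0.01, 2.0)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("a seed is mandatory")
        for name in ("n_generations", "families_per_generation",
                     "offspring_per_family", "n_chromosomes",
                     "snps_per_chromosome"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if self.n_qtl < 0:
            raise SimulationError("n_qtl must be >= 0")
        if not (0 < self.selection.proportion <= 1):
            raise SimulationError("selection proportion must be in (0, 1]")


@dataclass
class Genome:
    """Locus layout: genetic positions per chromosome, QTL flags."""

    chrom: np.ndarray          # chromosome id per locus
    genpos: np.ndarray         # genetic position in Morgans within chromosome
    is_qtl: np.ndarray         # bool per locus
    map_length: float

    @property
    def n_loci(self) -> int:
        return len(self.chrom)

    @property
    def snp_index(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    @property
    def qtl_index(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)


def _build_genome(cfg: SimConfig, rng: np.random.Generator) -> Genome:
    per_chr_qtl = np.full(cfg.n_chromosomes, cfg.n_qtl // cfg.n_chromosomes)
    per_chr_qtl[: cfg.n_qtl % cfg.n_chromosomes] += 1
    chroms, genpos, is_qtl = [], [], []
    for c in range(cfg.n_chromosomes):
        n_loc = cfg.snps_per_chromosome + per_chr_qtl[c]
        gp = np.sort(rng.uniform(0.0, cfg.map_length_morgans, n_loc))
        qtl_mask = np.zeros(n_loc, dtype=bool)
        if per_chr_qtl[c] > 0:
            qtl_mask[rng.choice(n_loc, per_chr_qtl[c], replace=False)] = True
        chroms.append(np.full(n_loc, c + 1))
        genpos.append(gp)
        is_qtl.append(qtl_mask)
    return Genome(
        chrom=np.concatenate(chroms),
        genpos=np.concatenate(genpos),
        is_qtl=np.concatenate(is_qtl),
        map_length=cfg.map_length_morgans,
    )


def _le_founders(
    cfg: SimConfig, genome: Genome, n_founders: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Founder haplotypes in linkage equilibrium at uniform frequencies."""
    lo, hi = cfg.founder_freq_range
    freqs = rng.uniform(lo, hi, genome.n_loci)
    haps = (
        rng.random((n_founders, 2, genome.n_loci)) < freqs[None, None, :]
    ).astype(np.int8)
    return haps, freqs


def _coalescent_founders(
    cfg: SimConfig, n_founders: int, rng: np.random.Generator
) -> tuple[Genome, np.ndarray, np.ndarray]:
    """Founders from a finite-Ne coalescent with recombination.

    A small long-term effective size gives the founder population the
    ancestral linkage disequilibrium that a real SNP-array population
    carries, so markers tag nearby QTL across (not only within) families.
    """
    import msprime

    per_chr_qtl = np.full(cfg.n_chromosomes, cfg.n_qtl // cfg.n_chromosomes)
    per_chr_qtl[: cfg.n_qtl % cfg.n_chromosomes] += 1
    lo, hi = cfg.founder_freq_range
    seq_len = 1e6
    rec_rate = cfg.map_length_morgans / seq_len
    chroms, genpos, qtl_flags, hap_cols, freq_cols = [], [], [], [], []
    for c in range(cfg.n_chromosomes):
        n_loc = cfg.snps_per_chromosome + per_chr_qtl[c]
        ts = msprime.sim_ancestry(
            samples=n_founders,
            population_size=cfg.founder_ne,
            sequence_length=seq_len,
            recombination_rate=rec_rate,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        mu = 3.0 * n_loc / (4.0 * cfg.founder_ne * np.log(2 * n_founders) * seq_len)
        for attempt in range(6):
            mts = msprime.sim_mutations(
                ts, rate=mu, random_seed=int(rng.integers(1, 2**31 - 1)),
                model=msprime.BinaryMutationModel(),
            )
            gm = mts.genotype_matrix()  # sites x haplotypes, 0/1
            freqs = gm.mean(axis=1)
            ok = (freqs >= lo) & (freqs <= hi)
            if ok.sum() >= n_loc:
                break
            mu *= 2.0
        else:
            raise SimulationError(
                "coalescent founders: not enough segregating sites in the "
                "requested frequency range; widen founder_freq_range"
            )
        sites = np.sort(rng.choice(np.flatnonzero(ok), n_loc, replace=False))
        pos = mts.sites_position[sites] / seq_len * cfg.map_length_morgans
        qtl_mask = np.zeros(n_loc, dtype=bool)
        if per_chr_qtl[c] > 0:
            qtl_mask[rng.choice(n_loc, per_chr_qtl[c], replace=False)] = True
        chroms.append(np.full(n_loc, c + 1))
        genpos.append(pos)
        qtl_flags.append(qtl_mask)
        hap_cols.append(gm[sites].T)  # haplotypes x loci
        freq_cols.append(freqs[sites])
    genome = Genome(
        chrom=np.concatenate(chroms),
        genpos=np.concatenate(genpos),
        is_qtl=np.concatenate(qtl_flags),
        map_length=cfg.map_length_morgans,
    )
    H = np.concatenate(hap_cols, axis=1).astype(np.int8)  # 2n x loci
    haps = H.reshape(n_founders, 2, genome.n_loci)
    return genome, haps, np.concatenate(freq_cols)


def simulate_founders(
    cfg: SimConfig,
    n_founders: int,
    rng: np.random.Generator,
    genome: Genome | None = None,
) -> tuple[Genome, np.ndarray, np.ndarray]:
    """Founder genome and haplotypes.

    With ``cfg.founder_ld`` (default) the founders come from a coalescent
    with recombination (ancestral LD); otherwise loci are independent
    (linkage equilibrium) on a uniform-random map.  Returns
    ``(genome, haplotypes (n_founders, 2, n_loci) int8, allele freqs)``.
    """
    if n_founders <= 0:
        raise SimulationError("need at least one founder")
    if cfg.founder_ld:
        return _coalescent_founders(cfg, n_founders, rng)
    if genome is None:
        genome = _build_genome(cfg, rng)
    haps, freqs = _le_founders(cfg, genome, n_founders, rng)
    return genome, haps, freqs


def _meiosis(
    parent_haps: np.ndarray, genome: Genome, rng: np.random.Generator
) -> np.ndarray:
    """One gamete from a (2, n_loci) parent: Haldane recombination per chromosome."""
    gamete = np.empty(genome.n_loci, dtype=np.int8)
    for c in np.unique(genome.chrom):
        sel = genome.chrom == c
        gp = genome.genpos[sel]
        L = genome.map_length
        k = rng.poisson(L)
        phase0 = rng.integers(0, 2)
        if k == 0:
            phase = np.full(sel.sum(), phase0)
        else:
            bp = np.sort(rng.uniform(0.0, L, k))
            phase = (phase0 + np.searchsorted(bp, gp)) % 2
        gamete[sel] = parent_haps[phase, sel]
    return gamete


def gene_drop(
    ped: Pedigree,
    founder_haps: np.ndarray,
    genome: Genome,
    rng: np.random.Generator,
    haps: np.ndarray | None = None,
    start_at: int = 0,
) -> np.ndarray:
    """Drop alleles down the (topologically ordered) pedigree.

    Founders take the pre-simulated haplotypes in pedigree order; each
    non-founder receives one recombinant gamete per parent.  ``haps`` plus
    ``start_at`` allow incremental extension when the pedigree grows.
    """
    n = len(ped)
    if haps is None:
        haps = np.zeros((n, 2, genome.n_loci), dtype=np.int8)
    elif haps.shape[0] < n:
        haps = np.concatenate(
            [haps, np.zeros((n - haps.shape[0], 2, genome.n_loci), np.int8)]
        )
    founder_count = 0
    for i in range(n):
        if i < start_at:
            if ped.sire[i] == UNKNOWN and ped.dam[i] == UNKNOWN:
                founder_count += 1
            continue
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            haps[i] = founder_haps[founder_count]
            founder_count += 1
            continue
        if s == UNKNOWN or d == UNKNOWN:
            raise SimulationError("simulated pedigrees must have both parents known")
        haps[i, 0] = _meiosis(haps[s], genome, rng)
        haps[i, 1] = _meiosis(haps[d], genome, rng)
    return haps


def assign_trait_architecture(
    cfg: SimConfig,
    qtl_dosages_founders: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bivariate QTL effects rescaled exactly to the target ``Su``.

    Raw effects are iid bivariate standard normal; an exact 2x2 transform
    ``B`` with ``B' C B = Su`` is applied (symmetric square root of ``Su``
    against the Cholesky factor of ``C``).  The calibrated quantity ``C``
    depends on the founder mode:

    * LE founders — the realized founder TBV sample covariance, so founder
      TBVs hit ``Su`` to machine precision;
    * LD (coalescent) founders — the *genic* covariance
      ``sum_q 2 p_q (1-p_q) beta_q beta_q'``.  Under LD the observed founder
      variance additionally carries the realized between-QTL disequilibrium
      covariance, which averages to zero over seeds; calibrating the genic
      part keeps the within-family (Mendelian-sampling) variance at the
      ``0.5 Su`` a pedigree model expects, which is what the estimation
      machinery is validated against.
    """
    n_qtl = qtl_dosages_founders.shape[1]
    if n_qtl == 0:
        return np.zeros((0, 2))
    Q = qtl_dosages_founders - qtl_dosages_founders.mean(axis=0, keepdims=True)
    if np.allclose(Q, 0):
        raise SimulationError("all QTL are monomorphic in the founders")
    Su = cfg.vc.Su
    w, U = np.linalg.eigh(Su)
    # symmetric square root (valid for singular Su, e.g. r_g = +-1)
    root = U @ np.diag(np.sqrt(np.maximum(w, 0.0))) @ U.T

    def scale_pair(alpha, C):
        """Effects = alpha @ B with B' C B = Su exactly."""
        Lc = np.linalg.cholesky(C)
        return alpha @ np.linalg.solve(Lc.T, root)

    if not cfg.founder_ld:
        alpha = rng.standard_normal((n_qtl, 2))
        return scale_pair(alpha, np.cov((Q @ alpha).T, ddof=1))

    # LD founders: calibrate the genic covariance AND cancel the realized
    # between-QTL disequilibrium contribution, so the founder TBV sample
    # covariance equals Su exactly as well.  Draw m raw effect vectors and
    # pick a 2-dim combination inside an isotropic subspace of the
    # disequilibrium quadratic form.
    p = qtl_dosages_founders.mean(axis=0) / 2.0
    w_het = 2.0 * p * (1.0 - p)
    m = min(8, n_qtl)
    alpha = rng.standard_normal((n_qtl, m))
    A_m = alpha.T @ (w_het[:, None] * alpha)             # genic form
    C_samp = np.cov((Q @ alpha).T, ddof=1)               # realized form
    B_ld = C_samp - A_m                                  # disequilibrium form
    if m >= 6:
        R = np.linalg.cholesky(A_m)
        Bt = np.linalg.solve(R, np.linalg.solve(R, B_ld.T).T)
        ev, V = np.linalg.eigh(0.5 * (Bt + Bt.T))
        pos = np.argsort(ev)[::-1]
        neg = np.argsort(ev)
        if ev[pos[1]] > 1e-10 and ev[neg[1]] < -1e-10:
            U_iso = np.column_stack([
                V[:, pos[k]] / np.sqrt(ev[pos[k]])
                + V[:, neg[k]] / np.sqrt(-ev[neg[k]])
                for k in (0, 1)
            ])
            W0 = np.linalg.solve(R.T, U_iso)             # W0' A_m W0 = U'U
            Gm = U_iso.T @ U_iso
            W = W0 @ np.linalg.solve(np.linalg.cholesky(Gm).T, root)
            return alpha @ W
    # fallback: genic calibration only
    return scale_pair(alpha[:, :2], A_m[:2, :2])


def _true_breeding_values(haps: np.ndarray, genome: Genome, effects: np.ndarray) -> np.ndarray:
    if effects.shape[0] == 0:
        return np.zeros((haps.shape[0], 2))
    dos = haps[:, 0, genome.qtl_index] + haps[:, 1, genome.qtl_index]
    return dos.astype(float) @ effects


@dataclass
class SimOutput:
    config: SimConfig
    pedigree: Pedigree
    data: pd.DataFrame            # one row per grown fish
    genotypes: GenotypeMatrix     # genotyped subset, SNP panel only
    truth: pd.DataFrame           # animal, tbv_fy, tbv_bw, F
    founder_freqs: np.ndarray     # per SNP-panel locus
    mean_f_by_generation: pd.Series
    realized_delta_f: float

    def write_bundle(self, out_dir) -> dict:
        """Write the CSV/PLINK-RAW bundle the pipeline reads, plus truth."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        ped_df = pd.DataFrame(
            {
                "animal": self.pedigree.ids,
                "sire": ["0" if s == UNKNOWN else self.pedigree.ids[s] for s in self.pedigree.sire],
                "dam": ["0" if d == UNKNOWN else self.pedigree.ids[d] for d in self.pedigree.dam],
            }
        )
        paths["pedigree"] = out / "pedigree.csv"
        ped_df.to_csv(paths["pedigree"], index=False)
        paths["phenotypes"] = out / "phenotypes.csv"
        self.data.to_csv(paths["phenotypes"], index=False)
        g = self.genotypes
        raw = pd.DataFrame({"FID": "0", "IID": g.animal_ids, "PAT": "0", "MAT": "0",
                            "SEX": "0", "PHENOTYPE": "-9"})
        X = g.X.copy()
        cols = {}
        for j, s in enumerate(g.snp_ids):
            col = X[:, j]
            cols[f"{s}_A"] = pd.Series(col).astype("Int64")
        raw = pd.concat([raw, pd.DataFrame(cols)], axis=1)
        paths["genotypes"] = out / "genotypes.raw"
        raw.to_csv(paths["genotypes"], sep=" ", index=False, na_rep="NA")
        paths["snp_map"] = out / "snp_map.csv"
        pd.DataFrame(
            {"snp": g.snp_ids, "chrom": g.chrom, "pos": g.pos}
        ).to_csv(paths["snp_map"], index=False)
        paths["truth"] = out / "truth.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def simulate_phenotypes(
    tbv: np.ndarray,
    families: np.ndarray,
    lines: np.ndarray,
    generation: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    fixed_draws: dict,
) -> pd.DataFrame:
    """Phenotype table for one cohort of grown fish.

    Body weight is recorded on every fish; fillet yield on up to
    ``fy_sampled_per_family`` fish per family, picked by sorting the family
    on descending body weight, excluding fish beyond 3 SD from the family
    mean, and keeping every second fish down the ranking.  Sampled fish are
    assigned to five weekly harvest groups in descending body-weight order.
    """
    n = len(families)
    Sf = cfg.vc.Sf
    Se = cfg.vc.Se
    fam_levels, fam_codes = np.unique(families, return_inverse=True)
    fam_eff = rng.multivariate_normal(np.zeros(2), Sf, size=len(fam_levels))
    resid = rng.multivariate_normal(np.zeros(2), Se, size=n)
    age = rng.normal(cfg.age_mean, cfg.age_sd, n)
    harvest_age = age + cfg.harvest_age_offset

    mu = np.array(cfg.trait_means)
    slope = np.array(cfg.age_slope)
    line_eff = np.array(cfg.line_effect)
    is_low = (lines == "L").astype(float)

    y = np.empty((n, 2))
    for t in range(2):
        year_eff = np.array([fixed_draws["year"][g][t] for g in generation])
        y[:, t] = (
            mu[t]
            + year_eff
            + line_eff[t] * (1.0 - 2.0 * is_low) * 0.5
            + slope[t] * (age - cfg.age_mean)
            + tbv[:, t]
            + fam_eff[fam_codes, t]
            + resid[:, t]
        )

    bw = y[:, 1]
    fy = np.full(n, np.nan)
    group = np.zeros(n, dtype=int)
    sampled = np.zeros(n, dtype=bool)
    for f in range(len(fam_levels)):
        members = np.flatnonzero(fam_codes == f)
        bw_f = bw[members]
        sd = bw_f.std(ddof=1) if len(members) > 1 else 0.0
        ok = (
            np.abs(bw_f - bw_f.mean()) <= 3 * sd if sd > 0 else np.ones(len(members), bool)
        )
        eligible = members[ok][np.argsort(-bw_f[ok], kind="stable")]
        want = cfg.fy_sampled_per_family
        picked = eligible[::2][:want]
        if len(picked) < want:
            picked = eligible[:want]
        sampled[picked] = True
        # harvest groups 1..5 in descending body-weight order
        group[picked] = (np.arange(len(picked)) % 5) + 1
    # FY phenotype with its harvest-year x group effect
    gsd = cfg.group_effect_sd[0]
    for i in np.flatnonzero(sampled):
        key = (generation[i], group[i])
        if key not in fixed_draws["group"]:
            fixed_draws["group"][key] = rng.normal(0.0, gsd)
        fy[i] = y[i, 0] + fixed_draws["group"][key]

    return pd.DataFrame(
        {
            "family": families,
            "line": lines,
            "hatch_year": 2010 + 2 * generation,
            "harvest_year": 2010 + 2 * generation + 1,
            "harvest_group": np.where(sampled, group, 0),
            "age": age,
            "harvest_age": harvest_age,
            "fy": fy,
            "bw": bw,
        }
    )


def _family_merit(
    data: pd.DataFrame, ped: Pedigree, cfg: SimConfig, spec: ModelSpec
) -> pd.Series:
    """Family-mean EBVs from an internal PBLUP on the data so far."""
    sel = cfg.selection
    if sel.on == "phenotype":
        return data.groupby("family")[sel.trait].mean()
    A_inv = build_A_inverse(ped)
    system = build_mme(spec, data, A_inv, cfg.vc, ped)
    sol = solve_mme(system)
    ebv = sol.u[sel.trait]
    fam_of = data.set_index("animal")["family"]
    merit = ebv.reindex(fam_of.index).groupby(fam_of).mean()
    return merit


def run_breeding_program(cfg: SimConfig) -> SimOutput:
    """Run the full seeded breeding program and return the dataset bundle.

    Generation 1 families come from unrelated founders; afterwards parents
    are taken from the top (or bottom, for the low line's single downward
    generation) families by family-mean EBV, one sire and one dam per new
    family, greedily paired so that expected progeny inbreeding
    ``a(sire, dam)/2`` stays within the parental-generation mean plus the
    configured per-generation limit.  Fillet-yield-harvested fish are dead
    and never become parents.
    """
    ss = np.random.SeedSequence(cfg.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ["genome", "founders", "genedrop", "effects", "phenotypes", "selection"],
            ss.spawn(6),
        )
    }

    n_fam = cfg.families_per_generation
    n_low = max(1, int(round(cfg.low_line_fraction * n_fam))) if cfg.low_line_fraction > 0 else 0
    n_high = n_fam - n_low
    n_founders = 2 * n_fam

    genome, founder_haps, freqs = simulate_founders(cfg, n_founders, streams["founders"])

    records: list[tuple] = []   # (animal, sire, dam)
    sex: dict[str, str] = {}
    line_of: dict[str, str] = {}
    fam_of_animal: dict[str, str] = {}
    founders = []
    for i in range(n_founders):
        a = f"G0_{i:04d}"
        records.append((a, "0", "0"))
        sex[a] = "M" if i % 2 == 0 else "F"
        line_of[a] = "H" if i < 2 * n_high else "L"
        founders.append(a)

    effects = None
    ped = renumber_pedigree(records)
    haps = gene_drop(ped, founder_haps, genome, streams["genedrop"])
    qtl_dos_f = (
        haps[:, 0, genome.qtl_index] + haps[:, 1, genome.qtl_index]
    ).astype(float)
    effects = assign_trait_architecture(cfg, qtl_dos_f, streams["effects"])

    spec = fy_bw_default()
    fixed_draws = {
        "year": {
            g: (
                streams["phenotypes"].normal(0.0, cfg.year_effect_sd[0]),
                streams["phenotypes"].normal(0.0, cfg.year_effect_sd[1]),
            )
            for g in range(1, cfg.n_generations + 1)
        },
        "group": {},
    }

    all_data: list[pd.DataFrame] = []
    mean_f = {0: 0.0}
    low_line_selections = 0

    # candidate parents per line: groups of fish in preference order (for the
    # founder generation, a single group with everyone), plus how many groups
    # are primary (selected); lower-merit groups are drawn in only when the
    # inbreeding constraint cannot be met inside the selected pool
    parent_groups = {
        "H": [[a for a in founders if line_of[a] == "H"]],
        "L": [[a for a in founders if line_of[a] == "L"]],
    }
    n_primary = {"H": 1, "L": 1}

    for g in range(1, cfg.n_generations + 1):
        rng_sel = streams["selection"]
        A_full, _ = build_A(ped)
        f_parent_gen = {}
        for ln in ("H", "L"):
            primary = [a for grp in parent_groups[ln][: n_primary[ln]] for a in grp]
            f_parent_gen[ln] = (
                float(np.mean(ped.f[ped.index_of(primary)])) if primary else 0.0
            )

        matings: list[tuple[str, str, str]] = []  # (line, sire, dam)
        for ln, n_fam_line in (("H", n_high), ("L", n_low)):
            if n_fam_line == 0:
                continue
            groups = parent_groups[ln]
            limit = f_parent_gen[ln] + cfg.inbreeding_limit_per_gen
            max_use = 2  # matings per individual
            used: dict[str, int] = {}

            males: list[str] = []
            females: list[str] = []

            def add_group(grp):
                grp = list(grp)
                rng_sel.shuffle(grp)
                for a in grp:
                    (males if sex[a] == "M" else females).append(a)

            n_active = 0
            for _ in range(n_primary[ln]):
                add_group(groups[n_active])
                n_active += 1
            if not males or not females:
                # degenerate single-sex selection: pull in more families
                while (not males or not females) and n_active < len(groups):
                    add_group(groups[n_active])
                    n_active += 1
            if not males or not females:
                raise SimulationError(f"no parents of both sexes in line {ln}")

            relaxed = False
            for k in range(n_fam_line):
                while True:
                    midx = ped.index_of(males)
                    fidx = ped.index_of(females)
                    rel = A_full[np.ix_(midx, fidx)].copy()
                    used_up_m = np.array([used.get(a, 0) >= max_use for a in males])
                    used_up_f = np.array([used.get(a, 0) >= max_use for a in females])
                    rel[used_up_m, :] = np.inf
                    rel[:, used_up_f] = np.inf
                    feasible = rel / 2.0 <= limit
                    if feasible.any():
                        # spread usage across parents first (protects Ne),
                        # then take the least-related feasible pair; random
                        # tie-breaking keeps the pedigree irregular (a
                        # deterministic choice builds a regular lattice whose
                        # families all become equally related at once)
                        use_m = np.array([used.get(a, 0) for a in males])
                        use_f = np.array([used.get(a, 0) for a in females])
                        usage = use_m[:, None] + use_f[None, :]
                        usage = np.where(feasible, usage, np.iinfo(np.int32).max)
                        best_use = usage.min()
                        jitter = rng_sel.uniform(0.0, 1e-9, rel.shape)
                        masked = np.where(usage == best_use, rel + jitter, np.inf)
                        mi, fi = np.unravel_index(np.argmin(masked), rel.shape)
                        break
                    if n_active < len(groups):
                        # expand the pool with the next-best family
                        add_group(groups[n_active])
                        n_active += 1
                        continue
                    # genuinely infeasible: least-related available pair
                    relaxed = True
                    if np.isfinite(rel).any():
                        mi, fi = np.unravel_index(np.argmin(rel), rel.shape)
                    else:  # everyone used up: ignore the usage cap
                        rel = A_full[np.ix_(midx, fidx)]
                        mi, fi = np.unravel_index(np.argmin(rel), rel.shape)
                    break
                s, d = males[int(mi)], females[int(fi)]
                used[s] = used.get(s, 0) + 1
                used[d] = used.get(d, 0) + 1
                matings.append((ln, s, d))
            if relaxed:
                warnings.warn(
                    f"inbreeding constraint infeasible in line {ln}; "
                    "least-related pairs used",
                    RuntimeWarning,
                )

        # register offspring
        new_records = []
        new_animals, new_fams, new_lines = [], [], []
        for fam_no, (ln, s, d) in enumerate(matings):
            fam_id = f"G{g}F{fam_no:03d}"
            for o in range(cfg.offspring_per_family):
                a = f"G{g}_{fam_no:03d}_{o:02d}"
                new_records.append((a, s, d))
                sex[a] = "M" if streams["genedrop"].random() < 0.5 else "F"
                line_of[a] = ln
                fam_of_animal[a] = fam_id
                new_animals.append(a)
                new_fams.append(fam_id)
                new_lines.append(ln)

        prev_n = len(ped)
        prev_ids = list(ped.ids)
        records.extend(new_records)
        ped = renumber_pedigree(records)
        # insertion-order renumbering appends the new offspring after the
        # existing animals, so haplotypes extend incrementally
        if ped.ids[:prev_n] != prev_ids:
            raise SimulationError("pedigree order changed while growing")
        haps = gene_drop(ped, founder_haps, genome, streams["genedrop"], haps=haps,
                         start_at=prev_n)

        # index by id: robust to any topological ordering of the new cohort
        new_idx = ped.index_of(new_animals)
        tbv_new = _true_breeding_values(haps[new_idx], genome, effects)
        cohort = simulate_phenotypes(
            tbv_new,
            np.array(new_fams),
            np.array(new_lines),
            np.full(len(new_animals), g),
            cfg,
            streams["phenotypes"],
            fixed_draws,
        )
        cohort.insert(0, "animal", new_animals)
        all_data.append(cohort)
        mean_f[g] = float(np.mean(ped.f[prev_n:]))

        # choose next generation's parents
        if g == cfg.n_generations:
            break
        data_so_far = pd.concat(all_data, ignore_index=True)
        sel = cfg.selection
        if sel.direction == "random":
            merit = None
        else:
            merit = _family_merit(data_so_far, ped, cfg, spec)
        cohort_alive = cohort[cohort["fy"].isna()]  # FY fish were harvested
        by_family = cohort_alive.groupby("family")["animal"].apply(list)
        for ln in ("H", "L"):
            fams_line = sorted(
                cohort_alive.loc[cohort_alive["line"] == ln, "family"].unique()
            )
            if not fams_line:
                parent_groups[ln], n_primary[ln] = [], 0
                continue
            n_keep = max(2, int(np.ceil(sel.proportion * len(fams_line))))
            if sel.direction == "random" or (ln == "L" and low_line_selections >= 1):
                # random-mating phase: parents sampled from all families,
                # preserving diversity within the line
                ordered = list(fams_line)
                rng_sel.shuffle(ordered)
                n_keep = len(ordered)
            else:
                fam_merit = merit.reindex(fams_line)
                # the high line follows the configured direction; the low
                # line diverges (opposite direction) in its one selection
                take_top = (sel.direction == "up") == (ln == "H")
                ordered = fam_merit.sort_values(ascending=not take_top).index.tolist()
            parent_groups[ln] = [by_family[f] for f in ordered]
            n_primary[ln] = n_keep
        if n_low > 0:
            low_line_selections += 1

    data = pd.concat(all_data, ignore_index=True)
    f_series = pd.Series(mean_f).sort_index()
    delta_f = float(np.mean(np.diff(f_series.to_numpy()))) if len(f_series) > 1 else 0.0

    # genotyped subset: FY-sampled fish plus all parents that produced them
    genotyped = data.loc[~data["fy"].isna(), "animal"].tolist()
    parent_ids = set()
    for a in data["animal"]:
        i = ped.index_of([a])[0]
        if ped.sire[i] != UNKNOWN:
            parent_ids.add(ped.ids[ped.sire[i]])
        if ped.dam[i] != UNKNOWN:
            parent_ids.add(ped.ids[ped.dam[i]])
    genotyped = sorted(set(genotyped) | parent_ids)
    gen_idx = ped.index_of(genotyped)
    snp_idx = genome.snp_index
    dosages = (
        haps[np.ix_(gen_idx, [0], snp_idx)][:, 0, :]
        + haps[np.ix_(gen_idx, [1], snp_idx)][:, 0, :]
    ).astype(float)
    pos_bp = np.round(genome.genpos[snp_idx] * 1e8).astype(np.int64)
    genotypes = GenotypeMatrix(
        animal_ids=genotyped,
        snp_ids=[f"snp{c}_{i}" for i, c in enumerate(genome.chrom[snp_idx])],
        chrom=genome.chrom[snp_idx],
        pos=pos_bp,
        X=dosages,
    )

    tbv_all = _true_breeding_values(haps, genome, effects)
    truth = pd.DataFrame(
        {
            "animal": ped.ids,
            "tbv_fy": tbv_all[:, 0],
            "tbv_bw": tbv_all[:, 1],
            "F": ped.f,
        }
    )
    return SimOutput(
        config=cfg,
        pedigree=ped,
        data=data,
        genotypes=genotypes,
        truth=truth,
        founder_freqs=freqs[snp_idx],
        mean_f_by_generation=f_series,
        realized_delta_f=delta_f,
    )
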