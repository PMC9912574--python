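import numpy as np
import pandas as pd
import pytest

import ssgblup as sg
from ssgblup.simulate import (
    Genome,
    SelectionConfig,
    SimConfig,
    SimulationError,
    _build_genome,
    _meiosis,
    assign_trait_architecture,
    gene_drop,
    run_breeding_program,
    simulate_founders,
)


def small_cfg(**kw):
    base = dict(
        seed=1, n_generations=2, families_per_generation=8, offspring_per_family=8,
        n_chromosomes=2, snps_per_chromosome=20, n_qtl=16,
    )
    base.update(kw)
    return SimConfig(**base)


class TestConfig:
    def test_counts_must_be_positive(self):
        with pytest.raises(SimulationError, match="positive"):
            small_cfg(families_per_generation=0)

    def test_selection_proportion_bounds(self):
        with pytest.raises(SimulationError, match="proportion"):
            small_cfg(selection=SelectionConfig(proportion=1.5))


class TestFounders:
    def test_fixed_frequency_heterozygosity(self):
        cfg = small_cfg(founder_freq_range=(0.5, 0.5), founder_ld=False)
        rng = np.random.default_rng(0)
        _, haps, freqs = simulate_founders(cfg, 400, rng)
        np.testing.assert_allclose(freqs, 0.5)
        het = np.mean(haps[:, 0, :] != haps[:, 1, :])
        assert het == pytest.approx(0.5, abs=0.02)

    def test_zero_founders_raises(self):
        with pytest.raises(SimulationError, match="founder"):
            simulate_founders(small_cfg(), 0, np.random.default_rng(0))

    def test_seed_determinism(self):
        cfg = small_cfg()
        _, h1, f1 = simulate_founders(cfg, 10, np.random.default_rng(3))
        _, h2, f2 = simulate_founders(cfg, 10, np.random.default_rng(3))
        np.testing.assert_array_equal(h1, h2)
        np.testing.assert_array_equal(f1, f2)

    def test_coalescent_founders_carry_ld(self):
        """Adjacent loci show more LD (r^2) than far-apart loci."""
        cfg = small_cfg(snps_per_chromosome=60, n_qtl=0)
        _, haps, freqs = simulate_founders(cfg, 100, np.random.default_rng(8))
        H = haps.reshape(200, -1).astype(float)  # haplotype x locus
        n = 60  # loci on chromosome 1
        R = np.corrcoef(H[:, :n].T) ** 2
        near = np.mean([R[i, i + 1] for i in range(n - 1)])
        far = np.mean([R[i, j] for i in range(0, n // 3) for j in range(2 * n // 3, n)])
        assert near > far + 0.05

    def test_frequencies_lie_in_requested_range(self):
        cfg = small_cfg(founder_freq_range=(0.2, 0.8))
        _, _, freqs = simulate_founders(cfg, 50, np.random.default_rng(9))
        assert freqs.min() >= 0.2 and freqs.max() <= 0.8


class TestGeneDrop:
    def test_zero_map_length_transmits_intact_haplotypes(self):
        cfg = small_cfg(map_length_morgans=0.0)
        rng = np.random.default_rng(1)
        genome = _build_genome(cfg, rng)
        parent = rng.integers(0, 2, size=(2, genome.n_loci)).astype(np.int8)
        gam = _meiosis(parent, genome, rng)
        # per chromosome, the gamete is one of the two parental haplotypes
        for c in np.unique(genome.chrom):
            sel = genome.chrom == c
            assert (
                np.array_equal(gam[sel], parent[0, sel])
                or np.array_equal(gam[sel], parent[1, sel])
            )

    def test_mendelian_consistency(self, tiny_sim):
        out = tiny_sim
        ped = out.pedigree
        g = out.genotypes
        idx = {a: i for i, a in enumerate(g.animal_ids)}
        checked = 0
        for a in g.animal_ids:
            i = ped.index_of([a])[0]
            s, d = ped.sire[i], ped.dam[i]
            sid = ped.ids[s] if s >= 0 else None
            did = ped.ids[d] if d >= 0 else None
            if sid in idx and did in idx:
                off, sire, dam = g.X[idx[a]], g.X[idx[sid]], g.X[idx[did]]
                lo = (sire > 1).astype(int) + (dam > 1).astype(int) * 0  # not a bound
                # offspring dosage must lie within the Mendelian range
                min_d = np.floor(sire / 2) + np.floor(dam / 2)
                max_d = np.ceil(sire / 2) + np.ceil(dam / 2)
                assert np.all(off >= min_d) and np.all(off <= max_d)
                checked += 1
        assert checked > 10

    def test_gene_content_tracks_pedigree_relationship(self, small_sim):
        """Correlation of centered gene content between relatives scales with A."""
        out = small_sim
        g = out.genotypes
        A, _ = sg.build_A(out.pedigree, subset=g.animal_ids)
        Z = g.X - g.X.mean(axis=0)
        C = np.corrcoef(Z)
        off = ~np.eye(len(A), dtype=bool)
        r = np.corrcoef(A[off], C[off])[0, 1]
        assert r > 0.6


class TestArchitecture:
    @pytest.mark.parametrize("ld", [False, True])
    def test_founder_covariance_matches_target_exactly(self, ld):
        """Realized founder TBV covariance equals Su exactly in both founder
        modes (in the LD mode the disequilibrium contribution is cancelled)."""
        cfg = small_cfg(seed=14, founder_ld=ld)
        out = run_breeding_program(cfg)
        tr = out.truth.set_index("animal")
        founders = [a for a in out.pedigree.ids if a.startswith("G0")]
        C = np.cov(tr.loc[founders, ["tbv_fy", "tbv_bw"]].to_numpy().T, ddof=1)
        np.testing.assert_allclose(C, cfg.vc.Su, rtol=1e-8)

    def test_ld_founders_calibrate_genic_covariance(self):
        """LD mode: sum_q 2 p_q (1-p_q) beta_q beta_q' equals Su exactly."""
        cfg = small_cfg(seed=4)  # founder_ld default True
        rng = np.random.default_rng(3)
        Q = rng.binomial(2, rng.uniform(0.2, 0.8, 16), size=(40, 16)).astype(float)
        eff = assign_trait_architecture(cfg, Q, rng)
        p = Q.mean(axis=0) / 2.0
        w = 2.0 * p * (1.0 - p)
        genic = eff.T @ (w[:, None] * eff)
        np.testing.assert_allclose(genic, cfg.vc.Su, rtol=1e-10)

    def test_within_family_tbv_variance_near_half_su(self, small_sim):
        """Mendelian-sampling variance is ~0.5 Su under LD founders."""
        tr = small_sim.truth.set_index("animal")
        d = small_sim.data.set_index("animal")
        wfv = tr.loc[d.index].groupby(d["family"])[["tbv_fy", "tbv_bw"]].var(ddof=1).mean()
        expect = 0.5 * np.diag(small_sim.config.vc.Su)
        np.testing.assert_allclose(wfv.to_numpy(), expect, rtol=0.35)

    def test_unit_genetic_correlation(self):
        cfg = small_cfg()
        cfg.vc.Su = np.array(
            [[2.0, np.sqrt(2.0 * 18000.0)], [np.sqrt(2.0 * 18000.0), 18000.0]]
        )
        rng = np.random.default_rng(2)
        Q = rng.binomial(2, 0.5, size=(50, 16)).astype(float)
        eff = assign_trait_architecture(cfg, Q, rng)
        T = (Q - Q.mean(axis=0)) @ eff
        assert np.corrcoef(T.T)[0, 1] == pytest.approx(1.0, abs=1e-8)

    def test_zero_qtl_zero_tbv(self):
        cfg = small_cfg(n_qtl=0)
        out = run_breeding_program(cfg)
        assert np.all(out.truth[["tbv_fy", "tbv_bw"]].to_numpy() == 0)

    def test_monomorphic_qtl_raise(self):
        cfg = small_cfg()
        Q = np.full((30, 16), 2.0)
        with pytest.raises(SimulationError, match="monomorphic"):
            assign_trait_architecture(cfg, Q, np.random.default_rng(0))


class TestPhenotypes:
    def test_noise_free_phenotype_equals_fixed_plus_tbv(self):
        cfg = small_cfg(
            seed=9, selection=SelectionConfig(on="phenotype", proportion=0.9)
        )
        cfg.vc.Su = np.zeros((2, 2))
        cfg.vc.Sf = np.zeros((2, 2))
        cfg.vc.Se = np.zeros((2, 2))
        out = run_breeding_program(cfg)
        d = out.data
        # without genetic, family and residual noise, all BW within a
        # hatch-year/line cell differ only through the age covariate
        resid = d["bw"] - cfg.age_slope[1] * (d["age"] - cfg.age_mean)
        spread = resid.groupby([d["hatch_year"], d["line"]]).std(ddof=0)
        assert spread.max() < 1e-9

    def test_five_fy_records_per_family(self, small_sim):
        counts = small_sim.data.groupby("family")["fy"].count()
        assert (counts == small_sim.config.fy_sampled_per_family).all()

    def test_fy_sampling_prefers_spread_bw_ranks(self, small_sim):
        d = small_sim.data
        sampled = d[d["fy"].notna()]
        assert set(sampled["harvest_group"].unique()) <= {1, 2, 3, 4, 5}

    def test_phenotypic_variance_close_to_target(self):
        cfg = small_cfg(seed=21, families_per_generation=30, offspring_per_family=12)
        out = run_breeding_program(cfg)
        gen1 = out.data[out.data["hatch_year"] == 2012]
        target = cfg.vc.Su[1, 1] + cfg.vc.Sf[1, 1] + cfg.vc.Se[1, 1]
        assert gen1["bw"].var() == pytest.approx(target, rel=0.25)


class TestBreedingProgram:
    def test_seed_determinism_full_run(self):
        o1 = run_breeding_program(small_cfg(seed=33))
        o2 = run_breeding_program(small_cfg(seed=33))
        pd.testing.assert_frame_equal(o1.data, o2.data)
        pd.testing.assert_frame_equal(o1.truth, o2.truth)
        np.testing.assert_array_equal(o1.genotypes.X, o2.genotypes.X)

    def test_no_selection_no_trend(self):
        cfg = small_cfg(
            seed=13, n_generations=3,
            selection=SelectionConfig(direction="random", proportion=1.0),
        )
        out = run_breeding_program(cfg)
        tr = out.truth.set_index("animal")
        means = {}
        for g in (1, 3):
            ids = [a for a in out.pedigree.ids if a.startswith(f"G{g}_")]
            means[g] = tr.loc[ids, "tbv_fy"].mean()
        assert abs(means[3] - means[1]) < 1.5  # ~ one genetic SD, drift only

    def test_upward_selection_positive_trend(self):
        cfg = SimConfig(
            seed=17, n_generations=3, families_per_generation=20,
            offspring_per_family=10, n_chromosomes=3, snps_per_chromosome=20,
            n_qtl=60, low_line_fraction=0.0,
            selection=SelectionConfig(trait="fy", direction="up", proportion=0.3),
        )
        out = run_breeding_program(cfg)
        tr = out.truth.set_index("animal")
        g1 = [a for a in out.pedigree.ids if a.startswith("G1_")]
        g3 = [a for a in out.pedigree.ids if a.startswith("G3_")]
        assert tr.loc[g3, "tbv_fy"].mean() > tr.loc[g1, "tbv_fy"].mean()

    def test_divergent_lines(self):
        cfg = SimConfig(
            seed=19, n_generations=3, families_per_generation=20,
            offspring_per_family=12, n_chromosomes=3, snps_per_chromosome=20,
            n_qtl=60, low_line_fraction=0.3,
            selection=SelectionConfig(trait="fy", direction="up", proportion=0.4),
        )
        out = run_breeding_program(cfg)
        tr = out.truth.set_index("animal")
        d = out.data[out.data["hatch_year"] == out.data["hatch_year"].max()]
        hi = tr.loc[d.loc[d["line"] == "H", "animal"], "tbv_fy"].mean()
        lo = tr.loc[d.loc[d["line"] == "L", "animal"], "tbv_fy"].mean()
        assert hi > lo

    def test_inbreeding_constraint_holds(self):
        cfg = SimConfig(
            seed=23, n_generations=3, families_per_generation=20,
            offspring_per_family=10, n_chromosomes=2, snps_per_chromosome=15,
            n_qtl=30, selection=SelectionConfig(proportion=0.5),
        )
        out = run_breeding_program(cfg)
        dF = np.diff(out.mean_f_by_generation.to_numpy())
        assert np.mean(dF) <= 0.01 + 1e-12

    def test_genotyped_subset_includes_parents_and_fy_fish(self, small_sim):
        gen = set(small_sim.genotypes.animal_ids)
        fy_fish = set(small_sim.data.loc[small_sim.data["fy"].notna(), "animal"])
        assert fy_fish <= gen


def test_bundle_roundtrip(small_sim, tmp_path):
    paths = small_sim.write_bundle(tmp_path)
    ped = sg.read_pedigree_csv(paths["pedigree"])
    assert ped.ids == small_sim.pedigree.ids
    data = pd.read_csv(paths["phenotypes"])
    assert len(data) == len(small_sim.data)
    truth = pd.read_csv(paths["truth"], sep="\t")
    assert {"animal", "tbv_fy", "tbv_bw", "F"} <= set(truth.columns)
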