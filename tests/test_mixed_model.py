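import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import ssgblup as sg
from ssgblup.mixed_model import ModelError, TraitModel, ModelSpec, build_design

from conftest import model_exact_dataset, random_pedigree


def two_trait_spec():
    """Intercept-only fixed part for both traits (clean oracle algebra)."""
    return ModelSpec(
        traits=["fy", "bw"],
        models={"fy": TraitModel(), "bw": TraitModel()},
    )


def family_data(ped, rng, n_per_fam=4, fy_all=True):
    """One founder pair per family, offspring carry the records."""
    rows = []
    for i in range(len(ped)):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0:
            continue
        fam = f"{ped.ids[s]}x{ped.ids[d]}"
        rows.append(
            {"animal": ped.ids[i], "family": fam,
             "fy": rng.normal(50, 2), "bw": rng.normal(1000, 200)}
        )
    df = pd.DataFrame(rows)
    if not fy_all:
        df.loc[df.index % 3 != 0, "fy"] = np.nan
    return df


@pytest.fixture(scope="module")
def vc_simple():
    return sg.VarianceComponents(
        Su=np.array([[2.0, 10.0], [10.0, 18000.0]]),
        Sf=np.array([[0.3, 5.0], [5.0, 5000.0]]),
        Se=np.array([[2.5, 30.0], [30.0, 30000.0]]),
    )


class TestDesign:
    def test_intercept_when_no_factors(self):
        X, names = build_design(pd.DataFrame({"x": [1, 2]}), TraitModel())
        assert names == ["intercept"]
        np.testing.assert_array_equal(X, [[1.0], [1.0]])

    def test_first_factor_full_later_drop_first(self):
        df = pd.DataFrame({"a": ["u", "v", "u"], "b": ["x", "y", "y"]})
        X, names = build_design(df, TraitModel(factors=["a", "b"]))
        assert names == ["a=u", "a=v", "b=y"]

    def test_interaction_term(self):
        df = pd.DataFrame({"y": [2012, 2012, 2014], "g": [1, 2, 1]})
        X, names = build_design(df, TraitModel(factors=["y:g"]))
        assert names == ["y:g=2012:1", "y:g=2012:2", "y:g=2014:1"]


class TestSolve:
    def test_intercept_only_mean(self):
        """With huge prior variances off, the intercept estimate is the mean."""
        ped = sg.renumber_pedigree(
            [("s", 0, 0), ("d", 0, 0)] + [(f"o{i}", "s", "d") for i in range(3)]
        )
        data = pd.DataFrame(
            {"animal": ["o0", "o1", "o2"], "family": "f1",
             "fy": [1.0, 2.0, 3.0], "bw": [1.0, 2.0, 3.0]}
        )
        vc = sg.VarianceComponents(Su=np.eye(2) * 1e-6, Sf=np.eye(2) * 1e-6,
                                   Se=np.eye(2))
        system = sg.build_mme(two_trait_spec(), data, sg.build_A_inverse(ped), vc, ped)
        sol = sg.solve_mme(system)
        assert sol.b["fy"]["intercept"] == pytest.approx(2.0, abs=1e-4)

    def test_zero_variance_ratio_equals_least_squares(self):
        rng = np.random.default_rng(0)
        ped = random_pedigree(40, rng, n_founders=8)
        data = family_data(ped, rng)
        vc = sg.VarianceComponents(Su=np.eye(2) * 1e-8, Sf=np.eye(2) * 1e-8,
                                   Se=np.diag([2.5, 30000.0]))
        system = sg.build_mme(two_trait_spec(), data, sg.build_A_inverse(ped), vc, ped)
        sol = sg.solve_mme(system)
        assert sol.b["fy"]["intercept"] == pytest.approx(data["fy"].mean(), abs=1e-4)
        assert sol.b["bw"]["intercept"] == pytest.approx(data["bw"].mean(), abs=1e-2)

    def test_shrinkage_limit_zero_ebv(self):
        rng = np.random.default_rng(1)
        ped = random_pedigree(30, rng, n_founders=6)
        data = family_data(ped, rng)
        vc = sg.VarianceComponents(Su=np.eye(2) * 1e-9, Sf=np.eye(2) * 1e-9,
                                   Se=np.diag([2.5, 30000.0]))
        sol = sg.solve_mme(
            sg.build_mme(two_trait_spec(), data, sg.build_A_inverse(ped), vc, ped)
        )
        assert np.abs(sol.u.to_numpy()).max() < 1e-4

    def test_trait_without_records_gets_zero_ebv(self, vc_simple):
        rng = np.random.default_rng(2)
        ped = random_pedigree(30, rng, n_founders=6)
        data = family_data(ped, rng)
        data["fy"] = np.nan
        vc = sg.VarianceComponents(Su=np.diag([2.0, 18000.0]),
                                   Sf=np.diag([0.3, 5000.0]),
                                   Se=np.diag([2.5, 30000.0]))
        sol = sg.solve_mme(
            sg.build_mme(two_trait_spec(), data, sg.build_A_inverse(ped), vc, ped)
        )
        # with diagonal covariances nothing flows into the FY equations
        assert np.abs(sol.u["fy"].to_numpy()).max() < 1e-10

    def test_sparse_solution_matches_dense_solve(self, vc_simple):
        rng = np.random.default_rng(3)
        ped = random_pedigree(100, rng, n_founders=20)
        data = family_data(ped, rng, fy_all=False)
        system = sg.build_mme(two_trait_spec(), data, sg.build_A_inverse(ped),
                              vc_simple, ped)
        sol = sg.solve_mme(system)
        dense = np.linalg.solve(system.C.toarray(), system.rhs)
        stacked = np.concatenate(
            [sol.b["fy"].to_numpy(), sol.b["bw"].to_numpy(),
             sol.u["fy"].to_numpy(), sol.u["bw"].to_numpy(),
             sol.f["fy"].to_numpy(), sol.f["bw"].to_numpy()]
        )
        np.testing.assert_allclose(stacked, dense, atol=1e-8)

    def test_direct_and_cg_agree(self, vc_simple):
        rng = np.random.default_rng(4)
        ped = random_pedigree(60, rng, n_founders=12)
        data = family_data(ped, rng)
        system = sg.build_mme(two_trait_spec(), data, sg.build_A_inverse(ped),
                              vc_simple, ped)
        direct = sg.solve_mme(system, method="direct")
        cg = sg.solve_mme(system, method="cg", tol=1e-12)
        np.testing.assert_allclose(
            direct.u.to_numpy(), cg.u.to_numpy(), atol=1e-6
        )

    def test_animal_permutation_permutes_solutions(self, vc_simple):
        rng = np.random.default_rng(5)
        ped = random_pedigree(40, rng, n_founders=8)
        data = family_data(ped, rng)
        sol1 = sg.solve_mme(
            sg.build_mme(two_trait_spec(), data, sg.build_A_inverse(ped), vc_simple, ped)
        )
        data2 = data.sample(frac=1.0, random_state=0)
        sol2 = sg.solve_mme(
            sg.build_mme(two_trait_spec(), data2, sg.build_A_inverse(ped), vc_simple, ped)
        )
        pd.testing.assert_frame_equal(sol1.u, sol2.u, atol=1e-9, rtol=0)

    def test_ssgblup_without_genotypes_reproduces_pblup(self, vc_simple):
        rng = np.random.default_rng(6)
        ped = random_pedigree(40, rng, n_founders=8)
        data = family_data(ped, rng)
        A_inv = sg.build_A_inverse(ped)
        H_inv = sg.build_H_inverse(A_inv, np.zeros((0, 0)), np.zeros((0, 0)),
                                   np.array([], dtype=int))
        s1 = sg.solve_mme(sg.build_mme(two_trait_spec(), data, A_inv, vc_simple, ped))
        s2 = sg.solve_mme(sg.build_mme(two_trait_spec(), data, H_inv, vc_simple, ped))
        np.testing.assert_array_equal(s1.u.to_numpy(), s2.u.to_numpy())

    def test_unknown_animal_raises(self, vc_simple, trio_pedigree):
        data = pd.DataFrame({"animal": ["ghost"], "family": "f", "fy": [1.0], "bw": [1.0]})
        with pytest.raises(Exception, match="absent"):
            sg.build_mme(two_trait_spec(), data, sg.build_A_inverse(trio_pedigree),
                         vc_simple, trio_pedigree)


class TestAdjustPhenotypes:
    def test_subtracts_fixed_and_family(self):
        ped = sg.renumber_pedigree(
            [("s", 0, 0), ("d", 0, 0)] + [(f"o{i}", "s", "d") for i in range(4)]
        )
        data = pd.DataFrame(
            {"animal": [f"o{i}" for i in range(4)], "family": "f1",
             "fy": [5.0, 6.0, 7.0, 8.0], "bw": [1.0, 1.0, 2.0, 2.0]}
        )
        vc = sg.VarianceComponents(Su=np.eye(2), Sf=np.eye(2), Se=np.eye(2))
        spec = two_trait_spec()
        sol = sg.solve_mme(sg.build_mme(spec, data, sg.build_A_inverse(ped), vc, ped))
        adj = sg.adjust_phenotypes(data, sol, spec)
        expected = (
            data["fy"].to_numpy()
            - sol.b["fy"]["intercept"]
            - sol.f["fy"]["f1"]
        )
        np.testing.assert_allclose(adj["fy"].to_numpy(), expected, atol=1e-12)

    def test_mean_near_zero_when_intercept_absorbed(self, small_sim):
        spec = sg.fy_bw_default()
        vc = small_sim.config.vc
        ped = small_sim.pedigree
        sol = sg.solve_mme(
            sg.build_mme(spec, small_sim.data, sg.build_A_inverse(ped), vc, ped)
        )
        adj = sg.adjust_phenotypes(small_sim.data, sol, spec)
        for t in spec.traits:
            vals = adj[t].dropna()
            assert abs(vals.mean()) < 0.2 * vals.std()


class TestGeneticParameters:
    def test_fy_row_of_reported_components(self):
        vc = sg.VarianceComponents(Su=[[1.99]], Sf=[[0.24]], Se=[[2.60]])
        gp = sg.compute_genetic_parameters(vc, ["fy"])
        assert round(gp.h2["fy"], 2) == 0.41

    def test_bw_row_of_reported_components(self):
        vc = sg.VarianceComponents(Su=[[17648.0]], Sf=[[5679.0]], Se=[[29913.0]])
        gp = sg.compute_genetic_parameters(vc, ["bw"])
        assert round(gp.h2["bw"], 2) == 0.33
        assert round(gp.f2["bw"], 2) == 0.11

    def test_zero_covariance_zero_correlation(self):
        vc = sg.VarianceComponents(Su=np.diag([2.0, 18000.0]),
                                   Sf=np.diag([0.2, 5000.0]),
                                   Se=np.diag([2.6, 30000.0]))
        gp = sg.compute_genetic_parameters(vc)
        assert gp.r_g == 0.0

    def test_zero_total_variance_raises(self):
        vc = sg.VarianceComponents(Su=np.zeros((2, 2)), Sf=np.zeros((2, 2)),
                                   Se=np.zeros((2, 2)))
        with pytest.raises(ModelError, match="total variance"):
            sg.compute_genetic_parameters(vc)


class TestReml:
    def test_boundary_family_variance(self):
        """Data with no family effect: f2 estimates end up at/near zero."""
        rng = np.random.default_rng(10)
        ped = random_pedigree(220, rng, n_founders=40)
        fam = np.array([f"fam{i % 30}" for i in range(len(ped) - 40)])
        vc_gen = sg.VarianceComponents(
            Su=np.array([[2.0, 20.0], [20.0, 18000.0]]),
            Sf=np.zeros((2, 2)),
            Se=np.array([[2.5, 40.0], [40.0, 30000.0]]),
        )
        # model_exact_dataset draws family effects from Sf = 0 -> none
        data, _ = model_exact_dataset(ped, np.ones(len(fam), bool), fam, 3, vc=vc_gen)
        start = sg.VarianceComponents(Su=np.diag([2.0, 20000.0]),
                                      Sf=np.diag([0.5, 4000.0]),
                                      Se=np.diag([2.5, 28000.0]))
        spec = two_trait_spec()
        vc, _ = sg.estimate_vc_aireml(spec, data, sg.build_A_inverse(ped), start, ped,
                                      max_iter=80)
        gp = sg.compute_genetic_parameters(vc)
        assert gp.f2["fy"] < 0.02
        assert gp.f2["bw"] < 0.02

    def test_balanced_half_sib_matches_anova(self):
        """REML sire-model variance equals the ANOVA estimator on a balanced
        half-sib design (family covariance held at ~zero)."""
        rng = np.random.default_rng(11)
        n_sires, n_off = 40, 12
        records = [(f"S{i}", 0, 0) for i in range(n_sires)]
        rows = []
        s2s_true, s2e_true = 1.0, 4.0  # sire variance = Su/4
        for i in range(n_sires):
            s_eff = rng.normal(0, np.sqrt(s2s_true))
            for k in range(n_off):
                a = f"O{i}_{k}"
                records.append((a, f"S{i}", "0"))
                rows.append({"animal": a, "family": f"fam{i}",
                             "fy": 10 + s_eff + rng.normal(0, np.sqrt(s2e_true)),
                             "bw": np.nan})
        ped = sg.renumber_pedigree(records)
        data = pd.DataFrame(rows)
        data["bw"] = data["fy"]  # second trait unused; fit single trait
        spec = ModelSpec(traits=["fy"], models={"fy": TraitModel()})
        start = sg.VarianceComponents(Su=[[1.0]], Sf=[[1e-8]], Se=[[4.0]])
        vc, _ = sg.estimate_vc_aireml(
            spec, data, sg.build_A_inverse(ped), start, ped,
            fix_components=("f",), max_iter=100,
        )
        # ANOVA oracle
        y = data["fy"].to_numpy().reshape(n_sires, n_off)
        msb = n_off * np.var(y.mean(axis=1), ddof=1)
        msw = np.mean(np.var(y, axis=1, ddof=1))
        s2s_anova = (msb - msw) / n_off
        su_anova = 4 * s2s_anova
        se_anova = msw - s2s_anova  # residual = within - 3/4 Su ... see below
        # within-half-sib-family variance = 3/4 Su + Se
        se_anova = msw - 3 * s2s_anova
        assert vc.Su[0, 0] == pytest.approx(su_anova, rel=1e-4, abs=1e-4)
        assert vc.Se[0, 0] == pytest.approx(se_anova, rel=1e-4, abs=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_parameter_recovery_model_exact(self, seed, recovery_results):
        """Generating values sit inside the replicate mean +- 2 MC-SE."""
        # accumulation happens in the fixture; assert once on the last seed
        if seed < 4:
            assert recovery_results[seed] is not None
            return
        ests = np.array([r for r in recovery_results if r is not None])
        mean = ests.mean(axis=0)
        mcse = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
        true = np.array([2.0, 18000.0, 0.4, 4000.0, 2.5, 28000.0])
        assert np.all(np.abs(mean - true) <= 2.5 * np.maximum(mcse, 0.05 * true))


@pytest.fixture(scope="module")
def recovery_results():
    """Five small model-exact replicates fitted by AI-REML."""
    results = []
    vc_gen = sg.VarianceComponents(
        Su=np.array([[2.0, 30.0], [30.0, 18000.0]]),
        Sf=np.array([[0.4, 10.0], [10.0, 4000.0]]),
        Se=np.array([[2.5, 50.0], [50.0, 28000.0]]),
    )
    start = sg.VarianceComponents(Su=np.diag([1.5, 15000.0]),
                                  Sf=np.diag([0.6, 6000.0]),
                                  Se=np.diag([3.0, 30000.0]))
    spec = two_trait_spec()
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        ped = random_pedigree(360, rng, n_founders=60)
        fam = np.array([f"fam{i % 50}" for i in range(len(ped) - 60)])
        data, _ = model_exact_dataset(ped, np.ones(len(fam), bool), fam,
                                      200 + seed, vc=vc_gen)
        vc, _ = sg.estimate_vc_aireml(spec, data, sg.build_A_inverse(ped),
                                      start, ped, max_iter=80)
        results.append([vc.Su[0, 0], vc.Su[1, 1], vc.Sf[0, 0], vc.Sf[1, 1],
                        vc.Se[0, 0], vc.Se[1, 1]])
    return results
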