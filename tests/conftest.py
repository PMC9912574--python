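import numpy as np
import pandas as pd
import pytest

import ssgblup as sg
from ssgblup.simulate import SimConfig, run_breeding_program, default_variance_components


@pytest.fixture(scope="session")
def trio_pedigree():
    """Two unrelated founders and their offspring."""
    return sg.renumber_pedigree([("s", "0", "0"), ("d", "0", "0"), ("c", "s", "d")])


def random_pedigree(n, rng, n_founders=10):
    """A random valid pedigree: founders first, then random matings."""
    records = [(f"F{i}", "0", "0") for i in range(n_founders)]
    ids = [r[0] for r in records]
    for i in range(n - n_founders):
        s, d = rng.choice(len(ids), 2, replace=False)
        records.append((f"A{i}", ids[s], ids[d]))
        ids.append(f"A{i}")
    return sg.renumber_pedigree(records)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete breeding-program dataset (2 generations)."""
    cfg = SimConfig(
        seed=42,
        n_generations=2,
        families_per_generation=12,
        offspring_per_family=10,
        n_chromosomes=3,
        snps_per_chromosome=40,
        n_qtl=60,
    )
    return run_breeding_program(cfg)


@pytest.fixture(scope="session")
def tiny_sim():
    cfg = SimConfig(
        seed=5,
        n_generations=2,
        families_per_generation=8,
        offspring_per_family=8,
        n_chromosomes=2,
        snps_per_chromosome=25,
        n_qtl=20,
    )
    return run_breeding_program(cfg)


def model_exact_dataset(ped, fy_pattern, fam, seed, vc=None, mu=(50.0, 1000.0)):
    """Phenotypes drawn exactly from the two-trait animal model.

    ``fy_pattern`` is a boolean mask (per data row) of FY-recorded animals;
    ``fam`` the family label per row (aligned with ``ped`` order subset).
    Returns a data frame with the model's required columns.
    """
    if vc is None:
        vc = default_variance_components()
    def msqrt(S):  # symmetric square root, valid for singular matrices
        w, V = np.linalg.eigh(S)
        return V @ np.diag(np.sqrt(np.maximum(w, 0.0))) @ V.T

    rng = np.random.default_rng(seed)
    n = len(ped)
    A, _ = sg.build_A(ped)
    L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
    U = L @ rng.standard_normal((n, 2)) @ msqrt(vc.Su).T
    fams = pd.unique(fam)
    sf_root = msqrt(vc.Sf)
    Fq = {f: sf_root @ rng.standard_normal(2) for f in fams}
    E = (msqrt(vc.Se) @ rng.standard_normal((2, len(fam)))).T
    idx = np.arange(n - len(fam), n)  # data rows = youngest animals
    fy = mu[0] + U[idx, 0] + np.array([Fq[f][0] for f in fam]) + E[:, 0]
    bw = mu[1] + U[idx, 1] + np.array([Fq[f][1] for f in fam]) + E[:, 1]
    return pd.DataFrame(
        {
            "animal": [ped.ids[i] for i in idx],
            "family": fam,
            "line": "H",
            "hatch_year": 2012,
            "harvest_year": 2013,
            "harvest_group": 1,
            "age": 400.0,
            "harvest_age": 445.0,
            "fy": np.where(fy_pattern, fy, np.nan),
            "bw": bw,
        }
    ), U[idx]
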