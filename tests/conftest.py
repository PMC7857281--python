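import numpy as np
import pandas as pd
import pytest

from genegroups import pedigree as pdg
from genegroups.simulate import reduced_config, simulate_reliable


def random_pedigree(n: int, seed: int, immigrant_prob: float = 0.3,
                    founder_frac: float = 0.25) -> pdg.Pedigree:
    """Random valid pedigree: founders first, later individuals draw parents
    from earlier ones (possibly unknown), so arbitrary inbreeding arises."""
    rng = np.random.default_rng(seed)
    n_founders = max(2, int(n * founder_frac))
    inds = []
    for i in range(n_founders):
        inds.append(pdg.Individual(
            id=f"P{i}", cohort=0,
            sex="F" if i % 2 else "M",
            immigrant_founder=bool(rng.random() < immigrant_prob)))
    for i in range(n_founders, n):
        k = rng.integers(max(1, i - 40), i)  # parents among recent individuals
        sire = f"P{rng.integers(0, i)}" if rng.random() < 0.9 else ""
        dam = f"P{k}" if rng.random() < 0.9 else ""
        inds.append(pdg.Individual(id=f"P{i}", sire=sire, dam=dam, cohort=1 + i // 10))
    return pdg.Pedigree(inds)


def tabular_relatedness(ped: pdg.Pedigree) -> np.ndarray:
    """Independent oracle: additive relationship matrix A by the tabular method
    (A_ii = 1 + f_i with f_i = 0.5 A_sd; A_ij = 0.5 (A_i,sire(j) + A_i,dam(j)))."""
    n = len(ped)
    A = np.zeros((n, n))
    for j in range(n):
        s, d = ped.sire_idx[j], ped.dam_idx[j]
        for i in range(j):
            val = 0.0
            if s >= 0:
                val += 0.5 * A[i, s]
            if d >= 0:
                val += 0.5 * A[i, d]
            A[i, j] = A[j, i] = val
        A[j, j] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def allele_drop_q(ped: pdg.Pedigree, ga: dict, n_rep: int, seed: int) -> np.ndarray:
    """Monte-Carlo oracle for q: drop group-labelled alleles down the pedigree
    and average the immigrant-allele fraction over replicates."""
    rng = np.random.default_rng(seed)
    n = len(ped)
    al1 = np.empty((n, n_rep), dtype=np.int8)
    al2 = np.empty((n, n_rep), dtype=np.int8)
    for k, ind in enumerate(ped.individuals):
        s, d = ped.sire_idx[k], ped.dam_idx[k]
        if s < 0 and d < 0:
            lab = 1 if ga[ind.id] == pdg.IMMIGRANT else 0
            al1[k] = lab
            al2[k] = lab
            continue
        if s >= 0:
            pick = rng.integers(0, 2, n_rep)
            al1[k] = np.where(pick == 0, al1[s], al2[s])
        else:
            al1[k] = 0  # phantom native parent
        if d >= 0:
            pick = rng.integers(0, 2, n_rep)
            al2[k] = np.where(pick == 0, al1[d], al2[d])
        else:
            al2[k] = 0
    return (al1.astype(float) + al2) / 2.0


@pytest.fixture(scope="session")
def trio_pedigree() -> pdg.Pedigree:
    return pdg.Pedigree([
        pdg.Individual(id="S", sex="M", cohort=1),
        pdg.Individual(id="D", sex="F", cohort=1, immigrant_founder=True),
        pdg.Individual(id="O", sire="S", dam="D", sex="F", cohort=2),
    ])


@pytest.fixture(scope="session")
def reduced_dataset():
    """One reduced-scale simulated study (10 cohorts of ~60), shared by tests."""
    res = simulate_reliable(reduced_config(seed=3), min_observations=450)
    ped = pdg.prune_to_phenotyped(res.build_pedigree(), res.observations["id"])
    return res, ped


def toy_observations(n: int, seed: int = 0) -> tuple[pd.DataFrame, pdg.Pedigree]:
    """Unrelated individuals with simple covariates, for design-matrix tests."""
    rng = np.random.default_rng(seed)
    ped = pdg.Pedigree([
        pdg.Individual(id=f"I{i}", cohort=2000 + i % 4) for i in range(n)])
    obs = pd.DataFrame({
        "id": [f"I{i}" for i in range(n)],
        "survival": rng.integers(0, 2, n),
        "sex": np.where(rng.random(n) < 0.5, "F", "M"),
        "clutch_date": rng.normal(45, 10, n).round(1),
        "brood_id": [f"{2000 + i % 4}_b{i // 2}" for i in range(n)],
        "cohort": [2000 + i % 4 for i in range(n)],
        "q": rng.random(n),
        "f": rng.random(n) * 0.2,
    })
    return obs, ped
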