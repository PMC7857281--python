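import io

import numpy as np
import pandas as pd
import pytest

from genegroups import pedigree as pdg
from conftest import allele_drop_q, random_pedigree, tabular_relatedness


def _read(text: str) -> pdg.Pedigree:
    return pdg.read_pedigree(io.StringIO(text))


class TestReadPedigree:
    def test_smallest_valid_pedigree(self):
        ped = _read(
            "id,sire,dam,cohort,sex,immigrant\n"
            "A,,,1990,M,0\nB,,,1990,F,1\nC,A,B,1991,F,0\n")
        assert len(ped) == 3
        assert ped.ids[:2] == ["A", "B"]  # founders first
        assert ped.individuals[1].immigrant_founder

    def test_order_invariance(self):
        fwd = _read("id,sire,dam,cohort,sex,immigrant\n"
                    "A,,,1,M,0\nB,,,1,F,0\nC,A,B,2,F,0\n")
        rev = _read("id,sire,dam,cohort,sex,immigrant\n"
                    "C,A,B,2,F,0\nA,,,1,M,0\nB,,,1,F,0\n")
        assert fwd.ids == rev.ids

    def test_cycle_detected(self):
        with pytest.raises(pdg.PedigreeError, match="cycle"):
            _read("id,sire,dam,cohort,sex,immigrant\n"
                  "A,B,,1,M,0\nB,A,,1,M,0\n")

    def test_missing_parent_named(self):
        with pytest.raises(pdg.PedigreeError, match="GHOST"):
            _read("id,sire,dam,cohort,sex,immigrant\nA,GHOST,,1,M,0\n")

    def test_duplicate_id(self):
        with pytest.raises(pdg.PedigreeError, match="duplicate"):
            _read("id,sire,dam,cohort,sex,immigrant\nA,,,1,M,0\nA,,,1,F,0\n")

    def test_immigrant_with_parent_rejected(self):
        with pytest.raises(pdg.PedigreeError, match="immigrant"):
            _read("id,sire,dam,cohort,sex,immigrant\n"
                  "A,,,1,M,0\nB,A,,2,F,1\n")

    def test_na_encodes_unknown(self):
        ped = _read("id,sire,dam,cohort,sex,immigrant\nA,NA,NA,1,U,0\n")
        assert ped.is_founder(0)


class TestPrune:
    def test_single_founder(self):
        ped = random_pedigree(30, seed=1)
        founder = ped.ids[0]
        assert len(pdg.prune_to_phenotyped(ped, [founder])) == 1

    def test_ancestor_closure_matches_brute_force(self):
        ped = random_pedigree(60, seed=2)
        target = ped.ids[-1]
        pruned = pdg.prune_to_phenotyped(ped, [target])
        # brute force ancestor walk
        expect = set()
        stack = [ped.index[target]]
        while stack:
            k = stack.pop()
            if k in expect:
                continue
            expect.add(k)
            stack += [p for p in (ped.sire_idx[k], ped.dam_idx[k]) if p >= 0]
        assert set(pruned.ids) == {ped.ids[k] for k in expect}

    def test_empty_set_rejected(self):
        with pytest.raises(pdg.PedigreeError, match="empty"):
            pdg.prune_to_phenotyped(random_pedigree(10, seed=0), [])


class TestAssignGroups:
    def test_flag_partition(self):
        ped = random_pedigree(40, seed=3)
        ga = pdg.assign_groups(ped)
        founders = [k for k in range(len(ped)) if ped.is_founder(k)]
        assert set(ga) == {ped.ids[k] for k in founders}
        for k in founders:
            expect = pdg.IMMIGRANT if ped.individuals[k].immigrant_founder \
                else pdg.NATIVE
            assert ga[ped.ids[k]] == expect

    def test_no_immigrants_all_native(self):
        ped = random_pedigree(30, seed=4, immigrant_prob=0.0)
        assert set(pdg.assign_groups(ped).values()) == {pdg.NATIVE}


class TestGroupCoefficients:
    def test_immigrant_native_cross(self, trio_pedigree):
        gc = pdg.group_coefficients(trio_pedigree,
                                    pdg.assign_groups(trio_pedigree))
        k = gc.index["O"]
        assert gc.q[k] == 0.5
        assert gc.f[k] == 0.0

    def test_full_sib_mating(self):
        ped = pdg.Pedigree([
            pdg.Individual(id="S", immigrant_founder=True),
            pdg.Individual(id="D"),
            pdg.Individual(id="C1", sire="S", dam="D"),
            pdg.Individual(id="C2", sire="S", dam="D"),
            pdg.Individual(id="X", sire="C1", dam="C2"),
        ])
        gc = pdg.group_coefficients(ped, pdg.assign_groups(ped))
        k = gc.index["X"]
        assert gc.q[k] == 0.5
        assert gc.f[k] == 0.25  # textbook full-sib kinship

    def test_row_order_invariance(self):
        ped = random_pedigree(50, seed=5)
        gc = pdg.group_coefficients(ped, pdg.assign_groups(ped))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ped))
        shuffled = pdg.Pedigree([ped.individuals[k] for k in perm])
        gc2 = pdg.group_coefficients(shuffled, pdg.assign_groups(shuffled))
        for pid in ped.ids:
            assert gc.q[gc.index[pid]] == pytest.approx(
                gc2.q[gc2.index[pid]], abs=1e-15)
            assert gc.f[gc.index[pid]] == pytest.approx(
                gc2.f[gc2.index[pid]], abs=1e-15)

    def test_q_bounds_and_native_complement(self):
        ped = random_pedigree(80, seed=6)
        gc = pdg.group_coefficients(ped, pdg.assign_groups(ped))
        assert np.all((gc.q >= 0) & (gc.q <= 1))
        assert np.allclose(gc.q + (1 - gc.q), 1.0)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_random_pedigree_oracles(self, seed):
        """q matches allele-dropping Monte Carlo; f matches tabular kinship."""
        ped = random_pedigree(50, seed=seed)
        ga = pdg.assign_groups(ped)
        gc = pdg.group_coefficients(ped, ga)
        q_mc = allele_drop_q(ped, ga, n_rep=40_000, seed=seed).mean(axis=1)
        assert np.abs(gc.q - q_mc).max() < 0.01
        A = tabular_relatedness(ped)
        assert np.abs(gc.f - (np.diag(A) - 1.0)).max() < 1e-12

    def test_kinship_pairwise_matches_tabular(self):
        ped = random_pedigree(40, seed=14)
        A = tabular_relatedness(ped)
        rng = np.random.default_rng(1)
        for _ in range(20):
            i, j = rng.integers(0, len(ped), 2)
            phi = ped.kinship(ped.ids[i], ped.ids[j])
            assert phi == pytest.approx(0.5 * A[i, j], abs=1e-12)


class TestAInverse:
    def test_single_founder(self):
        ped = pdg.Pedigree([pdg.Individual(id="A")])
        rs = pdg.a_inverse(ped)
        assert rs.a_inv.toarray() == pytest.approx(np.array([[1.0]]))

    def test_trio_matches_direct_inverse(self, trio_pedigree):
        rs = pdg.a_inverse(trio_pedigree)
        A = np.array([[1, 0, .5], [0, 1, .5], [.5, .5, 1]])
        assert np.abs(rs.a_inv.toarray() - np.linalg.inv(A)).max() < 1e-12

    @pytest.mark.parametrize("seed", [21, 22, 23])
    def test_inverse_of_tabular_a(self, seed):
        ped = random_pedigree(60, seed=seed)
        rs = pdg.a_inverse(ped)
        A = tabular_relatedness(ped)
        err = np.abs(rs.a_inv @ A - np.eye(len(ped))).max()
        assert err < 1e-8

    def test_mendelian_variance_cases(self):
        ped = pdg.Pedigree([
            pdg.Individual(id="S"),
            pdg.Individual(id="D"),
            pdg.Individual(id="O", sire="S", dam="D"),
            pdg.Individual(id="H", sire="S"),  # phantom dam
        ])
        d = pdg.mendelian_variances(ped)
        assert d[ped.index["S"]] == 1.0
        assert d[ped.index["O"]] == 0.5
        assert d[ped.index["H"]] == 0.75


def test_coefficients_roundtrip_csv(tmp_path, trio_pedigree):
    gc = pdg.group_coefficients(trio_pedigree, pdg.assign_groups(trio_pedigree))
    path = tmp_path / "coef.csv"
    gc.write(path)
    back = pd.read_csv(path)
    assert list(back.columns) == ["id", "q", "f"]
    assert back["q"].tolist() == pytest.approx(list(gc.q))
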