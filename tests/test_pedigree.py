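"""Pedigree parsing, haplodiploid kinship algebra, and the gene-drop oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haploquant import (
    Individual,
    Pedigree,
    PedigreeError,
    additive_matrix,
    gene_drop_relatedness,
    kinship,
    random_pedigree,
    read_pedigree,
)


def _write_csv(tmp_path, rows, header="id,dam,sire,sex,nest,cohort"):
    path = tmp_path / "ped.csv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestReadPedigree:
    def test_minimal_trio(self, tmp_path):
        path = _write_csv(
            tmp_path,
            ["m,,,female,n1,2008", "s,,,male,n1,", "d,m,s,female,n1,2009"],
        )
        ped = read_pedigree(path)
        assert len(ped) == 3
        assert ped.ids[-1] == "d"
        assert ped["d"].dam == "m" and ped["d"].sire == "s"

    def test_order_invariance(self, tmp_path):
        """A daughter listed before her dam yields the same sorted pedigree."""
        a = read_pedigree(
            _write_csv(tmp_path, ["d,m,s,female,,", "m,,,female,,", "s,,,male,,"])
        )
        b = read_pedigree(
            _write_csv(tmp_path, ["m,,,female,,", "s,,,male,,", "d,m,s,female,,"])
        )
        assert a.ids == b.ids
        assert [i.dam for i in a] == [i.dam for i in b]

    def test_cycle_is_fatal(self, tmp_path):
        path = _write_csv(
            tmp_path,
            ["a,c,,female,,", "b,a,,female,,", "c,b,,female,,"],
        )
        with pytest.raises(PedigreeError, match="cycle"):
            read_pedigree(path)

    def test_sex_role_conflicts_fatal(self, tmp_path):
        with pytest.raises(PedigreeError, match="not female"):
            read_pedigree(
                _write_csv(tmp_path, ["x,,,male,,", "d,x,,female,,"])
            )
        with pytest.raises(PedigreeError, match="not male"):
            read_pedigree(
                _write_csv(tmp_path, ["x,,,female,,", "d,,x,female,,"])
            )

    def test_duplicate_id_fatal(self, tmp_path):
        with pytest.raises(PedigreeError, match="duplicate"):
            read_pedigree(_write_csv(tmp_path, ["a,,,female,,", "a,,,female,,"]))

    def test_missing_parent_becomes_implicit_founder(self, tmp_path):
        ped = read_pedigree(_write_csv(tmp_path, ["d,m,s,female,,"]))
        assert set(ped.implicit_founders) == {"m", "s"}
        assert ped["m"].sex == "female" and ped["s"].sex == "male"


class TestKinship:
    def test_unrelated_founders(self):
        ped = Pedigree(
            [Individual("a", "female"), Individual("b", "female")]
        )
        phi = kinship(ped)
        assert phi.loc("a", "b") == 0.0
        assert phi.loc("a", "a") == 0.5

    def test_mother_daughter(self, sister_pedigree):
        assert kinship(sister_pedigree).loc("dam", "d1") == pytest.approx(0.25)

    def test_full_sisters(self, sister_pedigree):
        assert kinship(sister_pedigree).loc("d1", "d2") == pytest.approx(0.375)

    def test_male_self_kinship_is_one(self, sister_pedigree):
        assert kinship(sister_pedigree).loc("sire", "sire") == 1.0


class TestAdditiveMatrix:
    def test_super_relatedness_of_full_sisters(self, sister_pedigree):
        a = additive_matrix(sister_pedigree)
        assert a.loc("d1", "d2") == pytest.approx(0.75)

    def test_mother_daughter(self, sister_pedigree):
        assert additive_matrix(sister_pedigree).loc("dam", "d1") == pytest.approx(0.5)

    def test_aunt_niece(self, aunt_niece_pedigree):
        a = additive_matrix(aunt_niece_pedigree)
        assert a.loc("aunt", "niece") == pytest.approx(0.375)

    def test_noninbred_diagonal_is_one(self, aunt_niece_pedigree):
        a = additive_matrix(aunt_niece_pedigree)
        assert np.allclose(np.diag(a.values), 1.0)

    def test_male_in_subset_rejected(self, sister_pedigree):
        with pytest.raises(ValueError, match="all-female"):
            additive_matrix(sister_pedigree, ("d1", "sire"))

    def test_computed_through_full_pedigree(self, aunt_niece_pedigree):
        """Restricting to aunt+niece must keep their ancestral relationship."""
        a = additive_matrix(aunt_niece_pedigree, ("aunt", "niece"))
        assert a.loc("aunt", "niece") == pytest.approx(0.375)


class TestGeneDrop:
    def test_unrelated_founders_exactly_zero(self):
        ped = Pedigree([Individual("a", "female"), Individual("b", "female")])
        gd = gene_drop_relatedness(ped, reps=50, seed=0)
        assert gd.loc("a", "b") == 0.0

    def test_full_sisters_match_075(self, sister_pedigree):
        gd = gene_drop_relatedness(sister_pedigree, reps=100_000, seed=1)
        se = gd.stderr[2, 3]
        assert abs(gd.loc("d1", "d2") - 0.75) < 3 * se

    def test_deterministic_under_seed(self, sister_pedigree):
        a = gene_drop_relatedness(sister_pedigree, reps=500, seed=42)
        b = gene_drop_relatedness(sister_pedigree, reps=500, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_nonpositive_reps_fatal(self, sister_pedigree):
        with pytest.raises(ValueError, match="reps"):
            gene_drop_relatedness(sister_pedigree, reps=0, seed=0)


class TestInvariants:
    @given(st.integers(min_value=0, max_value=200))
    @settings(max_examples=25, deadline=None)
    def test_additive_equals_twice_kinship(self, seed):
        ped = random_pedigree(seed, n=25)
        phi = kinship(ped)
        a = additive_matrix(ped, phi=phi)
        sub = phi.submatrix(ped.females)
        np.testing.assert_allclose(a.values, 2.0 * sub.values)

    @given(st.integers(min_value=0, max_value=200))
    @settings(max_examples=25, deadline=None)
    def test_kinship_matrix_psd(self, seed):
        ped = random_pedigree(seed, n=40)
        a = additive_matrix(ped)
        assert a.min_eigenvalue() >= -1e-8

    @given(st.integers(min_value=0, max_value=30))
    @settings(max_examples=8, deadline=None)
    def test_gene_drop_agrees_with_recursion(self, seed):
        """Monte-Carlo relatedness within 4 SE of the exact recursion."""
        ped = random_pedigree(seed, n=30)
        exact = 2.0 * kinship(ped).values
        gd = gene_drop_relatedness(ped, reps=3000, seed=seed + 1000)
        off = ~np.eye(len(ped), dtype=bool)
        se = np.maximum(gd.stderr, 1e-12)
        bad = np.abs(gd.values - exact) > 4.0 * se
        assert not np.any(bad & off & (exact > 0))

    def test_monogamous_nests_are_075_blocks(self):
        from haploquant import SimulationConfig, simulate_pedigree

        cfg = SimulationConfig(n_nests=6, brood_mean=4.0, cross_generation_links=0, seed=3)
        ped = simulate_pedigree(cfg)
        a = additive_matrix(ped)
        pos = {i: k for k, i in enumerate(a.ids)}
        for nest, members in ped.nests().items():
            daughters = [i for i in members if ped[i].dam is not None]
            for x in daughters:
                for y in daughters:
                    if x != y:
                        assert a.values[pos[x], pos[y]] == pytest.approx(0.75)
        # between unlinked nests everything is unrelated
        nests = ped.nests()
        labels = list(nests)
        for x in nests[labels[0]]:
            for y in nests[labels[1]]:
                if x in pos and y in pos:
                    assert a.values[pos[x], pos[y]] == 0.0


class TestRelatednessMatrixIO:
    def test_wide_and_long_roundtrip(self, tmp_path, sister_pedigree):
        a = additive_matrix(sister_pedigree)
        wide = tmp_path / "wide.csv"
        a.write_csv(wide, format="wide")
        frame = pd.read_csv(wide, index_col="id")
        np.testing.assert_allclose(frame.to_numpy(), a.values)
        long = tmp_path / "long.csv"
        a.write_csv(long, format="long")
        rows = pd.read_csv(long)
        pair = rows[(rows.id1 == "d1") & (rows.id2 == "d2")]
        assert pair["a"].iloc[0] == pytest.approx(0.75)
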