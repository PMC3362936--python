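"""Pedigree algebra: sorting, inbreeding, relationships, A-inverse."""

import io

import numpy as np
import pytest

from tolgen import pedigree as P

from .conftest import random_pedigree


class TestLoadingAndValidation:
    def test_trio_is_topologically_sorted(self, trio_pedigree):
        ids = list(trio_pedigree.ids)
        assert ids.index("O") == 2  # offspring after both parents

    def test_self_parent_rejected(self):
        with pytest.raises(P.PedigreeError, match="own parent"):
            P.make_pedigree([("O", "O", "D"), ("D", None, None)])

    def test_duplicate_id_rejected(self):
        with pytest.raises(P.PedigreeError, match="duplicate"):
            P.make_pedigree([("A", None, None), ("A", None, None)])

    def test_cycle_rejected(self):
        with pytest.raises(P.PedigreeError, match="cycle"):
            P.make_pedigree([("A", "B", None), ("B", "A", None)])

    def test_shuffled_chain_sorted_founders_first(self, rng):
        # 5-generation chain presented in shuffled order
        trips = [(f"g{i}", f"g{i-1}" if i else None, None) for i in range(5)]
        order = rng.permutation(5)
        ped = P.make_pedigree([trips[i] for i in order])
        pos = {a: i for i, a in enumerate(ped.ids)}
        for i in range(1, 5):
            assert pos[f"g{i-1}"] < pos[f"g{i}"]

    def test_load_from_file_with_missing_tokens(self, tmp_path):
        f = tmp_path / "ped.csv"
        f.write_text("animal,sire,dam\nS,0,NA\nD,,-\nO,S,D\n")
        ped = P.load_pedigree(f)
        assert len(ped) == 3
        assert ped.founder_mask.sum() == 2

    def test_unlisted_parents_become_founders(self):
        ped = P.make_pedigree([("O", "S", "D")])
        assert len(ped) == 3
        assert ped.inbreeding[ped.index_of("O")] == 0.0


class TestInbreedingAndRelationship:
    def test_unrelated_parents_give_f_zero(self, trio_pedigree):
        assert trio_pedigree.inbreeding[trio_pedigree.index_of("O")] == 0.0

    def test_full_sib_mating_offspring_f(self):
        ped = P.make_pedigree(
            [("S", None, None), ("D", None, None), ("A", "S", "D"),
             ("B", "S", "D"), ("O", "A", "B")]
        )
        assert ped.inbreeding[ped.index_of("O")] == pytest.approx(0.25)

    def test_parent_offspring_mating_f(self):
        ped = P.make_pedigree(
            [("S", None, None), ("D", None, None), ("A", "S", "D"), ("O", "S", "A")]
        )
        assert ped.inbreeding[ped.index_of("O")] == pytest.approx(0.25)

    @pytest.mark.parametrize(
        "pair, expected",
        [(("S", "S"), 1.0), (("S", "O"), 0.5), (("S", "D"), 0.0)],
    )
    def test_relationship_basic_values(self, trio_pedigree, pair, expected):
        assert P.relationship(trio_pedigree, *pair) == pytest.approx(expected)

    def test_half_sibs_related_quarter(self):
        ped = P.make_pedigree(
            [("S", None, None), ("D1", None, None), ("D2", None, None),
             ("A", "S", "D1"), ("B", "S", "D2")]
        )
        assert P.relationship(ped, "A", "B") == pytest.approx(0.25)

    def test_unknown_id_raises(self, trio_pedigree):
        with pytest.raises(P.PedigreeError):
            P.relationship(trio_pedigree, "O", "nope")


class TestAInverse:
    def test_single_founder(self):
        ped = P.make_pedigree([("A", None, None)])
        assert P.build_a_inverse(ped).toarray() == pytest.approx(np.array([[1.0]]))

    def test_trio_exact_values(self, trio_pedigree):
        Ainv = P.build_a_inverse(trio_pedigree).toarray()
        idx = {a: trio_pedigree.index_of(a) for a in "SDO"}
        assert Ainv[idx["O"], idx["O"]] == pytest.approx(2.0)
        assert Ainv[idx["S"], idx["S"]] == pytest.approx(1.5)
        assert Ainv[idx["S"], idx["D"]] == pytest.approx(0.5)
        assert Ainv[idx["O"], idx["S"]] == pytest.approx(-1.0)

    @pytest.mark.parametrize("trial", range(6))
    def test_a_inverse_inverts_tabular_a(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(20, 200))
        ped = random_pedigree(rng, n=n, n_founders=max(5, n // 6))
        A = P.tabular_a(ped)
        Ainv = P.build_a_inverse(ped).toarray()
        assert np.abs(Ainv @ A - np.eye(n)).max() < 1e-8
        # diagonal identity A_ii = 1 + F_i and PSD-ness
        assert np.diag(A) == pytest.approx(1.0 + ped.inbreeding)
        assert np.linalg.eigvalsh(A).min() > 0

    def test_relationship_matches_tabular(self, rng):
        ped = random_pedigree(rng, n=40, n_founders=8)
        A = P.tabular_a(ped)
        for i, j in [(3, 30), (12, 35), (39, 39)]:
            assert P.relationship(ped, ped.ids[i], ped.ids[j]) == pytest.approx(A[i, j])

    def test_log_det_matches_dense(self, rng):
        ped = random_pedigree(rng, n=50, n_founders=10)
        A = P.tabular_a(ped)
        assert P.log_det_a(ped) == pytest.approx(np.linalg.slogdet(A)[1])
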