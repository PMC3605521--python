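import itertools
import json

import dendropy
import numpy as np
import pytest

import nutribalance as nb
from nutribalance.balances import (
    sbp_from_csv,
    sbp_from_json,
    sbp_to_csv,
    transform_table,
)
from nutribalance.errors import DimensionError, HierarchyViolationError, LabelError

from conftest import LABELS5, random_composition, random_table

TABLE1 = [
    [+1, +1, +1, -1, -1],
    [+1, +1, -1, 0, 0],
    [+1, -1, 0, 0, 0],
    [0, 0, 0, +1, -1],
]


def enumerate_valid_3part_sbps():
    """Independent oracle: construct every valid 3-part SBP directly.

    The first row splits {0,1,2} into two nonempty sign groups (6 ways);
    the remaining 2-element group then splits in 2 ways.
    """
    out = []
    for signs in itertools.product((1, -1), repeat=3):
        if len(set(signs)) == 1:
            continue
        row1 = np.array(signs)
        pair = np.flatnonzero(row1 == (1 if (row1 == 1).sum() == 2 else -1))
        i, j = pair
        for a, b in ((1, -1), (-1, 1)):
            row2 = np.zeros(3, dtype=int)
            row2[i], row2[j] = a, b
            out.append(np.array([row1, row2]))
    return out


class TestSbpValidate:
    def test_table1_ionome(self):
        sbp = nb.sbp_validate(TABLE1, LABELS5)
        assert sbp.row_names == ("[N,P,K | Ca,Mg]", "[N,P | K]",
                                 "[N | P]", "[Ca | Mg]")

    def test_two_part_minimal(self):
        sbp = nb.sbp_validate([[1, -1]], ("N", "P"))
        assert sbp.n_balances == 1
        assert sbp.row_names == ("[N | P]",)

    def test_hierarchy_violation_example(self):
        with pytest.raises(HierarchyViolationError, match="not a group"):
            nb.sbp_validate([[1, 1, -1], [-1, 0, 1]], ("a", "b", "c"))

    def test_exhaustive_3part_enumeration(self):
        valid = {m.tobytes() for m in enumerate_valid_3part_sbps()}
        assert len(valid) == 12
        accepted = set()
        for cells in itertools.product((-1, 0, 1), repeat=6):
            mat = np.array(cells, dtype=int).reshape(2, 3)
            try:
                nb.sbp_validate(mat, ("a", "b", "c"))
            except (HierarchyViolationError, DimensionError):
                continue
            accepted.add(mat.tobytes())
        assert accepted == valid

    def test_wrong_shape(self):
        with pytest.raises(DimensionError):
            nb.sbp_validate([[1, -1, 0]], ("a", "b"))

    def test_one_signed_row(self):
        with pytest.raises(HierarchyViolationError):
            nb.sbp_validate([[1, 1, 1, -1, -1],
                             [1, 1, 1, 0, 0],
                             [1, -1, 0, 0, 0],
                             [0, 0, 0, 1, -1]], LABELS5)

    def test_bad_entries(self):
        with pytest.raises(HierarchyViolationError):
            nb.sbp_validate([[2, -1]], ("a", "b"))

    def test_row_order_preserved(self):
        sbp = nb.sbp_validate(TABLE1, LABELS5)
        np.testing.assert_array_equal(sbp.matrix, TABLE1)


class TestBasis:
    def test_single_pair_row_closed_form(self):
        sbp = nb.sbp_validate(TABLE1, LABELS5)
        psi = nb.sbp_to_basis(sbp).psi
        np.testing.assert_allclose(
            psi[2], [np.sqrt(0.5), -np.sqrt(0.5), 0, 0, 0], atol=1e-15)

    def test_first_row_magnitudes(self):
        sbp = nb.sbp_validate(TABLE1, LABELS5)
        psi = nb.sbp_to_basis(sbp).psi
        mag_plus = np.sqrt(6 / 5) / 3
        mag_minus = np.sqrt(6 / 5) / 2
        np.testing.assert_allclose(psi[0, :3], mag_plus, rtol=1e-14)
        np.testing.assert_allclose(psi[0, 3:], -mag_minus, rtol=1e-14)

    @pytest.mark.parametrize("D", range(2, 11))
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_orthonormality_random_sbps(self, D, seed):
        rng = np.random.default_rng(seed)
        sbp = nb.random_sbp([f"x{i}" for i in range(D)], rng)
        psi = nb.sbp_to_basis(sbp).psi
        np.testing.assert_allclose(psi @ psi.T, np.eye(D - 1), atol=1e-12)
        np.testing.assert_allclose(psi.sum(axis=1), 0, atol=1e-12)


class TestIlr:
    def test_worked_np_balance(self, np_tissue):
        sbp = nb.sbp_validate([[1, -1]], ("N", "P"))
        val = nb.ilr(np_tissue, sbp).values[0]
        assert round(float(val), 2) == 1.99

    def test_equal_parts_zero(self, ionome_sbp):
        c = nb.Composition(np.full(5, 2.0), LABELS5)
        assert np.allclose(nb.ilr(c, ionome_sbp).values, 0)

    def test_against_per_row_oracle(self, leaf_composition, ionome_sbp):
        # independent oracle: evaluate each balance from its definition,
        # geometric means and the orthogonal coefficient, row by row
        parts = dict(zip(leaf_composition.labels, leaf_composition.parts))
        expected = []
        for row in ionome_sbp.matrix:
            plus = [parts[l] for l, s in zip(LABELS5, row) if s > 0]
            minus = [parts[l] for l, s in zip(LABELS5, row) if s < 0]
            r, s = len(plus), len(minus)
            gp = np.exp(np.mean(np.log(plus)))
            gm = np.exp(np.mean(np.log(minus)))
            expected.append(np.sqrt(r * s / (r + s)) * np.log(gp / gm))
        got = nb.ilr(leaf_composition, ionome_sbp).values
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_scale_invariance(self, rng, ionome_sbp):
        c = random_composition(rng, D=5, labels=LABELS5)
        v1 = nb.ilr(c.close(1.0), ionome_sbp).values
        v2 = nb.ilr(c.close(1000.0), ionome_sbp).values
        np.testing.assert_allclose(v1, v2, atol=1e-12)

    def test_equals_psi_times_clr(self, rng, ionome_sbp):
        c = random_composition(rng, D=5, labels=LABELS5)
        psi = nb.sbp_to_basis(ionome_sbp).psi
        np.testing.assert_allclose(nb.ilr(c, ionome_sbp).values,
                                   psi @ nb.clr(c).to_numpy(), atol=1e-12)

    def test_isometry_across_sbps(self, rng):
        c1 = random_composition(rng, D=6)
        c2 = random_composition(rng, D=6)
        n1 = n2 = None
        for seed in (0, 1):
            sbp = nb.random_sbp(c1.labels, np.random.default_rng(seed))
            diff = nb.ilr(c1, sbp).values - nb.ilr(c2, sbp).values
            if n1 is None:
                n1 = np.linalg.norm(diff)
            else:
                n2 = np.linalg.norm(diff)
        assert abs(n1 - n2) < 1e-10

    def test_label_mismatch(self, np_tissue, ionome_sbp):
        with pytest.raises(LabelError, match="missing"):
            nb.ilr(np_tissue, ionome_sbp)

    def test_table_matches_per_sample(self, rng, ionome_sbp):
        table = random_table(rng, n=8, labels=LABELS5)
        coords = nb.ilr(table, ionome_sbp)
        for i, comp in enumerate(table.iter_compositions()):
            np.testing.assert_allclose(coords.values[i],
                                       nb.ilr(comp, ionome_sbp).values,
                                       atol=1e-12)


class TestIlrInverse:
    def test_zero_gives_barycenter(self, ionome_sbp):
        comp = nb.ilr_inverse(np.zeros(4), ionome_sbp, kappa=100)
        np.testing.assert_allclose(comp.parts, 20.0, rtol=1e-12)

    def test_round_trip_100_random(self, rng, ionome_sbp):
        for _ in range(100):
            c = random_composition(rng, D=5, labels=LABELS5, kappa=1000.0)
            coords = nb.ilr(c, ionome_sbp)
            back = nb.ilr_inverse(coords, ionome_sbp, kappa=1000.0)
            np.testing.assert_allclose(back.parts, c.close(1000.0).parts,
                                       rtol=1e-10)

    def test_inverts_worked_example(self):
        sbp = nb.sbp_validate([[1, -1]], ("N", "P"))
        comp = nb.ilr_inverse(np.array([1.99]), sbp, kappa=2.65)
        # printed precision of the inputs limits agreement to ~2 d.p.
        np.testing.assert_allclose(comp.parts, [2.50, 0.15], atol=5e-3)

    def test_length_mismatch(self, ionome_sbp):
        with pytest.raises(DimensionError):
            nb.ilr_inverse(np.zeros(3), ionome_sbp)

    def test_table_round_trip(self, rng, ionome_sbp):
        table = random_table(rng, n=10, labels=LABELS5, kappa=100.0)
        coords = nb.ilr(table, ionome_sbp)
        back = nb.ilr_inverse(coords, ionome_sbp, kappa=100.0)
        np.testing.assert_allclose(back.data.to_numpy(),
                                   table.close(100.0).data.to_numpy(),
                                   rtol=1e-10)


class TestDefaultIonomeSbp:
    def test_five_part(self):
        sbp = nb.default_ionome_sbp()
        np.testing.assert_array_equal(sbp.matrix[0], [1, 1, 1, -1, -1])
        assert sbp.part_labels == LABELS5

    def test_with_filling_value(self):
        sbp = nb.default_ionome_sbp(include_fv=True)
        assert sbp.part_labels[-1] == "Fv"
        np.testing.assert_array_equal(sbp.matrix[0], [1, 1, 1, 1, 1, -1])
        assert sbp.matrix.shape == (5, 6)

    def test_both_variants_validate(self):
        for fv in (False, True):
            sbp = nb.default_ionome_sbp(include_fv=fv)
            # revalidating must succeed and reproduce the same matrix
            again = nb.sbp_validate(sbp.matrix, sbp.part_labels)
            np.testing.assert_array_equal(again.matrix, sbp.matrix)


class TestDendrogram:
    def test_table1_tree_structure(self, ionome_sbp):
        tree = nb.balance_dendrogram(ionome_sbp)
        assert tree.name == "[N,P,K | Ca,Mg]"
        kid_names = {c.name for c in tree.children}
        assert kid_names == {"[N,P | K]", "[Ca | Mg]"}
        npk = next(c for c in tree.children if c.name == "[N,P | K]")
        assert {c.name for c in npk.children} == {"[N | P]", "K"}

    def test_two_part_single_node(self):
        sbp = nb.sbp_validate([[1, -1]], ("N", "P"))
        tree = nb.balance_dendrogram(sbp)
        assert tree.name == "[N | P]"
        assert [c.name for c in tree.children] == ["N", "P"]

    @pytest.mark.parametrize("seed", range(5))
    def test_leaf_set_conservation(self, seed):
        rng = np.random.default_rng(seed)
        labels = tuple(f"x{i}" for i in range(rng.integers(2, 9)))
        sbp = nb.random_sbp(labels, rng)
        tree = nb.balance_dendrogram(sbp)
        assert sorted(tree.leaf_labels()) == sorted(labels)

    def test_newick_parses(self, ionome_sbp):
        text = nb.balance_dendrogram(ionome_sbp).to_newick()
        tree = dendropy.Tree.get(data=text, schema="newick")
        taxa = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert taxa == set(LABELS5)

    def test_json_export(self, ionome_sbp):
        summ = {"[N | P]": {"median": 1.9}}
        tree = nb.balance_dendrogram(ionome_sbp, summaries=summ)
        d = json.loads(json.dumps(tree.to_dict()))
        assert d["name"] == "[N,P,K | Ca,Mg]"

        def find(node, name):
            if node["name"] == name:
                return node
            for c in node.get("children", []):
                got = find(c, name)
                if got:
                    return got

        assert find(d, "[N | P]")["stats"] == {"median": 1.9}


class TestSbpIO:
    def test_csv_round_trip(self, tmp_path, ionome_sbp):
        path = tmp_path / "sbp.csv"
        sbp_to_csv(ionome_sbp, path)
        back = sbp_from_csv(path)
        np.testing.assert_array_equal(back.matrix, ionome_sbp.matrix)
        assert back.part_labels == ionome_sbp.part_labels

    def test_json_round_trip(self, ionome_sbp):
        back = sbp_from_json(ionome_sbp.to_json())
        np.testing.assert_array_equal(back.matrix, ionome_sbp.matrix)

    def test_safe_row_names(self, ionome_sbp):
        assert ionome_sbp.safe_row_names()[0] == "N.P.K_vs_Ca.Mg"


class TestTransformTable:
    def test_representations_shapes(self, rng, ionome_sbp):
        table = random_table(rng, n=6, labels=LABELS5)
        assert transform_table(table, "raw").shape == (6, 5)
        assert transform_table(table, "log").shape == (6, 5)
        assert transform_table(table, "clr").shape == (6, 5)
        assert transform_table(table, "alr").shape == (6, 4)
        assert transform_table(table, "ilr", sbp=ionome_sbp).shape == (6, 4)

    def test_alr_denominator_default_first(self, rng):
        table = random_table(rng, n=4, labels=LABELS5)
        X = transform_table(table, "alr")
        assert list(X.columns) == ["P/N", "K/N", "Ca/N", "Mg/N"]

    def test_ilr_requires_sbp(self, rng):
        table = random_table(rng, n=4, labels=LABELS5)
        with pytest.raises(LabelError):
            transform_table(table, "ilr")

    def test_unknown_representation(self, rng):
        table = random_table(rng, n=4)
        with pytest.raises(LabelError):
            transform_table(table, "sqrt")
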