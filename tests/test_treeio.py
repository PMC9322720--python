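import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dtlroot as dr
from dtlroot.simulate import simulate_species_tree
from dtlroot.treeio import (
    GeneFamilyTree,
    NewickParseError,
    SpeciesTree,
    TreeValidationError,
    UnrootedSpeciesTree,
    enumerate_root_branches,
    map_leaves_to_species,
    parse_newick,
)


def canonical(t: SpeciesTree, i=None) -> tuple:
    """Rotation-invariant form of a rooted tree, for topology comparison."""
    i = t.root if i is None else i
    if t.child_left[i] < 0:
        return (t.leaf_names[i],)
    kids = sorted([canonical(t, int(t.child_left[i])),
                   canonical(t, int(t.child_right[i]))], key=repr)
    return tuple(kids)


class TestParsing:
    def test_rooted_basics(self):
        t = parse_newick("((A,B),C);")
        assert isinstance(t, SpeciesTree)
        assert t.n_leaves == 3 and t.n_branches == 5
        assert canonical(t) == canonical(parse_newick("(C,(B,A));"))

    def test_basal_trifurcation_is_unrooted(self):
        t = parse_newick("(A,B,C);")
        assert isinstance(t, UnrootedSpeciesTree)
        assert t.n_branches == 3  # 2*3 - 3

    def test_malformed_raises(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A,B);")

    def test_duplicate_leaf_labels_rejected(self):
        with pytest.raises(TreeValidationError):
            parse_newick("((A,A),C);")

    def test_polytomy_rejected(self):
        with pytest.raises(TreeValidationError):
            parse_newick("((A,B,C,D),E);", rooted_hint=True)

    def test_rooted_hint_enforced(self):
        with pytest.raises(TreeValidationError):
            parse_newick("(A,B,C);", rooted_hint=True)

    def test_quoted_labels_and_comments(self):
        t = parse_newick("(('sp one',B)[a comment],C);")
        assert "sp one" in t.species

    @settings(max_examples=25, deadline=None)
    @given(st.integers(3, 64), st.integers(0, 10_000))
    def test_roundtrip_and_branch_counts(self, L, seed):
        t = simulate_species_tree(L, seed)
        again = SpeciesTree.from_newick(t.to_newick(lengths=True))
        assert canonical(again) == canonical(t)
        assert t.to_newick() == again.to_newick()
        u = t.unroot()
        assert len(enumerate_root_branches(u)) == 2 * L - 3


class TestRerooting:
    def test_three_leaf_reroot(self):
        u = parse_newick("(A,B,C);")
        # rooting on A's pendant branch gives (A,(B,C))
        b = next(b for b in enumerate_root_branches(u)
                 if u.branch_bipartition(b) == frozenset({"B", "C"}))
        r = u.reroot_on_branch(b)
        assert canonical(r) == canonical(parse_newick("(A,(B,C));"))

    def test_all_rootings_of_4_leaf_tree_distinct(self):
        u = parse_newick("((A,B),(C,D));", rooted_hint=False)
        assert u.n_branches == 5
        forms = {canonical(u.reroot_on_branch(b)) for b in range(5)}
        assert len(forms) == 5

    @settings(max_examples=10, deadline=None)
    @given(st.integers(4, 24), st.integers(0, 1000))
    def test_reroot_unroot_identity(self, L, seed):
        u = simulate_species_tree(L, seed).unroot()
        bips = {u.branch_bipartition(b) for b in range(u.n_branches)}
        for b in range(u.n_branches):
            back = u.reroot_on_branch(b).unroot()
            assert {back.branch_bipartition(k)
                    for k in range(back.n_branches)} == bips

    def test_invalid_branch_index(self):
        u = parse_newick("(A,B,C);")
        with pytest.raises(TreeValidationError):
            u.reroot_on_branch(99)

    def test_missing_fractions_propagate(self):
        u = UnrootedSpeciesTree.from_newick("(A,B,C);", missing={"A": 0.3})
        assert u.reroot_on_branch(0).missing == {"A": 0.3}


class TestLeafMapping:
    def test_delimiter_prefix(self, species3):
        g = map_leaves_to_species("(ECOLI_0042,(B_1,C_1));",
                                  species=["ECOLI", "B", "C"])
        assert g.copy_counts == {"ECOLI": 1, "B": 1, "C": 1}

    def test_unresolvable_leaf(self):
        with pytest.raises(TreeValidationError):
            map_leaves_to_species("(orphan,(B_1,C_1));")

    def test_table_overrides_delimiter(self):
        table = {"x1": "A", "x2": "B", "x3": "C"}
        g = map_leaves_to_species("(x1,(x2,x3));", rule=table,
                                  species=["A", "B", "C"])
        assert sorted(g.leaf_species.values()) == ["A", "B", "C"]

    def test_species_not_in_tree_listed(self, species3):
        with pytest.raises(TreeValidationError, match="ZZZ"):
            map_leaves_to_species("(A_1,(B_1,ZZZ_1));", species=species3.species)

    def test_copy_counts_multicopy(self, species3):
        g = GeneFamilyTree.from_newick("((A_1,A_2),(A_3,B_1));", "f")
        assert g.copy_counts == {"A": 3, "B": 1}
        assert not g.is_single_copy(["A", "B"])
        assert GeneFamilyTree.from_newick("(A_1,B_1);", "f").is_single_copy(["A", "B"])


class TestSpeciesTreeInvariants:
    def test_branch_count_includes_stem(self, species3):
        assert species3.n_branches == 2 * species3.n_leaves - 1

    def test_m_vector_validation(self, species3):
        with pytest.raises(TreeValidationError):
            species3.with_missing({"A": 1.5})
        with pytest.raises(TreeValidationError):
            species3.with_missing({"NOPE": 0.1})
        m = species3.with_missing({"A": 0.25}).m_vector()
        assert m.sum() == pytest.approx(0.25)

    def test_node_depths_ultrametric(self):
        t = simulate_species_tree(10, 3)
        depths = t.node_depths()
        leaf_depths = depths[t.child_left < 0]
        assert np.allclose(leaf_depths, 1.0, atol=1e-12)


def test_read_missing_fractions(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("A\t0.1\nB\t0.0\n")
    assert dr.treeio.read_missing_fractions(p) == {"A": 0.1, "B": 0.0}
    p.write_text("A\t1.7\n")
    with pytest.raises(TreeValidationError):
        dr.treeio.read_missing_fractions(p)


def test_read_gene_families_unique_ids(tmp_path):
    p = tmp_path / "fams.nwk"
    p.write_text("(A_1,(B_1,C_1));\n(A_1,(A_2,C_1));\n")
    fams = dr.treeio.read_gene_families(p, species=["A", "B", "C"])
    assert [f.family_id for f in fams] == ["fam00000", "fam00001"]
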