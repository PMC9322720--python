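"""Phylogenetic tree input/output, branch indexing, re-rooting and leaf mapping.

Three tree containers are provided:

* :class:`SpeciesTree` — a rooted binary species tree.  Every node owns the
  branch directly above it, so a tree with ``L`` leaves has ``2L - 1``
  branches including a *stem* branch above the root (the stem lets gene
  families originate before the first speciation).  Branches are indexed by
  postorder position; the stem branch is always the last index.
* :class:`UnrootedSpeciesTree` — an unrooted binary tree with ``2L - 3``
  branches, each a candidate root position.  Branch indices are canonical
  (derived from leaf-label bipartitions) and therefore stable across
  different newick rotations of the same topology.
* :class:`GeneFamilyTree` — an unrooted binary gene tree whose leaves map to
  species of the species tree; may contain paralogues (several copies per
  species) and may miss species entirely.

Newick parsing and writing is delegated to dendropy; quoted labels and
square-bracket comments are accepted, branch lengths are optional (they are
ignored by reconciliation and used only by the simulator).  Polytomies are
rejected rather than silently resolved, because the reconciliation dynamic
program assumes binary trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "SpeciesTree",
    "UnrootedSpeciesTree",
    "GeneFamilyTree",
    "parse_newick",
    "enumerate_root_branches",
    "reroot_on_branch",
    "map_leaves_to_species",
    "read_gene_families",
    "read_missing_fractions",
    "read_species_map",
]


class NewickParseError(ValueError):
    """Malformed newick input (message carries the offending position)."""


class TreeValidationError(ValueError):
    """Structurally invalid tree (polytomy, duplicate labels, bad mapping)."""


# ---------------------------------------------------------------------------
# dendropy helpers
# ---------------------------------------------------------------------------


def _dendropy_parse(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate leaf labels: {exc}") from exc
        raise NewickParseError(f"malformed newick: {exc}") from exc
    return tree


def _leaf_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    raise TreeValidationError("leaf with empty label")


def _check_unique_labels(labels: Sequence[str]) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise TreeValidationError(f"duplicate leaf label: {lab!r}")
        seen.add(lab)


# ---------------------------------------------------------------------------
# SpeciesTree
# ---------------------------------------------------------------------------


@dataclass
class SpeciesTree:
    """Rooted binary species tree with postorder-indexed branches.

    Branch ``i`` is the edge above node ``i``; nodes are stored in postorder
    so children always precede parents and the root (stem branch) is the
    last index, ``2L - 2``.
    """

    child_left: np.ndarray  # int32, -1 for leaves
    child_right: np.ndarray
    parent: np.ndarray  # int32, -1 for the root
    lengths: np.ndarray  # float64 branch length above each node (stem incl.)
    leaf_names: list  # str for leaf branches, None for internal
    missing: dict = field(default_factory=dict)  # species -> m_s in [0, 1]

    def __post_init__(self) -> None:
        for s, m in self.missing.items():
            if not (0.0 <= m <= 1.0):
                raise TreeValidationError(f"missing fraction for {s} not in [0,1]: {m}")
        _check_unique_labels([n for n in self.leaf_names if n is not None])

    # -- basic accessors ----------------------------------------------------

    @property
    def n_branches(self) -> int:
        return len(self.leaf_names)

    @property
    def n_leaves(self) -> int:
        return int(np.sum(self.child_left < 0))

    @property
    def root(self) -> int:
        return self.n_branches - 1

    @property
    def species(self) -> list:
        return sorted(n for n in self.leaf_names if n is not None)

    @property
    def branch_of_species(self) -> dict:
        return {
            name: i for i, name in enumerate(self.leaf_names) if name is not None
        }

    def m_vector(self) -> np.ndarray:
        """Per-branch missing fraction (zero on internal branches)."""
        m = np.zeros(self.n_branches)
        for i, name in enumerate(self.leaf_names):
            if name is not None:
                m[i] = float(self.missing.get(name, 0.0))
        return m

    def node_depths(self) -> np.ndarray:
        """Time of each node measured from the root (root = 0)."""
        depth = np.zeros(self.n_branches)
        order = np.argsort(-np.arange(self.n_branches))  # root first is last idx
        for i in order:
            p = self.parent[i]
            if p >= 0:
                depth[i] = depth[p] + self.lengths[i]
        return depth

    def with_missing(self, missing: Mapping[str, float]) -> "SpeciesTree":
        unknown = set(missing) - set(self.species)
        if unknown:
            raise TreeValidationError(f"missing-fraction species not in tree: {sorted(unknown)}")
        return SpeciesTree(
            self.child_left, self.child_right, self.parent,
            self.lengths, list(self.leaf_names), dict(missing),
        )

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, stem_length: float = 0.0,
                      missing: Mapping[str, float] | None = None) -> "SpeciesTree":
        root = tree.seed_node
        if len(root.child_nodes()) != 2:
            raise TreeValidationError(
                f"rooted tree must have a bifurcating root, found degree {len(root.child_nodes())}"
            )
        nodes = list(tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        B = len(nodes)
        cl = np.full(B, -1, dtype=np.int32)
        cr = np.full(B, -1, dtype=np.int32)
        par = np.full(B, -1, dtype=np.int32)
        lengths = np.zeros(B)
        leaf_names: list = [None] * B
        for i, n in enumerate(nodes):
            kids = n.child_nodes()
            if len(kids) == 0:
                leaf_names[i] = _leaf_label(n)
            elif len(kids) == 2:
                cl[i], cr[i] = index[id(kids[0])], index[id(kids[1])]
                par[cl[i]] = i
                par[cr[i]] = i
            else:
                raise TreeValidationError(
                    f"polytomy of degree {len(kids)} — resolve it before reconciliation"
                )
            lengths[i] = n.edge.length if n.edge.length is not None else 0.0
        lengths[B - 1] = stem_length
        return cls(cl, cr, par, lengths, leaf_names, dict(missing or {}))

    @classmethod
    def from_newick(cls, text: str, stem_length: float = 0.0,
                    missing: Mapping[str, float] | None = None) -> "SpeciesTree":
        return cls.from_dendropy(_dendropy_parse(text), stem_length, missing)

    # -- output -------------------------------------------------------------

    def to_newick(self, lengths: bool = False) -> str:
        def rec(i: int) -> str:
            if self.child_left[i] < 0:
                s = self.leaf_names[i]
            else:
                s = f"({rec(self.child_left[i])},{rec(self.child_right[i])})"
            if lengths and self.parent[i] >= 0:
                s += f":{self.lengths[i]:.10g}"
            return s

        return rec(self.root) + ";"

    def unroot(self) -> "UnrootedSpeciesTree":
        """Collapse the root, merging its two child edges into one."""
        if self.n_leaves < 3:
            raise TreeValidationError("cannot unroot a tree with fewer than 3 leaves")
        return UnrootedSpeciesTree.from_newick(self.to_newick(), missing=self.missing)


# ---------------------------------------------------------------------------
# UnrootedSpeciesTree
# ---------------------------------------------------------------------------


@dataclass
class UnrootedSpeciesTree:
    """Unrooted binary species tree with canonically indexed branches.

    Each of the ``2L - 3`` branches corresponds to a bipartition of the leaf
    set; branches are sorted by (clade size, clade labels) of the side not
    containing the alphabetically first leaf, which makes the index stable
    under newick rotation.
    """

    adjacency: list  # adjacency[v] = list of neighbour vertex ids
    leaf_name_of: dict  # vertex id -> leaf label (leaves only)
    edges: list  # branch index -> (u, v) vertex pair
    missing: dict = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_name_of)

    @property
    def n_branches(self) -> int:
        return len(self.edges)

    @property
    def species(self) -> list:
        return sorted(self.leaf_name_of.values())

    def branch_bipartition(self, b: int) -> frozenset:
        """Leaf labels on the side of branch ``b`` away from the first leaf."""
        u, v = self.edges[b]
        ref = min(self.leaf_name_of.values())
        side = self._leafset_away(u, v)
        if ref in side:
            side = frozenset(self.leaf_name_of.values()) - side
        return frozenset(side)

    def _leafset_away(self, u: int, v: int) -> frozenset:
        """Leaves reachable from u without crossing edge (u, v)."""
        out, stack, seen = [], [u], {v, u}
        while stack:
            x = stack.pop()
            if x in self.leaf_name_of:
                out.append(self.leaf_name_of[x])
            for y in self.adjacency[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(out)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree,
                      missing: Mapping[str, float] | None = None) -> "UnrootedSpeciesTree":
        root = tree.seed_node
        if len(root.child_nodes()) == 2:
            # rooted shape: suppress the root to recover the unrooted topology
            tree.deroot()
            root = tree.seed_node
        nodes = list(tree.preorder_node_iter())
        if len(nodes) < 3:
            raise TreeValidationError("unrooted tree needs at least 3 leaves")
        vid = {id(n): i for i, n in enumerate(nodes)}
        adjacency: list = [[] for _ in nodes]
        leaf_name_of: dict = {}
        raw_edges = []
        for n in nodes:
            i = vid[id(n)]
            if not n.child_nodes():
                leaf_name_of[i] = _leaf_label(n)
            for c in n.child_nodes():
                j = vid[id(c)]
                adjacency[i].append(j)
                adjacency[j].append(i)
                raw_edges.append((i, j))
        _check_unique_labels(list(leaf_name_of.values()))
        for v, nb in enumerate(adjacency):
            if len(nb) not in (1, 3):
                raise TreeValidationError(
                    f"unrooted binary tree requires vertex degrees 1 or 3, found {len(nb)}"
                )
        obj = cls(adjacency, leaf_name_of, raw_edges, dict(missing or {}))
        # canonical branch order: by bipartition away from the first leaf
        keyed = []
        for e in raw_edges:
            clade = obj._leafset_away(e[0], e[1])
            ref = min(leaf_name_of.values())
            if ref in clade:
                clade = frozenset(leaf_name_of.values()) - clade
            keyed.append(((len(clade), tuple(sorted(clade))), e))
        keyed.sort(key=lambda t: t[0])
        obj.edges = [e for _, e in keyed]
        return obj

    @classmethod
    def from_newick(cls, text: str,
                    missing: Mapping[str, float] | None = None) -> "UnrootedSpeciesTree":
        return cls.from_dendropy(_dendropy_parse(text), missing)

    # -- output and rooting -------------------------------------------------

    def to_newick(self) -> str:
        # write with a basal trifurcation rooted at an internal vertex
        start = next(v for v, nb in enumerate(self.adjacency) if len(nb) == 3)

        def rec(v: int, parent: int) -> str:
            if v in self.leaf_name_of:
                return self.leaf_name_of[v]
            kids = [rec(u, v) for u in self.adjacency[v] if u != parent]
            return "(" + ",".join(kids) + ")"

        kids = [rec(u, start) for u in self.adjacency[start]]
        return "(" + ",".join(kids) + ");"

    def reroot_on_branch(self, b: int) -> SpeciesTree:
        """Rooted binary tree whose root bisects branch ``b``."""
        if not (0 <= b < self.n_branches):
            raise TreeValidationError(f"branch index out of range: {b}")
        u, v = self.edges[b]

        def rec(x: int, parent: int) -> str:
            if x in self.leaf_name_of:
                return self.leaf_name_of[x]
            kids = [rec(y, x) for y in self.adjacency[x] if y != parent]
            if len(kids) != 2:
                raise TreeValidationError("non-binary vertex during rerooting")
            return f"({kids[0]},{kids[1]})"

        newick = f"({rec(u, v)},{rec(v, u)});"
        return SpeciesTree.from_newick(newick, missing=self.missing)


def enumerate_root_branches(t: UnrootedSpeciesTree) -> list:
    """All candidate root branches of an unrooted binary tree (``2L - 3``)."""
    if t.n_leaves < 3:
        raise TreeValidationError("root enumeration needs at least 3 leaves")
    return list(range(t.n_branches))


def reroot_on_branch(t: UnrootedSpeciesTree, b: int) -> SpeciesTree:
    return t.reroot_on_branch(b)


# ---------------------------------------------------------------------------
# GeneFamilyTree
# ---------------------------------------------------------------------------


@dataclass
class GeneFamilyTree:
    """Unrooted binary gene tree with a leaf-to-species mapping.

    ``adjacency``/``leaf_vertex`` describe the unrooted topology (internal
    vertices of degree 3); a two-leaf family is the degenerate single-edge
    case and is treated as rooted at its unique internal point.  The message
    ``schedule`` used by the likelihood kernels is built lazily and cached —
    it depends only on the gene-tree topology, never on the species tree.
    """

    family_id: str
    adjacency: list  # adjacency[v] = neighbour ids
    leaf_species: dict  # leaf vertex id -> species name
    leaf_labels: dict  # leaf vertex id -> original label
    _schedule: dict | None = field(default=None, repr=False)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_species)

    @property
    def species_used(self) -> list:
        return sorted(set(self.leaf_species.values()))

    @property
    def copy_counts(self) -> dict:
        out: dict = {}
        for s in self.leaf_species.values():
            out[s] = out.get(s, 0) + 1
        return out

    def is_single_copy(self, species: Iterable[str]) -> bool:
        """True if exactly one copy in *every* given species."""
        cc = self.copy_counts
        return all(cc.get(s, 0) == 1 for s in species) and set(cc) == set(species)

    @property
    def edges(self) -> list:
        es = []
        for u, nb in enumerate(self.adjacency):
            for v in nb:
                if u < v:
                    es.append((u, v))
        return es

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, family_id: str = "fam",
                    rule: str | Mapping[str, str] = "_",
                    species: Iterable[str] | None = None) -> "GeneFamilyTree":
        tree = _dendropy_parse(text)
        root = tree.seed_node
        kids = root.child_nodes()
        leaves = [n for n in tree.leaf_node_iter()]
        if len(leaves) < 2:
            raise TreeValidationError("gene tree needs at least 2 leaves")
        if len(kids) == 2 and len(leaves) >= 3:
            tree.deroot()
            root = tree.seed_node
        nodes = list(tree.preorder_node_iter())
        vid = {id(n): i for i, n in enumerate(nodes)}
        adjacency: list = [[] for _ in nodes]
        leaf_labels: dict = {}
        for n in nodes:
            i = vid[id(n)]
            if not n.child_nodes():
                leaf_labels[i] = _leaf_label(n)
            for c in n.child_nodes():
                j = vid[id(c)]
                adjacency[i].append(j)
                adjacency[j].append(i)
        _check_unique_labels(list(leaf_labels.values()))
        if len(leaves) == 2:
            # collapse "(A,B);" to a single edge between the two leaves; the
            # family is then rooted at the unique point on that edge
            labs = list(leaf_labels.values())
            adjacency = [[1], [0]]
            leaf_labels = {0: labs[0], 1: labs[1]}
        else:
            for v, nb in enumerate(adjacency):
                if len(nb) not in (1, 3):
                    raise TreeValidationError(
                        f"gene tree not binary: vertex degree {len(nb)}"
                    )
        leaf_species = {v: _resolve_species(lab, rule) for v, lab in leaf_labels.items()}
        if species is not None:
            known = set(species)
            offenders = sorted({s for s in leaf_species.values() if s not in known})
            if offenders:
                raise TreeValidationError(
                    f"gene-tree species absent from the species tree: {offenders}"
                )
        return cls(family_id, adjacency, leaf_species, leaf_labels)

    def to_newick(self) -> str:
        if self.n_leaves == 2:
            a, b = sorted(self.leaf_labels)
            return f"({self.leaf_labels[a]},{self.leaf_labels[b]});"

        start = next(v for v, nb in enumerate(self.adjacency) if len(nb) == 3)

        def rec(v: int, parent: int) -> str:
            if v in self.leaf_labels:
                return self.leaf_labels[v]
            kids = [rec(u, v) for u in self.adjacency[v] if u != parent]
            return "(" + ",".join(kids) + ")"

        kids = [rec(u, start) for u in self.adjacency[start]]
        return "(" + ",".join(kids) + ");"

    # -- kernel schedule ----------------------------------------------------

    def schedule(self) -> dict:
        """Directed-edge message schedule for the likelihood kernels.

        For every directed edge ``x -> y`` of the unrooted gene tree there is
        one message: the likelihood vector of the clade rooted at ``x`` when
        cut away from ``y``.  Messages are ordered so that dependencies come
        first (inward pass to a reference leaf, then outward pass); the two
        opposite messages of edge ``i`` are ids ``2i`` and ``2i + 1``.
        """
        if self._schedule is not None:
            return self._schedule
        edges = self.edges
        eid = {}
        for i, (u, v) in enumerate(edges):
            eid[(u, v)] = 2 * i
            eid[(v, u)] = 2 * i + 1
        nmsg = 2 * len(edges)
        species_list = self.species_used
        sp_idx = {s: i for i, s in enumerate(species_list)}
        msg_leafsp = np.full(nmsg, -1, dtype=np.int32)
        msg_dep1 = np.full(nmsg, -1, dtype=np.int32)
        msg_dep2 = np.full(nmsg, -1, dtype=np.int32)
        for (x, y), m in eid.items():
            if x in self.leaf_species:
                msg_leafsp[m] = sp_idx[self.leaf_species[x]]
            else:
                deps = [eid[(a, x)] for a in self.adjacency[x] if a != y]
                msg_dep1[m], msg_dep2[m] = deps  # degree-3 internal: exactly 2

        # dependency-respecting order: inward to leaf r (postorder), then outward
        r = min(self.leaf_species)  # a leaf vertex
        order: list = []
        parent = {r: -1}
        stack, post = [r], []
        while stack:
            x = stack.pop()
            post.append(x)
            for y in self.adjacency[x]:
                if y != parent[x]:
                    parent[y] = x
                    stack.append(y)
        for x in reversed(post):  # postorder: children before parents
            if parent[x] != -1:
                order.append(eid[(x, parent[x])])
        for x in post:  # preorder: parents before children
            if parent[x] != -1:
                order.append(eid[(parent[x], x)])
        assert len(order) == nmsg

        self._schedule = {
            "order": np.asarray(order, dtype=np.int32),
            "leafsp": msg_leafsp,
            "dep1": msg_dep1,
            "dep2": msg_dep2,
            "n_edges": len(edges),
            "species": species_list,
        }
        return self._schedule


def _resolve_species(label: str, rule: str | Mapping[str, str]) -> str:
    if isinstance(rule, Mapping):
        try:
            return rule[label]
        except KeyError:
            raise TreeValidationError(f"leaf {label!r} not in the mapping table") from None
    if rule not in label or label.startswith(rule):
        raise TreeValidationError(
            f"cannot resolve species of leaf {label!r} with delimiter {rule!r}"
        )
    return label.split(rule)[0]


# ---------------------------------------------------------------------------
# module-level plumbing
# ---------------------------------------------------------------------------


def parse_newick(text: str, rooted_hint: bool | None = None):
    """Parse a newick string into a rooted or unrooted species tree.

    With ``rooted_hint=None`` the arity of the basal node decides: a
    bifurcation gives a :class:`SpeciesTree`, a trifurcation an
    :class:`UnrootedSpeciesTree`.
    """
    tree = _dendropy_parse(text)
    degree = len(tree.seed_node.child_nodes())
    if rooted_hint is True:
        if degree != 2:
            raise TreeValidationError("rooted tree expected but basal node is not binary")
        return SpeciesTree.from_dendropy(tree)
    if rooted_hint is False:
        return UnrootedSpeciesTree.from_dendropy(tree)
    if degree == 2:
        return SpeciesTree.from_dendropy(tree)
    return UnrootedSpeciesTree.from_dendropy(tree)


def map_leaves_to_species(gene_tree: "GeneFamilyTree | str",
                          rule: str | Mapping[str, str] = "_",
                          species: Iterable[str] | None = None,
                          family_id: str = "fam") -> GeneFamilyTree:
    """Attach species identities to gene-tree leaves.

    ``rule`` is either a delimiter (species = label prefix up to its first
    occurrence) or an explicit label->species table, which takes precedence.
    """
    if isinstance(gene_tree, str):
        return GeneFamilyTree.from_newick(gene_tree, family_id, rule, species)
    leaf_species = {v: _resolve_species(lab, rule) for v, lab in gene_tree.leaf_labels.items()}
    if species is not None:
        known = set(species)
        offenders = sorted({s for s in leaf_species.values() if s not in known})
        if offenders:
            raise TreeValidationError(
                f"gene-tree species absent from the species tree: {offenders}"
            )
    return GeneFamilyTree(gene_tree.family_id, gene_tree.adjacency,
                          leaf_species, gene_tree.leaf_labels)


def read_gene_families(source, rule: str | Mapping[str, str] = "_",
                       species: Iterable[str] | None = None) -> list:
    """Read a one-newick-per-line gene-family collection (path, file or str)."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    elif isinstance(source, str) and "(" in source:
        lines = source.splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    fams = []
    for i, line in enumerate(lines):
        line = line.strip()
        if not line:
            continue
        fams.append(GeneFamilyTree.from_newick(line, f"fam{i:05d}", rule, species))
    ids = [f.family_id for f in fams]
    if len(set(ids)) != len(ids):
        raise TreeValidationError("duplicate family ids")
    return fams


def read_missing_fractions(source) -> dict:
    """Two-column TSV ``species<TAB>m_s`` with m_s in [0, 1]."""
    import pandas as pd

    df = pd.read_csv(source, sep="\t", header=None, names=["species", "m"], comment="#")
    out = dict(zip(df["species"].astype(str), df["m"].astype(float)))
    bad = {s: m for s, m in out.items() if not (0.0 <= m <= 1.0)}
    if bad:
        raise TreeValidationError(f"missing fractions outside [0,1]: {bad}")
    return out


def read_species_map(source) -> dict:
    """Two-column TSV ``leaf_label<TAB>species``."""
    import pandas as pd

    df = pd.read_csv(source, sep="\t", header=None, names=["leaf", "species"], comment="#")
    return dict(zip(df["leaf"].astype(str), df["species"].astype(str)))
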