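"""Forward simulation of gene families under duplication, transfer and loss.

The generator produces the synthetic study conditions for the rooting
analysis: a dated, ultrametric species tree (Yule process, unit root-to-tip
depth) and gene families evolved along it.  A family starts as a single copy
at the top of a uniformly chosen origination branch (the stem above the root
included); each gene lineage then experiences exponentially distributed
waiting times to duplication, transfer and loss per unit branch length,
bifurcates at speciations, and is sampled at the present with probability
1 - m_s (the per-species missing-gene fraction).  Transfers pick a recipient
uniformly among the branches alive at the moment of the event, excluding the
donor; a transfer drawn when no contemporaneous recipient exists (possible
on the stem) is discarded and not counted.

Two regime presets bracket the biological contrast the analysis probes:

* ``bacteria_like`` — transfer-dominated (tau:delta of 50-100) with losses
  slightly exceeding gains (lambda = 1.05 x (delta + tau)), i.e. the
  deletional-bias, genome-reduction regime reported for prokaryotes;
* ``eukaryote_like`` — duplication-rich (delta:tau >= 2, here 5:1, i.e.
  T:D = 1:5) with gains exceeding losses.

Every family records ground-truth event counts both over the full history
and restricted to events ancestral to observed leaves, so inference can be
validated against a reconciliation-independent reference.  Unlike the
inference model, the simulator is *dated*: transfers only connect
contemporaneous branches.  This deliberate model mismatch mirrors the
situation with real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .treeio import GeneFamilyTree, SpeciesTree

__all__ = [
    "SimConfig",
    "SimFamily",
    "SimDataset",
    "simulate_species_tree",
    "simulate_family",
    "simulate_dataset",
    "bacteria_like",
    "eukaryote_like",
]

_NODE_CAP = 200_000  # safety valve against runaway birth rates


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_species: int
    delta: float  # duplication rate per unit branch length
    tau: float  # transfer rate
    lam: float  # loss rate
    n_families: int
    seed: int
    missing: Mapping[str, float] | float = 0.0  # m_s per species, or one value
    min_leaves: int = 3  # families with fewer observed leaves are redrawn
    stem_length: float = 0.1  # stem above the root, fraction of unit depth
    regime: str = "custom"

    def __post_init__(self):
        if self.n_species < 3:
            raise ValueError("need at least 3 species")
        for name, v in (("delta", self.delta), ("tau", self.tau), ("lam", self.lam)):
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and >= 0")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")

    def missing_for(self, species: Sequence[str]) -> dict:
        if isinstance(self.missing, Mapping):
            return {s: float(self.missing.get(s, 0.0)) for s in species}
        return {s: float(self.missing) for s in species}


def bacteria_like(n_species: int = 16, n_families: int = 300, seed: int = 0,
                  td_ratio: float = 50.0, total_gain: float = 0.7,
                  missing: Mapping[str, float] | float = 0.0) -> SimConfig:
    """Transfer-dominated, loss-exceeds-gain regime (T:D 50-100)."""
    if not (50.0 <= td_ratio <= 100.0):
        raise ValueError("bacteria-like regime requires tau:delta in [50, 100]")
    delta = total_gain / (1.0 + td_ratio)
    tau = total_gain * td_ratio / (1.0 + td_ratio)
    return SimConfig(n_species, delta, tau, 1.05 * total_gain, n_families, seed,
                     missing=missing, regime="bacteria-like")


def eukaryote_like(n_species: int = 12, n_families: int = 300, seed: int = 0,
                   dt_ratio: float = 2.0, total_gain: float = 0.5,
                   missing: Mapping[str, float] | float = 0.0) -> SimConfig:
    """Duplication-rich regime (delta:tau >= 2, i.e. T:D <= 1:2, the ratio
    reported for fungi-metazoan gene families)."""
    if dt_ratio < 2.0:
        raise ValueError("eukaryote-like regime requires delta:tau >= 2")
    delta = total_gain * dt_ratio / (1.0 + dt_ratio)
    tau = total_gain / (1.0 + dt_ratio)
    return SimConfig(n_species, delta, tau, 0.9 * total_gain, n_families, seed,
                     missing=missing, regime="eukaryote-like")


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


def simulate_species_tree(L: int, seed: int, stem_length: float = 0.1) -> SpeciesTree:
    """Yule (pure-birth) species tree with ``L`` leaves, rescaled to unit
    root-to-tip depth.  Species are named S001..S{L}; deterministic per seed."""
    if L < 3:
        raise ValueError("need at least 3 species")
    rng = np.random.default_rng(seed)
    next_id = [0]

    def new_node(t):
        n = {"id": next_id[0], "time": t, "children": []}
        next_id[0] += 1
        return n

    t = 0.0
    root = new_node(0.0)
    a, b = new_node(0.0), new_node(0.0)
    root["children"] = [a, b]
    active = [a, b]
    while len(active) < L:
        t += rng.exponential(1.0 / len(active))
        i = rng.integers(len(active))
        node = active[i]
        node["time"] = t
        c1, c2 = new_node(t), new_node(t)
        node["children"] = [c1, c2]
        active[i] = c1
        active.append(c2)
    present = t + rng.exponential(1.0 / L)
    for leaf in active:
        leaf["time"] = present

    pad = max(3, len(str(L)))
    names = iter(f"S{i + 1:0{pad}d}" for i in range(L))

    def newick(n) -> str:
        if not n["children"]:
            return f"{next(names)}:{(n['time'] - n['parent_time']) / present:.12g}"
        for c in n["children"]:
            c["parent_time"] = n["time"]
        inner = ",".join(newick(c) for c in n["children"])
        if n is root:
            return f"({inner})"
        return f"({inner}):{(n['time'] - n['parent_time']) / present:.12g}"

    return SpeciesTree.from_newick(newick(root) + ";", stem_length=stem_length)


# ---------------------------------------------------------------------------
# gene families
# ---------------------------------------------------------------------------


@dataclass
class SimFamily:
    """One simulated gene family with its ground truth."""

    family_id: str
    newick: str  # pruned observed gene tree, species-prefixed leaf labels
    gene_tree: GeneFamilyTree
    origination_branch: int  # branch index in the rooted species tree
    n_dup_all: int
    n_trans_all: int
    n_loss_all: int
    n_dup_obs: int  # events ancestral to at least one observed leaf
    n_trans_obs: int
    n_loss_obs: int  # losses whose parent event retains observed descendants
    transfer_records: list = field(default_factory=list, repr=False)
    # (time, donor branch, recipient branch, n available recipients)

    @property
    def n_leaves(self) -> int:
        return self.gene_tree.n_leaves


class _BranchGeometry:
    """Branch time intervals of a dated species tree."""

    def __init__(self, s: SpeciesTree):
        self.tree = s
        depth = s.node_depths()
        self.bottom = depth
        self.top = np.where(s.parent >= 0, depth[np.maximum(s.parent, 0)], 0.0)
        self.top[s.root] = -s.lengths[s.root]  # stem starts above the root
        self.m = s.m_vector()
        self.leaf = s.child_left < 0

    def alive_at(self, t: float) -> np.ndarray:
        return np.flatnonzero((self.top <= t) & (t < self.bottom))


def simulate_family(s: SpeciesTree, c: SimConfig, rng: np.random.Generator,
                    family_id: str = "fam00000") -> SimFamily | None:
    """One forward draw; ``None`` if the observed family has too few leaves."""
    geom = _BranchGeometry(s)
    missing = c.missing_for(s.species)
    mvec = np.array([missing.get(n, 0.0) if n else 0.0 for n in s.leaf_names])
    total = c.delta + c.tau + c.lam
    counts = {"D": 0, "T": 0, "L": 0}
    transfer_records: list = []
    n_nodes = [0]

    def make(kind, time, branch, children=()):
        n_nodes[0] += 1
        if n_nodes[0] > _NODE_CAP:
            raise RuntimeError(
                "simulated family exceeded the node cap — lower the gain rates"
            )
        return {"kind": kind, "time": time, "branch": branch,
                "children": list(children)}

    def evolve(e: int, t: float) -> dict:
        while True:
            t_end = geom.bottom[e]
            dt = rng.exponential(1.0 / total) if total > 0 else math.inf
            if t + dt >= t_end:
                break
            t += dt
            u = rng.random() * total
            if u < c.delta:
                counts["D"] += 1
                return make("D", t, e, (evolve(e, t), evolve(e, t)))
            if u < c.delta + c.tau:
                alive = geom.alive_at(t)
                alive = alive[alive != e]
                if alive.size == 0:
                    continue  # no contemporaneous recipient: discarded
                h = int(alive[rng.integers(alive.size)])
                counts["T"] += 1
                transfer_records.append((t, e, h, int(alive.size)))
                return make("T", t, e, (evolve(e, t), evolve(h, t)))
            counts["L"] += 1
            return make("L", t, e)
        if geom.leaf[e]:
            observed = rng.random() >= mvec[e]
            return make("leaf" if observed else "unobs", t_end, e)
        f = int(s.child_left[e])
        g = int(s.child_right[e])
        return make("S", t_end, e, (evolve(f, t_end), evolve(g, t_end)))

    origin = int(rng.integers(s.n_branches))
    root = evolve(origin, geom.top[origin])

    # ------------------------------------------------------------------ truth
    def mark_obs(n) -> int:
        n["obs"] = (1 if n["kind"] == "leaf" else 0) \
            + sum(mark_obs(ch) for ch in n["children"])
        return n["obs"]

    mark_obs(root)
    if root["obs"] < c.min_leaves:
        return None

    obs_counts = {"D": 0, "T": 0, "L": 0}

    def count_obs(n):
        for ch in n["children"]:
            count_obs(ch)
        if n["kind"] in ("D", "T") and n["obs"] >= 1:
            obs_counts[n["kind"]] += 1
        if n["kind"] in ("D", "T", "S") and n["obs"] >= 1:
            obs_counts["L"] += sum(1 for ch in n["children"] if ch["kind"] == "L")

    count_obs(root)

    # ------------------------------------------------------- pruned gene tree
    def prune(n):
        if n["kind"] == "leaf":
            return n
        kept = [p for p in (prune(ch) for ch in n["children"]) if p is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        return {"kind": "node", "time": n["time"], "branch": n["branch"],
                "children": kept}

    pruned = prune(root)
    copy_counter: dict = {}

    def label(n) -> str:
        sp = s.leaf_names[n["branch"]]
        copy_counter[sp] = copy_counter.get(sp, 0) + 1
        return f"{sp}_{copy_counter[sp]}"

    def newick(n, parent_time) -> str:
        if n["kind"] == "leaf":
            body = label(n)
        else:
            body = "(" + ",".join(newick(ch, n["time"]) for ch in n["children"]) + ")"
        return f"{body}:{n['time'] - parent_time:.10g}"

    nwk = newick(pruned, geom.top[origin]).rsplit(":", 1)[0] + ";"
    gt = GeneFamilyTree.from_newick(nwk, family_id, rule="_", species=s.species)
    return SimFamily(family_id, nwk, gt, origin,
                     counts["D"], counts["T"], counts["L"],
                     obs_counts["D"], obs_counts["T"], obs_counts["L"],
                     transfer_records)


@dataclass
class SimDataset:
    """A simulated study: species tree, families, truth and subsets."""

    config: SimConfig
    species_tree: SpeciesTree
    families: list  # SimFamily
    n_rejected: int

    @property
    def gene_trees(self) -> list:
        return [f.gene_tree for f in self.families]

    def single_copy_ids(self) -> list:
        """Families present as exactly one copy in every species."""
        species = self.species_tree.species
        return [f.family_id for f in self.families
                if f.gene_tree.is_single_copy(species)]

    def truth_table(self) -> "object":
        import pandas as pd

        return pd.DataFrame([
            {
                "family_id": f.family_id,
                "n_leaves": f.n_leaves,
                "origination_branch": f.origination_branch,
                "n_dup_true": f.n_dup_all,
                "n_trans_true": f.n_trans_all,
                "n_loss_true": f.n_loss_all,
                "n_dup_obs": f.n_dup_obs,
                "n_trans_obs": f.n_trans_obs,
                "n_loss_obs": f.n_loss_obs,
            }
            for f in self.families
        ])

    def write(self, outdir) -> None:
        """species_tree.nwk, families.nwk, truth.tsv, singlecopy_ids.txt."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "species_tree.nwk").write_text(
            self.species_tree.to_newick(lengths=True) + "\n")
        (out / "families.nwk").write_text(
            "".join(f.newick + "\n" for f in self.families))
        self.truth_table().to_csv(out / "truth.tsv", sep="\t", index=False)
        (out / "singlecopy_ids.txt").write_text(
            "".join(i + "\n" for i in self.single_copy_ids()))


def simulate_dataset(c: SimConfig) -> SimDataset:
    """Simulate ``c.n_families`` accepted families (deterministic per seed).

    Families failing the minimum-observed-leaves filter are redrawn; an
    acceptance rate below 1% raises instead of looping forever.
    """
    tree = simulate_species_tree(c.n_species, c.seed, c.stem_length)
    tree = tree.with_missing(c.missing_for(tree.species))
    rng = np.random.default_rng([c.seed, 0xD71])
    families: list = []
    attempts = 0
    while len(families) < c.n_families:
        attempts += 1
        fam = simulate_family(tree, c, rng, family_id=f"fam{len(families):05d}")
        if fam is not None:
            families.append(fam)
        elif attempts >= 1000 and len(families) < 0.01 * attempts:
            raise RuntimeError(
                f"rejection rate above 99% ({len(families)}/{attempts} accepted):"
                " adjust the simulation rates"
            )
    return SimDataset(c, tree, families, attempts - len(families))
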