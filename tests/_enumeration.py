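"""Independent oracle for the undated DTL family likelihood.

Computes the probability of observing a gene family by *explicit enumeration
of event histories* with at most ``max_events`` counted events (duplications,
transfers, losses; speciations and sampling are free), instead of the
package's fixed-point/message-passing dynamic programme.  Probabilities are
carried as polynomials in the event count (arrays indexed by the number of
events consumed), so products become truncated convolutions and every
history of a given order is enumerated exactly once.

Recursion structure: the table F_u[e, k] of one gene clade u depends on
  (a) strictly smaller clades (recursion over clades),
  (b) the same clade at *child* species branches at the same order
      (speciation terms; resolved by postorder within an order), and
  (c) the same clade anywhere at order <= k - 1 (the event-consuming
      duplication/transfer terms; resolved by ascending order).

The non-extinction conditioning denominator is solved independently with
scipy (fsolve on the full extinction system), not by history truncation: the
conditioning is a normalisation, not part of the history space.  Small rates
keep the truncation error negligible: with all rates <= 0.05 the histories
with more than three events contribute < 1e-8 of the total.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import fsolve

from dtlroot.dtl_model import RateTriple, event_probs
from dtlroot.treeio import GeneFamilyTree, SpeciesTree


def extinction_by_orders(s: SpeciesTree, p, max_events: int) -> np.ndarray:
    """ext[e, k]: P(lineage entering branch e unobserved, exactly k events)."""
    B = s.n_branches
    m = s.m_vector()
    K = max_events + 1
    ext = np.zeros((B, K))
    for k in range(K):
        for e in range(B):  # postorder: children precede parents
            f, g = int(s.child_left[e]), int(s.child_right[e])
            total = 0.0
            if k == 1:
                total += p.p_L
            if f < 0:
                if k == 0:
                    total += p.p_S * m[e]
            else:
                total += p.p_S * sum(ext[f, i] * ext[g, k - i]
                                     for i in range(k + 1))
            if k >= 1:
                # duplication: both copies on e must vanish
                total += p.p_D * sum(ext[e, i] * ext[e, k - 1 - i]
                                     for i in range(k))
                # transfer: the copy sent to h and the resident both vanish
                for h in range(B):
                    if h == e:
                        continue
                    total += p.p_T / (B - 1) * sum(
                        ext[h, i] * ext[e, k - 1 - i] for i in range(k))
            ext[e, k] = total
    return ext


def extinction_exact(s: SpeciesTree, p) -> np.ndarray:
    """Full extinction vector via an independent numerical solve (fsolve)."""
    B = s.n_branches
    m = s.m_vector()
    leaf = s.child_left < 0

    def defect(E):
        Em = (E.sum() - E) / (B - 1)
        term = np.where(leaf, p.p_S * m, 0.0)
        idx = np.flatnonzero(~leaf)
        term[idx] = p.p_S * E[s.child_left[idx]] * E[s.child_right[idx]]
        return p.p_L + p.p_D * E ** 2 + p.p_T * Em * E + term - E

    E = fsolve(defect, np.full(B, 0.1), xtol=1e-13)
    assert np.max(np.abs(defect(E))) < 1e-12
    return E


def _canon(u):
    """Canonical nested-tuple form of a clade (children order-insensitive)."""
    if isinstance(u, str):
        return u
    a, b = _canon(u[0]), _canon(u[1])
    return (a, b) if repr(a) <= repr(b) else (b, a)


def clades_of_rootings(g: GeneFamilyTree) -> list:
    """All rooted versions of the unrooted gene tree, as (clade, clade)
    pairs of nested species-name tuples; one rooting per gene-tree edge."""
    def clade(x, away_from):
        if x in g.leaf_species:
            return g.leaf_species[x]
        kids = [clade(y, x) for y in g.adjacency[x] if y != away_from]
        assert len(kids) == 2
        return (kids[0], kids[1])

    return [(clade(u, v), clade(v, u)) for u, v in g.edges]


def family_likelihood_enumerated(g: GeneFamilyTree, s: SpeciesTree,
                                 r: RateTriple, max_events: int = 3,
                                 include_stem: bool = True) -> float:
    """log P(family) by history enumeration up to ``max_events`` events."""
    p = event_probs(r)
    B = s.n_branches
    K = max_events + 1
    m = s.m_vector()
    ext = extinction_by_orders(s, p, max_events)
    branch_of = s.branch_of_species
    tables: dict = {}

    def table(u) -> np.ndarray:
        u = _canon(u)
        if u in tables:
            return tables[u]
        if isinstance(u, tuple):
            Fv, Fw = table(u[0]), table(u[1])
        F = np.zeros((B, K))
        for k in range(K):
            for e in range(B):  # postorder
                f, gch = int(s.child_left[e]), int(s.child_right[e])
                total = 0.0
                if isinstance(u, str):
                    if k == 0 and f < 0 and branch_of[u] == e:
                        total += p.p_S * (1.0 - m[e])
                else:
                    if k >= 1:
                        # visible duplication: both copies leave descendants
                        total += p.p_D * sum(Fv[e, i] * Fw[e, k - 1 - i]
                                             for i in range(k))
                        # visible transfer: one child clade stays on e, the
                        # other continues on a uniformly drawn recipient h
                        for h in range(B):
                            if h == e:
                                continue
                            total += p.p_T / (B - 1) * sum(
                                Fv[e, i] * Fw[h, k - 1 - i]
                                + Fw[e, i] * Fv[h, k - 1 - i]
                                for i in range(k))
                    if f >= 0:
                        # speciation: the two child clades split f/g
                        total += p.p_S * sum(
                            Fv[f, i] * Fw[gch, k - i] + Fv[gch, i] * Fw[f, k - i]
                            for i in range(k + 1))
                # propagation terms, identical for leaf and internal clades
                if f >= 0:
                    # speciation-loss: u survives in one child branch only
                    total += p.p_S * sum(
                        F[f, i] * ext[gch, k - i] + F[gch, i] * ext[f, k - i]
                        for i in range(k + 1))
                if k >= 1:
                    # duplication with one extinct copy (either of the two)
                    total += 2.0 * p.p_D * sum(F[e, i] * ext[e, k - 1 - i]
                                               for i in range(k))
                    for h in range(B):
                        if h == e:
                            continue
                        # transfer with extinct donor resident / extinct copy
                        total += p.p_T / (B - 1) * sum(
                            F[h, i] * ext[e, k - 1 - i]
                            + F[e, i] * ext[h, k - 1 - i]
                            for i in range(k))
                F[e, k] = total
        tables[u] = F
        return F

    n_orig = B if include_stem else B - 1
    lik = 0.0
    for c1, c2 in clades_of_rootings(g):
        Froot = table((c1, c2))
        lik += float(Froot[:n_orig].sum())
    E = extinction_exact(s, p)
    denom = 1.0 - float(E[:n_orig].mean())
    if lik <= 0.0:
        return -math.inf
    return math.log(lik) - math.log(n_orig) - math.log(denom)
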