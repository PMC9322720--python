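import math

import numpy as np
import pytest

from dtlroot.dtl_model import (
    RateTriple,
    event_probs,
    extinction_probabilities,
    family_loglik,
    optimize_rates,
)
from dtlroot.simulate import simulate_species_tree
from dtlroot.treeio import GeneFamilyTree

from _enumeration import extinction_exact


class TestEventProbs:
    @pytest.mark.parametrize("rates, expected", [
        ((1, 1, 1), (0.25, 0.25, 0.25, 0.25)),
        ((0, 0, 0), (0.0, 0.0, 0.0, 1.0)),
        ((0.5, 0.5, 0), (0.25, 0.25, 0.0, 0.5)),
    ])
    def test_normalisation(self, rates, expected):
        p = event_probs(RateTriple(*rates))
        assert (p.p_D, p.p_T, p.p_L, p.p_S) == pytest.approx(expected)
        assert p.p_D + p.p_T + p.p_L + p.p_S == pytest.approx(1.0, abs=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            RateTriple(-0.1, 0, 0)

    def test_td_ratio(self):
        assert RateTriple(0.01, 0.5, 0).td_ratio == pytest.approx(50.0)
        assert math.isinf(RateTriple(0.0, 0.5, 0).td_ratio)
        assert math.isnan(RateTriple(0.0, 0.0, 0).td_ratio)


class TestExtinction:
    def test_no_loss_no_missing_is_zero(self, species3):
        E = extinction_probabilities(species3, event_probs(RateTriple(0.3, 0.2, 0.0)))
        assert np.all(E.values == 0.0)

    def test_leaf_closed_form(self, species2):
        # with delta = tau = 0 and m = 0 a leaf lineage dies iff lost
        lam = 0.4
        p = event_probs(RateTriple(0, 0, lam))
        E = extinction_probabilities(species2, p).values
        leaf = species2.child_left < 0
        assert E[leaf] == pytest.approx(lam / (lam + 1.0), abs=1e-12)

    def test_matches_independent_solver(self, species3):
        p = event_probs(RateTriple(0.1, 0.1, 0.1))
        mine = extinction_probabilities(species3, p).values
        ref = extinction_exact(species3, p)
        assert np.max(np.abs(mine - ref)) < 1e-12

    def test_monotone_in_loss_rate(self, species3):
        prev = None
        for lam in (0.05, 0.2, 0.6, 1.5):
            E = extinction_probabilities(
                species3, event_probs(RateTriple(0.05, 0.05, lam))).values
            if prev is not None:
                assert np.all(E >= prev - 1e-14)
            prev = E

    def test_missing_fraction_enters(self, species3):
        t = species3.with_missing({"A": 0.5, "B": 0.5, "C": 0.5})
        E = extinction_probabilities(t, event_probs(RateTriple(0, 0, 0))).values
        leaf = t.child_left < 0
        assert E[leaf] == pytest.approx(0.5)


class TestFamilyLoglik:
    def test_probability_bound(self, species3, bact_small):
        ds = bact_small
        for fam in ds.families[:10]:
            ll = family_loglik(fam.gene_tree, ds.species_tree,
                               RateTriple(0.05, 0.3, 0.4))
            assert math.isfinite(ll) and ll <= 0.0

    def test_multicopy_without_gains_is_infeasible(self, species3):
        g = GeneFamilyTree.from_newick("(A_1,(A_2,B_1));", "f",
                                       species=species3.species)
        assert family_loglik(g, species3, RateTriple(0, 0, 0.2)) == -math.inf

    def test_congruent_family_zero_rates(self, species3):
        # only one rooting x origination survives: the matching one at the stem
        g = GeneFamilyTree.from_newick("(A_1,(B_1,C_1));", "f",
                                       species=species3.species)
        ll = family_loglik(g, species3, RateTriple(0, 0, 0))
        assert ll == pytest.approx(math.log(1.0 / species3.n_branches), abs=1e-12)

    def test_rotation_invariance(self, species3):
        rotations = ["((A_1,B_1),(C_1,C_2));", "((C_2,C_1),(B_1,A_1));",
                     "((B_1,A_1),(C_1,C_2));", "(C_1,((A_1,B_1),C_2));"]
        r = RateTriple(0.08, 0.15, 0.3)
        lls = [family_loglik(
            GeneFamilyTree.from_newick(n, "f", species=species3.species),
            species3, r) for n in rotations]
        assert np.ptp(lls) < 1e-12

    def test_continuity_in_rates(self, species3):
        g = GeneFamilyTree.from_newick("(A_1,(B_1,C_1));", "f",
                                       species=species3.species)
        base = family_loglik(g, species3, RateTriple(0.1, 0.1, 0.1))
        eps = family_loglik(g, species3, RateTriple(0.1 + 1e-9, 0.1, 0.1))
        assert abs(base - eps) < 1e-6

    def test_scaling_safety_large_family(self):
        # a 200-copy family on a 64-leaf species tree stays finite
        t = simulate_species_tree(64, 7)
        species = t.species
        labels = [f"{species[i % 64]}_{i // 64 + 1}" for i in range(200)]

        def nest(ls):
            if len(ls) == 1:
                return ls[0]
            mid = len(ls) // 2
            return f"({nest(ls[:mid])},{nest(ls[mid:])})"

        g = GeneFamilyTree.from_newick(nest(labels) + ";", "big", species=species)
        ll = family_loglik(g, t, RateTriple(0.2, 0.3, 0.4))
        assert math.isfinite(ll) and ll < 0.0

    def test_stem_origination_toggle(self, species3):
        g = GeneFamilyTree.from_newick("(A_1,(B_1,C_1));", "f",
                                       species=species3.species)
        r = RateTriple(0.05, 0.05, 0.1)
        with_stem = family_loglik(g, species3, r, include_stem=True)
        without = family_loglik(g, species3, r, include_stem=False)
        assert with_stem != without


class TestOptimizeRates:
    def test_fixed_td_holds_rates_exactly(self, species3):
        g = GeneFamilyTree.from_newick("(A_1,(B_1,C_1));", "f",
                                       species=species3.species)
        fit = optimize_rates(g, species3, mode="fixed_TD", delta0=0.01, tau0=0.5)
        assert fit.rates.delta == 0.01 and fit.rates.tau == 0.5
        assert fit.rates.td_ratio == pytest.approx(50.0)
        assert fit.loglik <= 0.0 and fit.mode == "fixed_TD"

    def test_free_dominates_fixed(self, bact_small):
        ds = bact_small
        for fam in ds.families[:5]:
            free = optimize_rates(fam.gene_tree, ds.species_tree, mode="free")
            fixed = optimize_rates(fam.gene_tree, ds.species_tree,
                                   mode="fixed_TD", delta0=0.02, tau0=0.3)
            assert free.loglik >= fixed.loglik - 1e-6

    def test_deterministic(self, bact_small):
        ds = bact_small
        fam = ds.families[0].gene_tree
        a = optimize_rates(fam, ds.species_tree, mode="free")
        b = optimize_rates(fam, ds.species_tree, mode="free")
        assert (a.rates, a.loglik, a.n_evals) == (b.rates, b.loglik, b.n_evals)

    def test_fixed_requires_rates(self, species3):
        g = GeneFamilyTree.from_newick("(A_1,(B_1,C_1));", "f",
                                       species=species3.species)
        with pytest.raises(ValueError):
            optimize_rates(g, species3, mode="fixed_TD")
        with pytest.raises(ValueError):
            optimize_rates(g, species3, mode="bogus")
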