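import numpy as np
import pytest
from scipy import stats

from dtlroot.simulate import (
    SimConfig,
    bacteria_like,
    eukaryote_like,
    simulate_dataset,
    simulate_family,
    simulate_species_tree,
)


class TestSpeciesTree:
    def test_leaf_count_and_branches(self):
        t = simulate_species_tree(31, 0)
        assert t.n_leaves == 31
        assert t.unroot().n_branches == 59

    def test_deterministic_per_seed(self):
        a = simulate_species_tree(12, 5).to_newick(lengths=True)
        b = simulate_species_tree(12, 5).to_newick(lengths=True)
        c = simulate_species_tree(12, 6).to_newick(lengths=True)
        assert a == b and a != c

    def test_unit_depth_ultrametric(self):
        t = simulate_species_tree(20, 1)
        depths = t.node_depths()[t.child_left < 0]
        assert np.allclose(depths, 1.0, atol=1e-12)

    def test_species_names(self):
        t = simulate_species_tree(5, 0)
        assert t.species == ["S001", "S002", "S003", "S004", "S005"]

    def test_too_few_species(self):
        with pytest.raises(ValueError):
            simulate_species_tree(2, 0)


class TestSimulateFamily:
    def test_zero_rates_congruent_single_copy(self):
        # with no events a family is a faithful copy of the species tree
        # below its (uniformly drawn) origination branch
        t = simulate_species_tree(8, 3)
        cfg = SimConfig(8, 0.0, 0.0, 0.0, n_families=1, seed=0)
        rng = np.random.default_rng(0)
        seen_complete = False
        for _ in range(60):
            fam = simulate_family(t, cfg, rng)
            if fam is None:  # originated below fewer than 3 species
                continue
            assert max(fam.gene_tree.copy_counts.values()) == 1
            assert (fam.n_dup_all, fam.n_trans_all, fam.n_loss_all) == (0, 0, 0)
            assert (fam.n_dup_obs, fam.n_trans_obs, fam.n_loss_obs) == (0, 0, 0)
            if fam.n_leaves == 8:
                assert fam.gene_tree.is_single_copy(t.species)
                seen_complete = True
        assert seen_complete  # stem/root originations cover all species

    def test_transfer_only_regime_has_no_duplications(self):
        t = simulate_species_tree(8, 3)
        cfg = SimConfig(8, 0.0, 0.8, 0.3, n_families=1, seed=0)
        rng = np.random.default_rng(1)
        for _ in range(20):
            fam = simulate_family(t, cfg, rng)
            if fam is not None:
                assert fam.n_dup_all == 0

    def test_observed_counts_bounded_by_full_history(self, bact_small):
        for fam in bact_small.families:
            assert 0 <= fam.n_dup_obs <= fam.n_dup_all
            assert 0 <= fam.n_trans_obs <= fam.n_trans_all
            assert 0 <= fam.n_loss_obs <= fam.n_loss_all

    def test_leaf_labels_carry_species(self, bact_small):
        species = set(bact_small.species_tree.species)
        for fam in bact_small.families[:10]:
            assert set(fam.gene_tree.leaf_species.values()) <= species

    def test_missing_fraction_thins_leaves(self):
        t = simulate_species_tree(10, 2)
        rng = np.random.default_rng(0)

        def mean_size(missing):
            cfg = SimConfig(10, 0.2, 0.2, 0.1, n_families=1, seed=0,
                            missing=missing)
            sizes = []
            while len(sizes) < 60:
                fam = simulate_family(t, cfg, rng)
                if fam is not None:
                    sizes.append(fam.n_leaves)
            return np.mean(sizes)

        assert mean_size(0.5) < mean_size(0.0)


class TestSimulateDataset:
    def test_byte_identical_per_seed(self, tmp_path):
        cfg = bacteria_like(n_species=6, n_families=15, seed=42)
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        d1.write(tmp_path / "a")
        d2.write(tmp_path / "b")
        for name in ("species_tree.nwk", "families.nwk", "truth.tsv",
                     "singlecopy_ids.txt"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_zero_rates_no_paralogs(self):
        cfg = SimConfig(6, 0.0, 0.0, 0.0, n_families=8, seed=1)
        ds = simulate_dataset(cfg)
        for fam in ds.families:
            assert max(fam.gene_tree.copy_counts.values()) == 1
        # the species-complete families are exactly the stem/root originations
        complete = {f.family_id for f in ds.families if f.n_leaves == 6}
        assert set(ds.single_copy_ids()) == complete

    def test_loss_dominated_regime_thins_copies(self, bact_small):
        # lambda > delta + tau: mean observed copies per species below one
        cfg = bact_small.config
        assert cfg.lam > cfg.delta + cfg.tau
        copies = np.mean([f.n_leaves for f in bact_small.families])
        assert copies / bact_small.species_tree.n_leaves < 1.0

    def test_rejection_rate_guard(self):
        cfg = SimConfig(6, 0.001, 0.0, 30.0, n_families=5, seed=0)
        with pytest.raises(RuntimeError, match="rejection"):
            simulate_dataset(cfg)

    def test_presets_satisfy_their_ratios(self):
        b = bacteria_like()
        assert b.tau / b.delta == pytest.approx(50.0)
        assert b.lam == pytest.approx(1.05 * (b.delta + b.tau))
        e = eukaryote_like()
        assert e.delta / e.tau >= 2.0
        with pytest.raises(ValueError):
            bacteria_like(td_ratio=10)
        with pytest.raises(ValueError):
            eukaryote_like(dt_ratio=1.0)

    def test_simulated_td_ratio_recovered(self):
        # total observed-history transfers : duplications near the configured
        # tau:delta (Monte-Carlo check, fixed seed)
        cfg = bacteria_like(n_species=16, n_families=800, seed=9)
        ds = simulate_dataset(cfg)
        tt = ds.truth_table()
        ratio = tt.n_trans_obs.sum() / tt.n_dup_obs.sum()
        assert 0.7 * 50 <= ratio <= 1.3 * 50

    def test_eukaryote_single_copy_families_duplication_poor(self):
        ds = simulate_dataset(eukaryote_like(n_species=8, n_families=150, seed=4))
        tt = ds.truth_table().set_index("family_id")
        sc = ds.single_copy_ids()
        if sc:
            assert tt.loc[sc, "n_dup_obs"].mean() <= tt["n_dup_obs"].mean()


class TestTransferRecipients:
    def test_uniform_among_contemporaneous(self):
        # chi-square against availability-weighted expectation
        t = simulate_species_tree(8, 13)
        cfg = SimConfig(8, 0.0, 1.2, 0.1, n_families=1, seed=0, min_leaves=3)
        rng = np.random.default_rng(99)
        records = []
        while len(records) < 10_000:
            fam = simulate_family(t, cfg, rng)
            if fam is not None:
                records.extend(fam.transfer_records)
        B = t.n_branches
        geom_top = np.where(t.parent >= 0, t.node_depths()[np.maximum(t.parent, 0)], 0.0)
        geom_top[t.root] = -t.lengths[t.root]
        bottom = t.node_depths()
        observed = np.zeros(B)
        expected = np.zeros(B)
        for time, donor, recipient, n_avail in records:
            observed[recipient] += 1
            alive = np.flatnonzero((geom_top <= time) & (time < bottom))
            alive = alive[alive != donor]
            expected[alive] += 1.0 / alive.size
        keep = expected > 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_pruning_preserves_species_labels(self, euk_small):
        species = set(euk_small.species_tree.species)
        for fam in euk_small.families:
            for label in fam.gene_tree.leaf_labels.values():
                assert label.split("_")[0] in species
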