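import numpy as np
import pytest

from dtlroot.rate_policy import RatePolicy
from dtlroot.rooting import AUResult, au_test, root_scan, root_set


class TestRootScan:
    def test_matrix_shape_and_fits(self, bact_small, bact_small_scan):
        scan = bact_small_scan
        L = bact_small.species_tree.n_leaves
        assert scan.n_roots == 2 * L - 3
        assert scan.n_families == len(bact_small.families)
        assert np.all(np.isfinite(scan.loglik))
        assert len(scan.fits) == scan.n_roots

    def test_family_order_does_not_change_entries(self, bact_small):
        unrooted = bact_small.species_tree.unroot()
        fams = bact_small.gene_trees[:6]
        a = root_scan(fams, unrooted, RatePolicy("free"), root_branches=[0, 3])
        b = root_scan(fams[::-1], unrooted, RatePolicy("free"), root_branches=[0, 3])
        assert np.allclose(a.loglik, b.loglik[:, ::-1], atol=0)

    def test_constrained_policy_needs_base_fits(self, bact_small):
        unrooted = bact_small.species_tree.unroot()
        with pytest.raises(ValueError, match="base_fits"):
            root_scan(bact_small.gene_trees[:3], unrooted,
                      RatePolicy("fixed_ratio", "50:1"))

    def test_constrained_rates_follow_policy(self, bact_small, bact_small_scan):
        unrooted = bact_small.species_tree.unroot()
        fams = bact_small.gene_trees[:5]
        base = bact_small_scan.fits[bact_small_scan.best_root()][:5]
        scan = root_scan(fams, unrooted, RatePolicy("fixed_ratio", "50:1"),
                         base_fits=base, root_branches=[0, 1])
        for row in scan.fits:
            for fit, bf in zip(row, base):
                assert fit.rates.tau == bf.rates.tau
                if bf.rates.tau > 0:
                    assert fit.rates.td_ratio == pytest.approx(50.0)

    def test_subset_columns(self, bact_small_scan):
        ids = bact_small_scan.family_ids[2:5]
        sub = bact_small_scan.subset(ids)
        assert sub.family_ids == ids
        assert np.array_equal(sub.loglik, bact_small_scan.loglik[:, 2:5])


class TestAUTest:
    def test_complete_separation(self, rng):
        N = 100
        base = rng.normal(size=N)
        ll = np.vstack([base + 1.0, base])  # root 0 better by 1 per family
        res = au_test(ll, n_boot=2000, seed=1)
        assert res.p[1] < 1e-3
        rs = root_set(res, 0.05, best_root_branch=0)
        assert rs.retained == [0] and rs.rejected == [1]

    def test_identical_rows_all_retained(self, rng):
        row = rng.normal(size=50)
        ll = np.vstack([row, row, row])
        res = au_test(ll, n_boot=1000, seed=2)
        assert np.allclose(res.bp, 1 / 3, atol=0.05)
        assert np.ptp(res.p) < 0.2  # statistically indistinguishable
        rs = root_set(res, 0.05, best_root_branch=0)
        assert rs.retained == [0, 1, 2]

    def test_column_shift_invariance(self, rng):
        ll = rng.normal(size=(4, 60))
        shifts = rng.uniform(-50, 50, size=60)
        a = au_test(ll, n_boot=500, seed=3)
        b = au_test(ll + shifts, n_boot=500, seed=3)
        assert np.array_equal(a.bp_by_scale, b.bp_by_scale)
        assert np.allclose(a.p, b.p, atol=0, rtol=1e-12)
        assert np.allclose(a.d, b.d) and np.allclose(a.c, b.c)

    def test_deterministic_given_seed(self, rng):
        ll = rng.normal(size=(3, 40))
        a = au_test(ll, n_boot=500, seed=9)
        b = au_test(ll, n_boot=500, seed=9)
        assert np.array_equal(a.p, b.p)

    def test_off_support_flag(self, rng):
        base = rng.normal(size=50)
        ll = np.vstack([base + 100.0, base])  # root 1 never wins a replicate
        res = au_test(ll, n_boot=500, seed=4)
        assert res.flags[1] == "off-support" and res.p[1] == 0.0
        assert res.flags[0] == "always-max" and res.p[0] == 1.0

    def test_argmax_root_has_top_bp(self, bact_small_scan):
        res = au_test(bact_small_scan, n_boot=1000, seed=5)
        best = bact_small_scan.best_root()
        assert np.argmax(res.bp) == best

    def test_input_validation(self):
        with pytest.raises(ValueError):
            au_test(np.zeros((1, 10)), n_boot=100)
        with pytest.raises(ValueError):
            au_test(np.zeros((3, 1)), n_boot=100)


class TestRootSet:
    def _result(self, ps):
        K = len(ps)
        return AUResult(list(range(K)), np.linspace(1, 0.5, K),
                        np.zeros(K), np.zeros(K), np.asarray(ps, float),
                        [""] * K, np.zeros((K, 1)), (1.0,), 100, 0)

    def test_simple_partition(self):
        rs = root_set(self._result([0.50, 0.01]), 0.05, best_root_branch=0)
        assert rs.retained == [0] and rs.rejected == [1]

    def test_all_above_alpha(self):
        rs = root_set(self._result([0.3, 0.2, 0.9]), 0.05, best_root_branch=2)
        assert rs.retained == [0, 1, 2] and rs.rejected == []

    def test_argmax_never_rejected(self):
        rs = root_set(self._result([0.04, 0.03]), 0.05, best_root_branch=0)
        assert rs.retained == [0] and rs.rejected == [1]
        assert rs.size >= 1

    def test_monotone_in_alpha(self, rng):
        ps = rng.uniform(size=12)
        res = self._result(ps)
        r1 = root_set(res, 0.01, best_root_branch=int(np.argmax(ps)))
        r2 = root_set(res, 0.10, best_root_branch=int(np.argmax(ps)))
        assert set(r2.retained) <= set(r1.retained)
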