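"""Exhaustive species-tree root scanning and AU-test root sets.

Every branch of the unrooted species tree is a candidate root.  For each
candidate the tree is rooted on that branch and every gene family is
reconciled against it, yielding a (roots x families) matrix of optimised
log-likelihoods.  Which roots are statistically distinguishable is then
decided by the approximately unbiased (AU) test: per-family log-likelihoods
are resampled at several scales (multiscale bootstrap), the bootstrap
proportion of each root being the best is tracked across scales, and the
signed distance / curvature decomposition

    z(sigma) = Phi^{-1}(1 - BP(sigma^2)) = d * sigma + c / sigma

is fitted by weighted least squares; the AU p-value of a root is
1 - Phi(d - c).  Roots with p <= alpha are rejected; the survivors — always
including the maximum-likelihood root — form the *root set*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .dtl_model import FamilyFit, optimize_rates
from .rate_policy import RatePolicy, apply_td_floor, constrain_td
from .treeio import GeneFamilyTree, UnrootedSpeciesTree

__all__ = [
    "RootScanMatrix",
    "AUResult",
    "RootSet",
    "root_scan",
    "au_test",
    "root_set",
    "DEFAULT_SCALES",
]

#: default multiscale-bootstrap scales sigma^2 (the resampling size is
#: n' = round(N / sigma^2)), the conventional 0.5 ... 1.4 grid
DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))


@dataclass
class RootScanMatrix:
    """Optimised log-likelihood of every family under every candidate root."""

    loglik: np.ndarray  # (K roots, N families)
    root_branches: list  # branch indices into the unrooted species tree
    family_ids: list
    fits: list  # fits[k][i] -> FamilyFit under root k
    policy: RatePolicy

    @property
    def n_roots(self) -> int:
        return self.loglik.shape[0]

    @property
    def n_families(self) -> int:
        return self.loglik.shape[1]

    def best_root(self) -> int:
        """Row index of the root with the largest total log-likelihood."""
        return int(np.argmax(self.loglik.sum(axis=1)))

    def subset(self, family_ids: Sequence[str]) -> "RootScanMatrix":
        """Column subset for a family subset (order of ``family_ids`` kept)."""
        pos = {fid: j for j, fid in enumerate(self.family_ids)}
        idx = [pos[f] for f in family_ids]
        return RootScanMatrix(
            self.loglik[:, idx], list(self.root_branches), list(family_ids),
            [[row[j] for j in idx] for row in self.fits], self.policy,
        )

    def to_frame(self) -> "object":
        import pandas as pd

        return pd.DataFrame(self.loglik,
                            index=[f"root{b}" for b in self.root_branches],
                            columns=self.family_ids)


def root_scan(families: Sequence[GeneFamilyTree], t: UnrootedSpeciesTree,
              policy: RatePolicy = RatePolicy("free"),
              base_fits: Sequence[FamilyFit] | None = None,
              root_branches: Sequence[int] | None = None,
              include_stem: bool = True) -> RootScanMatrix:
    """Reconcile every family against every candidate root of ``t``.

    Under the ``free`` policy all three rates are re-optimised per family and
    per root.  Under ``fixed_ratio``/``ratio_floor`` the per-family transfer
    rates must come from a reference free analysis (``base_fits``, aligned
    with ``families``); duplication rates are derived from the policy and
    only the loss rate is re-optimised per root.
    """
    if root_branches is None:
        root_branches = list(range(t.n_branches))
    if policy.kind != "free":
        if base_fits is None:
            raise ValueError(
                f"policy {policy.label} needs base_fits from a free analysis"
            )
        if len(base_fits) != len(families):
            raise ValueError("base_fits must align one-to-one with families")

    # per-family (delta, tau) under the constrained policies, root-independent
    fixed_dt: list | None = None
    if policy.kind == "fixed_ratio":
        fixed_dt = [constrain_td(bf.rates.tau, policy.ratio) for bf in base_fits]
    elif policy.kind == "ratio_floor":
        fixed_dt = [apply_td_floor(bf, policy.ratio) for bf in base_fits]

    K, N = len(root_branches), len(families)
    ll = np.empty((K, N))
    all_fits: list = []
    for k, b in enumerate(root_branches):
        rooted = t.reroot_on_branch(b)
        row: list = []
        for i, fam in enumerate(families):
            try:
                if policy.kind == "free":
                    fit = optimize_rates(fam, rooted, mode="free",
                                         include_stem=include_stem)
                else:
                    d0, t0 = fixed_dt[i]
                    fit = optimize_rates(fam, rooted, mode="fixed_TD",
                                         delta0=d0, tau0=t0,
                                         include_stem=include_stem,
                                         label_mode="td_floor"
                                         if policy.kind == "ratio_floor"
                                         else "fixed_TD")
            except Exception as exc:
                raise RuntimeError(
                    f"reconciliation failed at root branch {b}, family "
                    f"{fam.family_id}: {exc}"
                ) from exc
            if not math.isfinite(fit.loglik):
                raise RuntimeError(
                    f"family {fam.family_id} infeasible at root branch {b} "
                    f"(zero-probability under policy {policy.label})"
                )
            ll[k, i] = fit.loglik
            row.append(fit)
        all_fits.append(row)
    return RootScanMatrix(ll, list(root_branches),
                          [f.family_id for f in families], all_fits, policy)


@dataclass
class AUResult:
    """Multiscale-bootstrap AU test over candidate roots."""

    root_branches: list
    bp: np.ndarray  # naive bootstrap proportion at the scale closest to 1
    d: np.ndarray  # signed distance
    c: np.ndarray  # curvature
    p: np.ndarray  # AU p-value per root
    flags: list  # "" | "off-support" | "always-max"
    bp_by_scale: np.ndarray  # (K, n_scales)
    scales: tuple
    n_boot: int
    seed: int

    def to_frame(self) -> "object":
        import pandas as pd

        return pd.DataFrame({
            "root_branch": self.root_branches,
            "bp": self.bp, "d": self.d, "c": self.c, "au_p": self.p,
            "flag": self.flags,
        })


def au_test(m: RootScanMatrix | np.ndarray, n_boot: int = 10_000,
            scales: Sequence[float] = DEFAULT_SCALES, seed: int = 0) -> AUResult:
    """AU p-values for every candidate root from per-family log-likelihoods.

    For each scale sigma^2, ``n_boot`` resamples of n' = round(N / sigma^2)
    family columns (with replacement) are drawn; a replicate's best root is
    the one with the maximal resampled total log-likelihood, ties split
    equally.  The z-transformed bootstrap proportions are regressed on
    d * sigma + c / sigma by weighted least squares (weights from the
    binomial variance of BP), and the AU p-value is 1 - Phi(d - c).
    Deterministic for a given seed.
    """
    ll = m.loglik if isinstance(m, RootScanMatrix) else np.asarray(m, dtype=float)
    root_branches = m.root_branches if isinstance(m, RootScanMatrix) \
        else list(range(ll.shape[0]))
    K, N = ll.shape
    if K < 2 or N < 2:
        raise ValueError("AU test needs at least 2 roots and 2 families")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    scales = tuple(float(s) for s in scales)
    rng = np.random.default_rng(seed)

    # column-centring improves numerics and cannot change per-replicate
    # argmaxes (a per-family constant adds equally to every root's sum)
    llc = ll - ll.mean(axis=0, keepdims=True)

    bp_by_scale = np.empty((K, len(scales)))
    pvec = np.full(N, 1.0 / N)
    for j, s2 in enumerate(scales):
        nprime = max(1, int(round(N / s2)))
        counts = rng.multinomial(nprime, pvec, size=n_boot)  # (n_boot, N)
        sums = counts.astype(float) @ llc.T  # (n_boot, K)
        rowmax = sums.max(axis=1, keepdims=True)
        is_max = sums >= rowmax - 1e-9 * np.abs(rowmax) - 1e-12
        weights = is_max / is_max.sum(axis=1, keepdims=True)
        bp_by_scale[:, j] = weights.mean(axis=0)

    sigma = np.sqrt(np.asarray(scales))
    lo = 1.0 / (2.0 * n_boot)
    bp_clip = np.clip(bp_by_scale, lo, 1.0 - lo)
    z = norm.ppf(1.0 - bp_clip)  # (K, n_scales)
    X = np.column_stack([sigma, 1.0 / sigma])  # (n_scales, 2)

    d = np.empty(K)
    c = np.empty(K)
    p = np.empty(K)
    flags = []
    for k in range(K):
        if np.all(bp_by_scale[k] <= 0.0):
            d[k], c[k], p[k] = np.inf, 0.0, 0.0
            flags.append("off-support")
            continue
        if np.all(bp_by_scale[k] >= 1.0):
            d[k], c[k], p[k] = -np.inf, 0.0, 1.0
            flags.append("always-max")
            continue
        w = n_boot * norm.pdf(z[k]) ** 2 / (bp_clip[k] * (1.0 - bp_clip[k]))
        Xw = X * w[:, None]
        beta, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ z[k], rcond=None)
        d[k], c[k] = float(beta[0]), float(beta[1])
        p[k] = float(norm.sf(d[k] - c[k]))
        flags.append("")

    j1 = int(np.argmin(np.abs(np.asarray(scales) - 1.0)))
    return AUResult(list(root_branches), bp_by_scale[:, j1], d, c, p, flags,
                    bp_by_scale, scales, n_boot, seed)


@dataclass
class RootSet:
    """Roots surviving the AU test at threshold alpha.

    The maximum-likelihood root is always retained: the best root can never
    be rejected against itself, so the retained set is never empty.
    """

    alpha: float
    retained: list  # root branch indices, ascending
    rejected: list
    best: int  # root branch of the argmax-total-loglik root

    @property
    def size(self) -> int:
        return len(self.retained)

    def __contains__(self, branch: int) -> bool:
        return branch in self.retained


def root_set(a: AUResult, alpha: float = 0.05,
              scan: RootScanMatrix | None = None,
              best_root_branch: int | None = None) -> RootSet:
    """Partition candidate roots into retained (p > alpha) and rejected.

    The argmax root is forced into the retained set; it is identified from
    ``scan`` (or given explicitly), falling back to the root with the
    largest bootstrap proportion.
    """
    if best_root_branch is None:
        if scan is not None:
            best_root_branch = scan.root_branches[scan.best_root()]
        else:
            best_root_branch = a.root_branches[int(np.argmax(a.bp))]
    retained = {b for b, pk in zip(a.root_branches, a.p) if pk > alpha}
    retained.add(best_root_branch)
    rejected = [b for b in a.root_branches if b not in retained]
    return RootSet(alpha, sorted(retained), rejected, best_root_branch)
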