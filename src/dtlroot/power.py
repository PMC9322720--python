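"""Power analysis: which event type carries the rooting signal?

Families are ranked in decreasing order of one fitted rate (duplication,
transfer or loss), cut into consecutive non-overlapping blocks of equal
size, and the AU test is run on each block alone.  If the chosen rate
carries rooting information, blocks with a high mean rate resolve the root
better — i.e. retain *fewer* candidate roots — producing a negative Spearman
correlation between block mean rate and retained-root count.

Per-block AU tests reuse one global (roots x families) log-likelihood
matrix, subsetting its columns: a family's likelihood under a root does not
depend on which block it lands in, so re-scanning per block would compute
the same numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
from scipy import stats

from .dtl_model import FamilyFit
from .rate_policy import RatePolicy
from .rooting import DEFAULT_SCALES, RootScanMatrix, au_test, root_scan, root_set
from .treeio import GeneFamilyTree, UnrootedSpeciesTree

__all__ = ["PowerCurve", "rank_and_block", "power_analysis", "spearman"]

_RATE_ATTR = {"duplication": "delta", "transfer": "tau", "loss": "lam"}


def rank_and_block(fits: Sequence[FamilyFit], key: str,
                   block_size: int = 100) -> list:
    """Consecutive blocks of family ids, ranked by a fitted rate.

    Families are sorted in decreasing order of the chosen rate (ties broken
    by family id, so blocks are deterministic); the trailing remainder that
    cannot fill a block is discarded.  Returns a list of lists of family ids.
    """
    if key not in _RATE_ATTR:
        raise ValueError(f"rate key must be one of {sorted(_RATE_ATTR)}, got {key!r}")
    if len(fits) < block_size:
        raise ValueError(
            f"need at least block_size={block_size} families, got {len(fits)}"
        )
    attr = _RATE_ATTR[key]
    ordered = sorted(fits, key=lambda f: (-getattr(f.rates, attr), f.family_id))
    n_blocks = len(ordered) // block_size
    return [
        [f.family_id for f in ordered[b * block_size:(b + 1) * block_size]]
        for b in range(n_blocks)
    ]


@dataclass
class PowerCurve:
    """Retained-root counts across rate-ranked family blocks."""

    key: str
    block_size: int
    mean_rate: np.ndarray  # per block
    n_roots_retained: np.ndarray  # per block
    rho: float
    p_value: float

    def to_frame(self) -> "object":
        import pandas as pd

        return pd.DataFrame({
            "block_index": np.arange(len(self.mean_rate)),
            "mean_rate": self.mean_rate,
            "n_roots_retained": self.n_roots_retained,
        })


def power_analysis(families: Sequence[GeneFamilyTree], t: UnrootedSpeciesTree,
                   fits: Sequence[FamilyFit], key: str,
                   block_size: int = 100, scan: RootScanMatrix | None = None,
                   n_boot: int = 2000, scales: Sequence[float] = DEFAULT_SCALES,
                   alpha: float = 0.05, seed: int = 0) -> PowerCurve:
    """Block-wise AU rooting power for one rate key.

    ``fits`` are the per-family free fits used for ranking.  ``scan`` is the
    global free-policy root-scan matrix; if omitted it is computed here.
    Per-block bootstrap seeds are derived deterministically from ``seed``.
    """
    if scan is None:
        scan = root_scan(families, t, RatePolicy("free"))
    blocks = rank_and_block(fits, key, block_size)
    attr = _RATE_ATTR[key]
    rate_of = {f.family_id: getattr(f.rates, attr) for f in fits}

    mean_rate = np.empty(len(blocks))
    n_retained = np.empty(len(blocks), dtype=int)
    for b, ids in enumerate(blocks):
        sub = scan.subset(ids)
        res = au_test(sub, n_boot=n_boot, scales=scales, seed=seed * 100_003 + b)
        rs = root_set(res, alpha=alpha, scan=sub)
        mean_rate[b] = float(np.mean([rate_of[f] for f in ids]))
        n_retained[b] = rs.size

    rho, p = spearman(mean_rate, n_retained.astype(float))
    return PowerCurve(key, block_size, mean_rate, n_retained, rho, p)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple:
    """Tie-corrected Spearman rank correlation with a two-tailed p-value.

    rho is the Pearson correlation of midranks.  The p-value uses the
    t-approximation t = rho * sqrt((n - 2) / (1 - rho^2)) with n - 2 degrees
    of freedom for n >= 10, and the exact permutation distribution of rho
    below that.  Constant input leaves rho undefined (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = x.size
    if n < 3:
        raise ValueError("spearman needs n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan, math.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n >= 10:
        if abs(rho) >= 1.0:
            return rho, 0.0
        tstat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * stats.t.sf(abs(tstat), n - 2)
        return rho, float(min(p, 1.0))

    # exact two-tailed permutation distribution of rho
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    obs = abs(float(rxc @ ryc))
    count = 0
    total = 0
    for perm in permutations(range(n)):
        stat = abs(float(rxc @ ryc[list(perm)]))
        if stat >= obs - 1e-12:
            count += 1
        total += 1
    return rho, count / total
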