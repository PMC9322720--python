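"""Undated duplication-transfer-loss (DTL) reconciliation likelihood.

The model assigns each gene family a marginal likelihood given a rooted
species tree and three dimensionless event weights measured relative to the
unit speciation weight: a duplication rate ``delta``, a transfer rate
``tau`` and a loss rate ``lambda``.  Per event opportunity the four outcomes
have probabilities p_D, p_T, p_L, p_S summing to one.  "Undated" means
transfers may land on any species branch other than the donor — no
time-consistency constraint — which is the appropriate machinery when the
species tree carries no calibrated node ages.

The likelihood marginalises over all reconciliation scenarios *and* over all
rootings of the (unrooted) gene tree, and conditions on the family being
observed at all (division by one minus the mean extinction probability over
origination branches).  Only observed families ever enter an analysis, so
unconditioned likelihoods would be systematically too small for families
that are easy to lose.

Rate estimation is derivative-free (Nelder-Mead in log10-rate space) with
rates bounded to [1e-10, 10]; the free mode starts from equal duplication
and transfer rates, the conventional 1:1 T:D seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .treeio import GeneFamilyTree, SpeciesTree, TreeValidationError

__all__ = [
    "RateTriple",
    "EventProbs",
    "ExtinctionVector",
    "FamilyFit",
    "event_probs",
    "extinction_probabilities",
    "family_loglik",
    "optimize_rates",
    "RATE_BOUNDS",
]

#: hard box for all optimized rates (log10 space [-10, 1]).  Free fits on
#: real data are known to wander over many orders of magnitude; the upper
#: bound deliberately clips rates at 10 x the speciation weight.
RATE_BOUNDS = (1e-10, 10.0)

_EXT_TOL = 1e-12
_EXT_CAP = 10_000
_INNER_TOL = 1e-10
_INNER_CAP = 100


@dataclass(frozen=True)
class RateTriple:
    """Per-family DTL rates: duplication, transfer, loss."""

    delta: float
    tau: float
    lam: float

    def __post_init__(self):
        for name, v in (("delta", self.delta), ("tau", self.tau), ("lam", self.lam)):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v}")

    @property
    def td_ratio(self) -> float:
        """Transfer:duplication ratio tau/delta (inf/nan when delta = 0)."""
        if self.delta == 0.0:
            return math.inf if self.tau > 0 else math.nan
        return self.tau / self.delta

    @property
    def td_defined(self) -> bool:
        return self.delta > 0.0

    @property
    def gain(self) -> float:
        return self.delta + self.tau


@dataclass(frozen=True)
class EventProbs:
    """Per-opportunity event probabilities (sum to one)."""

    p_D: float
    p_T: float
    p_L: float
    p_S: float

    def __post_init__(self):
        total = self.p_D + self.p_T + self.p_L + self.p_S
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"event probabilities sum to {total}, not 1")


def event_probs(r: RateTriple) -> EventProbs:
    """Normalise rates against the unit speciation weight."""
    W = r.delta + r.tau + r.lam + 1.0
    return EventProbs(r.delta / W, r.tau / W, r.lam / W, 1.0 / W)


@dataclass
class ExtinctionVector:
    """Per-branch probability that a single entering gene copy is never observed."""

    values: np.ndarray
    n_sweeps: int
    residual: float


def extinction_probabilities(s: SpeciesTree, p: EventProbs) -> ExtinctionVector:
    """Solve the extinction fixed point on every species-tree branch."""
    E, n, ok = _kernels.extinction_fixed_point(
        s.child_left, s.child_right, s.m_vector(),
        p.p_D, p.p_T, p.p_L, p.p_S, _EXT_TOL, _EXT_CAP,
    )
    if not ok:
        resid = _ext_residual(s, p, E)
        raise RuntimeError(
            f"extinction fixed point did not converge in {_EXT_CAP} sweeps "
            f"(residual {resid:.3e})"
        )
    return ExtinctionVector(E, n, _ext_residual(s, p, E))


def _ext_residual(s: SpeciesTree, p: EventProbs, E: np.ndarray) -> float:
    """Max absolute defect of E against one application of the fixed-point map."""
    B = E.size
    m = s.m_vector()
    Em = (E.sum() - E) / (B - 1)
    leaf = s.child_left < 0
    term = np.where(leaf, p.p_S * m, 0.0)
    idx = ~leaf
    term[idx] = p.p_S * E[s.child_left[idx]] * E[s.child_right[idx]]
    mapped = p.p_L + p.p_D * E ** 2 + p.p_T * Em * E + term
    return float(np.max(np.abs(mapped - E)))


class _FamilyContext:
    """Precomputed arrays binding one family to one rooted species tree."""

    __slots__ = ("schedule", "spbranch", "tree", "mvec", "_args")

    def __init__(self, g: GeneFamilyTree, s: SpeciesTree):
        self.schedule = g.schedule()
        branch_of = s.branch_of_species
        try:
            self.spbranch = np.asarray(
                [branch_of[sp] for sp in self.schedule["species"]], dtype=np.int32
            )
        except KeyError as exc:
            raise TreeValidationError(
                f"family {g.family_id}: species {exc.args[0]!r} not in species tree"
            ) from None
        self.tree = s
        self.mvec = s.m_vector()
        sched = self.schedule
        self._args = (
            s.child_left, s.child_right, self.mvec, self.spbranch,
            sched["order"], sched["leafsp"], sched["dep1"], sched["dep2"],
            sched["n_edges"],
        )

    def loglik(self, r: RateTriple, include_stem: bool = True) -> float:
        return self.loglik_raw(r.delta, r.tau, r.lam, include_stem)

    def loglik_raw(self, delta: float, tau: float, lam: float,
                   include_stem: bool = True) -> float:
        W = delta + tau + lam + 1.0
        status, ll = _kernels.family_loglik_kernel(
            *self._args,
            delta / W, tau / W, lam / W, 1.0 / W, include_stem,
            _INNER_TOL, _INNER_CAP, _EXT_TOL, _EXT_CAP,
        )
        if status == 1:
            raise RuntimeError("extinction fixed point did not converge")
        if status == 2:
            raise RuntimeError("degenerate closure denominator (rates too extreme)")
        return float(ll)


def family_loglik(g: GeneFamilyTree, s: SpeciesTree, r: RateTriple,
                  include_stem: bool = True) -> float:
    """Marginal log-likelihood of a gene family; ``-inf`` signals an
    infeasible family (probability exactly zero under these rates, e.g. a
    multi-copy family with no gain events allowed)."""
    return _FamilyContext(g, s).loglik(r, include_stem)


@dataclass
class FamilyFit:
    """Fitted DTL rates and likelihood for one gene family."""

    family_id: str
    mode: str  # "free" | "fixed_TD" | "td_floor"
    rates: RateTriple
    loglik: float
    converged: bool
    n_evals: int
    simplex_spread: float = field(default=0.0)

    @property
    def td_ratio(self) -> float:
        return self.rates.td_ratio


_LOG_BOUNDS = (math.log10(RATE_BOUNDS[0]), math.log10(RATE_BOUNDS[1]))


def _clip_log(x: np.ndarray) -> np.ndarray:
    return np.clip(x, _LOG_BOUNDS[0], _LOG_BOUNDS[1])


def optimize_rates(g: GeneFamilyTree, s: SpeciesTree, mode: str = "free",
                   delta0: float | None = None, tau0: float | None = None,
                   include_stem: bool = True,
                   seed_rate: float = 0.1,
                   fatol: float = 1e-8,
                   maxfev: int = 600,
                   label_mode: str | None = None) -> FamilyFit:
    """Maximum-likelihood DTL rates for one family.

    ``mode="free"`` searches (delta, tau, lambda) jointly by Nelder-Mead in
    log10 space, seeded at delta = tau (= ``seed_rate``), restarting once
    from the best point if the first search fails to converge.
    ``mode="fixed_TD"`` holds delta and tau at ``delta0``/``tau0`` and
    profiles only the loss rate (bounded Brent).  The optimiser is
    deterministic; non-convergence is flagged, the best point is still
    returned.
    """
    ctx = _FamilyContext(g, s)
    lo, hi = _LOG_BOUNDS
    tail = (ctx._args + (include_stem, _INNER_TOL, _INNER_CAP, _EXT_TOL, _EXT_CAP))[4:]
    head = ctx._args[:4]

    if mode == "fixed_TD":
        if delta0 is None or tau0 is None:
            raise ValueError("fixed_TD mode requires delta0 and tau0")
        loglam, f, nfev, conv = _kernels.golden_loss_rate(
            math.log10(max(delta0, RATE_BOUNDS[0])),
            math.log10(max(tau0, RATE_BOUNDS[0])),
            lo, hi, 1e-4, 200, *head, *tail)
        # re-evaluate at the *exact* fixed (delta0, tau0), unclipped
        lam = 10.0 ** float(loglam)
        rates = RateTriple(delta0, tau0, lam)
        ll = ctx.loglik(rates, include_stem)
        return FamilyFit(g.family_id, label_mode or "fixed_TD", rates, ll,
                         bool(conv), int(nfev))

    if mode != "free":
        raise ValueError(f"unknown mode {mode!r}")

    x0 = np.log10([seed_rate, seed_rate, seed_rate])
    xb, f, nfev, conv = _kernels.nelder_mead_rates(
        x0, 1.0, lo, hi, fatol, 1e-3, maxfev, *head, *tail)
    if not conv:
        xb2, f2, nfev2, conv2 = _kernels.nelder_mead_rates(
            xb, 0.25, lo, hi, fatol, 1e-3, maxfev, *head, *tail)
        nfev += nfev2
        if f2 <= f:
            xb, f, conv = xb2, f2, conv2
    rates = RateTriple(10.0 ** xb[0], 10.0 ** xb[1], 10.0 ** xb[2])
    ll = -float(f) if f < 1e12 else float("-inf")
    return FamilyFit(g.family_id, label_mode or "free", rates, ll,
                     bool(conv), int(nfev), 0.0)


def fits_to_table(fits) -> "object":
    """Per-family fit table: family_id, mode, delta, tau, lambda, loglik,
    td_ratio, converged (pandas DataFrame)."""
    import pandas as pd

    rows = [
        {
            "family_id": f.family_id,
            "mode": f.mode,
            "delta": f.rates.delta,
            "tau": f.rates.tau,
            "lambda": f.rates.lam,
            "loglik": f.loglik,
            "td_ratio": f.rates.td_ratio,
            "converged": f.converged,
        }
        for f in fits
    ]
    return pd.DataFrame(rows)
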