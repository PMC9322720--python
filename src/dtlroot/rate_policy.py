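"""Transfer:duplication (T:D) rate constraints and gain/loss summaries.

Reconciliation programs optimise per-family transfer and duplication rates
jointly, seeded at a 1:1 T:D ratio.  To impose an externally estimated T:D
ratio rho (e.g. the 50:1 to 100:1 range measured for prokaryotes by
reconciliation-independent methods), the transfer rate is taken from the
free analysis and the duplication rate is *derived* from it: delta =
tau / rho.  A softer variant only floors the ratio: families whose freely
fitted T:D already exceeds rho_min keep their rates.

The gain/loss summary treats gain = duplication + transfer per family and
reports L:G = mean loss / mean gain across families: above one indicates net
genome reduction, below one net growth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dtl_model import FamilyFit, RateTriple

__all__ = [
    "RatePolicy",
    "RateSummary",
    "parse_td_ratio",
    "constrain_td",
    "apply_td_floor",
    "summarize_rates",
    "summary_table",
]


def parse_td_ratio(text: str | float) -> float:
    """Read a T:D ratio, accepting the literal colon form.

    ``"50:1"`` -> 50.0, ``"1:2"`` -> 0.5, a bare number is passed through.
    The orientation is always transfer:duplication.
    """
    if isinstance(text, str) and ":" in text:
        t, d = text.split(":")
        ratio = float(t) / float(d)
    else:
        ratio = float(text)
    if not (math.isfinite(ratio) and ratio > 0):
        raise ValueError(f"T:D ratio must be finite and > 0, got {text!r}")
    return ratio


@dataclass(frozen=True)
class RatePolicy:
    """How duplication/transfer rates are set during a root scan.

    ``free``        — all three rates optimised per family and per root.
    ``fixed_ratio`` — tau taken from a reference free fit, delta = tau/ratio.
    ``ratio_floor`` — as fixed_ratio, but only for families whose free T:D
                      falls below ``ratio``; others keep their free rates.
    In every mode the loss rate is re-optimised.
    """

    kind: str = "free"
    ratio: float | None = None

    def __post_init__(self):
        if self.kind not in ("free", "fixed_ratio", "ratio_floor"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind != "free":
            if self.ratio is None:
                raise ValueError(f"{self.kind} policy needs a ratio")
            object.__setattr__(self, "ratio", parse_td_ratio(self.ratio))

    @property
    def label(self) -> str:
        if self.kind == "free":
            return "free"
        r = self.ratio
        tag = f"{r:g}:1" if r >= 1 else f"1:{1 / r:g}"
        return f"{self.kind}({tag})"


def constrain_td(tau_opt: float, ratio: float | str) -> tuple[float, float]:
    """Duplication/transfer pair conforming to a target T:D ratio.

    The transfer rate is kept at its freely optimised value and the
    duplication rate is the transfer rate divided by the ratio, so that
    tau/delta = ratio exactly whenever tau_opt > 0.
    Returns ``(delta, tau)``.
    """
    rho = parse_td_ratio(ratio)
    if tau_opt < 0:
        raise ValueError(f"transfer rate must be >= 0, got {tau_opt}")
    if tau_opt == 0.0:
        warnings.warn("tau_opt is 0: constrained duplication rate degenerates to 0",
                      stacklevel=2)
        return 0.0, 0.0
    return tau_opt / rho, tau_opt


def apply_td_floor(fit: FamilyFit, ratio_min: float | str) -> tuple[float, float]:
    """Enforce a minimum T:D ratio on a freely fitted family.

    Families already at or above the floor (including delta = 0, where the
    ratio is infinite or undefined) are returned unchanged; the rest get
    delta = tau / ratio_min.  Idempotent.  Returns ``(delta, tau)``.
    """
    rho_min = parse_td_ratio(ratio_min)
    delta, tau = fit.rates.delta, fit.rates.tau
    if delta == 0.0:
        return delta, tau
    if tau / delta < rho_min:
        return tau / rho_min, tau
    return delta, tau


@dataclass
class RateSummary:
    """Across-family mean/median/std of the four rate statistics plus L:G."""

    n_families: int
    stats: dict  # {"transfer"|"duplication"|"loss"|"gain": {"mean","median","std"}}
    loss_gain_ratio: float  # nan when mean gain is 0
    classification: str  # "reduction" | "growth" | "balanced" | "undefined"


_KEYS = ("transfer", "duplication", "loss", "gain")


def summarize_rates(fits: Sequence[FamilyFit | RateTriple]) -> RateSummary:
    """Summary statistics of fitted rates across families.

    Gain is duplication + transfer per family; L:G divides the *mean* loss by
    the *mean* gain (means, not medians).  Sample std uses the n-1
    denominator (0 for a single family); the median is the midpoint for
    even counts.
    """
    if len(fits) == 0:
        raise ValueError("summarize_rates needs at least one family")
    rates = [f.rates if isinstance(f, FamilyFit) else f for f in fits]
    cols = {
        "transfer": np.array([r.tau for r in rates], dtype=float),
        "duplication": np.array([r.delta for r in rates], dtype=float),
        "loss": np.array([r.lam for r in rates], dtype=float),
    }
    cols["gain"] = cols["transfer"] + cols["duplication"]
    stats = {
        k: {
            "mean": float(np.mean(v)),
            "median": float(np.median(v)),
            "std": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        }
        for k, v in cols.items()
    }
    mean_gain = stats["gain"]["mean"]
    if mean_gain == 0.0:
        lg = math.nan
        cls = "undefined"
    else:
        lg = stats["loss"]["mean"] / mean_gain
        cls = "reduction" if lg > 1.0 else ("growth" if lg < 1.0 else "balanced")
    return RateSummary(len(rates), stats, lg, cls)


def summary_table(summaries: dict) -> "object":
    """Assemble per-dataset summaries into one table (pandas DataFrame).

    ``summaries`` maps a dataset tag (e.g. the policy label) to a
    :class:`RateSummary`; columns mirror the usual published layout:
    mean/median/std for transfer, duplication, loss, gain, plus the
    loss:gain ratio.
    """
    import pandas as pd

    rows = []
    for tag, s in summaries.items():
        row = {"dataset": tag}
        for k in _KEYS:
            for stat in ("mean", "median", "std"):
                row[f"{k}_{stat}"] = s.stats[k][stat]
        row["loss_gain_ratio"] = s.loss_gain_ratio
        row["classification"] = s.classification
        rows.append(row)
    return pd.DataFrame(rows)
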