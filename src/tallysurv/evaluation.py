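"""Survival-model evaluation: time-dependent concordance and IPCW Brier score.

Two metrics summarize predictive performance on a right-censored test set:

* the **time-dependent concordance index** (Antolini-style): over
  comparable pairs — (i, j) with T_i < T_j and subject i an observed
  event, plus tied times where i is an event and j censored — the
  fraction in which the earlier failer has the lower predicted survival
  evaluated at the earlier failure time, ties in the prediction scoring
  one half;
* the **integrated Brier score** (Graf): the mean squared difference
  between predicted survival S_i(t) and survival status 1{T_i > t},
  reweighted by the Kaplan-Meier estimate of the censoring distribution
  (inverse probability of censoring weighting, IPCW) and integrated over
  a time range by the trapezoid rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .models import SurvivalCurves

logger = logging.getLogger(__name__)

__all__ = [
    "KaplanMeier",
    "MetricsReport",
    "km_estimate",
    "concordance_td",
    "brier_at",
    "integrated_brier_score",
]


@dataclass
class KaplanMeier:
    """Product-limit estimate as a right-continuous step function.

    ``left(t)`` evaluates the left limit S(t-), needed by IPCW weights.
    """

    times: np.ndarray       # distinct times with at least one indicated event
    survival: np.ndarray    # S immediately after each time

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        padded = np.concatenate([[1.0], self.survival])
        out = padded[np.searchsorted(self.times, np.atleast_1d(t), side="right")]
        return float(out[0]) if t.ndim == 0 else out

    def left(self, t):
        t = np.asarray(t, dtype=float)
        padded = np.concatenate([[1.0], self.survival])
        out = padded[np.searchsorted(self.times, np.atleast_1d(t), side="left")]
        return float(out[0]) if t.ndim == 0 else out


def km_estimate(durations, indicators) -> KaplanMeier:
    """Kaplan-Meier estimator of P(T > t).

    Passing flipped indicators (1 - event) estimates the censoring
    distribution G used by IPCW.
    """
    d = np.asarray(durations, dtype=float)
    e = np.asarray(indicators).astype(bool)
    if d.size == 0:
        raise ValueError("empty input")
    times = np.unique(d[e])
    if times.size == 0:
        return KaplanMeier(np.array([]), np.array([]))
    n_at_risk = np.array([(d >= t).sum() for t in times], dtype=float)
    n_events = np.array([(e & (d == t)).sum() for t in times], dtype=float)
    surv = np.cumprod(1.0 - n_events / n_at_risk)
    return KaplanMeier(times, surv)


def concordance_td(curves: SurvivalCurves, durations, events) -> float:
    """Time-dependent concordance over comparable pairs.

    Comparable pairs: (i, j) with T_i < T_j and D_i = 1, plus T_i = T_j
    with D_i = 1 and D_j = 0.  A pair is concordant when
    S_i(T_i) < S_j(T_i); ties in the predicted survival score 1/2.
    Raises when no pair is comparable.
    """
    d = np.asarray(durations, dtype=float)
    e = np.asarray(events).astype(bool)
    n = len(d)
    if curves.n != n:
        raise ValueError("curves and outcomes disagree on n")

    S_at = curves.at(d)  # (n subjects) x (n times T_i): S_j(T_i) = S_at[j, i]
    comparable = (e[:, None] & (d[:, None] < d[None, :])) | (
        e[:, None] & ~e[None, :] & (d[:, None] == d[None, :]))
    np.fill_diagonal(comparable, False)
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise ValueError("concordance undefined: no comparable pairs")
    Si = np.diag(S_at)[:, None]     # S_i(T_i)
    Sj = S_at.T                     # S_j(T_i) as [i, j]
    conc = np.where(Si < Sj, 1.0, np.where(Si == Sj, 0.5, 0.0))
    return float((conc * comparable).sum() / n_pairs)


def brier_at(t: float, curves: SurvivalCurves, durations, events,
             censor_km: KaplanMeier) -> float:
    """IPCW Brier score at one time.

    BS(t) = (1/n) sum_i [ S_i(t)^2 1{T_i <= t, D_i=1} / G(T_i-)
                        + (1 - S_i(t))^2 1{T_i > t} / G(t) ].

    Subjects censored at or before t contribute nothing; terms whose G
    weight is 0 are dropped (count logged).
    """
    d = np.asarray(durations, dtype=float)
    e = np.asarray(events).astype(bool)
    n = len(d)
    S_t = curves.at(float(t))

    term = np.zeros(n)
    died = e & (d <= t)
    alive = d > t
    G_minus = censor_km.left(d)
    G_t = censor_km(float(t))

    dropped = 0
    ok = died & (G_minus > 0)
    dropped += int((died & ~ok).sum())
    term[ok] = S_t[ok] ** 2 / G_minus[ok]
    if G_t > 0:
        term[alive] = (1.0 - S_t[alive]) ** 2 / G_t
    else:
        dropped += int(alive.sum())
    if dropped:
        logger.info("brier_at(t=%g): dropped %d zero-weight terms", t, dropped)
    return float(term.sum() / n)


def integrated_brier_score(curves: SurvivalCurves, durations, events,
                           t_range: tuple[float, float] | None = None,
                           n_points: int = 100) -> float:
    """Trapezoidal integral of BS(t) over ``t_range``, divided by its length.

    Default range is (0, max observed duration); the censoring
    distribution is estimated on the same data with flipped indicators.
    """
    d = np.asarray(durations, dtype=float)
    e = np.asarray(events).astype(int)
    if t_range is None:
        t_range = (0.0, float(d.max()))
    lo, hi = map(float, t_range)
    if hi <= lo:
        raise ValueError("zero-length integration range")
    censor_km = km_estimate(d, 1 - e)
    ts = np.linspace(lo, hi, n_points)
    bs = np.array([brier_at(t, curves, d, e, censor_km) for t in ts])
    return float(np.trapezoid(bs, ts) / (hi - lo))


@dataclass
class MetricsReport:
    """Per-fold concordance and IBS with mean and dispersion."""

    c_td_folds: np.ndarray
    ibs_folds: np.ndarray
    t_range: tuple[float, float] | None = None

    def __post_init__(self):
        self.c_td_folds = np.atleast_1d(np.asarray(self.c_td_folds, dtype=float))
        self.ibs_folds = np.atleast_1d(np.asarray(self.ibs_folds, dtype=float))

    @property
    def c_td(self) -> float:
        return float(self.c_td_folds.mean())

    @property
    def ibs(self) -> float:
        return float(self.ibs_folds.mean())

    @property
    def c_td_sd(self) -> float | None:
        return float(self.c_td_folds.std(ddof=1)) if len(self.c_td_folds) >= 2 else None

    @property
    def ibs_sd(self) -> float | None:
        return float(self.ibs_folds.std(ddof=1)) if len(self.ibs_folds) >= 2 else None

    def summary(self) -> str:
        def fmt(mean, sd):
            return f"{mean:.3f} ± {sd:.3f}" if sd is not None else f"{mean:.3f}"

        return (f"c_td {fmt(self.c_td, self.c_td_sd)}, "
                f"IBS {fmt(self.ibs, self.ibs_sd)}")
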