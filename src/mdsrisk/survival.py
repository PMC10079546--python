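"""Survival statistics used by the validation analyses, from first principles.

* Kaplan–Meier product-limit estimator with Greenwood standard errors
  (at a tied time, events are processed before censorings).
* Aalen–Johansen cause-specific cumulative incidence for an event with a
  competing risk; with no competing events it reduces exactly to 1 - KM.
* Harrell's concordance index for right-censored data: a pair (i, j) is
  comparable iff t_i < t_j and patient i had the event; it is concordant when
  the earlier-event patient carries the higher risk score, and tied scores
  count one half.

These are the quantities a prognostic-score validation reports; they are
deliberately implemented here rather than delegated, and the test suite
cross-checks them against independent library implementations and brute-force
enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SurvivalCurve:
    """Step-function estimate on the grid of distinct observed times.

    ``estimate`` is survival probability (starts at 1, non-increasing) or
    cumulative incidence (starts at 0, non-decreasing) depending on ``kind``.
    """

    times: np.ndarray
    estimate: np.ndarray
    at_risk: np.ndarray
    se: np.ndarray | None
    kind: str  # "survival" | "incidence"

    def probability_at(self, t: float) -> float:
        """Step-function value at time t (1 or 0 before the first time)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0 if self.kind == "survival" else 0.0
        return float(self.estimate[idx])

    def median(self) -> float:
        """Smallest time with S(t) <= 0.5 (or incidence >= 0.5); inf if never reached."""
        if self.kind == "survival":
            hit = np.nonzero(self.estimate <= 0.5)[0]
        else:
            hit = np.nonzero(self.estimate >= 0.5)[0]
        return float(self.times[hit[0]]) if hit.size else float("inf")


def _check_inputs(times, *indicator_vectors) -> tuple[np.ndarray, ...]:
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("empty input")
    if np.any(t < 0):
        raise ValueError("negative times")
    out = [t]
    for ind in indicator_vectors:
        e = np.asarray(ind, dtype=int)
        if e.shape != t.shape:
            raise ValueError("length mismatch between times and event indicators")
        if np.any((e != 0) & (e != 1)):
            raise ValueError("event indicators must be 0/1")
        out.append(e)
    return tuple(out)


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate of the survival function."""
    t, e = _check_inputs(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    grid, first_idx = np.unique(t, return_index=True)
    n = t.size

    at_risk = np.empty(grid.size)
    surv = np.empty(grid.size)
    se = np.empty(grid.size)
    s = 1.0
    greenwood = 0.0
    for k, (tk, start) in enumerate(zip(grid, first_idx)):
        end = first_idx[k + 1] if k + 1 < grid.size else n
        n_risk = n - start
        d = int(e[start:end].sum())
        at_risk[k] = n_risk
        if d > 0:
            s *= 1.0 - d / n_risk
            if n_risk > d:
                greenwood += d / (n_risk * (n_risk - d))
        surv[k] = s
        se[k] = s * np.sqrt(greenwood)
    return SurvivalCurve(times=grid, estimate=surv, at_risk=at_risk, se=se, kind="survival")


def cuminc_competing(times, event_of_interest, competing_event) -> SurvivalCurve:
    """Aalen–Johansen cumulative incidence of the event of interest.

    ``competing_event`` marks subjects whose competing event (here: death
    without transformation) precludes the event of interest; the two
    indicators must be mutually exclusive.
    """
    t, e1, e2 = _check_inputs(times, event_of_interest, competing_event)
    if np.any((e1 == 1) & (e2 == 1)):
        raise ValueError("event_of_interest and competing_event overlap")
    order = np.argsort(t, kind="stable")
    t, e1, e2 = t[order], e1[order], e2[order]
    grid, first_idx = np.unique(t, return_index=True)
    n = t.size

    at_risk = np.empty(grid.size)
    cif = np.empty(grid.size)
    running = 0.0
    s_all = 1.0  # all-cause KM, entering each time point (left limit)
    for k, (tk, start) in enumerate(zip(grid, first_idx)):
        end = first_idx[k + 1] if k + 1 < grid.size else n
        n_risk = n - start
        d1 = int(e1[start:end].sum())
        d2 = int(e2[start:end].sum())
        at_risk[k] = n_risk
        running += s_all * d1 / n_risk
        cif[k] = running
        if d1 + d2 > 0:
            s_all *= 1.0 - (d1 + d2) / n_risk
    return SurvivalCurve(times=grid, estimate=cif, at_risk=at_risk, se=None, kind="incidence")


@dataclass(frozen=True)
class ConcordanceResult:
    """Harrell's c with its pair bookkeeping:
    c = (n_concordant + 0.5 * n_tied_score) / n_comparable_pairs."""

    c: float
    n_comparable_pairs: int
    n_concordant: int
    n_tied_score: int


def harrell_c(scores, times, events) -> ConcordanceResult:
    """Concordance between risk scores (higher = worse) and observed outcomes."""
    t, e = _check_inputs(times, events)
    s = np.asarray(scores, dtype=float)
    if s.shape != t.shape:
        raise ValueError("length mismatch between scores and times")

    comparable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs (all censored or all times tied)")
    diff = s[:, None] - s[None, :]
    n_conc = int((comparable & (diff > 0)).sum())
    n_tied = int((comparable & (diff == 0)).sum())
    return ConcordanceResult(
        c=(n_conc + 0.5 * n_tied) / n_pairs,
        n_comparable_pairs=n_pairs,
        n_concordant=n_conc,
        n_tied_score=n_tied,
    )


def curve_table(curve: SurvivalCurve):
    """Curve as a tidy DataFrame (time, at_risk, estimate, se)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "time": curve.times,
            "at_risk": curve.at_risk.astype(int),
            "estimate": curve.estimate,
            "se": curve.se if curve.se is not None else np.full(curve.times.size, np.nan),
        }
    )
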