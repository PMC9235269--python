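"""Turnbull nonparametric MLE for interval-censored event times.

Used as an informal goodness-of-fit check for the first transition: the
parametric F_X curve is compared with the NPMLE computed from the
(v_prev, v_last] intervals of the individuals who were observed to reach
the intermediate state.

The estimator places probability mass only on the Turnbull equivalence
intervals (l, r] — formed from a left endpoint and the nearest right
endpoint with no other endpoint strictly between — and finds the masses by
self-consistency (EM), iterated until the largest mass change is below
``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TurnbullResult", "turnbull", "npmle_first"]


@dataclass
class TurnbullResult:
    """Mass function on Turnbull intervals plus the implied survival steps."""

    intervals: pd.DataFrame  # columns left, right, prob
    loglik: float
    n_iter: int

    def survival(self, t) -> np.ndarray:
        """S(t) = mass strictly beyond t (left endpoints >= t).

        Within a Turnbull interval the NPMLE is undefined; the
        conventional right-continuous step through interval right
        endpoints is returned.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        right = self.intervals["right"].to_numpy()
        prob = self.intervals["prob"].to_numpy()
        return np.array([prob[right > ti].sum() for ti in t])

    def cdf(self, t) -> np.ndarray:
        return 1.0 - self.survival(t)


def _turnbull_intervals(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Equivalence-class intervals (l, r] for observations (L_i, R_i]."""
    pts = sorted(set(np.concatenate([left, right])))
    is_left = {p: False for p in pts}
    is_right = {p: False for p in pts}
    for val in left:
        is_left[val] = True
    for val in right:
        is_right[val] = True
    out = []
    for a, b in zip(pts, pts[1:]):
        if is_left[a] and is_right[b]:
            out.append((a, b))
    return np.array(out)


def turnbull(intervals, tol: float = 1e-8, max_iter: int = 10000) -> TurnbullResult:
    """Self-consistency NPMLE for observations ``(l_i, r_i]``.

    Parameters
    ----------
    intervals : sequence of (left, right) pairs
        Half-open censoring intervals; ``left = 0`` encodes left-censoring.
    """
    arr = np.asarray(list(intervals), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) == 0:
        raise ValueError("need a non-empty sequence of (left, right] pairs")
    L, R = arr[:, 0], arr[:, 1]
    if np.any(L >= R):
        raise ValueError("each interval needs left < right")
    tb = _turnbull_intervals(L, R)
    # membership: Turnbull (l, r] inside observation (L_i, R_i]
    alpha = (L[:, None] <= tb[None, :, 0]) & (tb[None, :, 1] <= R[:, None])
    if not np.all(alpha.any(axis=1)):
        raise RuntimeError("an observation contains no Turnbull interval")
    n, m = alpha.shape
    p = np.full(m, 1.0 / m)
    for it in range(1, max_iter + 1):
        denom = alpha @ p
        p_new = (alpha / denom[:, None]).sum(axis=0) * p / n
        change = np.max(np.abs(p_new - p))
        p = p_new
        if change < tol:
            break
    loglik = float(np.sum(np.log(alpha @ p)))
    tab = pd.DataFrame({"left": tb[:, 0], "right": tb[:, 1], "prob": p})
    return TurnbullResult(intervals=tab, loglik=loglik, n_iter=it)


def npmle_first(records: pd.DataFrame, **kw) -> TurnbullResult:
    """NPMLE of the first transition from AA-detected individuals.

    Restricts to rows with ``delta_aa == 1`` and uses their
    ``(v_prev, v_last]`` censoring intervals.
    """
    aa = records[records["delta_aa"] == 1]
    if len(aa) == 0:
        raise ValueError("no AA-detected individuals in the records")
    return turnbull(list(zip(aa["v_prev"], aa["v_last"])), **kw)
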