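"""Incidence-based (Chao2) richness estimation and sampling-completeness
diagnostics.

Plots are the sampling units: Q1 counts species seen in exactly one
plot of an interval, Q2 species seen in exactly two.  The
bias-corrected Chao2 estimator extrapolates unseen richness from the
ratio of uniques to duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import IntervalAssemblage


@dataclass
class ChaoResult:
    interval: str
    s_obs: int
    q1: int
    q2: int
    m: int  # number of plots
    s_chao: float
    pct_excess: float  # (S_chao - S_obs)/S_obs * 100
    insufficient: bool = False  # m < 2: estimator falls back to S_obs


def chao2(interval: IntervalAssemblage) -> ChaoResult:
    """Bias-corrected incidence-based Chao estimator for one interval.

        S_chao = S_obs + ((m-1)/m) * Q1(Q1-1) / (2(Q2+1))
    """
    inc = interval.incidence.to_numpy()
    m = inc.shape[0]
    counts = inc.sum(axis=0)
    s_obs = int((counts > 0).sum())
    q1 = int((counts == 1).sum())
    q2 = int((counts == 2).sum())
    if m < 2:
        return ChaoResult(interval.label, s_obs, q1, q2, m, float(s_obs), 0.0, True)
    s_chao = s_obs + ((m - 1) / m) * q1 * (q1 - 1) / (2 * (q2 + 1))
    pct = 100.0 * (s_chao - s_obs) / s_obs if s_obs else 0.0
    return ChaoResult(interval.label, s_obs, q1, q2, m, float(s_chao), pct)


def chao_table(assemblages: list[IntervalAssemblage]) -> pd.DataFrame:
    rows = [chao2(a).__dict__ for a in assemblages]
    return pd.DataFrame(rows)


def obs_vs_est_r2(pairs) -> float:
    """OLS R-squared of estimated on observed richness.

    ``pairs`` is an iterable of (S_obs, S_chao).  Used as a
    sampling-evenness diagnostic: high R-squared means incompleteness
    is spread evenly across intervals.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 (observed, estimated) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("observed richness has zero variance")
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2)
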