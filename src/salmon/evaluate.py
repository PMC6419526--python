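"""Survival evaluation: Harrell's concordance index, Kaplan-Meier curves,
the two-group log-rank test, median-risk dichotomisation, and the paired
t-test used to compare cross-validation results."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import SurvivalData

__all__ = [
    "concordance_index",
    "kaplan_meier",
    "logrank_test",
    "dichotomize_by_median",
    "paired_t_test",
]


def concordance_index(risk: np.ndarray, surv: SurvivalData) -> float:
    """Harrell's c-index of a risk score against censored outcomes.

    A pair (i, j) is usable iff the sample with the strictly earlier time
    carries an event; it is concordant when that sample has the higher risk,
    and risk ties count 0.5.  Raises ``ValueError`` with zero usable pairs.
    """
    risk = np.asarray(risk, dtype=float).ravel()
    if len(risk) != len(surv):
        raise ValueError("risk and survival data lengths differ")
    t, e = surv.time, surv.event
    # ordered mask: i is the earlier, event-carrying member of the pair
    earlier = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    usable = int(earlier.sum())
    if usable == 0:
        raise ValueError("no usable pairs for the concordance index")
    diff = risk[:, None] - risk[None, :]
    concordant = int((earlier & (diff > 0)).sum())
    tied = int((earlier & (diff == 0)).sum())
    return (concordant + 0.5 * tied) / usable


def kaplan_meier(surv: SurvivalData) -> pd.DataFrame:
    """Product-limit estimator, one row per distinct event time.

    Columns: ``time``, ``survival``, ``at_risk``.  Censored-only times shrink
    later risk sets but contribute no step.
    """
    if len(surv) == 0:
        raise ValueError("empty survival data")
    t, e = surv.time, surv.event
    event_times = np.unique(t[e == 1])
    rows = []
    s = 1.0
    for tk in event_times:
        n_k = int((t >= tk).sum())
        d_k = int(((t == tk) & (e == 1)).sum())
        s *= 1.0 - d_k / n_k
        rows.append((float(tk), s, n_k))
    return pd.DataFrame(rows, columns=["time", "survival", "at_risk"])


def logrank_test(surv_a: SurvivalData, surv_b: SurvivalData) -> tuple[float, float]:
    """Two-group log-rank (Mantel) test.

    At every distinct event time, observed events in group a are compared with
    the hypergeometric expectation; returns (chi-square statistic, two-sided
    p from the 1-df chi-square tail).  Zero total variance yields p = 1 with a
    warning.
    """
    if len(surv_a) == 0 or len(surv_b) == 0:
        raise ValueError("both groups must be non-empty")
    t = np.concatenate([surv_a.time, surv_b.time])
    e = np.concatenate([surv_a.event, surv_b.event])
    grp = np.concatenate([np.zeros(len(surv_a), dtype=int), np.ones(len(surv_b), dtype=int)])
    if e.sum() == 0:
        raise ValueError("no events in either group")
    o_minus_e = 0.0
    var = 0.0
    for tk in np.unique(t[e == 1]):
        at_risk = t >= tk
        n = int(at_risk.sum())
        n1 = int((at_risk & (grp == 0)).sum())
        dying = (t == tk) & (e == 1)
        d = int(dying.sum())
        d1 = int((dying & (grp == 0)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        warnings.warn("log-rank variance is zero; returning p = 1", stacklevel=2)
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def dichotomize_by_median(risk: np.ndarray) -> np.ndarray:
    """1 = high risk iff risk > median(risk); exact-median samples go low."""
    risk = np.asarray(risk, dtype=float).ravel()
    if len(risk) == 0:
        raise ValueError("empty risk vector")
    return (risk > np.median(risk)).astype(int)


def paired_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Classical paired t on a-b, two-sided, df = n-1.

    Identical vectors (zero difference variance) return (0.0, 1.0) rather
    than an undefined statistic.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0, 1.0
    n = len(d)
    tstat = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(tstat), df=n - 1)
    return float(tstat), float(p)
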