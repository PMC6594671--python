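"""Product-limit survival estimation and the log-rank (Mantel-Cox) test.

Both are implemented from the standard formulas rather than delegated,
so that small-sample behavior is checkable against a permutation oracle:

* Kaplan-Meier: ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` over distinct
  event times ``t_i`` with ``d_i`` events among ``n_i`` at risk;
* log-rank: per distinct pooled event time, observed minus expected
  events per group under the hypergeometric tie model, summed and
  normalized by the hypergeometric covariance; the omnibus statistic is
  chi-square with (#groups - 1) df.

A permutation p-value (relabeling group memberships, recomputing the
statistic) is available for small samples where the chi-square
approximation is in doubt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ValidationError

__all__ = ["KMCurve", "LogRankResult", "km_estimate", "median_survival", "logrank"]


@dataclass
class KMCurve:
    """Kaplan-Meier estimate at the distinct event times.

    ``survival[i]`` is S(t) just after ``times[i]``; ``at_risk[i]`` and
    ``events[i]`` are n_i and d_i at that time.  A censored-only dataset
    has no event times and S == 1 everywhere.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    n_subjects: int

    def survival_at(self, t: float) -> float:
        """S(t): the step function evaluated at time t."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def _check_times_events(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.ndim != 1 or times.shape != events.shape:
        raise ValidationError("times and events must be 1-D and the same length")
    if len(times) == 0:
        raise ValidationError("need at least one subject")
    if (times < 0).any():
        raise ValidationError("negative survival time")
    if not np.isin(events, (0, 1)).all():
        raise ValidationError("event flags must be 0 or 1")
    return times, events


def km_estimate(times, events) -> KMCurve:
    """Product-limit estimate of the survival function."""
    times, events = _check_times_events(times, events)
    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    event_times = np.unique(t_sorted[e_sorted == 1])
    n = len(times)
    at_risk = np.empty(len(event_times), dtype=int)
    d = np.empty(len(event_times), dtype=int)
    surv = np.empty(len(event_times))
    s = 1.0
    for i, t in enumerate(event_times):
        at_risk[i] = int((t_sorted >= t).sum())
        d[i] = int(((t_sorted == t) & (e_sorted == 1)).sum())
        s *= 1.0 - d[i] / at_risk[i]
        surv[i] = s
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk, events=d, n_subjects=n)


def median_survival(curve: KMCurve) -> float | None:
    """Smallest time with S(t) <= 0.5, or None if S never reaches 0.5."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if len(below) == 0:
        return None
    return float(curve.times[below[0]])


@dataclass
class LogRankResult:
    """Mantel-Cox comparison of k survival distributions."""

    statistic: float
    df: int
    p_value: float
    observed: np.ndarray   # per-group observed events
    expected: np.ndarray   # per-group expected events under H0
    group_names: list[str]
    method: str = "chi2"

    def __post_init__(self) -> None:
        if abs(self.observed.sum() - self.expected.sum()) > 1e-9:
            raise ValidationError("observed and expected totals disagree")


def _logrank_core(times: np.ndarray, events: np.ndarray, labels: np.ndarray, k: int):
    """Return (chi2, observed, expected) for integer labels 0..k-1."""
    event_times = np.unique(times[events == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in event_times:
        at_risk_mask = times >= t
        n_j = at_risk_mask.sum()
        d_j = int(((times == t) & (events == 1)).sum())
        n_gj = np.bincount(labels[at_risk_mask], minlength=k).astype(float)
        d_gj = np.bincount(labels[(times == t) & (events == 1)], minlength=k).astype(float)
        e_gj = n_gj * d_j / n_j
        observed += d_gj
        expected += e_gj
        if n_j > 1:
            frac = n_gj / n_j
            v = d_j * (n_j - d_j) / (n_j - 1)
            cov += v * (np.diag(frac) - np.outer(frac, frac))
    diff = (observed - expected)[: k - 1]
    sub = cov[: k - 1, : k - 1]
    try:
        chi2 = float(diff @ np.linalg.solve(sub, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(sub) @ diff)
    return max(chi2, 0.0), observed, expected


def logrank(
    groups: list[tuple],
    group_names: list[str] | None = None,
    method: str = "chi2",
    n_permutations: int = 10000,
    seed: int = 0,
) -> LogRankResult:
    """Log-rank test across two or more groups of (times, events).

    Ties at an event time are handled with the hypergeometric variance
    (all tied events counted at that time).  ``method="chi2"`` uses the
    asymptotic chi-square reference with (#groups - 1) df;
    ``method="permutation"`` resamples group labels ``n_permutations``
    times and reports the fraction of permuted statistics at least as
    large as the observed one (with the +1 continuity correction).
    """
    if len(groups) < 2:
        raise ValidationError("log-rank needs at least two groups")
    k = len(groups)
    if group_names is None:
        group_names = [f"group_{i + 1}" for i in range(k)]
    all_t, all_e, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t, e = _check_times_events(t, e)
        all_t.append(t)
        all_e.append(e)
        labels.append(np.full(len(t), g))
    times = np.concatenate(all_t)
    events = np.concatenate(all_e)
    labels = np.concatenate(labels)
    if events.sum() == 0:
        raise ValidationError("no events in any group; log-rank statistic undefined")

    chi2, observed, expected = _logrank_core(times, events, labels, k)
    if method == "chi2":
        p = float(stats.chi2.sf(chi2, df=k - 1))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        hits = 0
        perm = labels.copy()
        for _ in range(n_permutations):
            rng.shuffle(perm)
            stat_p, _, _ = _logrank_core(times, events, perm, k)
            if stat_p >= chi2 - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return LogRankResult(
        statistic=chi2,
        df=k - 1,
        p_value=p,
        observed=observed,
        expected=expected,
        group_names=list(group_names),
        method=method,
    )


def pairwise_logrank(groups: list[tuple], group_names: list[str] | None = None) -> dict:
    """Unadjusted pairwise log-rank tests between all group pairs."""
    k = len(groups)
    if group_names is None:
        group_names = [f"group_{i + 1}" for i in range(k)]
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            out[(group_names[i], group_names[j])] = logrank(
                [groups[i], groups[j]], [group_names[i], group_names[j]]
            )
    return out
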