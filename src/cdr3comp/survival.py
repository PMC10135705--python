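"""Kaplan–Meier product-limit estimation and the two-group logrank test.

Both statistics are implemented from first principles rather than delegated
to a survival library, because the median-split survival comparison is the
analysis this package exists for and its tie conventions must be explicit:

* subjects censored at time t are still at risk at t (events first);
* censored times reduce subsequent risk sets but contribute no factor to
  the product-limit estimator;
* the logrank statistic is the standard observed-minus-expected form with
  the hypergeometric variance, referred to chi-square on one degree of
  freedom, two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import UndefinedStatisticError, ValidationError


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's right-censored follow-up.

    ``time`` is follow-up in months; ``event`` is 1 if progression/relapse
    was observed at that time, 0 if the subject was censored.
    """

    case_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(
                f"negative follow-up time {self.time} for case {self.case_id!r}"
            )
        if self.event not in (0, 1):
            raise ValidationError(
                f"event indicator must be 0 or 1, got {self.event!r}"
            )


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate over the distinct event times.

    ``survival[i]`` is S(t) just after ``event_times[i]``; the curve is 1
    before the first event.
    """

    event_times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    events: tuple[int, ...]

    def survival_at(self, t: float) -> float:
        s = 1.0
        for et, sv in zip(self.event_times, self.survival):
            if et <= t:
                s = sv
            else:
                break
        return s

    def median_time(self) -> float:
        """First event time where the curve drops to 0.5 or below (inf if never)."""
        for et, sv in zip(self.event_times, self.survival):
            if sv <= 0.5:
                return et
        return float("inf")


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]


def km_estimate(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan–Meier estimator: S(t) = prod over event times t_i <= t of (1 - d_i/n_i)."""
    if not records:
        raise ValidationError("km_estimate requires at least one record")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    event_times = np.unique(times[events == 1])
    surv, n_risk, n_events = [], [], []
    s = 1.0
    for t in event_times:
        n = int(np.sum(times >= t))  # censored at t still at risk at t
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / n
        surv.append(s)
        n_risk.append(n)
        n_events.append(d)
    return KMCurve(tuple(float(t) for t in event_times), tuple(surv),
                   tuple(n_risk), tuple(n_events))


def logrank_test(group_a: list[SurvivalRecord],
                 group_b: list[SurvivalRecord]) -> LogrankResult:
    """Two-group logrank test.

    At each distinct event time with d total events, n at risk overall and
    n_a at risk in group a, group a expects d*n_a/n events; the variance is
    the hypergeometric d*(n_a/n)*(1-n_a/n)*(n-d)/(n-1).  The statistic
    (O_a - E_a)^2 / Var is referred to chi-square(1).
    """
    if not group_a or not group_b:
        raise ValidationError("both groups must be nonempty")
    ta = np.array([r.time for r in group_a])
    ea = np.array([r.event for r in group_a])
    tb = np.array([r.time for r in group_b])
    eb = np.array([r.event for r in group_b])
    all_times = np.concatenate([ta, tb])
    all_events = np.concatenate([ea, eb])
    if all_events.sum() == 0:
        raise UndefinedStatisticError(
            "logrank statistic undefined: no events in either group"
        )
    event_times = np.unique(all_times[all_events == 1])
    o_a = float(ea.sum())
    o_b = float(eb.sum())
    e_a = 0.0
    var = 0.0
    for t in event_times:
        n_a = int(np.sum(ta >= t))
        n_b = int(np.sum(tb >= t))
        n = n_a + n_b
        d = int(np.sum((all_times == t) & (all_events == 1)))
        if n == 0:
            continue
        e_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0.0:
        raise UndefinedStatisticError(
            "logrank variance is zero; groups cannot be compared"
        )
    chi2 = (o_a - e_a) ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    total_events = o_a + o_b
    return LogrankResult(
        chi_square=float(chi2),
        p_value=p,
        observed=(o_a, o_b),
        expected=(e_a, total_events - e_a),
    )


def plot_km(curves: dict[str, KMCurve], path: str,
            title: str = "Disease-free survival") -> None:
    """Step-plot of one KM curve per labelled group (e.g. upper/lower CS)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        xs = [0.0] + list(curve.event_times)
        ys = [1.0] + list(curve.survival)
        ax.step(xs, ys, where="post", label=label)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
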