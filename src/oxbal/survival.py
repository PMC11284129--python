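"""Weighted nonparametric survival methods and the turning-point model.

Provides the survey-weighted Kaplan-Meier (product-limit) estimator, a
weighted log-rank test across exposure groups, and a continuous
two-segment (broken-stick) Cox log-hazard model whose breakpoint is
chosen by profiling the weighted partial likelihood over observed
exposure values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survey import FitResult, SurveyDesign, ZeroEventsError, fit_weighted_cox


@dataclass(frozen=True)
class KMCurve:
    """One group's weighted product-limit curve (right-continuous steps)."""

    group: str
    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    n_risk: np.ndarray  # weighted number at risk at each event time
    n_events: np.ndarray  # weighted events at each event time

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """Evaluate S(t); S = 1 before the first event."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])


def km_estimate(
    time: np.ndarray,
    event: np.ndarray,
    weights: np.ndarray | None = None,
    groups: np.ndarray | None = None,
) -> dict[str, KMCurve]:
    """Weighted Kaplan-Meier survival curves, one per group.

    S(t) = prod_{event times s <= t} (1 - d(s) / Y(s)) with weighted
    event counts d and weighted at-risk totals Y.  With unit weights
    this is the textbook product-limit estimator.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if time.size == 0:
        raise ValueError("empty input: no observations to estimate a curve from")
    if np.any(time <= 0):
        raise ValueError("survival times must be strictly positive")
    n = len(time)
    weights = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be strictly positive")
    groups = np.zeros(n, dtype=int) if groups is None else np.asarray(groups)
    curves: dict[str, KMCurve] = {}
    for g in pd.unique(groups):
        m = groups == g
        if not np.any(m):
            raise ValueError(f"group {g!r} is empty")
        t_g, e_g, w_g = time[m], event[m], weights[m]
        order = np.argsort(t_g, kind="stable")
        t_g, e_g, w_g = t_g[order], e_g[order], w_g[order]
        event_times = np.unique(t_g[e_g > 0])
        surv = np.empty(event_times.size)
        n_risk = np.empty(event_times.size)
        n_ev = np.empty(event_times.size)
        s = 1.0
        for i, s_t in enumerate(event_times):
            at_risk = float(w_g[t_g >= s_t].sum())
            d = float(w_g[(t_g == s_t) & (e_g > 0)].sum())
            s *= 1.0 - d / at_risk
            surv[i], n_risk[i], n_ev[i] = s, at_risk, d
        curves[str(g)] = KMCurve(
            group=str(g), times=event_times, survival=surv, n_risk=n_risk, n_events=n_ev
        )
    return curves


def logrank_test(
    time: np.ndarray,
    event: np.ndarray,
    groups: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[float, float, int]:
    """(Weighted) log-rank test of equal survival across groups.

    At each event time the observed minus expected weighted events per
    group accumulate with the usual hypergeometric-style variance
    computed from weighted at-risk totals; the statistic is chi-squared
    with (groups - 1) degrees of freedom.  Returns (statistic, p, df).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    groups = np.asarray(groups)
    n = len(time)
    weights = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    labels = pd.unique(groups)
    if labels.size < 2:
        raise ValueError("log-rank test needs at least 2 non-empty groups")
    g_idx = {g: i for i, g in enumerate(labels)}
    gi = np.array([g_idx[g] for g in groups])
    k = labels.size
    event_times = np.unique(time[event > 0])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for s_t in event_times:
        at_risk_mask = time >= s_t
        Y = np.bincount(gi[at_risk_mask], weights=weights[at_risk_mask], minlength=k)
        Ytot = Y.sum()
        dead_mask = (time == s_t) & (event > 0)
        d = np.bincount(gi[dead_mask], weights=weights[dead_mask], minlength=k)
        dtot = d.sum()
        if Ytot <= 0 or dtot <= 0:
            continue
        O += d
        E += dtot * Y / Ytot
        frac = Y / Ytot
        # multivariate hypergeometric-style covariance; the finite
        # correction (Ytot - dtot)/(Ytot - 1) matches the unweighted case
        corr = (Ytot - dtot) / (Ytot - 1) if Ytot > 1 else 1.0
        V += dtot * corr * (np.diag(frac) - np.outer(frac, frac))
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        stat = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(Vsub) @ diff)
    df = k - 1
    return stat, float(stats.chi2.sf(stat, df)), df


@dataclass
class SegmentedFit:
    """Two-segment continuous log-hazard fit in one exposure.

    The log-hazard is beta_left * x below the breakpoint and continues
    with slope beta_right above it (hinge parametrization keeps the fit
    continuous at the break).  ``identifiable`` is False when the hinge
    term does not improve on a single straight line.
    """

    breakpoint: float
    left_slope: float
    right_slope: float
    left_ci: tuple[float, float]
    right_ci: tuple[float, float]
    left_p: float
    right_p: float
    identifiable: bool
    profile: pd.DataFrame = field(repr=False)
    fit: FitResult = field(repr=False)

    @property
    def left_hr(self) -> float:
        return float(np.exp(self.left_slope))

    @property
    def right_hr(self) -> float:
        return float(np.exp(self.right_slope))


def segmented_cox(
    time: np.ndarray,
    event: np.ndarray,
    exposure: np.ndarray,
    design: SurveyDesign,
    covariates: pd.DataFrame | None = None,
    grid: np.ndarray | None = None,
) -> SegmentedFit:
    """Continuous two-piece linear log-hazard with profiled breakpoint.

    For each candidate breakpoint b (by default every distinct observed
    exposure value between the 5th and 95th percentiles) the model with
    columns [x, (x - b)+] (+ covariates) is fitted by weighted partial
    likelihood; the b maximizing the likelihood is the turning point.
    Left slope = coefficient of x; right slope = left + hinge.  A break
    whose hinge term fails a 5%-level Wald test is reported as
    non-identifiable (profile effectively flat).
    """
    exposure = np.asarray(exposure, dtype=float)
    if np.unique(exposure).size < 5:
        raise ValueError("need at least 5 distinct exposure values for a breakpoint search")
    if np.asarray(event, dtype=float).sum() == 0:
        raise ZeroEventsError("no events observed")
    if grid is None:
        lo, hi = np.quantile(exposure, [0.05, 0.95])
        grid = np.unique(exposure)
        grid = grid[(grid >= lo) & (grid <= hi)]
        # a breakpoint at the grid edge leaves one side without support
        if grid.size > 2:
            grid = grid[1:-1] if grid[0] == exposure.min() else grid
    grid = np.asarray(grid, dtype=float)
    records = []
    best = None
    for b in grid:
        X = pd.DataFrame({"x": exposure, "hinge": np.clip(exposure - b, 0, None)})
        if covariates is not None:
            X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
        try:
            fit = fit_weighted_cox(time, event, X, design)
        except (np.linalg.LinAlgError, ValueError):
            continue
        records.append({"breakpoint": float(b), "loglik": fit.loglik})
        if best is None or fit.loglik > best[1].loglik:
            best = (float(b), fit)
    if best is None:
        raise RuntimeError("no candidate breakpoint admitted a converged fit")
    b_hat, fit = best
    beta = fit.params
    V = fit.cov
    left = float(beta["x"])
    hinge = float(beta["hinge"])
    right = left + hinge
    se_left = float(np.sqrt(V.loc["x", "x"]))
    var_right = float(V.loc["x", "x"] + 2 * V.loc["x", "hinge"] + V.loc["hinge", "hinge"])
    se_right = float(np.sqrt(var_right))
    z = stats.norm.ppf(0.975)
    hinge_se = float(np.sqrt(V.loc["hinge", "hinge"]))
    hinge_p = float(2 * stats.norm.sf(abs(hinge / hinge_se)))
    return SegmentedFit(
        breakpoint=b_hat,
        left_slope=left,
        right_slope=right,
        left_ci=(left - z * se_left, left + z * se_left),
        right_ci=(right - z * se_right, right + z * se_right),
        left_p=float(2 * stats.norm.sf(abs(left / se_left))),
        right_p=float(2 * stats.norm.sf(abs(right / se_right))),
        identifiable=hinge_p < 0.05,
        profile=pd.DataFrame.from_records(records),
        fit=fit,
    )
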