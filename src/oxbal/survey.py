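"""Design-based inference for stratified, clustered, weighted samples.

Point estimates solve the weight-multiplied score equations (logistic
IRLS; Cox partial likelihood with Breslow handling of ties).  Variances
are design-based by Taylor linearization: per-row weighted score
contributions are aggregated to PSU totals within strata, and the
between-PSU covariance within strata forms the meat of a sandwich with
the model information as bread.  Strata with a single PSU contribute
their deviation from the grand mean of PSU totals (logged as a warning)
rather than being silently dropped.

Wald-type tests on the design-based covariance provide the nonlinearity
test for spline exposures, the quartile trend test, and effect-modifier
interaction tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MODEL2_COVARIATES = ["sex", "age", "ethnicity", "education"]
MODEL3_COVARIATES = MODEL2_COVARIATES + [
    "creatinine",
    "lymphocyte_pct",
    "wbc",
    "alt",
    "alcohol_user",
    "diabetes",
    "hypertension",
    "hyperlipidemia",
    "anemia",
    "total_energy",
]


class ConvergenceError(RuntimeError):
    """Iterative fit failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation detected in a logistic fit."""


class ZeroEventsError(ValueError):
    """A survival fit was requested with no observed events."""


@dataclass(frozen=True)
class SurveyDesign:
    """Stratum and PSU identifiers plus analysis weight per row.

    ``from_frame`` reads the three columns from a participant table;
    ``iid`` builds the degenerate design (one stratum, each row its own
    PSU, unit weights) under which design-based standard errors collapse
    to heteroskedasticity-robust ones.
    """

    stratum: np.ndarray
    psu: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.stratum) == len(self.psu) == len(self.weight)):
            raise ValueError("design columns must have equal length")
        if np.any(~(np.asarray(self.weight, dtype=float) > 0)):
            raise ValueError("all survey weights must be strictly positive")

    def __len__(self) -> int:
        return len(self.weight)

    def subset(self, mask: np.ndarray) -> "SurveyDesign":
        return SurveyDesign(self.stratum[mask], self.psu[mask], self.weight[mask])

    @classmethod
    def from_frame(
        cls,
        data: pd.DataFrame,
        stratum_col: str = "stratum",
        psu_col: str = "psu",
        weight_col: str = "weight",
    ) -> "SurveyDesign":
        return cls(
            stratum=data[stratum_col].to_numpy(),
            psu=data[psu_col].to_numpy(),
            weight=data[weight_col].to_numpy(dtype=float),
        )

    @classmethod
    def iid(cls, n: int) -> "SurveyDesign":
        return cls(
            stratum=np.zeros(n, dtype=int),
            psu=np.arange(n),
            weight=np.ones(n),
        )


@dataclass(frozen=True)
class ModelSpec:
    """Outcome, exposure (and its form) and covariates for one model.

    ``model_id`` 1 fits the exposure alone; 2 adds sex, age, ethnicity
    and education; 3 adds the blood-test, lifestyle and comorbidity
    covariates on top of model 2.
    """

    outcome: str
    exposure: str
    form: str = "continuous"  # continuous | quartile | spline
    model_id: int = 1
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.form not in ("continuous", "quartile", "spline"):
            raise ValueError(f"unknown exposure form {self.form!r}")
        if self.model_id not in (1, 2, 3):
            raise ValueError("model_id must be 1, 2 or 3")

    @classmethod
    def standard(cls, outcome: str, exposure: str, form: str, model_id: int) -> "ModelSpec":
        covs: Sequence[str] = ()
        if model_id == 2:
            covs = MODEL2_COVARIATES
        elif model_id == 3:
            covs = MODEL3_COVARIATES
        return cls(outcome, exposure, form, model_id, tuple(covs))


@dataclass
class FitResult:
    """Coefficients with design-based covariance and derived effects."""

    model: str  # "logistic" | "cox"
    params: pd.Series
    cov: pd.DataFrame
    n: int
    n_iter: int
    converged: bool
    exposure_terms: tuple[str, ...] = ()
    nonlinear_terms: tuple[str, ...] = ()
    loglik: float = np.nan
    extra: dict = field(default_factory=dict)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    @property
    def effects(self) -> pd.Series:
        """exp(coefficient): odds ratios or hazard ratios."""
        return np.exp(self.params)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        lo = np.exp(self.params - z * self.se)
        hi = np.exp(self.params + z * self.se)
        return pd.DataFrame({"low": lo, "high": hi})

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.se
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.se,
                "effect": self.effects,
                "ci_low": ci["low"],
                "ci_high": ci["high"],
                "p": self.pvalues,
            }
        )


def taylor_covariance(
    scores: np.ndarray,
    design: SurveyDesign,
    bread_inv: np.ndarray,
) -> np.ndarray:
    """Sandwich covariance from per-row weighted score contributions.

    ``scores`` (n x p) are summed to PSU totals; within each stratum the
    empirical covariance of PSU totals about the stratum mean, scaled by
    n_h/(n_h - 1), forms the meat.  A lonely-PSU stratum contributes the
    squared deviation of its single PSU total from the grand mean of all
    PSU totals, with a warning, to avoid silently underestimating the
    variance.
    """
    p = scores.shape[1]
    df = pd.DataFrame(scores)
    df["_stratum"] = design.stratum
    df["_psu"] = design.psu
    psu_totals = df.groupby(["_stratum", "_psu"], sort=False).sum()
    strata = psu_totals.index.get_level_values("_stratum")
    totals = psu_totals.to_numpy()
    grand_mean = totals.mean(axis=0)
    meat = np.zeros((p, p))
    lonely = []
    for h in pd.unique(strata):
        z = totals[strata == h]
        n_h = z.shape[0]
        if n_h == 1:
            d = z[0] - grand_mean
            meat += np.outer(d, d)
            lonely.append(h)
        else:
            d = z - z.mean(axis=0)
            meat += (n_h / (n_h - 1)) * d.T @ d
    if lonely:
        logger.warning(
            "strata %s contain a single PSU; using centered-at-grand-mean contributions",
            lonely,
        )
    return bread_inv @ meat @ bread_inv


def _check_design_matrix(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("design matrix contains non-finite values")
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear columns)")


def fit_weighted_logistic(
    y: np.ndarray,
    X: pd.DataFrame,
    design: SurveyDesign,
    max_iter: int = 50,
    tol: float = 1e-10,
    exposure_terms: Sequence[str] = (),
    nonlinear_terms: Sequence[str] = (),
) -> FitResult:
    """Survey-weighted logistic regression with Taylor-linearized variance.

    The point estimate solves sum_i w_i (y_i - p_i) x_i = 0 by
    Newton/IRLS; with equal weights this is the ordinary maximum
    likelihood estimate.  ``X`` must include any intercept column.
    """
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    _check_design_matrix(X)
    Xa = X.to_numpy(dtype=float)
    w = design.weight
    n, p = Xa.shape
    beta = np.zeros(p)
    trace: list[float] = []
    converged = False
    for it in range(1, max_iter + 1):
        eta = Xa @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        resid = y - mu
        grad = Xa.T @ (w * resid)
        wgt = w * mu * (1.0 - mu)
        if np.max(wgt) < 1e-12:
            raise SeparationError("all fitted probabilities degenerate; separation suspected")
        info = Xa.T @ (Xa * wgt[:, None])
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix at iteration {it}") from exc
        beta = beta + step
        trace.append(float(np.max(np.abs(grad))))
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not converged:
        if np.max(np.abs(beta)) > 30:
            raise SeparationError(
                "coefficients diverging (|beta| > 30); complete or quasi-complete separation"
            )
        raise ConvergenceError(
            f"logistic fit did not converge in {max_iter} iterations", trace
        )
    eta = Xa @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    if np.max(np.abs(beta)) > 30:
        raise SeparationError(
            "coefficients diverging (|beta| > 30); complete or quasi-complete separation"
        )
    info = Xa.T @ (Xa * (w * mu * (1 - mu))[:, None])
    bread_inv = np.linalg.inv(info)
    scores = Xa * (w * (y - mu))[:, None]
    cov = taylor_covariance(scores, design, bread_inv)
    loglik = float(np.sum(w * (y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300))))
    return FitResult(
        model="logistic",
        params=pd.Series(beta, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        n=n,
        n_iter=it,
        converged=True,
        exposure_terms=tuple(exposure_terms),
        nonlinear_terms=tuple(nonlinear_terms),
        loglik=loglik,
    )


def _breslow_quantities(
    time: np.ndarray,
    event: np.ndarray,
    Xa: np.ndarray,
    w: np.ndarray,
    beta: np.ndarray,
):
    """Risk-set sums S0, S1 (and log-lik/grad/Hessian) under Breslow ties.

    Arrays must already be sorted by ascending time.  Returns per-row
    S0(t_i), m(t_i)=S1/S0 evaluated at each row's time, plus the summed
    log partial likelihood, gradient and negative Hessian over events.
    """
    n, p = Xa.shape
    eta = Xa @ beta
    r = w * np.exp(np.clip(eta, -700, 700))
    # reverse cumulative sums give risk-set totals for t_j >= t_i, but tied
    # times must share the total of the whole tie group
    rx = r[:, None] * Xa
    s0_rev = np.cumsum(r[::-1])[::-1]
    s1_rev = np.cumsum(rx[::-1], axis=0)[::-1]
    # first index of each tie group (sorted ascending): risk set of a time
    # starts at the group's first row
    first_idx = np.zeros(n, dtype=int)
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    new_group[1:] = time[1:] != time[:-1]
    first_idx = np.maximum.accumulate(np.where(new_group, np.arange(n), 0))
    S0 = s0_rev[first_idx]
    S1 = s1_rev[first_idx]
    m = S1 / S0[:, None]
    ev = event.astype(bool)
    loglik = float(np.sum(w[ev] * (eta[ev] - np.log(S0[ev]))))
    grad = (w[ev, None] * (Xa[ev] - m[ev])).sum(axis=0)
    # Hessian needs S2/S0 - m m' summed over events
    hess = np.zeros((p, p))
    s2_rev = np.cumsum((rx[:, :, None] * Xa[:, None, :])[::-1], axis=0)[::-1]
    S2 = s2_rev[first_idx]
    for i in np.flatnonzero(ev):
        mm = m[i]
        hess += w[i] * (S2[i] / S0[i] - np.outer(mm, mm))
    return eta, r, S0, m, loglik, grad, hess


def fit_weighted_cox(
    time: np.ndarray,
    event: np.ndarray,
    X: pd.DataFrame,
    design: SurveyDesign,
    max_iter: int = 50,
    tol: float = 1e-9,
    exposure_terms: Sequence[str] = (),
    nonlinear_terms: Sequence[str] = (),
) -> FitResult:
    """Survey-weighted Cox regression with design-based sandwich variance.

    Maximizes the weight-multiplied partial likelihood with the Breslow
    approximation for tied event times; the design variance aggregates
    per-subject score contributions (score residuals scaled by weight)
    to PSU totals within strata.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if np.any(time <= 0):
        raise ValueError("survival times must be strictly positive")
    if event.sum() == 0:
        raise ZeroEventsError("no events observed; cannot fit a Cox model")
    _check_design_matrix(X)
    order = np.argsort(time, kind="stable")
    t_s = time[order]
    e_s = event[order]
    X_s = X.to_numpy(dtype=float)[order]
    w_s = design.weight[order]
    n, p = X_s.shape
    beta = np.zeros(p)
    trace: list[float] = []
    converged = False
    loglik = -np.inf
    for it in range(1, max_iter + 1):
        eta, r, S0, m, ll, grad, hess = _breslow_quantities(t_s, e_s, X_s, w_s, beta)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Hessian at iteration {it}", trace) from exc
        # step-halving if the likelihood would decrease
        halving = 0
        while halving < 30:
            cand = beta + step
            ll_new = _cox_loglik(t_s, e_s, X_s, w_s, cand)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2
            halving += 1
        beta = beta + step
        trace.append(float(np.max(np.abs(grad))))
        if np.max(np.abs(step)) < tol:
            converged = True
            loglik = _cox_loglik(t_s, e_s, X_s, w_s, beta)
            break
        loglik = ll_new
    if not converged:
        raise ConvergenceError(f"Cox fit did not converge in {max_iter} iterations", trace)
    eta, r, S0, m, ll, grad, hess = _breslow_quantities(t_s, e_s, X_s, w_s, beta)
    bread_inv = np.linalg.inv(hess)
    # per-subject score contributions u_k (sorted order):
    # u_k = w_k [ delta_k (x_k - m(t_k))
    #             - exp(eta_k) * sum_{events i: t_i <= t_k} w_i/S0(t_i) (x_k - m(t_i)) ]
    a_i = np.where(e_s > 0, w_s * e_s / S0, 0.0)
    cumA = np.cumsum(a_i)
    cumB = np.cumsum(a_i[:, None] * m, axis=0)
    # tied times: the cumulative sums through a subject's time must include
    # every event at that time -> evaluate at the last index of the tie group
    last_idx = np.empty(n, dtype=int)
    new_group = np.empty(n, dtype=bool)
    new_group[-1] = True
    new_group[:-1] = t_s[1:] != t_s[:-1]
    idx = np.where(new_group, np.arange(n), n - 1)
    last_idx = np.minimum.accumulate(idx[::-1])[::-1]
    cumA_k = cumA[last_idx]
    cumB_k = cumB[last_idx]
    exp_eta = np.exp(np.clip(eta, -700, 700))
    u = w_s[:, None] * (
        e_s[:, None] * (X_s - m)
        - exp_eta[:, None] * (X_s * cumA_k[:, None] - cumB_k)
    )
    design_sorted = SurveyDesign(
        stratum=design.stratum[order], psu=design.psu[order], weight=w_s
    )
    cov = taylor_covariance(u, design_sorted, bread_inv)
    return FitResult(
        model="cox",
        params=pd.Series(beta, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        n=n,
        n_iter=it,
        converged=True,
        exposure_terms=tuple(exposure_terms),
        nonlinear_terms=tuple(nonlinear_terms),
        loglik=float(ll),
        extra={"n_events": float(e_s.sum())},
    )


def _cox_loglik(t_s, e_s, X_s, w_s, beta) -> float:
    eta = X_s @ beta
    r = w_s * np.exp(np.clip(eta, -700, 700))
    n = len(t_s)
    s0_rev = np.cumsum(r[::-1])[::-1]
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    new_group[1:] = t_s[1:] != t_s[:-1]
    first_idx = np.maximum.accumulate(np.where(new_group, np.arange(n), 0))
    S0 = s0_rev[first_idx]
    ev = e_s.astype(bool)
    return float(np.sum(w_s[ev] * ((X_s @ beta)[ev] - np.log(S0[ev]))))


def wald_test(fit: FitResult, terms: Sequence[str]) -> tuple[float, float, int]:
    """Joint Wald test that the named coefficients are all zero.

    Uses the design-based covariance; returns (statistic, p, df).
    """
    terms = list(terms)
    if not terms:
        raise ValueError("no terms supplied to the Wald test")
    b = fit.params[terms].to_numpy()
    V = fit.cov.loc[terms, terms].to_numpy()
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular covariance for Wald test on {terms}"
        ) from exc
    df = len(terms)
    return stat, float(stats.chi2.sf(stat, df)), df


def test_nonlinearity(fit: FitResult) -> float:
    """Wald p-value that all nonlinear spline coefficients vanish."""
    if not fit.nonlinear_terms:
        raise ValueError("fit has no nonlinear spline terms; nothing to test")
    _, p, _ = wald_test(fit, fit.nonlinear_terms)
    return p


def build_design_matrix(
    data: pd.DataFrame,
    columns: Sequence[str],
    intercept: bool = True,
) -> pd.DataFrame:
    """Numeric model matrix: dummy-code categoricals, keep numerics.

    String/categorical columns are expanded to treatment-coded
    indicators (first level dropped); binary/numeric columns pass
    through as float.
    """
    parts: list[pd.DataFrame] = []
    if intercept:
        parts.append(pd.DataFrame({"intercept": np.ones(len(data))}, index=data.index))
    for col in columns:
        s = data[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(s.astype(float).to_frame(col))
    out = pd.concat(parts, axis=1)
    out.index = data.index
    return out


def _fit_by_model(model, outcome, X, design, time=None, **kw) -> FitResult:
    if model == "logistic":
        return fit_weighted_logistic(outcome, X, design, **kw)
    if model == "cox":
        return fit_weighted_cox(time, outcome, X, design, **kw)
    raise ValueError(f"unknown model kind {model!r}")


def trend_test(
    outcome: np.ndarray,
    quartile_labels,
    covariates: pd.DataFrame | None,
    design: SurveyDesign,
    model: str = "logistic",
    time: np.ndarray | None = None,
) -> float:
    """p-trend: Wald p of a single ordinal term replacing the quartile dummies.

    The ordinal coding is the 1-based quartile rank; any affine recoding
    gives the identical p-value.
    """
    labels = pd.Categorical(quartile_labels)
    present = labels.remove_unused_categories()
    if len(present.categories) < 2:
        raise ValueError("fewer than 2 quartiles represented; trend test undefined")
    ordinal = pd.Series(labels.codes + 1.0, name="quartile_ordinal")
    X = pd.DataFrame({"intercept": np.ones(len(ordinal)), "quartile_ordinal": ordinal})
    if model == "cox":
        X = X.drop(columns="intercept")
    if covariates is not None:
        X = pd.concat([X.reset_index(drop=True), covariates.reset_index(drop=True)], axis=1)
    fit = _fit_by_model(model, outcome, X, design, time=time)
    return float(fit.pvalues["quartile_ordinal"])


def interaction_test(
    outcome: np.ndarray,
    exposure: np.ndarray,
    modifier,
    covariates: pd.DataFrame | None,
    design: SurveyDesign,
    model: str = "logistic",
    time: np.ndarray | None = None,
) -> float:
    """p-interaction: joint Wald test of exposure-by-modifier product terms."""
    mod = pd.Series(modifier, name="modifier").reset_index(drop=True)
    if mod.nunique() < 2:
        raise ValueError("modifier is constant; interaction test undefined")
    mod_dummies = pd.get_dummies(mod.astype(str), prefix="mod", drop_first=True, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    X = pd.DataFrame({"intercept": np.ones(len(mod)), "exposure": exposure})
    if model == "cox":
        X = X.drop(columns="intercept")
    X = pd.concat([X, mod_dummies], axis=1)
    product_terms = []
    for col in mod_dummies.columns:
        name = f"exposure_x_{col}"
        X[name] = exposure * mod_dummies[col].to_numpy()
        product_terms.append(name)
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    fit = _fit_by_model(model, outcome, X, design, time=time)
    _, p, _ = wald_test(fit, product_terms)
    return p
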