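"""Synthetic NHANES-like cohort generator with known ground truth.

Emulates the structure of a national examination-survey sample: 20 OBS
component exposures (sex-shifted, positively cross-correlated, right-
skewed nutrient intakes plus lifestyle variables), the nine pooled-
cohort-equation risk factors, the model-3 adjustment covariates, a
stratified two-PSU-per-stratum survey design with skewed weights, a
binary high-risk outcome drawn from a logistic model in the *scored*
OBS, and censored exponential survival with a log-hazard linear in the
scored OBS.  Because the outcome links to the scored OBS rather than to
the latent components, the generator's truth parameters are exactly the
quantities the downstream analysis estimates, making parameter-recovery
tests sharp.

Hidden ground-truth columns are prefixed ``_truth_`` and must never be
read by analysis code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .components import default_components
from .scoring import score_cohort

#: Per-component log-normal parameters (meanlog, sdlog, male log-shift)
#: chosen to give realistic intake scales for a US adult sample
#: (means roughly: fiber 17 g/d, carotene 240 RE/d, riboflavin 2.3 mg/d,
#: niacin 25 mg/d, B6 2.1 mg/d, folate 417 mcg/d, B12 5.4 mcg/d,
#: vitamin C 88 mg/d, vitamin E 8.5 mg/d, calcium 944 mg/d, magnesium
#: 313 mg/d, zinc 12 mg/d, copper 1.4 mg/d, selenium 113 mcg/d, total
#: fat 82 g/d, iron 15.5 g/d; physical activity ~2900 MET-min/week,
#: BMI ~28.6 kg/m2).  Men report systematically higher intakes.
DEFAULT_COMPONENT_PARAMS: dict[str, tuple[float, float, float]] = {
    "dietary_fiber": (2.70, 0.55, 0.20),
    "carotene": (5.00, 1.00, 0.10),
    "riboflavin": (0.70, 0.50, 0.25),
    "niacin": (3.10, 0.50, 0.25),
    "vitamin_b6": (0.60, 0.55, 0.25),
    "total_folate": (5.90, 0.50, 0.20),
    "vitamin_b12": (1.40, 0.70, 0.25),
    "vitamin_c": (4.10, 0.90, 0.05),
    "vitamin_e": (1.95, 0.60, 0.15),
    "calcium": (6.70, 0.50, 0.20),
    "magnesium": (5.65, 0.45, 0.20),
    "zinc": (2.35, 0.55, 0.25),
    "copper": (0.20, 0.50, 0.15),
    "selenium": (4.60, 0.50, 0.25),
    "total_fat": (4.30, 0.50, 0.20),
    "iron": (2.65, 0.50, 0.20),
    "physical_activity": (7.50, 1.00, 0.25),
    "bmi": (3.33, 0.20, 0.00),
}


class SimulationConfigError(ValueError):
    """Invalid simulation configuration; message lists offending fields."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Outcome truth: ``logit P(high risk) = intercept + beta_obs * OBS``
    and hazard ``baseline_hazard * exp(gamma_obs * OBS)`` per month.
    When ``intercept`` is None it is set to ``logit(0.33) - 20 *
    beta_obs`` so that prevalence sits near the one-third high-risk
    share typical of a US adult sample (the mean total OBS is close to
    20 by construction of the tertile scores).
    """

    n: int = 2000
    seed: int = 0
    rho_dietary: float = 0.30
    rho_lifestyle: float = 0.10
    male_prob: float = 0.49
    abstainer_prob: float = 0.55
    alcohol_meanlog: float = 2.10
    alcohol_sdlog: float = 1.00
    alcohol_male_shift: float = 0.45
    component_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_PARAMS)
    )
    # outcome truth
    beta_obs: float = float(np.log(0.94))
    intercept: float | None = None
    gamma_obs: float = float(np.log(0.97))
    baseline_hazard: float = 0.0037  # per month at OBS = 0
    horizon: float | None = 192.0  # administrative censoring, months
    dropout_scale: float | None = None  # Uniform(0, scale) dropout, None = none
    cvd_death_frac: float = 0.35
    # survey design truth
    n_strata: int = 15
    psus_per_stratum: int = 2
    weight_sdlog: float = 0.5
    # data-quality knobs for exclusion testing
    prevalent_ascvd_prob: float = 0.02

    def __post_init__(self) -> None:
        problems = []
        if self.n <= 0:
            problems.append(f"n={self.n} (must be positive)")
        for name in ("rho_dietary", "rho_lifestyle"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                problems.append(f"{name}={v} (must lie in [0, 1))")
        for name in ("male_prob", "abstainer_prob", "cvd_death_frac", "prevalent_ascvd_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}={v} (must lie in [0, 1])")
        if self.baseline_hazard <= 0:
            problems.append(f"baseline_hazard={self.baseline_hazard} (must be positive)")
        if self.horizon is not None and self.horizon <= 0:
            problems.append(f"horizon={self.horizon} (must be positive or None)")
        if self.dropout_scale is not None and self.dropout_scale <= 0:
            problems.append(f"dropout_scale={self.dropout_scale} (must be positive or None)")
        if self.n_strata <= 0 or self.psus_per_stratum <= 0:
            problems.append("n_strata and psus_per_stratum must be positive")
        if problems:
            raise SimulationConfigError("invalid simulation config: " + "; ".join(problems))

    @property
    def effective_intercept(self) -> float:
        if self.intercept is not None:
            return self.intercept
        return float(logit(0.33) - 20.0 * self.beta_obs)


def _correlated_normals(rng: np.random.Generator, n: int, k: int, rho: float) -> np.ndarray:
    """Exchangeable-correlation standard normals via a single common factor."""
    common = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, k))
    return np.sqrt(rho) * common + np.sqrt(1.0 - rho) * eps


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw one synthetic participant table; deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    comps = default_components()

    sex = np.where(rng.random(n) < config.male_prob, "male", "female")
    male = (sex == "male").astype(float)
    age = stats.truncnorm.rvs(
        (20 - 55) / 12, (79 - 55) / 12, loc=55, scale=12, size=n, random_state=rng
    )
    race = rng.choice(["white", "black", "other"], size=n, p=[0.55, 0.20, 0.25])
    education = rng.choice(["lt_high", "high", "college"], size=n, p=[0.12, 0.22, 0.66])
    married = rng.random(n) < 0.66

    # dietary components: Gaussian copula with exchangeable correlation on
    # the log scale, sex-shifted log-normal marginals
    dietary_names = [c.name for c in comps if c.cls == "dietary"]
    z_diet = _correlated_normals(rng, n, len(dietary_names), config.rho_dietary)
    data: dict[str, np.ndarray] = {}
    for j, name in enumerate(dietary_names):
        mu, sd, shift = config.component_params[name]
        data[name] = np.exp(mu + shift * male + sd * z_diet[:, j])

    z_life = _correlated_normals(rng, n, 3, config.rho_lifestyle)
    for j, name in enumerate(["physical_activity", "bmi"]):
        mu, sd, shift = config.component_params[name]
        data[name] = np.exp(mu + shift * male + sd * z_life[:, j])

    current_smoker = rng.random(n) < 0.17
    # serum cotinine tracks smoking status: high, tight distribution in
    # smokers; low, dispersed environmental exposure otherwise
    cot_mu = np.where(current_smoker, np.log(180.0), np.log(0.6))
    cot_sd = np.where(current_smoker, 0.7, 1.6)
    data["cotinine"] = np.exp(cot_mu + cot_sd * z_life[:, 2])

    # zero-inflated alcohol: abstainers report exactly 0 on the recall
    u = rng.random(n)
    drinkers = u >= config.abstainer_prob
    v = (u - config.abstainer_prob) / (1 - config.abstainer_prob)
    v = np.clip(v, 1e-12, 1 - 1e-12)
    intake = np.exp(
        config.alcohol_meanlog
        + config.alcohol_male_shift * male
        + config.alcohol_sdlog * stats.norm.ppf(v)
    )
    data["alcohol"] = np.where(drinkers, intake, 0.0)

    # pooled-cohort-equation risk factors
    total_cholesterol = np.clip(rng.normal(206, 40, n), 90, None)
    hdl = np.clip(rng.normal(55, 15, n), 15, None)
    sbp = np.clip(rng.normal(124, 18, n), 80, None)
    on_htn_treatment = rng.random(n) < 0.25
    diabetes = rng.random(n) < 0.13

    # model-3 covariates
    creatinine = np.exp(rng.normal(np.log(0.88), 0.2, n) + 0.1 * male)
    lymphocyte_pct = np.clip(rng.normal(30, 7, n), 5, 70)
    wbc = np.clip(rng.normal(7.0, 1.7, n), 2, None)
    alt = np.exp(rng.normal(np.log(24), 0.4, n) + 0.15 * male)
    total_energy = np.exp(rng.normal(np.log(2000), 0.35, n) + 0.2 * male)
    hypertension = on_htn_treatment | (sbp > 140) | (rng.random(n) < 0.1)
    hyperlipidemia = (total_cholesterol > 240) | (rng.random(n) < 0.35)
    anemia = rng.random(n) < 0.05
    gfr = np.clip(rng.normal(90, 20, n), 10, None)
    alcohol_user = np.select(
        [data["alcohol"] == 0, data["alcohol"] < 5, data["alcohol"] < 15, data["alcohol"] < 30],
        ["never", "mild", "moderate", "heavy_moderate"],
        default="heavy",
    )

    # survey design: equal-probability assignment to strata and PSUs,
    # weights from a shifted log-normal, independent of the outcome
    stratum = rng.integers(1, config.n_strata + 1, size=n)
    psu = rng.integers(1, config.psus_per_stratum + 1, size=n)
    weight = 0.5 + np.exp(rng.normal(0.0, config.weight_sdlog, n))

    prevalent_ascvd = rng.random(n) < config.prevalent_ascvd_prob

    df = pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "sex": sex,
            "age": age,
            "race": race,
            "education": education,
            "married": married.astype(int),
            **data,
            "total_cholesterol": total_cholesterol,
            "hdl": hdl,
            "sbp": sbp,
            "on_htn_treatment": on_htn_treatment.astype(int),
            "diabetes": diabetes.astype(int),
            "current_smoker": current_smoker.astype(int),
            "creatinine": creatinine,
            "lymphocyte_pct": lymphocyte_pct,
            "wbc": wbc,
            "alt": alt,
            "total_energy": total_energy,
            "alcohol_user": alcohol_user,
            "hypertension": hypertension.astype(int),
            "hyperlipidemia": hyperlipidemia.astype(int),
            "anemia": anemia.astype(int),
            "gfr": gfr,
            "prevalent_ascvd": prevalent_ascvd.astype(int),
            "stratum": stratum,
            "psu": psu,
            "weight": weight,
        }
    )

    # ground-truth outcomes are driven by the scored OBS so the analysis
    # estimand equals the generator parameter exactly
    scored = score_cohort(df, comps)
    obs = scored["obs_total"].to_numpy(dtype=float)
    lp = config.effective_intercept + config.beta_obs * obs
    df["high_risk"] = (rng.random(n) < expit(lp)).astype(int)

    rate = config.baseline_hazard * np.exp(config.gamma_obs * obs)
    t_event = rng.exponential(1.0 / rate)
    censor = np.full(n, np.inf)
    if config.horizon is not None:
        censor = np.minimum(censor, config.horizon)
    if config.dropout_scale is not None:
        censor = np.minimum(censor, rng.uniform(0.0, config.dropout_scale, n))
    follow = np.minimum(t_event, censor)
    death = (t_event <= censor).astype(int)
    df["follow_months"] = np.maximum(follow, 1e-6)
    df["death"] = death
    df["cvd_death"] = (death.astype(bool) & (rng.random(n) < config.cvd_death_frac)).astype(int)

    df["_truth_obs_total"] = obs.astype(int)
    df["_truth_p_high_risk"] = expit(lp)
    df["_truth_hazard"] = rate
    return df


TINY_SEED = 20010
FIXTURE_PROFILES = ("tiny", "exclusion-demo", "mortality-demo")


def make_fixture(profile: str) -> tuple[pd.DataFrame, dict]:
    """Build one of the small deterministic fixtures plus its ledger.

    ``tiny``: 50 clean rows for hand-checkable scoring.
    ``exclusion-demo``: 80 rows with disjoint injected defects and a
    ledger of the exact per-rule exclusion counts they construct.
    ``mortality-demo``: 300 high-event-rate rows for survival checks.
    """
    if profile == "tiny":
        cfg = SimulationConfig(n=50, seed=TINY_SEED, prevalent_ascvd_prob=0.0)
        df = generate_cohort(cfg)
        ledger = {"profile": "tiny", "n": 50, "seed": TINY_SEED}
        return df, ledger
    if profile == "exclusion-demo":
        cfg = SimulationConfig(n=80, seed=TINY_SEED + 1, prevalent_ascvd_prob=0.0)
        df = generate_cohort(cfg)
        # disjoint row blocks so first-match attribution is unambiguous
        df.loc[0:4, "vitamin_c"] = np.nan  # 5 rows: missing OBS component
        df.loc[5:8, "age"] = 85.0  # 4 rows: outside PCE age range
        df.loc[9:11, "prevalent_ascvd"] = 1  # 3 rows: prevalent disease
        df.loc[12:13, "education"] = np.nan  # 2 rows: missing covariate
        df.loc[[14], "follow_months"] = np.nan  # 1 row: missing mortality linkage
        ledger = {
            "profile": "exclusion-demo",
            "n": 80,
            "seed": TINY_SEED + 1,
            "expected_counts": {
                "missing_obs_component": 5,
                "missing_or_invalid_pce_input": 4,
                "prevalent_ascvd": 3,
                "missing_covariate": 2,
                "missing_mortality_linkage": 1,
            },
            "expected_remaining": 65,
        }
        return df, ledger
    if profile == "mortality-demo":
        cfg = SimulationConfig(
            n=300,
            seed=TINY_SEED + 2,
            baseline_hazard=0.02,
            horizon=120.0,
            prevalent_ascvd_prob=0.0,
        )
        df = generate_cohort(cfg)
        ledger = {"profile": "mortality-demo", "n": 300, "seed": TINY_SEED + 2}
        return df, ledger
    raise ValueError(f"unknown fixture profile {profile!r}; expected one of {FIXTURE_PROFILES}")


def packaged_fixture_path(name: str = "tiny") -> Path:
    return Path(str(resources.files("oxbal").joinpath(f"data/fixtures/{name}.csv")))


def load_packaged_fixture(name: str = "tiny") -> tuple[pd.DataFrame, dict]:
    """Load the packaged copy of a fixture and its ledger."""
    df = pd.read_csv(packaged_fixture_path(name))
    ledger_path = Path(str(resources.files("oxbal").joinpath(f"data/fixtures/{name}_ledger.json")))
    ledger = json.loads(ledger_path.read_text())
    return df, ledger
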