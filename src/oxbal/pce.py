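"""Pooled Cohort Equations: 10-year atherosclerotic CVD risk.

The Pooled Cohort Equations (PCE) are the ACC/AHA sex- and race-specific
proportional-hazards equations for the 10-year probability of a first
hard ASCVD event.  They take nine inputs: race, sex, age, total
cholesterol, HDL cholesterol, systolic blood pressure, antihypertensive
treatment, diabetes, and current smoking.  Risk is

    risk = 1 - S10 ** exp(LP - mean_lp)

where LP is a linear predictor over log-transformed continuous inputs
(with age interactions), mean_lp the group's mean linear predictor, and
S10 the group's 10-year baseline survival.  Coefficients live in a
versioned data file, not in code, so the transcription is auditable.

Participants with predicted risk at or above 7.5% are classified as
"high ASCVD risk"; below, "low".
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

HIGH_RISK_THRESHOLD = 0.075
PCE_AGE_RANGE = (20.0, 79.0)

_GROUPS = (
    "white_or_other_female",
    "black_female",
    "white_or_other_male",
    "black_male",
)

_TERMS = frozenset(
    {
        "ln_age",
        "ln_age_sq",
        "ln_tc",
        "ln_age_x_ln_tc",
        "ln_hdl",
        "ln_age_x_ln_hdl",
        "ln_sbp_treated",
        "ln_age_x_ln_sbp_treated",
        "ln_sbp_untreated",
        "ln_age_x_ln_sbp_untreated",
        "smoker",
        "ln_age_x_smoker",
        "diabetes",
    }
)


class PCESchemaError(ValueError):
    """The coefficient file violates the PCE schema."""


class AgeOutOfRangeError(ValueError):
    """Age outside the PCE validity window [20, 79]."""


@dataclass(frozen=True)
class RiskProfile:
    """The nine PCE inputs for one participant."""

    age: float
    sex: str  # male | female
    race_group: str  # black | white_or_other
    total_cholesterol: float  # mg/dL
    hdl: float  # mg/dL
    sbp: float  # mmHg
    on_htn_treatment: bool
    diabetes: bool
    current_smoker: bool

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.race_group not in ("black", "white_or_other"):
            raise ValueError(f"unknown race group {self.race_group!r}")
        for name in ("total_cholesterol", "hdl", "sbp"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def group(self) -> str:
        race = "black" if self.race_group == "black" else "white_or_other"
        return f"{race}_{self.sex}"


@dataclass(frozen=True)
class PCECoefficientSet:
    """Coefficients, mean linear predictors and baseline survivals per group."""

    groups: dict[str, dict]
    provenance: str
    checksum: str

    def linear_predictor(self, profile: RiskProfile) -> float:
        terms = _term_values(profile)
        coefs = self.groups[profile.group]["terms"]
        return sum(coef * terms[name] for name, coef in coefs.items())


@dataclass(frozen=True)
class RiskOutput:
    """PCE risk, high/low classification, and any validity flag."""

    risk: float
    high_risk: bool
    threshold: float = HIGH_RISK_THRESHOLD
    age_out_of_range: bool = False


def _term_values(profile: RiskProfile) -> dict[str, float]:
    la = math.log(profile.age)
    ltc = math.log(profile.total_cholesterol)
    lhdl = math.log(profile.hdl)
    lsbp = math.log(profile.sbp)
    treated = bool(profile.on_htn_treatment)
    smoker = float(profile.current_smoker)
    return {
        "ln_age": la,
        "ln_age_sq": la * la,
        "ln_tc": ltc,
        "ln_age_x_ln_tc": la * ltc,
        "ln_hdl": lhdl,
        "ln_age_x_ln_hdl": la * lhdl,
        "ln_sbp_treated": lsbp if treated else 0.0,
        "ln_age_x_ln_sbp_treated": la * lsbp if treated else 0.0,
        "ln_sbp_untreated": 0.0 if treated else lsbp,
        "ln_age_x_ln_sbp_untreated": 0.0 if treated else la * lsbp,
        "smoker": smoker,
        "ln_age_x_smoker": la * smoker,
        "diabetes": float(profile.diabetes),
    }


def default_coefficient_path() -> Path:
    return Path(str(resources.files("oxbal").joinpath("data/pce_coefficients.yaml")))


def load_pce_coefficients(path: str | Path | None = None) -> PCECoefficientSet:
    """Load and validate a PCE coefficient file.

    Raises :class:`PCESchemaError` naming the offending entry if a group
    is missing, a baseline survival falls outside (0, 1), or a term does
    not belong to the documented vocabulary.
    """
    path = Path(path) if path is not None else default_coefficient_path()
    raw_bytes = path.read_bytes()
    raw = yaml.safe_load(raw_bytes)
    groups = raw.get("groups", {})
    for g in _GROUPS:
        if g not in groups:
            raise PCESchemaError(f"missing PCE group {g!r}")
    for g, entry in groups.items():
        if g not in _GROUPS:
            raise PCESchemaError(f"unknown PCE group {g!r}")
        s10 = entry.get("s10")
        if s10 is None or not (0.0 < float(s10) < 1.0):
            raise PCESchemaError(f"group {g!r}: baseline survival s10={s10!r} outside (0, 1)")
        if "mean_lp" not in entry:
            raise PCESchemaError(f"group {g!r}: missing mean_lp")
        terms = entry.get("terms", {})
        if not terms:
            raise PCESchemaError(f"group {g!r}: empty term list")
        for t in terms:
            if t not in _TERMS:
                raise PCESchemaError(f"group {g!r}: unknown term {t!r}")
    return PCECoefficientSet(
        groups=groups,
        provenance=str(raw.get("provenance", "")),
        checksum=hashlib.sha256(raw_bytes).hexdigest(),
    )


def pce_risk(profile: RiskProfile, coefs: PCECoefficientSet) -> RiskOutput:
    """Compute 10-year ASCVD risk for one profile.

    Ages outside [20, 79] are flagged (never clamped); the pipeline
    excludes flagged rows rather than reporting a distorted risk.
    """
    out_of_range = not (PCE_AGE_RANGE[0] <= profile.age <= PCE_AGE_RANGE[1])
    entry = coefs.groups[profile.group]
    lp = coefs.linear_predictor(profile)
    risk = 1.0 - float(entry["s10"]) ** math.exp(lp - float(entry["mean_lp"]))
    return RiskOutput(
        risk=risk,
        high_risk=risk >= HIGH_RISK_THRESHOLD,
        age_out_of_range=out_of_range,
    )


def classify_high_risk(risk: float, threshold: float = HIGH_RISK_THRESHOLD) -> str:
    """Dichotomize a PCE risk at the threshold (right-closed: >= is high)."""
    if not 0.0 <= risk <= 1.0:
        raise ValueError(f"risk must lie in [0, 1], got {risk!r}")
    return "high" if risk >= threshold else "low"


def score_risk_table(
    data: pd.DataFrame,
    coefs: PCECoefficientSet | None = None,
    threshold: float = HIGH_RISK_THRESHOLD,
) -> pd.DataFrame:
    """Append ``ascvd_risk``, ``high_risk`` and ``pce_age_ok`` columns.

    Expects columns ``age``, ``sex``, ``race`` (black/white/other — white
    and other map to the white-or-other equations), ``total_cholesterol``,
    ``hdl``, ``sbp``, ``on_htn_treatment``, ``diabetes``,
    ``current_smoker``.
    """
    if coefs is None:
        coefs = load_pce_coefficients()
    risks = np.empty(len(data), dtype=float)
    ok = np.empty(len(data), dtype=bool)
    for i, row in enumerate(data.itertuples(index=False)):
        profile = RiskProfile(
            age=float(row.age),
            sex=str(row.sex),
            race_group="black" if str(row.race) == "black" else "white_or_other",
            total_cholesterol=float(row.total_cholesterol),
            hdl=float(row.hdl),
            sbp=float(row.sbp),
            on_htn_treatment=bool(row.on_htn_treatment),
            diabetes=bool(row.diabetes),
            current_smoker=bool(row.current_smoker),
        )
        out = pce_risk(profile, coefs)
        risks[i] = out.risk
        ok[i] = not out.age_out_of_range
    res = data.copy()
    res["ascvd_risk"] = risks
    res["high_risk"] = (risks >= threshold).astype(int)
    res["pce_age_ok"] = ok
    return res
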