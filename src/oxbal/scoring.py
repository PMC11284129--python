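"""Sex-stratified tertile scoring of OBS components.

Every tertile-rule component is scored against sex-specific tertile
cutpoints fitted on the analytic sample: within each sex stratum the 1/3
and 2/3 empirical quantiles (inverted-CDF convention, i.e. order
statistics) split the distribution into three groups with right-closed
boundaries (value <= cutpoint falls in the lower group).  Antioxidant
components score 0/1/2 across ascending tertiles; pro-oxidants score
2/1/0.  Alcohol intake is scored by fixed thresholds instead: abstainers
(0 g/day) score 2, drinkers below the sex-specific heavy-drinking
threshold (15 g/day women, 30 g/day men) score 1, and heavy drinkers
(at or above the threshold) score 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .components import (
    ALCOHOL_RULE,
    ALCOHOL_THRESHOLD_G_PER_DAY,
    ANTIOXIDANT,
    DIETARY,
    PROOXIDANT,
    TERTILE_RULE,
    ComponentSpec,
    validate_components,
)

SEXES = ("male", "female")


class DegenerateComponentError(ValueError):
    """A component stratum has too few distinct values to form tertiles."""


class DegenerateQuartileError(ValueError):
    """A score vector has too few distinct values to form quartiles."""


class MissingComponentError(ValueError):
    """A participant row is missing one or more OBS component values."""


@dataclass
class ScoringTable:
    """Sex-stratified tertile cutpoints for every tertile-rule component.

    ``cutpoints[(component, sex)] = (t1, t2)`` with ``t1 <= t2``; the
    alcohol-rule component has no entry.  ``provenance`` records the
    sample the table was fitted on.
    """

    cutpoints: dict[tuple[str, str], tuple[float, float]]
    provenance: str = ""
    fitted_at: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def __post_init__(self) -> None:
        for key, (t1, t2) in self.cutpoints.items():
            if not t1 <= t2:
                raise ValueError(f"cutpoints out of order for {key}: {t1} > {t2}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"component": comp, "sex": sex, "t1": t1, "t2": t2}
            for (comp, sex), (t1, t2) in sorted(self.cutpoints.items())
        ]
        return pd.DataFrame(rows, columns=["component", "sex", "t1", "t2"])

    def to_csv(self, path: str | Path) -> None:
        """Serialize cutpoints to a delimited text file for audit/reuse."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "") -> "ScoringTable":
        df = pd.read_csv(path)
        cuts = {
            (str(r.component), str(r.sex)): (float(r.t1), float(r.t2))
            for r in df.itertuples()
        }
        return cls(cutpoints=cuts, provenance=provenance or str(path))


@dataclass(frozen=True)
class OBSResult:
    """Per-participant OBS decomposition."""

    total: int
    dietary: int
    lifestyle: int
    per_component: dict[str, int]


@dataclass(frozen=True)
class QuartileAssignment:
    """Quartile labels for a score vector plus the boundaries used."""

    labels: pd.Categorical
    boundaries: tuple[float, float, float]


def score_alcohol(intake_g_per_day: float, sex: str) -> int:
    """Score alcohol intake 0-2 by the sex-specific heavy-drinking rule.

    Abstainers (exactly 0 g/day) score 2; drinkers below the threshold
    (15 g/day for women, 30 g/day for men) score 1; intake at or above
    the threshold scores 0.
    """
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}; expected one of {SEXES}")
    intake = float(intake_g_per_day)
    if not np.isfinite(intake) or intake < 0:
        raise ValueError(f"alcohol intake must be a finite non-negative number, got {intake!r}")
    threshold = ALCOHOL_THRESHOLD_G_PER_DAY[sex]
    if intake == 0.0:
        return 2
    if intake < threshold:
        return 1
    return 0


def _tertile_cutpoints(values: np.ndarray, component: str, sex: str) -> tuple[float, float]:
    finite = values[np.isfinite(values)]
    if np.unique(finite).size < 3:
        raise DegenerateComponentError(
            f"component {component!r} has fewer than 3 distinct values in the {sex} stratum"
        )
    t1, t2 = np.quantile(finite, [1 / 3, 2 / 3], method="inverted_cdf")
    return float(t1), float(t2)


def fit_scoring_table(
    data: pd.DataFrame,
    components: Iterable[ComponentSpec],
    sex_col: str = "sex",
    provenance: str = "",
) -> ScoringTable:
    """Fit sex-stratified tertile cutpoints on an analytic sample.

    Cutpoints are the 1/3 and 2/3 empirical quantiles (inverted-CDF
    order-statistic convention) computed unweighted within each sex
    stratum, for every tertile-rule component.
    """
    comps = validate_components(components)
    sexes = data[sex_col].astype(str)
    bad = set(sexes.unique()) - set(SEXES)
    if bad:
        raise ValueError(f"unknown sex labels {sorted(bad)}; expected {SEXES}")
    cuts: dict[tuple[str, str], tuple[float, float]] = {}
    for comp in comps:
        if comp.rule != TERTILE_RULE:
            continue
        if comp.name not in data.columns:
            raise KeyError(f"component column {comp.name!r} not in data")
        for sex in SEXES:
            vals = data.loc[sexes == sex, comp.name].to_numpy(dtype=float)
            cuts[(comp.name, sex)] = _tertile_cutpoints(vals, comp.name, sex)
    return ScoringTable(cutpoints=cuts, provenance=provenance or f"n={len(data)}")


def score_component(value: float, cutpoints: tuple[float, float], polarity: str) -> int:
    """Score one tertile-rule component value 0-2 given fitted cutpoints.

    The tertile index g in {1,2,3} uses right-closed intervals
    (value <= t1 -> 1; t1 < value <= t2 -> 2; value > t2 -> 3); the
    score is g - 1 for antioxidants and 3 - g for pro-oxidants.
    """
    v = float(value)
    if not np.isfinite(v):
        raise MissingComponentError("component value is missing or non-finite")
    t1, t2 = cutpoints
    if v <= t1:
        g = 1
    elif v <= t2:
        g = 2
    else:
        g = 3
    if polarity == ANTIOXIDANT:
        return g - 1
    if polarity == PROOXIDANT:
        return 3 - g
    raise ValueError(f"unknown polarity {polarity!r}")


def compute_obs(
    row: Mapping[str, float],
    table: ScoringTable,
    components: Iterable[ComponentSpec],
    sex: str | None = None,
) -> OBSResult:
    """Compute total, dietary and lifestyle OBS for one participant row.

    ``row`` maps component names to values (and may carry a ``sex`` entry
    if ``sex`` is not given explicitly).  All 20 component values must be
    present and finite; missing data raises rather than imputes, matching
    the complete-case design of the analysis.
    """
    comps = validate_components(components)
    if sex is None:
        sex = str(row["sex"])
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    per: dict[str, int] = {}
    for comp in comps:
        if comp.name not in row:
            raise MissingComponentError(f"component {comp.name!r} missing from row")
        value = row[comp.name]
        if value is None or not np.isfinite(float(value)):
            raise MissingComponentError(f"component {comp.name!r} is missing for this row")
        if comp.rule == ALCOHOL_RULE:
            per[comp.name] = score_alcohol(float(value), sex)
        else:
            per[comp.name] = score_component(
                float(value), table.cutpoints[(comp.name, sex)], comp.polarity
            )
    dietary = sum(per[c.name] for c in comps if c.cls == DIETARY)
    lifestyle = sum(per[c.name] for c in comps if c.cls != DIETARY)
    return OBSResult(
        total=dietary + lifestyle, dietary=dietary, lifestyle=lifestyle, per_component=per
    )


def score_cohort(
    data: pd.DataFrame,
    components: Iterable[ComponentSpec],
    table: ScoringTable | None = None,
    sex_col: str = "sex",
) -> pd.DataFrame:
    """Vectorised OBS scoring of a participant table.

    Fits the scoring table on ``data`` itself when ``table`` is None.
    Returns a copy of ``data`` with ``obs_total``, ``obs_dietary`` and
    ``obs_lifestyle`` columns appended.  Rows with any missing component
    raise; exclusion happens upstream.
    """
    comps = validate_components(components)
    if table is None:
        table = fit_scoring_table(data, comps, sex_col=sex_col)
    sexes = data[sex_col].astype(str).to_numpy()
    n = len(data)
    dietary = np.zeros(n, dtype=int)
    lifestyle = np.zeros(n, dtype=int)
    for comp in comps:
        vals = data[comp.name].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = int(np.sum(~np.isfinite(vals)))
            raise MissingComponentError(
                f"component {comp.name!r} has {bad} missing values; exclude rows first"
            )
        scores = np.empty(n, dtype=int)
        if comp.rule == ALCOHOL_RULE:
            for sex in SEXES:
                m = sexes == sex
                thr = ALCOHOL_THRESHOLD_G_PER_DAY[sex]
                if np.any(vals[m] < 0):
                    raise ValueError(f"negative alcohol intake in {sex} stratum")
                scores[m] = np.where(vals[m] == 0.0, 2, np.where(vals[m] < thr, 1, 0))
        else:
            for sex in SEXES:
                m = sexes == sex
                t1, t2 = table.cutpoints[(comp.name, sex)]
                g = 1 + (vals[m] > t1).astype(int) + (vals[m] > t2).astype(int)
                scores[m] = (g - 1) if comp.polarity == ANTIOXIDANT else (3 - g)
        if comp.cls == DIETARY:
            dietary += scores
        else:
            lifestyle += scores
    out = data.copy()
    out["obs_dietary"] = dietary
    out["obs_lifestyle"] = lifestyle
    out["obs_total"] = dietary + lifestyle
    return out


def assign_quartiles(scores: np.ndarray | pd.Series) -> QuartileAssignment:
    """Assign Q1-Q4 labels at the 25/50/75 empirical percentiles.

    Boundaries use the same inverted-CDF order-statistic convention as
    tertile fitting; ties at a boundary fall in the lower quartile
    (right-closed intervals).
    """
    arr = np.asarray(scores, dtype=float)
    if np.unique(arr[np.isfinite(arr)]).size < 4:
        raise DegenerateQuartileError("need at least 4 distinct score values for quartiles")
    q1, q2, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="inverted_cdf")
    idx = (arr > q1).astype(int) + (arr > q2).astype(int) + (arr > q3).astype(int)
    labels = pd.Categorical.from_codes(
        idx, categories=["Q1", "Q2", "Q3", "Q4"], ordered=True
    )
    return QuartileAssignment(labels=labels, boundaries=(float(q1), float(q2), float(q3)))
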