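"""End-to-end orchestration: exclusions, scoring, risk, models, reporting.

Mirrors a two-part epidemiological design: a cross-sectional study of
the association between the oxidative balance score and high predicted
10-year ASCVD risk (survey-weighted logistic models), and a cohort study
of all-cause and CVD mortality among the high-risk subset (survey-
weighted Cox models), each with continuous, quartile and restricted-
cubic-spline exposure forms under three nested adjustment sets, plus
subgroup/interaction analyses, weighted Kaplan-Meier curves, and a
two-segment turning-point hazard model for the lifestyle sub-score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .components import ComponentSpec, default_components, validate_components
from .pce import PCE_AGE_RANGE
from .scoring import assign_quartiles, score_cohort
from .splines import SplineSpec, rcs_basis
from .survey import (
    MODEL2_COVARIATES,
    MODEL3_COVARIATES,
    FitResult,
    SurveyDesign,
    ZeroEventsError,
    build_design_matrix,
    fit_weighted_cox,
    fit_weighted_logistic,
    interaction_test,
    test_nonlinearity,
    trend_test,
)
from .survival import km_estimate, logrank_test, segmented_cox

logger = logging.getLogger(__name__)

PCE_INPUT_COLUMNS = [
    "age",
    "sex",
    "race",
    "total_cholesterol",
    "hdl",
    "sbp",
    "on_htn_treatment",
    "diabetes",
    "current_smoker",
]

EXPOSURES = ("obs_total", "obs_dietary", "obs_lifestyle")
FORMS = ("continuous", "quartile", "spline")

SUBGROUP_AGE_CUT = 60.0
SUBGROUP_GFR_CUT = 60.0


class ExclusionConfigError(ValueError):
    """An exclusion rule references a column absent from the table."""


@dataclass
class ExclusionLedger:
    """Ordered per-rule removal counts; conserves the row total."""

    initial: int
    steps: list[dict] = field(default_factory=list)

    def record(self, rule: str, removed: int, remaining: int) -> None:
        self.steps.append({"rule": rule, "removed": int(removed), "remaining": int(remaining)})

    @property
    def final_remaining(self) -> int:
        return self.steps[-1]["remaining"] if self.steps else self.initial

    @property
    def total_removed(self) -> int:
        return sum(s["removed"] for s in self.steps)

    def counts(self) -> dict[str, int]:
        return {s["rule"]: s["removed"] for s in self.steps}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _missing_any(columns: Sequence[str]) -> Callable[[pd.DataFrame], np.ndarray]:
    def rule(df: pd.DataFrame) -> np.ndarray:
        missing = set(columns) - set(df.columns)
        if missing:
            raise ExclusionConfigError(f"exclusion rule references unknown columns {sorted(missing)}")
        return df[list(columns)].isna().any(axis=1).to_numpy()

    return rule


def _pce_invalid(df: pd.DataFrame) -> np.ndarray:
    missing = set(PCE_INPUT_COLUMNS) - set(df.columns)
    if missing:
        raise ExclusionConfigError(f"exclusion rule references unknown columns {sorted(missing)}")
    bad = df[PCE_INPUT_COLUMNS].isna().any(axis=1).to_numpy()
    age = pd.to_numeric(df["age"], errors="coerce")
    out_of_range = ~age.between(*PCE_AGE_RANGE)
    return bad | out_of_range.to_numpy()


def default_exclusion_rules(
    components: Sequence[ComponentSpec] | None = None,
    covariates: Sequence[str] = ("education", "wbc", "alt", "lymphocyte_pct", "creatinine"),
) -> list[tuple[str, Callable[[pd.DataFrame], np.ndarray]]]:
    """The default ordered exclusion cascade.

    Order: missing OBS components, missing/out-of-range PCE inputs,
    prevalent ASCVD, missing named covariates, missing mortality
    linkage.  Each row is attributed to the first rule it matches.
    """
    comps = validate_components(components or default_components())
    comp_cols = [c.name for c in comps]

    def prevalent(df: pd.DataFrame) -> np.ndarray:
        if "prevalent_ascvd" not in df.columns:
            raise ExclusionConfigError("exclusion rule references unknown columns ['prevalent_ascvd']")
        return df["prevalent_ascvd"].fillna(0).astype(float).to_numpy() > 0

    return [
        ("missing_obs_component", _missing_any(comp_cols)),
        ("missing_or_invalid_pce_input", _pce_invalid),
        ("prevalent_ascvd", prevalent),
        ("missing_covariate", _missing_any(list(covariates))),
        ("missing_mortality_linkage", _missing_any(["follow_months", "death"])),
    ]


def apply_exclusions(
    raw: pd.DataFrame,
    rules: Sequence[tuple[str, Callable[[pd.DataFrame], np.ndarray]]] | None = None,
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Apply the ordered exclusion cascade with first-match attribution."""
    if rules is None:
        rules = default_exclusion_rules()
    ledger = ExclusionLedger(initial=len(raw))
    keep = np.ones(len(raw), dtype=bool)
    for name, rule in rules:
        flagged = np.asarray(rule(raw), dtype=bool)
        newly = flagged & keep
        keep &= ~flagged
        ledger.record(name, int(newly.sum()), int(keep.sum()))
    return raw.loc[keep].reset_index(drop=True), ledger


def _exposure_blocks(
    data: pd.DataFrame, exposure: str, form: str
) -> tuple[pd.DataFrame, tuple[str, ...], tuple[str, ...], dict]:
    """Exposure columns for one (exposure, form) cell plus metadata."""
    x = data[exposure].to_numpy(dtype=float)
    meta: dict = {}
    if form == "continuous":
        block = pd.DataFrame({exposure: x})
        return block, (exposure,), (), meta
    if form == "quartile":
        qa = assign_quartiles(x)
        dummies = pd.get_dummies(
            pd.Series(qa.labels, name="q"), prefix=exposure, drop_first=True, dtype=float
        )
        # tied boundaries on a discrete score can empty a quartile; its
        # all-zero indicator would make the model matrix singular
        dummies = dummies.loc[:, dummies.sum(axis=0) > 0]
        meta["quartile_boundaries"] = qa.boundaries
        meta["quartile_labels"] = qa.labels
        return dummies.reset_index(drop=True), tuple(dummies.columns), (), meta
    if form == "spline":
        spec = SplineSpec.from_data(x)
        basis = rcs_basis(x, spec, prefix=exposure)
        nonlinear = tuple(c for c in basis.columns if "_nl" in c)
        meta["knots"] = spec.knots
        return basis.reset_index(drop=True), tuple(basis.columns), nonlinear, meta
    raise ValueError(f"unknown form {form!r}")


def _covariate_matrix(data: pd.DataFrame, model_id: int, drop: Sequence[str] = ()) -> pd.DataFrame | None:
    covs = {1: [], 2: MODEL2_COVARIATES, 3: MODEL3_COVARIATES}[model_id]
    mapped = []
    for c in covs:
        col = "race" if c == "ethnicity" else c
        if col in drop:
            continue
        mapped.append(col)
    if not mapped:
        return None
    return build_design_matrix(data, mapped, intercept=False).reset_index(drop=True)


def _fit_cell(
    data: pd.DataFrame,
    design: SurveyDesign,
    outcome_col: str,
    exposure: str,
    form: str,
    model_id: int,
    kind: str,
    time_col: str | None = None,
) -> dict:
    """Fit one (exposure, form, model) cell and package the results."""
    block, exp_terms, nl_terms, meta = _exposure_blocks(data, exposure, form)
    covs = _covariate_matrix(data, model_id)
    X = block.reset_index(drop=True)
    if covs is not None:
        X = pd.concat([X, covs], axis=1)
    if kind == "logistic":
        X.insert(0, "intercept", 1.0)
        fit = fit_weighted_logistic(
            data[outcome_col].to_numpy(dtype=float),
            X,
            design,
            exposure_terms=exp_terms,
            nonlinear_terms=nl_terms,
        )
    else:
        fit = fit_weighted_cox(
            data[time_col].to_numpy(dtype=float),
            data[outcome_col].to_numpy(dtype=float),
            X,
            design,
            exposure_terms=exp_terms,
            nonlinear_terms=nl_terms,
        )
    cell: dict = {
        "exposure": exposure,
        "form": form,
        "model": model_id,
        "outcome": outcome_col,
        "kind": kind,
        "n": fit.n,
        "summary": fit.summary_frame().loc[list(exp_terms)],
        "fit": fit,
        **meta,
    }
    if form == "quartile":
        cell["p_trend"] = trend_test(
            data[outcome_col].to_numpy(dtype=float),
            meta["quartile_labels"],
            covs,
            design,
            model=kind,
            time=None if time_col is None else data[time_col].to_numpy(dtype=float),
        )
    if form == "spline":
        cell["p_nonlinearity"] = test_nonlinearity(fit)
    return cell


def run_cross_sectional(
    data: pd.DataFrame,
    design: SurveyDesign | None = None,
    outcome_col: str = "high_risk",
    exposures: Sequence[str] = EXPOSURES,
    forms: Sequence[str] = FORMS,
    models: Sequence[int] = (1, 2, 3),
) -> dict:
    """Survey-weighted logistic models of high ASCVD risk on the OBS.

    Every exposure x form x adjustment-model cell is fitted; quartile
    cells carry a p-trend, spline cells a nonlinearity p.  Fit errors
    are annotated with their cell and re-raised.
    """
    if design is None:
        design = SurveyDesign.from_frame(data)
    cells = []
    for exposure in exposures:
        for form in forms:
            for model_id in models:
                try:
                    cells.append(
                        _fit_cell(data, design, outcome_col, exposure, form, model_id, "logistic")
                    )
                except Exception as exc:
                    raise type(exc)(
                        f"cross-sectional fit failed for ({exposure}, {form}, model {model_id}): {exc}"
                    ) from exc
    return {"section": "cross_sectional", "outcome": outcome_col, "cells": cells}


def run_cohort(
    data: pd.DataFrame,
    design: SurveyDesign | None = None,
    risk_col: str = "high_risk",
    exposures: Sequence[str] = EXPOSURES,
    forms: Sequence[str] = FORMS,
    models: Sequence[int] = (1, 2, 3),
    restrict_high_risk: bool = True,
) -> dict:
    """Mortality analyses among the high-risk subset.

    Weighted Cox models for all-cause and CVD death across all cells,
    weighted Kaplan-Meier curves by total-OBS quartile with a log-rank
    test, and the two-segment turning-point model for the lifestyle
    sub-score against all-cause mortality.
    """
    if restrict_high_risk:
        mask = data[risk_col].to_numpy(dtype=float) > 0
        data = data.loc[mask].reset_index(drop=True)
    if design is None:
        design = SurveyDesign.from_frame(data)
    elif restrict_high_risk and len(design) != len(data):
        raise ValueError("pass the design built from the restricted table, or let run_cohort build it")
    cells = []
    for outcome_col in ("death", "cvd_death"):
        for exposure in exposures:
            for form in forms:
                for model_id in models:
                    try:
                        cells.append(
                            _fit_cell(
                                data,
                                design,
                                outcome_col,
                                exposure,
                                form,
                                model_id,
                                "cox",
                                time_col="follow_months",
                            )
                        )
                    except ZeroEventsError as exc:
                        raise ZeroEventsError(
                            f"cohort fit ({exposure}, {form}, model {model_id}, {outcome_col}): {exc}"
                        ) from exc
                    except Exception as exc:
                        raise type(exc)(
                            f"cohort fit failed for ({exposure}, {form}, model {model_id}, "
                            f"{outcome_col}): {exc}"
                        ) from exc
    qa = assign_quartiles(data["obs_total"].to_numpy(dtype=float))
    groups = np.asarray(qa.labels)
    time = data["follow_months"].to_numpy(dtype=float)
    death = data["death"].to_numpy(dtype=float)
    w = design.weight
    km = km_estimate(time, death, weights=w, groups=groups)
    lr_stat, lr_p, lr_df = logrank_test(time, death, groups, weights=w)
    seg = segmented_cox(
        time,
        death,
        data["obs_lifestyle"].to_numpy(dtype=float),
        design,
    )
    return {
        "section": "cohort",
        "n_high_risk": len(data),
        "cells": cells,
        "km": {"curves": km, "quartile_boundaries": qa.boundaries,
               "logrank": {"stat": lr_stat, "p": lr_p, "df": lr_df}},
        "segmented": seg,
    }


SUBGROUP_DEFS: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "age_ge_60": lambda d: (d["age"] >= SUBGROUP_AGE_CUT).map({True: "ge60", False: "lt60"}),
    "sex": lambda d: d["sex"].astype(str),
    "gfr_lt_60": lambda d: (d["gfr"] < SUBGROUP_GFR_CUT).map({True: "lt60", False: "ge60"}),
    "hyperlipidemia": lambda d: d["hyperlipidemia"].map({1: "yes", 0: "no"}).astype(str),
    "hypertension": lambda d: d["hypertension"].map({1: "yes", 0: "no"}).astype(str),
}


def run_subgroups(
    data: pd.DataFrame,
    design: SurveyDesign | None = None,
    outcome_col: str = "high_risk",
    exposure: str = "obs_total",
    modifiers: Sequence[str] = tuple(SUBGROUP_DEFS),
) -> dict:
    """Per-subgroup model-3 fits plus an interaction p per modifier.

    Within each level of each modifier the fully adjusted (model 3)
    continuous-exposure logistic model is refitted; the modifier itself
    (and sex, when it is the modifier) is dropped from the adjustment
    set.  Subgroups that cannot be fitted are reported as not estimable
    rather than dropped.
    """
    if design is None:
        design = SurveyDesign.from_frame(data)
    # modifiers that are themselves adjustment covariates leave the
    # covariate set while they act as the stratifying variable
    modifier_drop = {"sex": ("sex",), "hyperlipidemia": ("hyperlipidemia",),
                     "hypertension": ("hypertension",)}
    rows = []
    for modifier in modifiers:
        levels = SUBGROUP_DEFS[modifier](data)
        if levels.nunique() < 2:
            raise ValueError(f"modifier {modifier!r} is constant; subgroup analysis undefined")
        drop = modifier_drop.get(modifier, ())
        covs_full = _covariate_matrix(data, 3, drop=drop)
        try:
            p_int = interaction_test(
                data[outcome_col].to_numpy(dtype=float),
                data[exposure].to_numpy(dtype=float),
                levels,
                covs_full,
                design,
                model="logistic",
            )
        except Exception as exc:
            logger.warning("interaction test failed for %s: %s", modifier, exc)
            p_int = None
        for level in sorted(levels.unique()):
            mask = (levels == level).to_numpy()
            sub = data.loc[mask].reset_index(drop=True)
            entry = {
                "modifier": modifier,
                "level": str(level),
                "n": int(mask.sum()),
                "p_interaction": p_int,
            }
            if mask.sum() == 0:
                entry.update(estimable=False, reason="empty subgroup")
                rows.append(entry)
                continue
            try:
                covs = _covariate_matrix(sub, 3, drop=drop)
                X = pd.DataFrame({"intercept": np.ones(len(sub)), exposure: sub[exposure].astype(float)})
                if covs is not None:
                    X = pd.concat([X, covs], axis=1)
                fit = fit_weighted_logistic(
                    sub[outcome_col].to_numpy(dtype=float), X, design.subset(mask)
                )
                ci = fit.conf_int().loc[exposure]
                entry.update(
                    estimable=True,
                    odds_ratio=float(fit.effects[exposure]),
                    ci_low=float(ci["low"]),
                    ci_high=float(ci["high"]),
                    p=float(fit.pvalues[exposure]),
                )
            except Exception as exc:
                entry.update(estimable=False, reason=str(exc))
            rows.append(entry)
    return {"section": "subgroups", "exposure": exposure, "rows": rows}


def _cell_to_json(cell: dict) -> dict:
    out = {
        k: cell[k]
        for k in ("exposure", "form", "model", "outcome", "kind", "n")
    }
    summ = cell["summary"].reset_index(names="term")
    out["terms"] = summ.to_dict(orient="records")
    for k in ("p_trend", "p_nonlinearity"):
        if k in cell:
            out[k] = float(cell[k])
    if "quartile_boundaries" in cell:
        out["quartile_boundaries"] = list(cell["quartile_boundaries"])
    if "knots" in cell:
        out["knots"] = list(cell["knots"])
    return out


def _format_effect_table(cells: list[dict], exposure: str, kind: str, outcome: str) -> str:
    """A text table in the classic three-model layout: quartiles then continuous."""
    label = "OR" if kind == "logistic" else "HR"
    lines = [f"{exposure} vs {outcome}  ({label}, 95% CI)"]
    by_model: dict[int, dict] = {}
    for c in cells:
        if c["exposure"] == exposure and c["outcome"] == outcome and c["kind"] == kind:
            by_model.setdefault(c["model"], {})[c["form"]] = c
    for model_id in sorted(by_model):
        forms = by_model[model_id]
        lines.append(f"  Model {model_id}")
        if "quartile" in forms:
            cell = forms["quartile"]
            lines.append("    Q1  1.00 (reference)")
            for term, row in cell["summary"].iterrows():
                lines.append(
                    f"    {term.split('_')[-1]}  {row['effect']:.2f} "
                    f"({row['ci_low']:.2f}, {row['ci_high']:.2f})  p={row['p']:.3g}"
                )
            lines.append(f"    p-trend = {cell['p_trend']:.3g}")
        if "continuous" in forms:
            cell = forms["continuous"]
            row = cell["summary"].iloc[0]
            lines.append(
                f"    per unit  {row['effect']:.2f} "
                f"({row['ci_low']:.2f}, {row['ci_high']:.2f})  p={row['p']:.3g}"
            )
        if "spline" in forms:
            lines.append(f"    p-nonlinearity = {forms['spline']['p_nonlinearity']:.3g}")
    return "\n".join(lines)


def report(
    sections: dict,
    outdir: str | Path,
    metadata: dict | None = None,
    make_plots: bool = True,
) -> dict[str, Path]:
    """Write machine-readable results, formatted tables and figures.

    ``sections`` maps section names to the dicts produced by the
    ``run_*`` operations.  Returns the written file paths.
    """
    required = {"cross_sectional", "cohort"} & set(sections)
    for name in required:
        if "cells" not in sections[name]:
            raise ValueError(f"report section {name!r} is missing its fitted cells")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    payload: dict = {"metadata": metadata or {}}
    for name, section in sections.items():
        entry: dict = {}
        if "cells" in section:
            entry["cells"] = [_cell_to_json(c) for c in section["cells"]]
        if "rows" in section:
            entry["rows"] = section["rows"]
        if "km" in section:
            entry["logrank"] = section["km"]["logrank"]
            entry["km_quartile_boundaries"] = list(section["km"]["quartile_boundaries"])
        if "segmented" in section:
            seg = section["segmented"]
            entry["segmented"] = {
                "breakpoint": seg.breakpoint,
                "left_hr": seg.left_hr,
                "right_hr": seg.right_hr,
                "left_ci": [float(np.exp(v)) for v in seg.left_ci],
                "right_ci": [float(np.exp(v)) for v in seg.right_ci],
                "left_p": seg.left_p,
                "right_p": seg.right_p,
                "identifiable": seg.identifiable,
            }
        if "n_high_risk" in section:
            entry["n_high_risk"] = section["n_high_risk"]
        payload[name] = entry
    results_path = outdir / "results.json"
    results_path.write_text(json.dumps(payload, indent=2, default=float))
    written["results"] = results_path

    tables = []
    for name in ("cross_sectional", "cohort"):
        if name not in sections:
            continue
        section = sections[name]
        kind = "logistic" if name == "cross_sectional" else "cox"
        outcomes = sorted({c["outcome"] for c in section["cells"]})
        for outcome in outcomes:
            for exposure in sorted({c["exposure"] for c in section["cells"]}):
                tables.append(_format_effect_table(section["cells"], exposure, kind, outcome))
    tables_path = outdir / "tables.txt"
    tables_path.write_text("\n\n".join(tables) + "\n")
    written["tables"] = tables_path

    if make_plots:
        written.update(_write_plots(sections, outdir))
    return written


def _write_plots(sections: dict, outdir: Path) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: dict[str, Path] = {}
    if "cross_sectional" in sections:
        spline_cells = [
            c for c in sections["cross_sectional"]["cells"] if c["form"] == "spline"
        ]
        if spline_cells:
            fig, axes = plt.subplots(1, len(spline_cells[:3]), figsize=(4 * min(3, len(spline_cells)), 3.2))
            axes = np.atleast_1d(axes)
            for ax, cell in zip(axes, spline_cells[:3]):
                _plot_spline_curve(ax, cell)
            fig.tight_layout()
            p = outdir / "rcs_curves.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written["rcs_curves"] = p
    if "cohort" in sections and "km" in sections["cohort"]:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for label, curve in sections["cohort"]["km"]["curves"].items():
            ts = np.concatenate([[0.0], np.repeat(curve.times, 2)])
            ss = np.concatenate([[1.0, 1.0], np.repeat(curve.survival, 2)[:-1]])
            ax.plot(ts, ss, drawstyle="default", label=label)
        ax.set_xlabel("months")
        ax.set_ylabel("survival")
        ax.legend(title="OBS quartile", fontsize=8)
        fig.tight_layout()
        p = outdir / "km_curves.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written["km_curves"] = p
    return written


def _plot_spline_curve(ax, cell: dict) -> None:
    fit: FitResult = cell["fit"]
    knots = np.asarray(cell["knots"], dtype=float)
    grid = np.linspace(knots[0], knots[-1], 100)
    spec = SplineSpec(knots=tuple(knots))
    basis = rcs_basis(grid, spec, prefix=cell["exposure"])
    ref = rcs_basis(np.array([np.median(grid)]), spec, prefix=cell["exposure"])
    terms = list(cell["fit"].exposure_terms)
    D = basis[terms].to_numpy() - ref[terms].to_numpy()
    b = fit.params[terms].to_numpy()
    V = fit.cov.loc[terms, terms].to_numpy()
    lp = D @ b
    se = np.sqrt(np.einsum("ij,jk,ik->i", D, V, D))
    ax.plot(grid, np.exp(lp), color="C0")
    ax.fill_between(grid, np.exp(lp - 1.96 * se), np.exp(lp + 1.96 * se), alpha=0.2)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(cell["exposure"])
    ax.set_ylabel("OR" if cell["kind"] == "logistic" else "HR")


def prepare_analytic_table(
    raw: pd.DataFrame,
    components: Sequence[ComponentSpec] | None = None,
    rules=None,
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Exclusions, then OBS scoring on the analytic sample.

    Tertile cutpoints are fitted on the post-exclusion sample, matching
    the convention that scoring quantiles describe the analytic cohort.
    """
    comps = validate_components(components or default_components())
    analytic, ledger = apply_exclusions(raw, rules)
    analytic = score_cohort(analytic, comps)
    return analytic, ledger
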