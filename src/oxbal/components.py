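"""Oxidative balance score component definitions.

The oxidative balance score (OBS) aggregates 20 diet and lifestyle
exposures, each scored 0-2, into a single integer summarising whether a
participant's exposure profile is antioxidant- or pro-oxidant-dominant.
Sixteen components are dietary nutrient intakes and four are lifestyle
variables; five components are pro-oxidants (scored descending across
tertiles) and fifteen are antioxidants (scored ascending).

The default component table below is a config-overridable choice: the 16
nutrients are fiber, total carotene, riboflavin, niacin, vitamin B6, total
folate, vitamin B12, vitamin C, vitamin E, calcium, magnesium, zinc,
copper, selenium (antioxidants) plus total fat and iron (pro-oxidants);
the 4 lifestyle components are physical activity (antioxidant) plus BMI,
serum cotinine, and alcohol intake (pro-oxidants).  Alcohol is scored by
a dedicated threshold rule rather than by tertiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import yaml

DIETARY = "dietary"
LIFESTYLE = "lifestyle"
ANTIOXIDANT = "antioxidant"
PROOXIDANT = "prooxidant"
TERTILE_RULE = "tertile"
ALCOHOL_RULE = "alcohol"


@dataclass(frozen=True)
class ComponentSpec:
    """One OBS component: its name, class, polarity and scoring rule."""

    name: str
    cls: str
    polarity: str
    rule: str = TERTILE_RULE

    def __post_init__(self) -> None:
        if self.cls not in (DIETARY, LIFESTYLE):
            raise ValueError(f"unknown component class {self.cls!r} for {self.name!r}")
        if self.polarity not in (ANTIOXIDANT, PROOXIDANT):
            raise ValueError(f"unknown polarity {self.polarity!r} for {self.name!r}")
        if self.rule not in (TERTILE_RULE, ALCOHOL_RULE):
            raise ValueError(f"unknown scoring rule {self.rule!r} for {self.name!r}")


_DEFAULT_TABLE: tuple[tuple[str, str, str, str], ...] = (
    ("dietary_fiber", DIETARY, ANTIOXIDANT, TERTILE_RULE),
    ("carotene", DIETARY, ANTIOXIDANT, TERTILE_RULE),
    ("riboflavin", DIETARY, ANTIOXIDANT, TERTILE_RULE),
    ("niacin", DIETARY, ANTIOXIDANT, TERTILE_RULE),
    ("vitamin_b6", DIETARY, ANTIOXIDANT, TERTILE_RULE),
    ("total_folate", DIETARY, ANTIOXIDANT, TERTILE_RULE),
    ("vitamin_b12", DIETARY, ANTIOXIDANT, TERTILE_RULE),
    ("vitamin_c", DIETARY, ANTIOXIDANT, TERTILE_RULE),
    ("vitamin_e", DIETARY, ANTIOXIDANT, TERTILE_RULE),
    ("calcium", DIETARY, ANTIOXIDANT, TERTILE_RULE),
    ("magnesium", DIETARY, ANTIOXIDANT, TERTILE_RULE),
    ("zinc", DIETARY, ANTIOXIDANT, TERTILE_RULE),
    ("copper", DIETARY, ANTIOXIDANT, TERTILE_RULE),
    ("selenium", DIETARY, ANTIOXIDANT, TERTILE_RULE),
    ("total_fat", DIETARY, PROOXIDANT, TERTILE_RULE),
    ("iron", DIETARY, PROOXIDANT, TERTILE_RULE),
    ("physical_activity", LIFESTYLE, ANTIOXIDANT, TERTILE_RULE),
    ("bmi", LIFESTYLE, PROOXIDANT, TERTILE_RULE),
    ("cotinine", LIFESTYLE, PROOXIDANT, TERTILE_RULE),
    ("alcohol", LIFESTYLE, PROOXIDANT, ALCOHOL_RULE),
)

#: Maximum attainable sub-scores under the default 16/4 component split.
MAX_DIETARY_SCORE = 32
MAX_LIFESTYLE_SCORE = 8
MAX_TOTAL_SCORE = 40

#: Heavy-drinking thresholds in grams of ethanol per day.
ALCOHOL_THRESHOLD_G_PER_DAY = {"female": 15.0, "male": 30.0}


def default_components() -> list[ComponentSpec]:
    """Return the default 20-component table."""
    return [ComponentSpec(*row) for row in _DEFAULT_TABLE]


def validate_components(components: Iterable[ComponentSpec]) -> list[ComponentSpec]:
    """Validate a component table against the OBS structural constraints.

    The table must contain 16 dietary and 4 lifestyle components, of which
    exactly 5 are pro-oxidants, and exactly one component (a lifestyle
    pro-oxidant) uses the alcohol threshold rule.
    """
    comps = list(components)
    names = [c.name for c in comps]
    if len(set(names)) != len(names):
        raise ValueError("duplicate component names in table")
    n_diet = sum(c.cls == DIETARY for c in comps)
    n_life = sum(c.cls == LIFESTYLE for c in comps)
    if (n_diet, n_life) != (16, 4):
        raise ValueError(f"expected 16 dietary + 4 lifestyle components, got {n_diet}+{n_life}")
    n_pro = sum(c.polarity == PROOXIDANT for c in comps)
    if n_pro != 5:
        raise ValueError(f"expected 5 pro-oxidant components, got {n_pro}")
    alcohol = [c for c in comps if c.rule == ALCOHOL_RULE]
    if len(alcohol) != 1:
        raise ValueError(f"expected exactly one alcohol-rule component, got {len(alcohol)}")
    if alcohol[0].cls != LIFESTYLE or alcohol[0].polarity != PROOXIDANT:
        raise ValueError("the alcohol-rule component must be a lifestyle pro-oxidant")
    return comps


def load_components(path: str | Path) -> list[ComponentSpec]:
    """Load a component table from a YAML config file.

    The file holds a list of mappings with keys ``name``, ``cls``,
    ``polarity`` and optional ``rule`` (default ``tertile``).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"component config {path} must be a list of mappings")
    comps = [
        ComponentSpec(
            name=entry["name"],
            cls=entry["cls"],
            polarity=entry["polarity"],
            rule=entry.get("rule", TERTILE_RULE),
        )
        for entry in raw
    ]
    return validate_components(comps)


def dump_components(components: Iterable[ComponentSpec], path: str | Path) -> None:
    """Write a component table to a YAML config file."""
    rows = [
        {"name": c.name, "cls": c.cls, "polarity": c.polarity, "rule": c.rule}
        for c in components
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(rows, fh, sort_keys=False)
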