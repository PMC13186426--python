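"""Catalog of neighbourhood SDoH indicators and their dichotomization rules.

Each indicator is an area-level ACS estimate, carries the ACS table it comes
from, one of four thematic domains, and a *direction* flag saying how
median-dichotomization maps it onto a disadvantage indicator:

* ``standard``       -- strictly above the state median codes to 1;
* ``reversed``       -- at/above the median codes to 0 (median household
                        income: disadvantage is *low* income);
* ``zero_threshold`` -- any positive value codes to 1 (incomplete plumbing,
                        whose state median is 0).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

DOMAINS = (
    "housing conditions and resources",
    "economic security",
    "educational attainment",
    "social and community context",
)
DIRECTIONS = ("standard", "reversed", "zero_threshold")


@dataclass(frozen=True)
class Variable:
    name: str
    acs_table: str
    domain: str
    direction: str = "standard"

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")


class VariableCatalog:
    """Ordered collection of :class:`Variable` definitions."""

    def __init__(self, variables: list[Variable]):
        names = [v.name for v in variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in catalog")
        self.variables = list(variables)

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self):
        return iter(self.variables)

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({"variables": [asdict(v) for v in self.variables]}, sort_keys=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VariableCatalog":
        data = yaml.safe_load(Path(path).read_text())
        return cls([Variable(**v) for v in data["variables"]])

    def to_json(self) -> str:
        return json.dumps({"variables": [asdict(v) for v in self.variables]}, indent=2)


def default_catalog() -> VariableCatalog:
    """The 14-indicator Massachusetts catalog (ACS 2015-2019 5-year tables)."""
    H, E, ED, S = DOMAINS
    return VariableCatalog(
        [
            Variable("renter_occupied", "DP04", H),
            Variable("no_vehicle", "DP04", H),
            Variable("crowding", "DP04", H),
            Variable("no_plumbing", "DP04", H, direction="zero_threshold"),
            Variable("median_income", "B19013", E, direction="reversed"),
            Variable("female_head_household", "DP02", E),
            Variable("snap_benefits", "DP03", E),
            Variable("unemployment", "DP03", E),
            Variable("working_class", "C24010", E),
            Variable("no_high_school", "DP02", ED),
            Variable("limited_english", "DP02", S),
            Variable("hispanic_latino", "DP05", S),
            Variable("nh_black", "DP05", S),
            Variable("nh_asian", "DP05", S),
        ]
    )
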