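"""Baseline-rate tables with small-count suppression and provenance.

Rates are incidences or deaths per 100,000 persons per year, resolved by
region (county, state, or national), cause, age group ("all" for crude
rates, "age_standardized" for rates adjusted to a reference age
structure), and racial-ethnic subgroup. Public health agencies suppress
small counts (e.g. counties with fewer than 10 events), so entries carry
a suppression flag and, once resolved, a provenance record saying which
level of the county -> state -> national cascade supplied the rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

COLUMNS = [
    "level",        # county | state | national
    "region_id",    # county id, state id, or "US"
    "state_id",     # owning state (equals region_id for state rows, "US" for national)
    "cause",
    "age_group",    # "all" or "age_standardized"
    "subgroup",
    "rate",         # per 100,000 per year; NaN while suppressed
    "suppressed",
    "provenance",   # county | state | national | gap-filled:<source>
]


@dataclass
class RateTable:
    """Thin wrapper over a tidy rates DataFrame (see module docstring)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"rate table is missing columns {missing}")
        ok = self.table["suppressed"] | (self.table["rate"] >= 0)
        if not ok.all():
            raise ValueError("unsuppressed rates must be non-negative")
        if (self.table["suppressed"] & self.table["rate"].notna()).any():
            raise ValueError("suppressed entries must not carry a rate")

    def select(self, **criteria) -> pd.DataFrame:
        df = self.table
        for col, val in criteria.items():
            df = df[df[col] == val]
        return df

    @property
    def causes(self) -> list[str]:
        return sorted(self.table["cause"].unique())

    @property
    def subgroups(self) -> list[str]:
        return sorted(self.table["subgroup"].unique())

    def n_suppressed(self) -> int:
        return int(self.table["suppressed"].sum())

    def has_suppressed(self) -> bool:
        return bool(self.table["suppressed"].any())

    def copy(self) -> "RateTable":
        return RateTable(self.table.copy())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RateTable":
        df = pd.read_csv(path, float_precision="round_trip")
        df["suppressed"] = df["suppressed"].astype(bool)
        return cls(df)
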