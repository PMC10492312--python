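"""Health-risk classification and the trusted/untrusted cohort partition.

The method's core assumption is that participants at low health risk —
classified from body fat percentage, age and sex against a norms table —
report their food consumption accurately, so their responses can train
the predictive model, while everyone else's responses are candidates for
adjustment. Risk labels come from an ordered set
``excellent < good < normal < overfat < obese``; the trusted ("healthy")
subset is ``{excellent, good, normal}``.

The bundled norms table (``data/body_fat_norms_placeholder.csv``) is a
synthetic placeholder constructed to follow the shape of published
ACE-style body-fat norm brackets by age and sex; it is NOT a study
instrument and should be replaced by the user's own cutoffs — all logic
is table-driven, so a different CSV drops in without code changes.
Body-fat intervals are half-open ``[low, high)`` with the topmost
interval closed at 100; age brackets are closed integer-year ranges
(fractional ages are floored).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RISK_ORDER",
    "TRUSTED_RISK_LABELS",
    "NormsTable",
    "NormsCoverageError",
    "default_norms",
    "classify_health_risk",
    "split_cohort",
]

RISK_ORDER = ("excellent", "good", "normal", "overfat", "obese")
TRUSTED_RISK_LABELS = frozenset({"excellent", "good", "normal"})

_REQUIRED_COLUMNS = ["sex", "age_min", "age_max", "risk_label", "bf_min", "bf_max"]
_TOP_BF = 100.0


class NormsCoverageError(ValueError):
    """An (age, sex, body fat) probe falls outside the norms table."""


@dataclass(frozen=True)
class NormsTable:
    """Body-fat-% risk cutoffs stratified by sex and age bracket.

    Each row is one cell ``(sex, [age_min, age_max], risk_label,
    [bf_min, bf_max))``. Construction validates the tiling: for each
    sex the age brackets cover a contiguous span without overlap, and
    within each (sex, age bracket) the body-fat intervals tile
    ``[0, 100]`` without gaps.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"norms table missing columns: {missing}")
        df = self.table
        for sex, sex_df in df.groupby("sex"):
            brackets = (
                sex_df[["age_min", "age_max"]].drop_duplicates().sort_values("age_min")
            )
            prev_max = None
            for _, row in brackets.iterrows():
                if row.age_min > row.age_max:
                    raise ValueError(f"invalid age bracket {row.age_min}-{row.age_max}")
                if prev_max is not None and row.age_min != prev_max + 1:
                    raise ValueError(
                        f"age brackets for sex={sex!r} do not tile: gap or overlap "
                        f"at {prev_max}->{row.age_min}"
                    )
                prev_max = row.age_max
            for (amin, amax), cell in sex_df.groupby(["age_min", "age_max"]):
                cell = cell.sort_values("bf_min")
                lows = cell["bf_min"].to_numpy(dtype=float)
                highs = cell["bf_max"].to_numpy(dtype=float)
                if lows[0] != 0.0 or highs[-1] != _TOP_BF:
                    raise ValueError(
                        f"body-fat intervals for sex={sex!r}, age {amin}-{amax} "
                        f"must span [0, {_TOP_BF}]"
                    )
                if not np.all(lows[1:] == highs[:-1]):
                    raise ValueError(
                        f"body-fat intervals for sex={sex!r}, age {amin}-{amax} "
                        "have gaps or overlaps"
                    )
                unknown = set(cell["risk_label"]) - set(RISK_ORDER)
                if unknown:
                    raise ValueError(f"unknown risk labels {sorted(unknown)}")

    @property
    def sexes(self) -> list[str]:
        return sorted(self.table["sex"].unique())

    def age_span(self, sex: str) -> tuple[int, int]:
        sub = self.table[self.table["sex"] == sex]
        return int(sub["age_min"].min()), int(sub["age_max"].max())

    @classmethod
    def from_csv(cls, path: str | Path) -> "NormsTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def default_norms() -> NormsTable:
    """The bundled placeholder norms table (see module docstring)."""
    ref = resources.files("ffqadjust.data") / "body_fat_norms_placeholder.csv"
    with resources.as_file(ref) as path:
        return NormsTable.from_csv(path)


def classify_health_risk(
    body_fat_pct: float, age: float, sex: str, norms: NormsTable | None = None
) -> str:
    """Look up the risk label whose cell contains (sex, age, body fat %).

    Body-fat intervals are half-open ``[low, high)`` (topmost closed);
    fractional ages are floored onto the integer-year brackets. A probe
    outside the table's coverage raises :class:`NormsCoverageError` —
    there is no silent extrapolation.
    """
    norms = norms or default_norms()
    df = norms.table
    if sex not in set(df["sex"]):
        raise ValueError(f"unknown sex {sex!r}; norms cover {norms.sexes}")
    if not 0.0 <= body_fat_pct <= 100.0:
        raise NormsCoverageError(f"body_fat_pct={body_fat_pct} outside [0, 100]")
    age_year = int(np.floor(age))
    sub = df[(df["sex"] == sex) & (df["age_min"] <= age_year) & (age_year <= df["age_max"])]
    if sub.empty:
        lo, hi = norms.age_span(sex)
        raise NormsCoverageError(
            f"age {age} outside the norms coverage [{lo}, {hi}] for sex={sex!r}"
        )
    in_cell = (sub["bf_min"] <= body_fat_pct) & (
        (body_fat_pct < sub["bf_max"]) | (sub["bf_max"] == _TOP_BF)
    )
    hit = sub[in_cell]
    if hit.empty:  # unreachable for a validated table, guards hand-built frames
        raise NormsCoverageError(
            f"body_fat_pct={body_fat_pct} not covered for sex={sex!r}, age {age}"
        )
    return str(hit.iloc[0]["risk_label"])


def is_trusted_label(risk_label: str) -> bool:
    """Trusted iff the risk label is excellent, good or normal."""
    return risk_label in TRUSTED_RISK_LABELS


def split_cohort(
    table: pd.DataFrame,
    norms: NormsTable | None = None,
    body_fat_col: str = "body_fat_pct",
    age_col: str = "age",
    sex_col: str = "sex",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition cohort rows into trusted and untrusted subsets.

    Each row is classified independently from its body fat %, age and
    sex; rows labelled excellent/good/normal go to the trusted subset,
    the rest to the untrusted one. The partition is exhaustive and
    disjoint, preserves all columns and the original row index, and
    adds a ``risk_label`` column to both outputs.
    """
    norms = norms or default_norms()
    for col in (body_fat_col, age_col, sex_col):
        if col not in table.columns:
            raise ValueError(f"cohort table lacks required column {col!r}")
        na_rows = table.index[table[col].isna()].tolist()
        if na_rows:
            raise ValueError(f"missing values in {col!r} at rows {na_rows[:20]}")
    labels = [
        classify_health_risk(row[body_fat_col], row[age_col], row[sex_col], norms)
        for _, row in table.iterrows()
    ]
    out = table.copy()
    out["risk_label"] = labels
    trusted_mask = out["risk_label"].isin(TRUSTED_RISK_LABELS)
    trusted = out[trusted_mask]
    untrusted = out[~trusted_mask]
    if untrusted.empty:
        warnings.warn("untrusted subset is empty", UserWarning, stacklevel=2)
    if trusted.empty:
        warnings.warn("trusted subset is empty", UserWarning, stacklevel=2)
    return trusted, untrusted
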