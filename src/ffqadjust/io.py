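"""Cohort table round-tripping, ordinal validation, and run provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "OrdinalVariable",
    "ColumnMap",
    "read_cohort",
    "write_table",
    "provenance_block",
]


@dataclass(frozen=True)
class OrdinalVariable:
    """A named ordinal response with its ordered category set."""

    name: str
    categories: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValueError(f"{self.name}: need at least 2 categories")
        if list(self.categories) != sorted(set(self.categories)):
            raise ValueError(f"{self.name}: categories must be strictly increasing")

    def validate(self, series: pd.Series) -> None:
        """Raise if any value falls outside the category set."""
        bad = ~series.isin(self.categories)
        if bad.any():
            offending = series[bad]
            raise ValueError(
                f"response {self.name!r} has out-of-set values "
                f"{sorted(offending.unique().tolist())} at rows "
                f"{offending.index.tolist()[:20]}"
            )


@dataclass(frozen=True)
class ColumnMap:
    """Names the roles of a cohort CSV's columns.

    ``responses`` maps each ordinal response column to its category
    list; ``features`` are the explanatory columns fed to the model.
    """

    body_fat: str = "body_fat_pct"
    age: str = "age"
    sex: str = "sex"
    features: tuple[str, ...] = ()
    responses: dict[str, tuple[int, ...]] = field(default_factory=dict)

    @property
    def required_columns(self) -> list[str]:
        return [self.body_fat, self.age, self.sex, *self.features, *self.responses]

    def ordinal_variables(self) -> list[OrdinalVariable]:
        return [OrdinalVariable(n, tuple(c)) for n, c in self.responses.items()]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnMap":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            body_fat=raw.get("body_fat", "body_fat_pct"),
            age=raw.get("age", "age"),
            sex=raw.get("sex", "sex"),
            features=tuple(raw.get("features", ())),
            responses={k: tuple(v) for k, v in raw.get("responses", {}).items()},
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "body_fat": self.body_fat,
            "age": self.age,
            "sex": self.sex,
            "features": list(self.features),
            "responses": {k: list(v) for k, v in self.responses.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload))


def read_cohort(path: str | Path, column_map: ColumnMap) -> pd.DataFrame:
    """Read a cohort CSV and validate it against the column map.

    Checks that every mapped column exists and every ordinal response
    value belongs to its declared category set (errors list offending
    rows and values).
    """
    table = pd.read_csv(path)
    missing = [c for c in column_map.required_columns if c not in table.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks mapped columns: {missing}")
    for var in column_map.ordinal_variables():
        var.validate(table[var.name])
    return table


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def provenance_block(config: dict, seed: int) -> dict:
    """Config hash + seed + library versions; identifies a run exactly."""
    import sklearn

    import ffqadjust

    canonical = json.dumps(config, sort_keys=True, default=str)
    return {
        "config_hash": hashlib.sha256(canonical.encode()).hexdigest()[:16],
        "seed": int(seed),
        "versions": {
            "ffqadjust": ffqadjust.__version__,
            "numpy": __import__("numpy").__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
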