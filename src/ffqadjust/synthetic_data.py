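"""Synthetic multinomial FFQ-like datasets with known ground truth.

Real food-frequency-questionnaire responses are ordinal categories (a
consumption frequency or quantity level 1..L) driven by continuous,
objectively measured covariates (blood lipids, glucose, body fat, BMI).
Because cohort data with *known* misreporting is essentially unobtainable,
validation relies on synthetic data in which the true category of every
participant is known by construction: Gaussian clusters around
class-specific centroids placed on hypercube vertices, padded with
uninformative noise features, with an optional fraction of randomly
flipped labels.

The module also provides the two ingredients of the validation protocol:
a label-blind trusted/untrusted split (emulating the healthy/unhealthy
cohort partition) and an underreport corruption injector that lowers
untrusted labels by a random number of levels with known probabilities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.datasets import make_classification

__all__ = [
    "ConfigurationError",
    "SyntheticConfig",
    "CorruptionScheme",
    "LabeledDataset",
    "generate_multinomial",
    "split_trusted_untrusted",
    "corrupt_underreport",
]

TRUSTED = "trusted"
UNTRUSTED = "untrusted"

# Cap retries when a rare draw misses a class entirely; each retry uses a
# deterministically derived sub-seed so the output stays reproducible.
_MAX_RESAMPLE_ATTEMPTS = 32
_SEED_STRIDE = 9973
_SEED_MOD = 2**31


class ConfigurationError(ValueError):
    """A generator or scheme parameter is out of its valid range."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic multinomial generator.

    Parameters
    ----------
    n_samples:
        Number of simulated participants (rows).
    n_features:
        Total explanatory variables; ``n_informative`` of them carry class
        signal, the remainder are standard-normal noise.
    n_classes:
        Number of ordinal response categories L; labels are 1..L.
    n_informative:
        Informative feature count; defaults to ``n_features``.
    class_separation:
        Spacing of the class centroids on the informative-feature
        hypercube. Larger values make classes easier to tell apart.
    label_noise_frac:
        Fraction of labels randomly reassigned after cluster generation,
        i.e. irreducible response noise.
    seed:
        Seed for all randomness; identical config + seed gives
        bit-identical output.
    """

    n_samples: int
    n_features: int = 8
    n_classes: int = 7
    n_informative: int | None = None
    class_separation: float = 1.0
    label_noise_frac: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.n_samples < self.n_classes:
            raise ConfigurationError(
                f"n_samples must be >= n_classes, got n_samples={self.n_samples}"
            )
        if self.n_features < 1:
            raise ConfigurationError(f"n_features must be >= 1, got {self.n_features}")
        n_info = self.resolved_informative
        if n_info < 1 or n_info > self.n_features:
            raise ConfigurationError(
                f"n_informative must be in [1, n_features], got n_informative={n_info}"
            )
        if self.n_classes > 2**n_info:
            raise ConfigurationError(
                "n_informative too small: need n_classes <= 2**n_informative, "
                f"got n_informative={n_info} for n_classes={self.n_classes}"
            )
        if not 0.0 <= self.label_noise_frac <= 1.0:
            raise ConfigurationError(
                f"label_noise_frac must be in [0, 1], got {self.label_noise_frac}"
            )
        if not self.class_separation > 0:
            raise ConfigurationError(
                f"class_separation must be positive, got {self.class_separation}"
            )

    @property
    def resolved_informative(self) -> int:
        return self.n_features if self.n_informative is None else self.n_informative

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class CorruptionScheme:
    """Distribution over label decrements used to inject underreporting.

    ``decrement_probs`` maps a non-negative level decrement to its
    probability; any residual mass is assigned to decrement 0 (response
    unchanged). The default is the validation-study scheme: 50% of
    untrusted responses drop one level, 20% two, 10% three, 20% unchanged.
    """

    decrement_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.2, 3: 0.1}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for d, p in self.decrement_probs.items():
            if d < 0 or int(d) != d:
                raise ConfigurationError(f"decrements must be non-negative integers, got {d}")
            if p < 0:
                raise ConfigurationError(f"probability for decrement {d} is negative: {p}")
        total = sum(p for d, p in self.decrement_probs.items() if d != 0)
        declared_zero = self.decrement_probs.get(0)
        if total > 1 + 1e-9:
            raise ConfigurationError(f"decrement probabilities sum to {total} > 1")
        if declared_zero is not None and abs(declared_zero - (1 - total)) > 1e-9:
            raise ConfigurationError(
                "explicit decrement-0 probability inconsistent with residual mass"
            )

    @property
    def support(self) -> np.ndarray:
        """Decrement values including the residual 0, ascending."""
        ds = sorted(set(self.decrement_probs) | {0})
        return np.asarray(ds, dtype=int)

    @property
    def probabilities(self) -> np.ndarray:
        """Probabilities aligned with :attr:`support`, summing to 1."""
        total = sum(p for d, p in self.decrement_probs.items() if d != 0)
        probs = []
        for d in self.support:
            if d == 0:
                probs.append(1.0 - total)
            else:
                probs.append(self.decrement_probs[d])
        return np.asarray(probs, dtype=float)

    def expected_decrement(self) -> float:
        return float(np.dot(self.support, self.probabilities))

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "decrement_probs": {int(k): float(v) for k, v in self.decrement_probs.items()},
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CorruptionScheme":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            decrement_probs={int(k): float(v) for k, v in raw["decrement_probs"].items()},
            seed=int(raw.get("seed", 0)),
        )


@dataclass
class LabeledDataset:
    """Feature matrix plus true and reported ordinal labels.

    ``reported_labels`` equals ``true_labels`` until corruption is
    injected; ``subset_flag`` is ``None`` until the trusted/untrusted
    split is performed.
    """

    features: np.ndarray
    true_labels: np.ndarray
    reported_labels: np.ndarray
    n_classes: int
    subset_flag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.true_labels = np.asarray(self.true_labels, dtype=int)
        self.reported_labels = np.asarray(self.reported_labels, dtype=int)
        n = len(self.features)
        if not (len(self.true_labels) == len(self.reported_labels) == n):
            raise ValueError("features and label vectors must have equal length")
        if self.subset_flag is not None and len(self.subset_flag) != n:
            raise ValueError("subset_flag length mismatch")

    def __len__(self) -> int:
        return len(self.true_labels)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def categories(self) -> np.ndarray:
        return np.arange(1, self.n_classes + 1)

    @property
    def is_split(self) -> bool:
        return self.subset_flag is not None

    def mask(self, subset: str) -> np.ndarray:
        if self.subset_flag is None:
            raise ValueError("dataset has not been split; call split_trusted_untrusted first")
        return self.subset_flag == subset

    @property
    def trusted_mask(self) -> np.ndarray:
        return self.mask(TRUSTED)

    @property
    def untrusted_mask(self) -> np.ndarray:
        return self.mask(UNTRUSTED)

    def copy(self) -> "LabeledDataset":
        return LabeledDataset(
            features=self.features.copy(),
            true_labels=self.true_labels.copy(),
            reported_labels=self.reported_labels.copy(),
            n_classes=self.n_classes,
            subset_flag=None if self.subset_flag is None else self.subset_flag.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {f"f{i + 1}": self.features[:, i] for i in range(self.n_features)}
        cols["true_label"] = self.true_labels
        cols["reported_label"] = self.reported_labels
        if self.subset_flag is not None:
            cols["subset"] = self.subset_flag
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_classes: int | None = None) -> "LabeledDataset":
        feature_cols = [c for c in frame.columns if c.startswith("f") and c[1:].isdigit()]
        feature_cols.sort(key=lambda c: int(c[1:]))
        if n_classes is None:
            n_classes = int(frame["true_label"].max())
        return cls(
            features=frame[feature_cols].to_numpy(dtype=float),
            true_labels=frame["true_label"].to_numpy(dtype=int),
            reported_labels=frame["reported_label"].to_numpy(dtype=int),
            n_classes=n_classes,
            subset_flag=frame["subset"].to_numpy() if "subset" in frame.columns else None,
        )

    @classmethod
    def from_csv(cls, path: str | Path, n_classes: int | None = None) -> "LabeledDataset":
        return cls.from_frame(pd.read_csv(path), n_classes=n_classes)


def generate_multinomial(config: SyntheticConfig) -> LabeledDataset:
    """Draw an uncorrupted, unsplit multinomial classification dataset.

    Informative features are isotropic Gaussian clusters around
    class-specific centroids at distinct hypercube vertices scaled by
    ``class_separation``; the remaining features are pure noise. A
    ``label_noise_frac`` fraction of labels is reassigned uniformly at
    random. Every category 1..L is guaranteed to appear at least once
    (the draw is repeated with a derived sub-seed in the rare case one
    is missing).
    """
    n_info = config.resolved_informative
    for attempt in range(_MAX_RESAMPLE_ATTEMPTS):
        state = (config.seed + _SEED_STRIDE * attempt) % _SEED_MOD
        features, labels = make_classification(
            n_samples=config.n_samples,
            n_features=config.n_features,
            n_informative=n_info,
            n_redundant=0,
            n_repeated=0,
            n_classes=config.n_classes,
            n_clusters_per_class=1,
            class_sep=config.class_separation,
            flip_y=config.label_noise_frac,
            shuffle=True,
            random_state=state,
        )
        labels = labels + 1  # field convention: categories are 1..L
        if len(np.unique(labels)) == config.n_classes:
            return LabeledDataset(
                features=features,
                true_labels=labels,
                reported_labels=labels.copy(),
                n_classes=config.n_classes,
            )
    raise RuntimeError(
        f"could not draw all {config.n_classes} classes in "
        f"{_MAX_RESAMPLE_ATTEMPTS} attempts; increase n_samples"
    )


def split_trusted_untrusted(
    data: LabeledDataset, untrusted_ratio: float, seed: int
) -> LabeledDataset:
    """Flag ``floor(n * untrusted_ratio)`` rows untrusted, uniformly at random.

    The split is label-blind: it emulates the cohort partition's *sizes*
    (e.g. the 70/30 healthy/unhealthy split of the validation protocol)
    without using any covariate. Returns a new dataset; the input is not
    modified.
    """
    if not 0.0 < untrusted_ratio < 1.0:
        raise ValueError(f"untrusted_ratio must be in (0, 1), got {untrusted_ratio}")
    n = len(data)
    n_untrusted = int(np.floor(n * untrusted_ratio))
    if n_untrusted == 0 or n_untrusted == n:
        raise ValueError(
            f"untrusted_ratio={untrusted_ratio} leaves an empty subset for n={n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    flags = np.full(n, TRUSTED, dtype=object)
    flags[perm[:n_untrusted]] = UNTRUSTED
    out = data.copy()
    out.subset_flag = flags.astype(str)
    return out


def corrupt_underreport(
    data: LabeledDataset, scheme: CorruptionScheme
) -> tuple[LabeledDataset, pd.DataFrame]:
    """Lower untrusted reported labels by random decrements from ``scheme``.

    Each untrusted row independently draws a decrement; the reported
    label becomes ``max(1, true - decrement)`` (clamped at the lowest
    category). Trusted rows are untouched. Returns the corrupted dataset
    and a per-untrusted-row record with columns ``row`` (position in the
    full dataset), ``decrement`` (as drawn, pre-clamp) and ``clamped``.
    """
    if data.subset_flag is None:
        raise ValueError(
            "subset_flag is unassigned: split the dataset with "
            "split_trusted_untrusted before corrupting"
        )
    rng = np.random.default_rng(scheme.seed)
    mask = data.untrusted_mask
    rows = np.flatnonzero(mask)
    draws = rng.choice(scheme.support, size=rows.size, p=scheme.probabilities)
    out = data.copy()
    true = out.true_labels[rows]
    reported = np.maximum(1, true - draws)
    out.reported_labels[rows] = reported
    record = pd.DataFrame(
        {
            "row": rows,
            "decrement": draws,
            "clamped": (true - draws) < 1,
        }
    )
    return out, record
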