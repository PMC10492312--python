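import numpy as np
import pandas as pd
import pytest

from ffqadjust.error_adjust import TrainedResponseModel
from ffqadjust.synthetic_data import (
    CorruptionScheme,
    SyntheticConfig,
    corrupt_underreport,
    generate_multinomial,
    split_trusted_untrusted,
)


class OneHotOracle:
    """Test double: a 'classifier' that reads the true label from the
    first feature column and returns probability 1 on it."""

    def __init__(self, categories):
        self.classes_ = np.asarray(categories, dtype=int)

    def predict_proba(self, X):
        X = np.asarray(X)
        proba = np.zeros((len(X), len(self.classes_)))
        for i, row in enumerate(X):
            proba[i, np.flatnonzero(self.classes_ == int(row[0]))[0]] = 1.0
        return proba

    def predict(self, X):
        return np.asarray(X)[:, 0].astype(int)


def perfect_model(categories) -> TrainedResponseModel:
    categories = np.asarray(categories, dtype=int)
    return TrainedResponseModel(
        classifier=OneHotOracle(categories),
        categories=categories,
        best_depth=1,
        cv_folds=2,
        n_estimators=1,
        cv_table=pd.DataFrame({"depth": [1], "cv_accuracy": [1.0]}),
        training_accuracy=1.0,
    )


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_samples=300, n_features=5, n_classes=4, class_separation=1.5, seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_multinomial(small_config)


@pytest.fixture(scope="session")
def corrupted_small(small_dataset):
    data = split_trusted_untrusted(small_dataset, 0.3, seed=11)
    return corrupt_underreport(data, CorruptionScheme(seed=13))
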