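"""Shared fixtures: small planted-motif datasets and a trained model.

The expensive fixtures are session-scoped so the classifier is trained
once and shared by the learnability, interpretation and attribution
tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from tssmotif import cnn, prep, synthetic
from tssmotif.core import Pwm


def consensus_pwm(width: int = 10, seed: int = 5, name: str = "planted") -> Pwm:
    """Width-10 consensus-strength PWM (one certain letter per column)."""
    rng = np.random.default_rng(seed)
    mat = np.zeros((4, width))
    mat[rng.integers(0, 4, width), np.arange(width)] = 1.0
    return Pwm(mat, name=name)


def soft_pwm(width: int = 8, dominant: float = 0.7, seed: int = 3, name: str = "soft") -> Pwm:
    rng = np.random.default_rng(seed)
    mat = np.full((4, width), (1 - dominant) / 3)
    mat[rng.integers(0, 4, width), np.arange(width)] = dominant
    return Pwm(mat, name=name)


@pytest.fixture(scope="session")
def planted_motif() -> Pwm:
    return consensus_pwm()


@pytest.fixture(scope="session")
def small_dataset(planted_motif):
    """800 windows of 300 nt, plant at rate 1.0 vs 0.0 near offset 150."""
    cfg = synthetic.SyntheticDatasetConfig(
        n_expressed=400,
        n_low=400,
        window_length=300,
        n_char_rate=0.0,
        plants=[
            synthetic.PlantSpec(
                planted_motif, 1.0, 0.0,
                position_distribution=("gaussian", 150, 5),
            )
        ],
        seed=7,
    )
    records, truth = synthetic.sample_dataset(cfg)
    X, y = prep.encode_records(records)
    return {"cfg": cfg, "records": records, "truth": truth, "X": X, "y": y}


@pytest.fixture(scope="session")
def small_splits(small_dataset):
    return cnn.split_train(small_dataset["y"], seed=0)


@pytest.fixture(scope="session")
def small_model(small_dataset, small_splits):
    """One classifier trained on fold 0 of the small dataset."""
    X, y = small_dataset["X"], small_dataset["y"]
    tr, va = small_splits.folds[0]
    model = cnn.ConvNet(cnn.ModelConfig(16, 12, 10, seed=0), X.shape[1])
    cnn.train(model, X[tr], y[tr], X[va], y[va], max_epochs=80, patience=20, seed=0)
    return model
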