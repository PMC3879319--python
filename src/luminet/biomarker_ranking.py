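"""Single-probe perceptron ranking of class-predictive transcripts.

Every probe is used, alone, as the input of a tiny perceptron predicting
the binary class label; the probe's score is its mean early-stopping test
MSE across a set of Monte-Carlo cross-validation splits. The same splits
are reused for all probes so scores are directly comparable, and each
probe's weight-initialisation seed derives from its ID so the ranking is
invariant to probe ordering. Probes sort ascending by mean test MSE (lower
= more class-predictive), ties broken lexicographically by probe ID.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from luminet._seeds import derive_seed
from luminet.dataset import ExpressionDataset
from luminet.exceptions import ConfigError, DataError, LabelError
from luminet.mlp_core import DataSplit, TrainingConfig, make_mccv_splits, train_mlp

__all__ = ["ProbeScore", "rank_probes", "select_panel", "scores_to_frame"]


@dataclass(frozen=True)
class ProbeScore:
    """Predictive-capability score of one probe."""

    probe_id: str
    mean_test_mse: float
    n_models: int
    rank: int


def rank_probes(
    dataset: ExpressionDataset,
    labels: np.ndarray | None = None,
    config: TrainingConfig | None = None,
    n_iterations: int = 50,
    splits: list[DataSplit] | None = None,
) -> list[ProbeScore]:
    """Score and rank every probe by single-input class prediction.

    Parameters
    ----------
    dataset
        Expression matrix scaled to [0, 1] (see
        :func:`luminet.mlp_core.scale_to_unit`).
    labels
        Binary class labels; defaults to ``dataset.labels``.
    config
        Trainer hyper-parameters; ``config.seed`` seeds the shared MCCV
        splits and, mixed with each probe ID, the per-model initialisation.
    n_iterations
        Number of MCCV resamples per probe (each yields one trained model).
    splits
        Pre-drawn splits to reuse; overrides ``n_iterations``.
    """
    config = config or TrainingConfig()
    y = dataset.labels if labels is None else np.asarray(labels, dtype=int)
    if y is None:
        raise LabelError("dataset has no labels and none were provided")
    if set(np.unique(y)) != {0, 1}:
        raise LabelError("both classes must be present in the labels")
    if dataset.values.min() < -1e-9 or dataset.values.max() > 1 + 1e-9:
        raise DataError("dataset must be scaled to [0, 1] before ranking")

    if splits is None:
        splits = make_mccv_splits(dataset.n_samples, n_iterations, seed=config.seed)
    target = y.astype(float)

    # one initialisation seed per split, shared by every probe: scores then
    # depend only on a probe's values, so identical probes score identically
    # and probe order is irrelevant
    split_configs = [
        TrainingConfig(
            n_hidden=config.n_hidden,
            learning_rate=config.learning_rate,
            momentum=config.momentum,
            max_epochs=config.max_epochs,
            patience_epochs=config.patience_epochs,
            seed=derive_seed(config.seed, "rank", s_idx),
        )
        for s_idx in range(len(splits))
    ]
    records = []
    for row, probe_id in zip(dataset.values, dataset.probe_ids):
        X = row[None, :]
        mses = [
            train_mlp(X, target, split, cfg).best_test_mse
            for split, cfg in zip(splits, split_configs)
        ]
        records.append((probe_id, float(np.mean(mses)), len(splits)))

    records.sort(key=lambda r: (r[1], r[0]))
    return [
        ProbeScore(probe_id=p, mean_test_mse=m, n_models=n, rank=i + 1)
        for i, (p, m, n) in enumerate(records)
    ]


def select_panel(scores: list[ProbeScore], k: int = 100) -> list[str]:
    """The ``k`` best-ranked probe IDs (lowest mean test MSE)."""
    if k < 0:
        raise ConfigError("k must be >= 0")
    if k > len(scores):
        raise ConfigError(f"k={k} exceeds the {len(scores)} scored probes")
    ordered = sorted(scores, key=lambda s: s.rank)
    return [s.probe_id for s in ordered[:k]]


def scores_to_frame(scores: list[ProbeScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.probe_id, s.mean_test_mse, s.n_models, s.rank) for s in scores],
        columns=["probe_id", "mean_test_mse", "n_models", "rank"],
    )
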