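"""ANN-weight-based inference of signed directed probe interactions.

Over a panel of p probes, each probe in turn is predicted from the
remaining p-1 by a small sigmoid perceptron (leave-one-out regression).
The signed influence of input i on the predicted target is read off the
trained weights as the first-order pathway product

    score_i = sum_h  w_in_hidden[i, h] * w_hidden_out[h]

— positive scores are interpreted as stimulating, negative as inhibiting.
Averaging over several models (fresh MCCV split each) per target fills a
p x p matrix with p*(p-1) defined off-diagonal source->target entries
(9,900 for a 100-probe panel). Magnitudes are comparable within a run but
are not renormalised across targets.

To keep the matrix exactly permutation-equivariant, inputs are presented
in lexicographic probe-ID order and all per-target randomness is keyed by
the target's probe ID, never its position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from luminet._seeds import derive_seed
from luminet.dataset import ExpressionDataset
from luminet.exceptions import DataError, PanelError
from luminet.mlp_core import TrainedMLP, TrainingConfig, make_mccv_splits, train_mlp

__all__ = [
    "InteractionMatrix",
    "interaction_scores_from_weights",
    "infer_interactions",
    "pair_table",
]


@dataclass
class InteractionMatrix:
    """Signed source->target interaction intensities over a probe panel.

    ``scores[i, j]`` is the influence of panel probe i (source) on panel
    probe j (target); the diagonal is undefined and stored as zero.
    """

    panel: list[str]
    scores: np.ndarray
    n_models: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        p = len(self.panel)
        if self.scores.shape != (p, p):
            raise PanelError(
                f"scores must be {p}x{p} for a {p}-probe panel"
            )

    @property
    def n_entries(self) -> int:
        """Number of defined (off-diagonal) source->target entries."""
        p = len(self.panel)
        return p * (p - 1)

    def entry(self, source: str, target: str) -> float:
        i = self.panel.index(source)
        j = self.panel.index(target)
        if i == j:
            raise PanelError("diagonal entries are undefined")
        return float(self.scores[i, j])


def interaction_scores_from_weights(model: TrainedMLP) -> np.ndarray:
    """Per-input signed pathway strength of a trained perceptron.

    For each input, sums the (input->hidden) x (hidden->output) weight
    products over hidden units — sign-correct for monotone dependencies.
    """
    return model.w_in_hidden @ model.w_hidden_out


def infer_interactions(
    panel_data: ExpressionDataset,
    config: TrainingConfig | None = None,
    n_models: int = 10,
) -> InteractionMatrix:
    """Leave-one-out interaction inference over a probe panel.

    Parameters
    ----------
    panel_data
        Expression restricted to the panel, scaled to [0, 1].
    config
        Trainer hyper-parameters; ``config.seed`` is mixed with each target
        probe's ID to derive split and initialisation seeds.
    n_models
        Models trained per target (each on a fresh MCCV split); entry
        (i, j) is the arithmetic mean of input i's weight score across the
        models predicting target j.
    """
    config = config or TrainingConfig()
    p = panel_data.n_probes
    if p < 3:
        raise PanelError(f"panel must contain at least 3 probes, got {p}")
    if panel_data.values.min() < -1e-9 or panel_data.values.max() > 1 + 1e-9:
        raise DataError("panel data must be scaled to [0, 1]")

    panel = list(panel_data.probe_ids)
    pos = {pid: i for i, pid in enumerate(panel)}
    scores = np.zeros((p, p))

    for target_id in panel:
        j = pos[target_id]
        # canonical (ID-sorted) input order => permutation equivariance
        input_ids = sorted(pid for pid in panel if pid != target_id)
        X = np.stack([panel_data.probe_values(pid) for pid in input_ids])
        y = panel_data.probe_values(target_id)
        splits = make_mccv_splits(
            panel_data.n_samples,
            n_models,
            seed=derive_seed(config.seed, "splits", target_id),
        )
        acc = np.zeros(p - 1)
        for m, split in enumerate(splits):
            cfg = TrainingConfig(
                n_hidden=config.n_hidden,
                learning_rate=config.learning_rate,
                momentum=config.momentum,
                max_epochs=config.max_epochs,
                patience_epochs=config.patience_epochs,
                seed=derive_seed(config.seed, m, target_id),
            )
            model = train_mlp(X, y, split, cfg)
            acc += interaction_scores_from_weights(model)
        acc /= n_models
        for pid, val in zip(input_ids, acc):
            scores[pos[pid], j] = val

    return InteractionMatrix(panel=panel, scores=scores, n_models=n_models)


def pair_table(matrix: InteractionMatrix) -> pd.DataFrame:
    """All p*(p-1) directed (source, target, weight) rows of the matrix.

    Each unordered probe pair appears twice, once per direction.
    """
    rows = []
    for i, src in enumerate(matrix.panel):
        for j, tgt in enumerate(matrix.panel):
            if i != j:
                rows.append((src, tgt, float(matrix.scores[i, j])))
    return pd.DataFrame(rows, columns=["source", "target", "weight"])
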