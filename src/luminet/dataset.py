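"""The expression-matrix container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from luminet.exceptions import DataError


@dataclass
class ExpressionDataset:
    """A probes x samples expression matrix with optional binary labels.

    Parameters
    ----------
    values
        2-D float array, one row per probe, one column per sample.
    probe_ids
        Unique probe identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    labels
        Optional 0/1 class label per sample (e.g. ER status).
    """

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray | None = None
    _probe_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D probes x samples array")
        n_probes, n_samples = self.values.shape
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.probe_ids) != n_probes:
            raise DataError(
                f"{len(self.probe_ids)} probe IDs for {n_probes} matrix rows"
            )
        if len(self.sample_ids) != n_samples:
            raise DataError(
                f"{len(self.sample_ids)} sample IDs for {n_samples} matrix columns"
            )
        if len(set(self.probe_ids)) != n_probes:
            dupes = sorted({p for p in self.probe_ids if self.probe_ids.count(p) > 1})
            raise DataError(f"duplicate probe IDs: {dupes[:5]}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n_samples,):
                raise DataError("labels must align with samples")
            if not np.isin(self.labels, (0, 1)).all():
                raise DataError("labels must be binary 0/1")
        self._probe_index = {p: i for i, p in enumerate(self.probe_ids)}

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def probe_values(self, probe_id: str) -> np.ndarray:
        try:
            return self.values[self._probe_index[probe_id]]
        except KeyError:
            raise DataError(f"unknown probe ID {probe_id!r}") from None

    def subset_probes(self, probe_ids: list[str]) -> "ExpressionDataset":
        """Restrict to the given probes, in the given order."""
        idx = [self._probe_index[p] for p in probe_ids]
        return ExpressionDataset(
            values=self.values[idx].copy(),
            probe_ids=list(probe_ids),
            sample_ids=list(self.sample_ids),
            labels=None if self.labels is None else self.labels.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, labels: np.ndarray | None = None
    ) -> "ExpressionDataset":
        return cls(
            values=frame.to_numpy(dtype=float),
            probe_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            labels=labels,
        )
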