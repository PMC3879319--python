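"""Tab-delimited readers and writers for the pipeline's artifacts."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from luminet.dataset import ExpressionDataset
from luminet.exceptions import DataError

__all__ = [
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_cohort",
    "write_cohort",
]


def read_expression(path: str | Path) -> ExpressionDataset:
    """Read a probes x samples tab-delimited matrix.

    The first column holds probe IDs, the header row sample IDs. Fails
    loudly on duplicate probe IDs, ragged rows and non-numeric cells,
    naming the offending probe.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    probe_ids = [str(i) for i in frame.index]
    dupes = frame.index[frame.index.duplicated()].unique().tolist()
    if dupes:
        raise DataError(f"duplicate probe IDs in {path.name}: {dupes[:5]}")
    if frame.isna().any().any():
        bad = frame.index[frame.isna().any(axis=1)][0]
        raise DataError(f"missing/ragged cell at probe {bad!r} in {path.name}")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError:
        for pid, row in frame.iterrows():
            for col, cell in row.items():
                try:
                    float(cell)
                except ValueError:
                    raise DataError(
                        f"non-numeric cell at probe {pid!r}, sample {col!r}: {cell!r}"
                    ) from None
        raise
    return ExpressionDataset(
        values=values,
        probe_ids=probe_ids,
        sample_ids=[str(c) for c in frame.columns],
    )


def write_expression(dataset: ExpressionDataset, path: str | Path) -> Path:
    path = Path(path)
    dataset.to_frame().to_csv(path, sep="\t", index_label="probe_id")
    return path


def read_labels(path: str | Path) -> pd.Series:
    """Read per-sample binary labels (TSV: sample_id, label)."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return frame.set_index("sample_id")["label"].astype(int)


def write_labels(
    sample_ids: list[str], labels: np.ndarray, path: str | Path
) -> Path:
    path = Path(path)
    pd.DataFrame({"sample_id": sample_ids, "label": labels}).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort table (one row per patient, TSV with header)."""
    return pd.read_csv(path, sep="\t")


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path, sep="\t", index=False)
    return path
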