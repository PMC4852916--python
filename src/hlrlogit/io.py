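"""Reading delimited expression-style tables with binary labels."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ExpressionTable", "read_table"]


@dataclass
class ExpressionTable:
    """Numeric samples × features matrix with optional binary labels."""

    sample_ids: Sequence[str]
    feature_ids: Sequence[str]
    X: np.ndarray
    y: Optional[np.ndarray] = None
    label_mapping: Optional[dict] = None


def _coerce_numeric(df: pd.DataFrame) -> np.ndarray:
    out = df.apply(pd.to_numeric, errors="coerce")
    if out.isna().to_numpy().any():
        bad = np.argwhere(out.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r}"
        )
    return out.to_numpy(dtype=float)


def _map_labels(raw: pd.Series) -> tuple[np.ndarray, dict]:
    levels = sorted(pd.unique(raw.astype(str)))
    if len(levels) != 2:
        raise ValueError(
            f"labels must have exactly 2 levels, got {len(levels)}: {levels}"
        )
    # numeric {0,1} labels keep their coding; otherwise lexicographic ->
    # first level 0, second level 1
    if set(levels) == {"0", "1"} or set(levels) == {"0.0", "1.0"}:
        mapping = {lv: int(float(lv)) for lv in levels}
    else:
        mapping = {levels[0]: 0, levels[1]: 1}
    logger.info("label mapping: %s", mapping)
    y = raw.astype(str).map(mapping).to_numpy(dtype=float)
    return y, mapping


def read_table(path, label_column: Optional[str] = None,
               labels_path: Optional[str] = None,
               delimiter: Optional[str] = None,
               orientation: str = "auto") -> ExpressionTable:
    """Read a delimited numeric matrix, with labels in a column or sidecar.

    ``orientation`` is one of ``samples`` (samples in rows), ``features``
    (features in rows; the table is transposed) or ``auto``: detected from
    where the label column / label-file ids are found, defaulting to
    samples-in-rows.  Two-level labels are mapped to {0, 1}
    (lexicographically smaller level → 0) and the mapping is recorded.
    """
    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    labels_raw = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep=delimiter, index_col=0)
        labels_raw = lab.iloc[:, 0]
        labels_raw.index = labels_raw.index.astype(str)
        if orientation == "auto":
            in_rows = labels_raw.index.isin(df.index).sum()
            in_cols = labels_raw.index.isin(df.columns).sum()
            orientation = "features" if in_cols > in_rows else "samples"
    elif label_column is not None and orientation == "auto":
        if label_column in df.columns:
            orientation = "samples"
        elif label_column in df.index:
            orientation = "features"
        else:
            raise ValueError(f"label column {label_column!r} not found")
    elif orientation == "auto":
        orientation = "samples"

    if orientation == "features":
        df = df.T
    elif orientation != "samples":
        raise ValueError(f"unknown orientation {orientation!r}")

    y = mapping = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found")
        y, mapping = _map_labels(df[label_column])
        df = df.drop(columns=[label_column])
    elif labels_raw is not None:
        labels_raw = labels_raw.reindex(df.index)
        if labels_raw.isna().any():
            raise ValueError("label file does not cover every sample id")
        y, mapping = _map_labels(labels_raw)

    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature ids: {dups[:5]}")
    X = _coerce_numeric(df)
    return ExpressionTable(sample_ids=df.index.tolist(),
                           feature_ids=df.columns.tolist(),
                           X=X, y=y, label_mapping=mapping)
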