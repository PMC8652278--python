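"""CSV/TSV round-tripping for feature matrices and labelled square matrices."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .matrix import SimilarityMatrix

__all__ = [
    "read_feature_matrix",
    "write_feature_matrix",
    "read_similarity_matrix",
    "write_similarity_matrix",
]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_feature_matrix(path) -> pd.DataFrame:
    """Read a subject x feature matrix; first column holds subject labels."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index = df.index.map(str)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate subject labels in {path}: {dupes}")
    return df


def write_feature_matrix(data: pd.DataFrame, path) -> Path:
    path = Path(path)
    data.to_csv(path, sep=_sep(path))
    return path


def read_similarity_matrix(
    path, kind: str = "dissimilarity", **kwargs
) -> SimilarityMatrix:
    """Read a labelled square matrix; header row and first column are labels."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"matrix in {path} is not square: shape {df.shape[0]}x{df.shape[1]}"
        )
    if list(df.index) != list(df.columns):
        raise ValueError(f"row and column labels of {path} do not agree")
    return SimilarityMatrix.from_frame(df, kind=kind, **kwargs)


def write_similarity_matrix(y: SimilarityMatrix, path) -> Path:
    path = Path(path)
    y.to_frame().to_csv(path, sep=_sep(path))
    return path
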