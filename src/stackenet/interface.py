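"""Dataset loading, run configuration and tabular output.

Feature matrices are dense CSV/TSV (header row = feature names, first
column = sample ids) or MatrixMarket (.mtx) with `<stem>.rownames.txt` /
`<stem>.colnames.txt` sidecars. Outcomes are one-column CSV/TSV keyed by
sample id. Samples are rows by default; pass transpose=True for the
features-as-rows convention of expression matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.io import mmread

from .glm_core import Family, get_family

__all__ = ["Dataset", "RunConfig", "load_dataset", "write_coefficients"]

log = logging.getLogger("stackenet")


@dataclass
class Dataset:
    """Aligned samples x features matrix with outcome; no missing values."""

    X: np.ndarray
    feature_names: list
    sample_ids: list
    y: np.ndarray
    family: Family

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; embedded in every output."""

    family: str = "gaussian"
    m: int = 21
    K: int = 10
    nlambda: int = 100
    ratio: Optional[float] = None
    seed: int = 0
    methods: Sequence[str] = ("ridge", "lasso", "tune", "stack")
    criterion: str = "cv"
    nzero: Optional[int] = None
    transpose: bool = False

    def __post_init__(self):
        get_family(self.family)
        if self.m < 1 or self.K < 2 or self.nlambda < 2:
            raise ValueError("invalid run configuration (m >= 1, K >= 2, nlambda >= 2)")
        if self.ratio is not None and not 0 < self.ratio < 1:
            raise ValueError("ratio must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        return d


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _read_matrix(path: Path, transpose: bool):
    if path.suffix.lower() == ".mtx":
        M = mmread(str(path))
        M = np.asarray(M.toarray() if hasattr(M, "toarray") else M, dtype=float)
        rows = Path(str(path) + ".rownames.txt")
        cols = Path(str(path) + ".colnames.txt")
        if not rows.exists() or not cols.exists():
            raise FileNotFoundError(
                f"MatrixMarket input needs sidecar files {rows.name} and {cols.name}")
        row_names = rows.read_text().split()
        col_names = cols.read_text().split()
        df = pd.DataFrame(M, index=row_names, columns=col_names)
    else:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                         float_precision="round_trip")
    if transpose:
        df = df.T
    return df


def load_dataset(
    x_path,
    y_path,
    family: Union[str, Family] = "gaussian",
    transpose: bool = False,
) -> Dataset:
    """Load and align a feature matrix and outcome vector by sample id.

    Missing values, non-numeric cells and sample-id mismatches are hard
    errors. Binomial outcomes accept 0/1 or exactly two string labels
    (sorted; the first maps to 0, logged)."""
    fam = get_family(family)
    x_path, y_path = Path(x_path), Path(y_path)
    df = _read_matrix(x_path, transpose)
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature names: {dupes[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        cells = [(str(i), str(c)) for i, c in
                 zip(*np.where(numeric.isna().to_numpy()))][:10]
        raise ValueError(f"missing or non-numeric feature cells at (row, col) "
                         f"positions {cells}")
    ydf = pd.read_csv(y_path, sep=_sep_for(y_path), index_col=0,
                      float_precision="round_trip")
    if ydf.shape[1] != 1:
        raise ValueError("outcome file must have exactly one value column")
    missing = set(map(str, df.index)) ^ set(map(str, ydf.index))
    if missing:
        raise ValueError(f"sample ids differ between X and y: {sorted(missing)[:10]}")
    ydf = ydf.loc[df.index]
    yraw = ydf.iloc[:, 0]
    if yraw.isna().any():
        raise ValueError(f"missing outcome for samples "
                         f"{yraw.index[yraw.isna()].tolist()[:10]}")
    if fam.name == "binomial" and yraw.dtype == object:
        labels = sorted(yraw.unique())
        if len(labels) != 2:
            raise ValueError(f"binomial outcome needs exactly two labels, got {labels}")
        mapping = {labels[0]: 0.0, labels[1]: 1.0}
        log.info("binomial label coding: %s -> 0, %s -> 1", labels[0], labels[1])
        y = yraw.map(mapping).to_numpy(dtype=float)
    else:
        y = pd.to_numeric(yraw, errors="raise").to_numpy(dtype=float)
    return Dataset(
        X=numeric.to_numpy(dtype=float),
        feature_names=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
        y=y,
        family=fam,
    )


def write_coefficients(path, feature_names, dense, sparse=None) -> None:
    """Coefficient table as TSV: feature, pooled estimate, optional sparse
    estimate."""
    out = pd.DataFrame({"feature": list(feature_names), "estimate": np.asarray(dense)})
    if sparse is not None:
        out["sparse_estimate"] = np.asarray(sparse)
    out.to_csv(path, sep="\t", index=False)
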