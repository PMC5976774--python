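"""Reading, writing, alignment and feature pre-selection.

Matrices are samples x features everywhere: delimited files carry a
header row of feature ids (plus an optional leading ``sample_id`` column),
MatrixMarket files come with sibling feature/sample label files, one label
per line.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .core import DataMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_embedding",
    "align_features",
    "select_by_dispersion",
]

log = logging.getLogger("cpca")

# refuse to densify sparse inputs beyond this many entries (~400 MB float64)
MAX_DENSE_ENTRIES = 50_000_000

_SAMPLE_COL = "sample_id"


def _label_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}_features.txt"), Path(f"{stem}_samples.txt")


def read_matrix(
    path: str | Path,
    fmt: str | None = None,
    transpose: bool = False,
    features_path: str | Path | None = None,
    samples_path: str | Path | None = None,
) -> DataMatrix:
    """Read a samples x features matrix from csv, tsv or MatrixMarket.

    The format is inferred from the suffix unless given.  For ``mtx`` the
    feature/sample label files default to ``<stem>_features.txt`` and
    ``<stem>_samples.txt`` next to the matrix.  ``transpose`` flips a
    features x samples file into the canonical orientation after reading.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".mtx": "mtx"}.get(
            path.suffix.lower()
        )
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if fmt == "mtx":
        data = _read_mtx(path, features_path, samples_path)
    elif fmt in ("csv", "tsv"):
        data = _read_delimited(path, sep="," if fmt == "csv" else "\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if transpose:
        data = DataMatrix(data.values.T, data.sample_ids or
                          [f"s{i}" for i in range(data.values.shape[0])],
                          data.feature_ids)
    return data


def _read_delimited(path: Path, sep: str) -> DataMatrix:
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed delimited file ({exc})") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError(f"{path}: empty matrix")
    sample_ids = None
    if df.columns[0] == _SAMPLE_COL:
        sample_ids = df[_SAMPLE_COL].astype(str).tolist()
        df = df.drop(columns=[_SAMPLE_COL])
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad.index[0]) + 2  # header + 1-based
            raise ValueError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in column "
                f"{col!r}, line {row}"
            )
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise ValueError(f"{path}: missing value in column {col!r}")
    return DataMatrix(df.to_numpy(dtype=float), list(df.columns), sample_ids)


def _read_mtx(path: Path, features_path, samples_path) -> DataMatrix:
    fdefault, sdefault = _label_paths(path)
    fpath = Path(features_path) if features_path else fdefault
    spath = Path(samples_path) if samples_path else sdefault
    for p, what in ((fpath, "feature"), (spath, "sample")):
        if not p.exists():
            raise FileNotFoundError(
                f"{path}: missing {what} label file {p} (one label per line)"
            )
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        if mat.shape[0] * mat.shape[1] > MAX_DENSE_ENTRIES:
            raise ValueError(
                f"{path}: densifying a {mat.shape} matrix exceeds the "
                f"{MAX_DENSE_ENTRIES}-entry guard; subset features first"
            )
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    samples = spath.read_text().split()
    features = fpath.read_text().split()
    if mat.shape != (len(samples), len(features)):
        raise ValueError(
            f"{path}: matrix is {mat.shape} but label files give "
            f"{len(samples)} samples x {len(features)} features"
        )
    return DataMatrix(mat, features, samples)


def write_matrix(data: DataMatrix, path: str | Path, fmt: str | None = None) -> None:
    """Write a DataMatrix (csv/tsv with header, or mtx + label files)."""
    path = Path(path)
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".txt": "tsv", ".mtx": "mtx"}[
            path.suffix.lower()
        ]
    if fmt == "mtx":
        fpath, spath = _label_paths(path)
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(data.values))
        fpath.write_text("\n".join(data.feature_ids) + "\n")
        sids = data.sample_ids or [f"s{i}" for i in range(data.n_samples)]
        spath.write_text("\n".join(sids) + "\n")
        return
    df = pd.DataFrame(data.values, columns=data.feature_ids)
    if data.sample_ids is not None:
        df.insert(0, _SAMPLE_COL, data.sample_ids)
    df.to_csv(path, sep="," if fmt == "csv" else "\t", index=False)


def write_embedding(
    embedding: np.ndarray, path: str | Path, sample_ids: list[str] | None = None
) -> None:
    """Embedding TSV: sample_id column plus one column per component."""
    embedding = np.atleast_2d(np.asarray(embedding))
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(embedding.shape[0])]
    df = pd.DataFrame(
        embedding, columns=[f"cPC{j + 1}" for j in range(embedding.shape[1])]
    )
    df.insert(0, _SAMPLE_COL, sample_ids)
    df.to_csv(path, sep="\t", index=False)


def align_features(
    target: DataMatrix, background: DataMatrix
) -> tuple[DataMatrix, DataMatrix]:
    """Restrict both matrices to the shared features, in the target's order."""
    shared = [f for f in target.feature_ids if f in set(background.feature_ids)]
    if not shared:
        raise ValueError("target and background share no features")
    dropped_t = target.n_features - len(shared)
    dropped_b = background.n_features - len(shared)
    if dropped_t or dropped_b:
        log.warning(
            "feature alignment dropped %d target and %d background features",
            dropped_t, dropped_b,
        )
    t_idx = [target.feature_ids.index(f) for f in shared]
    b_pos = {f: i for i, f in enumerate(background.feature_ids)}
    b_idx = [b_pos[f] for f in shared]
    return (
        DataMatrix(target.values[:, t_idx], shared, target.sample_ids),
        DataMatrix(background.values[:, b_idx], shared, background.sample_ids),
    )


def select_by_dispersion(
    target: DataMatrix, background: DataMatrix, top_n: int = 500
) -> tuple[DataMatrix, DataMatrix]:
    """Keep the ``top_n`` features with the highest target dispersion.

    Dispersion is variance divided by mean, the standard informative-gene
    score for expression counts; it is computed on the target only and the
    selected subset is applied to both matrices (original column order
    preserved).  Features with non-positive target mean are excluded from
    the ranking with a warning.
    """
    if target.feature_ids != background.feature_ids:
        raise ValueError("align features before dispersion selection")
    if top_n < 1 or top_n > target.n_features:
        raise ValueError(f"top_n must be in [1, {target.n_features}]")
    means = target.values.mean(axis=0)
    variances = target.values.var(axis=0)
    eligible = means > 0
    if not eligible.all():
        log.warning(
            "excluding %d features with mean <= 0 from dispersion ranking",
            int((~eligible).sum()),
        )
    if not eligible.any():
        raise ValueError("no feature has positive mean; dispersion undefined")
    dispersion = np.where(eligible, variances / np.where(eligible, means, 1.0), -np.inf)
    n_keep = min(top_n, int(eligible.sum()))
    if n_keep < top_n:
        log.warning("only %d features eligible; keeping all of them", n_keep)
    ranked = np.argsort(-dispersion, kind="stable")[:n_keep]
    keep = np.sort(ranked)  # original column order
    ids = [target.feature_ids[j] for j in keep]
    return (
        DataMatrix(target.values[:, keep], ids, target.sample_ids),
        DataMatrix(background.values[:, keep], ids, background.sample_ids),
    )
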