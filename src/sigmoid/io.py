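"""Readers and writers: binary matrices (dense TSV/CSV, sparse MatrixMarket
with sidecar id files), model directories, and variable annotations.

Matrix orientation is fixed as samples x variables everywhere; callers with
transposed inputs use the ``transpose`` flag.  Model parameters are written
as TSV with 17 significant digits so a write/read round trip is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    BinaryDataset,
    FeatureMatrix,
    FitConfig,
    FitResult,
    LatentMatrix,
    ValidationError,
)

__all__ = [
    "read_binary_matrix",
    "write_binary_matrix",
    "read_model",
    "write_model",
    "read_annotations",
]

MODEL_FORMAT_VERSION = 1
_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed input file."""


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix == ".csv":
        return "csv"
    if suffix == ".mtx":
        return "mtx"
    raise ParseError(f"cannot infer matrix format from {path.name!r}")


def _validate_cells(frame: pd.DataFrame, path: Path) -> np.ndarray:
    values = frame.to_numpy()
    numeric = pd.to_numeric(values.ravel(), errors="coerce").reshape(values.shape)
    bad = np.argwhere(~np.isin(numeric, (0.0, 1.0)) | np.isnan(numeric.astype(float)))
    if bad.size:
        r, c = bad[0]
        raise ParseError(
            f"{path.name}: non-binary cell {values[r, c]!r} at data row {r + 1}, "
            f"column {c + 1} (sample {frame.index[r]!r}, variable {frame.columns[c]!r})"
        )
    return numeric.astype(np.int8)


def read_binary_matrix(
    path: str | Path, format: str | None = None, transpose: bool = False
) -> BinaryDataset:
    """Load a samples x variables 0/1 matrix.

    TSV/CSV: header row of variable ids, first column of sample ids.
    MTX: MatrixMarket file with sidecar id files ``<path>.rows`` and
    ``<path>.cols`` holding one identifier per line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt in ("tsv", "csv"):
        try:
            frame = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", index_col=0)
        except Exception as exc:  # ragged rows, broken header
            raise ParseError(f"{path.name}: {exc}") from exc
        values = _validate_cells(frame, path)
        data = BinaryDataset(values, tuple(map(str, frame.index)), tuple(map(str, frame.columns)))
    elif fmt == "mtx":
        matrix = scipy.io.mmread(path)
        if scipy.sparse.issparse(matrix):
            matrix = matrix.toarray()
        rows = _read_id_file(path.with_suffix(path.suffix + ".rows"))
        cols = _read_id_file(path.with_suffix(path.suffix + ".cols"))
        if len(rows) != matrix.shape[0] or len(cols) != matrix.shape[1]:
            raise ParseError(
                f"{path.name}: sidecar id counts ({len(rows)}, {len(cols)}) do not "
                f"match matrix shape {matrix.shape}"
            )
        if not np.isin(matrix, (0, 1)).all():
            bad = np.argwhere(~np.isin(matrix, (0, 1)))[0]
            raise ParseError(
                f"{path.name}: non-binary cell at row {bad[0] + 1}, column {bad[1] + 1}"
            )
        data = BinaryDataset(matrix.astype(np.int8), rows, cols)
    else:
        raise ParseError(f"unknown format {fmt!r}")
    if transpose:
        data = BinaryDataset(data.values.T, data.variable_ids, data.sample_ids)
    return data


def _read_id_file(path: Path) -> tuple[str, ...]:
    if not path.exists():
        raise ParseError(f"missing sidecar id file {path.name}")
    return tuple(line.strip() for line in path.read_text().splitlines() if line.strip())


def write_binary_matrix(data: BinaryDataset, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("tsv", "csv"):
        frame = pd.DataFrame(
            data.values, index=list(data.sample_ids), columns=list(data.variable_ids)
        )
        frame.to_csv(path, sep="\t" if fmt == "tsv" else ",")
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(data.values))
        path.with_suffix(path.suffix + ".rows").write_text(
            "\n".join(data.sample_ids) + "\n"
        )
        path.with_suffix(path.suffix + ".cols").write_text(
            "\n".join(data.variable_ids) + "\n"
        )
    else:
        raise ParseError(f"unknown format {fmt!r}")


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("sigmoid")
    except Exception:
        return "unknown"


def write_model(result: FitResult, out_dir: str | Path) -> None:
    """Serialise a fit as beta.tsv + features.tsv + model.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    beta = pd.DataFrame(
        result.latents.values,
        index=list(result.latents.sample_ids),
        columns=[f"k{j}" for j in range(result.latents.k)],
    )
    beta.to_csv(out / "beta.tsv", sep="\t", float_format=_FLOAT_FMT)
    feats = pd.DataFrame(
        result.features.values,
        index=[f"k{j}" for j in range(result.features.k)],
        columns=list(result.features.variable_ids),
    )
    feats.to_csv(out / "features.tsv", sep="\t", float_format=_FLOAT_FMT)
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "package_version": _package_version(),
        "K": result.latents.k,
        "log_likelihood": result.log_likelihood,
        "converged": result.converged,
        "n_iters": result.n_iters,
        "config": asdict(result.config) if result.config is not None else None,
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_model(model_dir: str | Path) -> FitResult:
    """Round-trip counterpart of :func:`write_model`."""
    model_dir = Path(model_dir)
    meta_path = model_dir / "model.json"
    if not meta_path.exists():
        raise ParseError(f"{model_dir}: missing model.json")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{meta_path.name}: corrupt metadata ({exc})") from exc
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"model format version {meta.get('format_version')!r} != "
            f"{MODEL_FORMAT_VERSION} supported by this package"
        )
    try:
        beta = pd.read_csv(model_dir / "beta.tsv", sep="\t", index_col=0,
                           float_precision="round_trip")
        feats = pd.read_csv(model_dir / "features.tsv", sep="\t", index_col=0,
                            float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"{model_dir}: corrupt parameter tables ({exc})") from exc
    config = FitConfig(**meta["config"]) if meta.get("config") else None
    return FitResult(
        latents=LatentMatrix(beta.to_numpy(float), tuple(map(str, beta.index))),
        features=FeatureMatrix(feats.to_numpy(float), tuple(map(str, feats.columns))),
        log_likelihood=float(meta["log_likelihood"]),
        trajectory=np.array([float(meta["log_likelihood"])]),
        converged=bool(meta["converged"]),
        n_iters=int(meta["n_iters"]),
        config=config,
    )


def read_annotations(path: str | Path) -> dict[str, str]:
    """Two-column TSV (variable id, category) -> mapping."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["variable", "category"])
    return dict(zip(frame["variable"].astype(str), frame["category"].astype(str)))
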