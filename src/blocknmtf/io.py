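"""Readers and writers for the supported plain-text formats.

Dense matrices travel as tab-separated text (optional header row and
index column, controlled by flags, never guessed); sparse matrices as
MatrixMarket coordinate files (1-based on disk, 0-based in memory —
:mod:`scipy.io` handles the convention).  Factors are written with 17
significant digits, which round-trips IEEE doubles exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Literal, Optional, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .model import DataMatrix, FactorTriple, ValidationError

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_factors",
    "read_factors",
    "write_cluster_labels",
    "write_ranked_pairs",
]

Format = Literal["dense-delim", "matrixmarket"]
_FLOAT_FMT = "%.17g"


class ParseError(ValidationError):
    """Malformed input file."""


def read_matrix(
    path: Union[str, Path],
    format: Format = "dense-delim",
    header: bool = False,
    index_col: bool = False,
) -> DataMatrix:
    """Load a matrix; negative entries are rejected with their coordinate."""
    path = Path(path)
    if format == "matrixmarket":
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as exc:
            raise ParseError(f"cannot parse MatrixMarket file {path}: {exc}") from exc
        return DataMatrix(sp.csr_matrix(mat))
    if format != "dense-delim":
        raise ValidationError(f"unknown format {format!r}")
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=0 if header else None,
            index_col=0 if index_col else None,
            float_precision="round_trip",
        )
        values = df.to_numpy(dtype=np.float64)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"cannot parse delimited file {path}: {exc}") from exc
    return DataMatrix(values)


def write_matrix(
    X: DataMatrix, path: Union[str, Path], format: Optional[Format] = None
) -> Path:
    """Write dense matrices as TSV, sparse as MatrixMarket (by default
    following the storage kind)."""
    path = Path(path)
    if format is None:
        format = "matrixmarket" if X.is_sparse else "dense-delim"
    if format == "matrixmarket":
        scipy.io.mmwrite(str(path), sp.coo_matrix(X.values), precision=17)
    else:
        np.savetxt(path, X.toarray(), fmt=_FLOAT_FMT, delimiter="\t")
    return path


def write_factors(f: FactorTriple, out_dir: Union[str, Path]) -> Dict[str, Path]:
    """Write U, S, V as TSV plus a JSON sidecar with the shapes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for name, mat in (("U", f.U), ("S", f.S), ("V", f.V)):
        p = out_dir / f"{name}.tsv"
        np.savetxt(p, mat, fmt=_FLOAT_FMT, delimiter="\t")
        paths[name] = p
    meta = out_dir / "factors.json"
    meta.write_text(
        json.dumps(
            {
                "U_shape": list(f.U.shape),
                "S_shape": list(f.S.shape),
                "V_shape": list(f.V.shape),
            },
            indent=2,
        )
    )
    paths["meta"] = meta
    return paths


def _load_tsv_matrix(p: Path) -> np.ndarray:
    arr = np.loadtxt(p, delimiter="\t", dtype=np.float64, ndmin=2)
    return arr


def read_factors(out_dir: Union[str, Path]) -> FactorTriple:
    out_dir = Path(out_dir)
    f = FactorTriple(
        _load_tsv_matrix(out_dir / "U.tsv"),
        _load_tsv_matrix(out_dir / "S.tsv"),
        _load_tsv_matrix(out_dir / "V.tsv"),
    )
    meta_path = out_dir / "factors.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        for name, mat in (("U", f.U), ("S", f.S), ("V", f.V)):
            if list(mat.shape) != meta[f"{name}_shape"]:
                raise ParseError(
                    f"{name}.tsv shape {mat.shape} disagrees with sidecar "
                    f"{meta[f'{name}_shape']}"
                )
    return f


def write_cluster_labels(labels: np.ndarray, path: Union[str, Path]) -> Path:
    """Two-column delimited text: index, label."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("index\tlabel\n")
        for idx, lab in enumerate(labels):
            fh.write(f"{idx}\t{int(lab)}\n")
    return path


def write_ranked_pairs(pairs, path: Union[str, Path]) -> Path:
    """Ranked co-cluster pairs as delimited text with a header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("row_cluster\tcol_cluster\tscore\n")
        for a, b, score in pairs:
            fh.write(f"{a}\t{b}\t{score:.17g}\n")
    return path
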