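"""Matrix and factorization I/O: delimited text, Matrix Market, HDF5.

All matrices are dense in memory.  Factorizations round-trip bit-exactly
through HDF5 and to 17 significant digits through paired delimited files.
A run manifest (JSON) captures everything needed to reproduce a run.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import scipy.io

from .exceptions import DimensionError, ValidationError
from .nmf import Factorization

__all__ = ["read_matrix", "write_matrix", "read_factorization",
           "write_factorization", "RunManifest"]

logger = logging.getLogger(__name__)

#: entries more negative than this are a validation error; smaller negatives
#: are clipped to zero with a warning
_NEGATIVE_TOL = -1e-12

#: element-count budget above which a size warning is emitted
_SIZE_WARN_ELEMENTS = 200_000_000


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    if suffix == ".mtx":
        return "matrix-market"
    return "delimited"


def _sniff_delimiter(path: Path) -> str | None:
    sample = path.read_text().splitlines()
    for line in sample:
        if line.strip() and not line.startswith("#"):
            try:
                return csv.Sniffer().sniff(line, delimiters=",\t ").delimiter
            except csv.Error:
                return None
    return None


def _validate_matrix(X: np.ndarray, source: str) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValidationError(f"{source}: non-finite entries")
    lo = X.min(initial=0.0)
    if lo < _NEGATIVE_TOL:
        i, j = np.unravel_index(np.argmin(X), X.shape)
        raise ValidationError(
            f"{source}: negative entry {X[i, j]:g} at ({i}, {j}); "
            "NMF requires nonnegative input")
    if lo < 0:
        warnings.warn(f"{source}: clipping tiny negative entries (>= {lo:g}) to 0")
        X = np.maximum(X, 0)
    if X.size > _SIZE_WARN_ELEMENTS:
        warnings.warn(f"{source}: matrix has {X.size:.2e} elements; "
                      "dense processing may be slow")
    return X


def read_matrix(path, format: str | None = None,
                dataset: str = "X") -> np.ndarray:
    """Read a dense nonnegative matrix from delimited text, .mtx, or HDF5."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        import h5py
        with h5py.File(path, "r") as f:
            if dataset in f:
                X = f[dataset][()]
            else:
                keys = [k for k in f if isinstance(f[k], h5py.Dataset)]
                if len(keys) != 1:
                    raise ValidationError(
                        f"{path}: expected dataset {dataset!r} or a single "
                        f"dataset, found {keys}")
                X = f[keys[0]][()]
    elif fmt == "matrix-market":
        X = scipy.io.mmread(path)
        if hasattr(X, "toarray"):
            X = X.toarray()
    elif fmt == "delimited":
        delim = _sniff_delimiter(path)
        try:
            X = np.loadtxt(path, delimiter=delim, comments="#", ndmin=2)
        except ValueError as exc:
            raise ValidationError(f"{path}: parse error: {exc}") from exc
    else:
        raise ValidationError(f"unknown format {fmt!r}")
    return _validate_matrix(X, str(path))


def write_matrix(X: np.ndarray, path, format: str | None = None,
                 dataset: str = "X") -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset(dataset, data=np.asarray(X, dtype=float))
    elif fmt == "matrix-market":
        scipy.io.mmwrite(path, np.asarray(X, dtype=float))
    else:
        np.savetxt(path, np.asarray(X, dtype=float), delimiter="\t", fmt="%.17g")


def write_factorization(fact: Factorization, path,
                        format: str | None = None) -> dict:
    """Write W, H (plus rank/provenance attrs); returns a manifest entry.

    HDF5 keeps full binary precision; the text format writes paired
    ``<stem>.W.tsv`` / ``<stem>.H.tsv`` files at 17 significant digits.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    entry = {"path": str(path), "format": fmt, "rank": fact.rank,
             "iterations": fact.iterations, "converged": fact.converged}
    if fmt == "hdf5":
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("W", data=fact.W)
            f.create_dataset("H", data=fact.H)
            f.attrs["rank"] = fact.rank
            f.attrs["iterations"] = fact.iterations
            f.attrs["converged"] = fact.converged
            for key in ("algorithm", "tolerance", "seed", "init"):
                if fact.meta.get(key) is not None:
                    f.attrs[key] = fact.meta[key]
    else:
        wpath = path.with_suffix(".W.tsv")
        hpath = path.with_suffix(".H.tsv")
        np.savetxt(wpath, fact.W, delimiter="\t", fmt="%.17g")
        np.savetxt(hpath, fact.H, delimiter="\t", fmt="%.17g")
        entry["paths"] = [str(wpath), str(hpath)]
    return entry


def read_factorization(path, format: str | None = None) -> Factorization:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        import h5py
        with h5py.File(path, "r") as f:
            W = f["W"][()]
            H = f["H"][()]
            meta = {k: f.attrs[k] for k in f.attrs}
        fact = Factorization(W, H)
        fact.meta.update(meta)
        fact.iterations = int(meta.get("iterations", 0))
        fact.converged = bool(meta.get("converged", False))
        return fact
    W = np.loadtxt(path.with_suffix(".W.tsv"), delimiter="\t", ndmin=2)
    H = np.loadtxt(path.with_suffix(".H.tsv"), delimiter="\t", ndmin=2)
    return Factorization(W, H)


class RunManifest:
    """Collects inputs, config, seeds and stage logs of one CLI run."""

    def __init__(self, command: str, config: dict):
        import gsvdnmf
        self.data = {
            "command": command,
            "config": config,
            "versions": {"gsvdnmf": gsvdnmf.__version__,
                         "numpy": np.__version__},
            "stages": [],
            "outputs": [],
        }

    def log_stage(self, name: str, **info) -> None:
        self.data["stages"].append({"stage": name, **info})

    def add_output(self, entry) -> None:
        self.data["outputs"].append(entry)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=2, default=str))
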