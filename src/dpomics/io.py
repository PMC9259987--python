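"""File formats and model serialization.

Matrices travel as tab-separated text: a header row of feature identifiers,
a first column of sample identifiers (rows are samples), numeric cells with
missing values spelled exactly ``NA``.  Trained models travel as a bundle
directory — ``manifest.json`` (format version, architecture record, privacy
ledger, provenance, checksum) plus an ``arrays.npz`` of layer weights and
biases.  A bundle is the ONLY published artifact and never contains data
rows; loading verifies the format version and the arrays checksum and must
reproduce the saved model's predictions bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .networks import NetworkParams, spec_from_record, spec_record
from .pipeline import TrainedModelBundle

logger = logging.getLogger("dpomics")

FORMAT_VERSION = "1"
NA_TOKEN = "NA"


class MatrixFormatError(ValueError):
    """A matrix file violates the TSV contract (named line/identifier in message)."""


class BundleFormatError(ValueError):
    """A bundle directory is unreadable: wrong version, checksum, or missing pieces."""


def read_matrix(path) -> pd.DataFrame:
    """Parse a samples-by-features TSV matrix; strict about shape and identifiers."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise MatrixFormatError(f"{path}: empty file")
        columns = header.split("\t")
        features = columns[1:]
        if not features:
            raise MatrixFormatError(f"{path}: no feature columns in header")
        if len(set(features)) != len(features):
            seen, dup = set(), None
            for f in features:
                if f in seen:
                    dup = f
                    break
                seen.add(f)
            raise MatrixFormatError(f"{path}: duplicate feature id {dup!r}")
        sample_ids: list[str] = []
        rows: list[list[float]] = []
        seen_samples: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(features) + 1:
                raise MatrixFormatError(
                    f"{path}: line {lineno} has {len(cells)} fields, expected {len(features) + 1}"
                )
            sid = cells[0]
            if sid in seen_samples:
                raise MatrixFormatError(f"{path}: duplicate sample id {sid!r} at line {lineno}")
            seen_samples.add(sid)
            sample_ids.append(sid)
            row = []
            for col, cell in zip(features, cells[1:]):
                if cell == NA_TOKEN:
                    row.append(np.nan)
                else:
                    try:
                        row.append(float(cell))
                    except ValueError:
                        raise MatrixFormatError(
                            f"{path}: line {lineno}, column {col!r}: non-numeric cell {cell!r}"
                        ) from None
            rows.append(row)
    if not rows:
        raise MatrixFormatError(f"{path}: no sample rows")
    frame = pd.DataFrame(rows, index=sample_ids, columns=features)
    frame.index.name = "sample_id"
    logger.info("event=read_matrix path=%s n_samples=%d n_features=%d", path, *frame.shape)
    return frame


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a samples-by-features TSV (header row, NA for missing, 10 significant digits)."""
    if matrix.shape[1] == 0:
        raise MatrixFormatError("refusing to write a matrix with no feature columns")
    if matrix.shape[0] == 0:
        raise MatrixFormatError("refusing to write a matrix with no sample rows")
    out = matrix.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format="%.10g")


def read_labels(path) -> pd.Series:
    """Two-column TSV (sample_id, label) -> integer label series."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] != 1:
        raise MatrixFormatError(f"{path}: expected exactly one label column")
    return frame.iloc[:, 0].astype(int)


def write_labels(labels: pd.Series, path) -> None:
    frame = labels.rename("label").to_frame()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# bundle directories
# ---------------------------------------------------------------------------

_ARRAYS_FILE = "arrays.npz"
_MANIFEST_FILE = "manifest.json"


def save_bundle(bundle: TrainedModelBundle, directory) -> Path:
    """Serialize a trained model (parameters, architecture, privacy ledger) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, (W, b) in enumerate(zip(bundle.params.weights, bundle.params.biases)):
        arrays[f"weight_{i}"] = W
        arrays[f"bias_{i}"] = b
    arrays_path = directory / _ARRAYS_FILE
    np.savez(arrays_path, **arrays)
    checksum = hashlib.sha256(arrays_path.read_bytes()).hexdigest()
    manifest = {
        "format_version": FORMAT_VERSION,
        "kind": bundle.kind,
        "spec": spec_record(bundle.spec),
        "privacy": bundle.privacy,
        "provenance": bundle.provenance,
        "history": bundle.history,
        "n_layers": bundle.params.n_layers,
        "arrays_file": _ARRAYS_FILE,
        "arrays_sha256": checksum,
    }
    (directory / _MANIFEST_FILE).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("event=save_bundle dir=%s kind=%s n_params=%d", directory, bundle.kind,
                bundle.params.n_params)
    return directory


def load_bundle(directory) -> TrainedModelBundle:
    """Load a bundle directory, verifying format version and arrays checksum."""
    directory = Path(directory)
    manifest_path = directory / _MANIFEST_FILE
    arrays_path = directory / _ARRAYS_FILE
    if not manifest_path.exists():
        raise BundleFormatError(f"{directory}: missing {_MANIFEST_FILE}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format_version") != FORMAT_VERSION:
        raise BundleFormatError(
            f"{directory}: unsupported format version {manifest.get('format_version')!r} "
            f"(this reader supports {FORMAT_VERSION!r})"
        )
    if not arrays_path.exists():
        raise BundleFormatError(f"{directory}: missing {manifest.get('arrays_file', _ARRAYS_FILE)}")
    checksum = hashlib.sha256(arrays_path.read_bytes()).hexdigest()
    if checksum != manifest.get("arrays_sha256"):
        raise BundleFormatError(f"{directory}: arrays checksum mismatch (file tampered or truncated)")
    with np.load(arrays_path) as arrays:
        n_layers = int(manifest["n_layers"])
        try:
            weights = [arrays[f"weight_{i}"] for i in range(n_layers)]
            biases = [arrays[f"bias_{i}"] for i in range(n_layers)]
        except KeyError as exc:
            raise BundleFormatError(f"{directory}: missing array {exc}") from exc
    return TrainedModelBundle(
        kind=manifest["kind"],
        params=NetworkParams(weights, biases),
        spec=spec_from_record(manifest["spec"]),
        privacy=manifest["privacy"],
        provenance=manifest["provenance"],
        history=manifest.get("history", {}),
    )
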