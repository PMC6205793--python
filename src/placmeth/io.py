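"""Dataset loading with validation, result writing, and run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
import sys
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import BetaMatrix, DataError, ProbeAnnotation, SampleSheet


def load_dataset(
    beta_path, sheet_path, annotation_path=None
) -> tuple[BetaMatrix, SampleSheet, ProbeAnnotation | None]:
    """Read and cross-validate a beta matrix (TSV), sample sheet (CSV) and
    optional probe annotation (TSV).

    The sheet is aligned to the matrix column order; samples present in one
    but not the other raise a load error naming the offending ids.  Out of
    range or duplicate entries fail inside the container constructors with
    the offending id in the message.
    """
    matrix = BetaMatrix.from_tsv(beta_path)
    sheet = SampleSheet.from_csv(sheet_path).aligned_to(matrix)
    annotation = None
    if annotation_path is not None:
        annotation = ProbeAnnotation.from_tsv(annotation_path)
    return matrix, sheet, annotation


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(out_dir, config: dict, seed: int | None) -> Path:
    """Emit a run manifest (config hash, seed, versions, timestamp)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "placmeth",
        "version": __version__,
        "python": sys.version.split()[0],
        "platform": platform.platform(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": seed,
        "config": config,
        "config_hash": _hash_obj(config),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path


def write_results(obj, path) -> Path:
    """Write a stage output: DataFrames as TSV (stable column order),
    mappings/dataclass-like reports as JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if hasattr(obj, "to_tsv"):
        obj.to_tsv(path)
    elif hasattr(obj, "to_json") and not isinstance(obj, pd.DataFrame):
        obj.to_json(path)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=True, na_rep="NA")
    elif isinstance(obj, dict):
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, default=str)
    else:
        raise DataError(f"do not know how to write {type(obj).__name__}")
    return path
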