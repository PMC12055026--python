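"""Flat-file input/output: TSV tables, dense array stores, manifests.

All tabular artifacts are plain TSV for inspectability; dense numeric
stacks that must round-trip bit-exactly between stages (feature arrays,
MSNs, gradient components) are stored as raw ``.npy``.  A YAML manifest
records the configuration, per-stage seeds and a SHA-256 content hash of
every artifact so a run can be audited and reproduced.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_array",
    "read_array",
    "sha256_file",
    "write_manifest",
    "read_manifest",
    "write_cohort",
]


def write_tsv(frame: pd.DataFrame, path: Path | str, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


def read_tsv(path: Path | str, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_array(arr: np.ndarray, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path, np.asarray(arr))
    return path


def read_array(path: Path | str) -> np.ndarray:
    return np.load(path)


def sha256_file(path: Path | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Path | str, payload: dict) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts = sorted(
        p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.yaml"
    )
    payload = dict(payload)
    payload["artifacts"] = {
        str(p.relative_to(out_dir)): sha256_file(p) for p in artifacts
    }
    path = out_dir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path


def read_manifest(out_dir: Path | str) -> dict:
    with open(Path(out_dir) / "manifest.yaml") as fh:
        return yaml.safe_load(fh)


def write_cohort(cohort, out_dir: Path | str, per_subject_tables: bool = False) -> None:
    """Write a synthetic cohort: metadata TSV, dense feature stack, and
    optionally one regions x features TSV per subject."""
    out_dir = Path(out_dir)
    write_tsv(cohort.metadata, out_dir / "metadata.tsv")
    write_array(cohort.features, out_dir / "features.npy")
    if per_subject_tables:
        sub_dir = out_dir / "subjects"
        for sid in cohort.metadata["subject_id"]:
            write_tsv(
                cohort.feature_table(sid).reset_index(), sub_dir / f"{sid}.tsv"
            )
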