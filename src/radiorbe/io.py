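"""Tidy CSV/JSON input-output with provenance headers.

Every file the pipelines write starts with ``#``-prefixed comment lines
recording the package version, the seed and a hash of the run configuration,
so an output table can always be traced back to the run that produced it.
Readers skip those lines transparently.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .errors import ValidationError

__all__ = [
    "provenance_header",
    "write_csv",
    "read_csv",
    "write_json",
    "read_colonies",
    "read_spheroids",
    "read_assays",
]


def _config_hash(config: dict | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance_header(seed: int | None = None, config: dict | None = None) -> list[str]:
    from . import __version__

    return [
        f"# radiorbe v{__version__}",
        f"# seed: {seed if seed is not None else 'none'}",
        f"# config_sha256: {_config_hash(config)}",
    ]


def write_csv(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> Path:
    """Write a DataFrame as CSV preceded by a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in provenance_header(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)
    return path


def read_csv(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a (possibly provenance-headed) CSV, checking required columns."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"input file is empty: {path}") from None
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"{path} is missing columns: {missing}")
    return df


def write_json(
    obj: dict, path: str | Path, seed: int | None = None, config: dict | None = None
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"provenance": {"seed": seed, "config_sha256": _config_hash(config)}}
    payload.update(obj)
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n", encoding="utf-8")
    return path


def read_colonies(path: str | Path) -> pd.DataFrame:
    from .clonogenic import COLONY_COLUMNS

    return read_csv(path, required=COLONY_COLUMNS)


def read_spheroids(path: str | Path) -> pd.DataFrame:
    from .spheroid import SPHEROID_COLUMNS

    return read_csv(path, required=SPHEROID_COLUMNS)


def read_assays(path: str | Path) -> pd.DataFrame:
    return read_csv(
        path, required=["assay", "condition", "cell_line", "modality", "dose_gy"]
    )
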