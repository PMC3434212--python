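"""Tabular interchange formats, run configuration and hashing helpers.

Everything on disk is UTF-8, tab-separated with a header row and '.' decimal
separators.  Readers validate a required-column schema and reject NaN in
required columns with the offending line number; extra columns pass through
untouched.  A small import shim parses GEO series-matrix-style expression
tables (probe rows, sample columns) so deposited data can enter the pipeline
at the normalization stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .beadproc import PRESENCE_TABLE, BeadArray

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "read_tabular",
    "write_tabular",
    "write_bead_array",
    "read_bead_array",
    "RunConfig",
    "read_series_matrix",
    "sha256_file",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def read_tabular(
    path: str | Path,
    required: Mapping[str, type] | Sequence[str],
    allow_nan: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a tab-separated table and validate required columns.

    ``required`` maps column names to dtypes (or just lists names).  Missing
    columns raise :class:`SchemaError`; NaN in a required column raises with
    the 1-based data line number unless the column is listed in
    ``allow_nan``.  Extra columns are preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0)
    names = list(required.keys()) if isinstance(required, Mapping) else list(required)
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    for col in names:
        if col in allow_nan:
            continue
        na = df[col].isna()
        if na.any():
            line = int(na.idxmax()) + 2  # header is line 1
            raise SchemaError(f"{path.name}: NaN in required column "
                              f"{col!r} at line {line}")
    if isinstance(required, Mapping):
        for col, dtype in required.items():
            if dtype is not None:
                try:
                    df[col] = df[col].astype(dtype)
                except (TypeError, ValueError) as exc:
                    raise SchemaError(
                        f"{path.name}: column {col!r} not castable to "
                        f"{dtype}: {exc}") from exc
    return df


def write_tabular(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a tab-separated UTF-8 table with a header row."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, encoding="utf-8")


# ---------------------------------------------------------------------------
# Bead-level dialect
# ---------------------------------------------------------------------------

BEAD_SCHEMA = {"probe_id": str, "bead_intensity": float,
               "is_negative_control": int}


def write_bead_array(array: BeadArray, path: str | Path) -> None:
    """One row per bead: probe_id, bead_intensity, is_negative_control."""
    probes = np.repeat(
        np.array(array.probe_ids),
        [array.beads[p].size for p in array.probe_ids],
    )
    intensities = np.concatenate([array.beads[p] for p in array.probe_ids])
    negflag = np.isin(probes, list(array.negative_control_ids)).astype(int)
    df = pd.DataFrame({
        "probe_id": probes,
        "bead_intensity": intensities,
        "is_negative_control": negflag,
    })
    write_tabular(df, path)


def read_bead_array(path: str | Path, sample_id: str) -> BeadArray:
    """Inverse of :func:`write_bead_array`."""
    df = read_tabular(path, BEAD_SCHEMA)
    beads = {p: g["bead_intensity"].to_numpy()
             for p, g in df.groupby("probe_id", sort=False)}
    neg = frozenset(df.loc[df["is_negative_control"] == 1, "probe_id"])
    return BeadArray(sample_id=sample_id, beads=beads, negative_control_ids=neg)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All pipeline parameters, serializable to a YAML round trip.

    ``sim`` holds the synthetic-cohort parameters as a plain dict of
    :class:`~beadpipe.simdata.SimConfig` field overrides so the config file
    stays a flat key-value document.
    """

    seed: int = 0
    sim: dict = field(default_factory=dict)
    mad_multiplier: float = 2.0
    mad_zero_policy: str = "strict"
    detection_alpha: float = 0.05
    presence_table: dict = field(default_factory=lambda: dict(PRESENCE_TABLE))
    window_size: int = 101
    confidence: float = 10.0
    flag_k: float = 2.0
    quality_threshold: float = 0.65
    heterogeneity_gene_set: str = "assessed"  # or "de"
    outdir: str = "run"

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["presence_table"] = {int(k): int(v)
                                  for k, v in data["presence_table"].items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "presence_table" in data:
            data["presence_table"] = {int(k): int(v)
                                      for k, v in data["presence_table"].items()}
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (the output path is excluded)."""
        data = dataclasses.asdict(self)
        data.pop("outdir", None)
        canonical = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# GEO series-matrix import shim
# ---------------------------------------------------------------------------


def read_series_matrix(path: str | Path) -> pd.DataFrame:
    """Parse the data block of a GEO series-matrix text file.

    Returns a probes x samples DataFrame of the values between the
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` markers,
    with quotes stripped.  Import only; no downloading.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines)
                   if l.startswith("!series_matrix_table_end"))
    except StopIteration as exc:
        raise SchemaError("no series-matrix table markers found") from exc
    block = [l.strip().split("\t") for l in lines[start + 1:end] if l.strip()]
    header = [c.strip('"') for c in block[0]]
    rows = [[c.strip('"') for c in r] for r in block[1:]]
    df = pd.DataFrame(rows, columns=header).set_index(header[0])
    df.index.name = "probe_id"
    return df.astype(float)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
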