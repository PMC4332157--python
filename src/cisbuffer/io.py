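"""Tab-separated readers/writers, run configuration and provenance.

One tabular dialect everywhere: UTF-8 TSV with '#'-prefixed header
comment lines (key=value metadata), then a header row.  Every CLI run
writes a JSON provenance record (config, seed, package version, input
hashes) from which the output is regenerable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import SPORE_HYBRID


def _read_comments(path):
    meta = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
    return meta


def write_table(df: pd.DataFrame, path, meta: dict | None = None,
                index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wt", encoding="utf-8") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"#{key}={val}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
    df.attrs.update(_read_comments(path))
    return df


def write_counts(counts: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Counts TSV: rows = genes, columns = <sample>_<allele> units."""
    write_table(counts, path, meta)


def read_counts(path) -> pd.DataFrame:
    """Read a counts TSV; every cell must be a non-negative integer."""
    df = read_table(path)
    arr = df.to_numpy()
    for j, col in enumerate(df.columns):
        colvals = pd.to_numeric(df[col], errors="coerce")
        bad = colvals.isna() | (colvals != np.floor(colvals)) | (colvals < 0)
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-integer or negative count at gene {row!r}, "
                f"column {col!r}")
    return df.astype(np.int64)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    meta = {k: v for k, v in sheet.attrs.items()}
    write_table(sheet, path, meta)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = read_table(path)
    return sheet


def check_counts_match_sheet(counts: pd.DataFrame, sheet: pd.DataFrame) -> None:
    missing = [c for c in counts.columns if c not in sheet.index]
    if missing:
        raise ValueError(
            f"count columns without a sample-sheet entry: {missing}")


def write_snp_table(snps: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_table(snps, path, meta, index=False)


def read_snp_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class RunConfig:
    """Paths and thresholds for a pipeline run (JSON/YAML round-trip)."""

    counts: str | None = None
    samples: str | None = None
    annotation: str | None = None
    snps: str | None = None
    min_mean: float = 10.0
    fold: float = 1.5
    fdr: float = 0.2
    grid: tuple = (0.0, 0.5, 0.05)  # start, stop, step
    bootstrap_b: int = 1000
    seed: int = 0
    dataset_kind: str = SPORE_HYBRID

    def __post_init__(self):
        if self.min_mean < 0 or self.fold <= 0 or not 0 < self.fdr <= 1:
            raise ValueError("thresholds out of range")

    def grid_values(self):
        start, stop, step = self.grid
        return np.round(np.arange(start, stop + step / 2, step), 6)

    @classmethod
    def load(cls, path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if "grid" in data:
            data["grid"] = tuple(data["grid"])
        return cls(**data)

    def dump(self, path) -> None:
        data = dataclasses.asdict(self)
        data["grid"] = list(self.grid)
        Path(path).write_text(json.dumps(data, indent=2) + "\n",
                              encoding="utf-8")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def provenance_record(command: str, config: dict, seed: int | None,
                      inputs: list | None = None) -> dict:
    return {
        "command": command,
        "config": config,
        "seed": seed,
        "version": __version__,
        "python": sys.version.split()[0],
        "inputs": {str(p): _sha256(p) for p in (inputs or [])},
    }


def write_provenance(path, record: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(record, indent=2, default=str) + "\n",
                    encoding="utf-8")
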