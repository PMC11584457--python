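"""Typed study-design inputs, pipeline configuration, and stage-table I/O.

The three inputs every run needs are a :class:`SampleManifest` (who the
samples are and which dual 8-bp barcodes tag them), a :class:`MarkerInfo`
table (the amplicon targets: primers, inner reference sequence and genomic
coordinates), and a :class:`PipelineConfig` carrying every filtering
threshold.  The config is the single source of truth for thresholds: each
stage receives it explicitly and it is immutable after construction.

Genomic coordinates are 1-based inclusive throughout, so a marker's inner
reference must satisfy ``len(seq) == end - start + 1``.  Intermediate stage
tables are persisted as TSV, one file per stage.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .errors import (
    BarcodeError,
    ConfigError,
    CoordinateError,
    DuplicateKeyError,
    EmptyTableError,
    MissingColumnError,
)

_DNA_RE = re.compile(r"^[ACGT]+$")

MANIFEST_COLUMNS = ["sample_id", "barcode_fwd", "barcode_rev", "sample", "info"]
MARKER_COLUMNS = ["marker_id", "primer_fwd", "primer_rev", "seq", "chrom", "start", "end"]

#: Haplotype status labels assigned during annotation.
STATUS_LABELS = (
    "pass",
    "low_sample_count",
    "low_asv_count",
    "low_asv_freq",
    "low_ident",
    "low_ident_z",
    "chimera",
    "multiple",
)


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{what}: missing required column(s) {missing}")


@dataclass(frozen=True)
class SampleManifest:
    """Validated sample sheet: one row per sample with its dual barcodes."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        _require_columns(df, MANIFEST_COLUMNS, "sample manifest")
        if len(df) == 0:
            raise EmptyTableError("sample manifest: no rows")
        df = df.copy()
        for col in MANIFEST_COLUMNS:
            df[col] = df[col].astype(str)
        df["barcode_fwd"] = df["barcode_fwd"].str.upper()
        df["barcode_rev"] = df["barcode_rev"].str.upper()
        if df["sample_id"].duplicated().any():
            dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
            raise DuplicateKeyError(f"sample manifest: duplicate sample_id {dups}")
        pairs = df[["barcode_fwd", "barcode_rev"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            raise DuplicateKeyError(
                "sample manifest: duplicate (barcode_fwd, barcode_rev) pair"
            )
        for col in ("barcode_fwd", "barcode_rev"):
            bad = df.loc[~df[col].str.match(_DNA_RE), "sample_id"].tolist()
            if bad:
                raise BarcodeError(f"sample manifest: non-DNA {col} for {bad}")
            if df[col].str.len().nunique() > 1:
                raise BarcodeError(f"sample manifest: ragged {col} lengths")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @property
    def sample_ids(self):
        return list(self.data["sample_id"])

    @property
    def barcode_fwd_len(self) -> int:
        return len(self.data["barcode_fwd"].iloc[0])

    @property
    def barcode_rev_len(self) -> int:
        return len(self.data["barcode_rev"].iloc[0])

    def write(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class MarkerInfo:
    """Validated amplicon marker table with primers and reference sequences."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        _require_columns(df, MARKER_COLUMNS, "marker info")
        if len(df) == 0:
            raise EmptyTableError("marker info: no rows")
        df = df.copy()
        for col in ("marker_id", "primer_fwd", "primer_rev", "seq", "chrom"):
            df[col] = df[col].astype(str)
        for col in ("primer_fwd", "primer_rev", "seq"):
            df[col] = df[col].str.upper()
        try:
            df["start"] = df["start"].astype(int)
            df["end"] = df["end"].astype(int)
        except (TypeError, ValueError) as exc:
            raise CoordinateError(f"marker info: non-numeric start/end ({exc})")
        if df["marker_id"].duplicated().any():
            raise DuplicateKeyError("marker info: duplicate marker_id")
        for _, row in df.iterrows():
            if row["end"] < row["start"]:
                raise CoordinateError(
                    f"marker {row['marker_id']}: end {row['end']} < start {row['start']}"
                )
            span = row["end"] - row["start"] + 1
            if len(row["seq"]) != span:
                raise CoordinateError(
                    f"marker {row['marker_id']}: seq length {len(row['seq'])} "
                    f"!= end - start + 1 = {span}"
                )
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @property
    def marker_ids(self):
        return list(self.data["marker_id"])

    def row(self, marker_id: str) -> pd.Series:
        hit = self.data[self.data["marker_id"] == marker_id]
        if len(hit) == 0:
            raise KeyError(f"unknown marker_id {marker_id!r}")
        return hit.iloc[0]

    def reference(self, marker_id: str) -> str:
        return self.row(marker_id)["seq"]

    def write(self, path) -> None:
        self.data.to_csv(path, index=False)


def read_sample_manifest(path) -> SampleManifest:
    """Read and validate a sample manifest CSV.

    Column order is irrelevant and extra columns are preserved as metadata.
    """
    df = pd.read_csv(path, dtype=str)
    return SampleManifest(df)


def read_marker_info(path) -> MarkerInfo:
    """Read and validate a marker info CSV (seq is upper-cased)."""
    df = pd.read_csv(path)
    return MarkerInfo(df)


@dataclass(frozen=True)
class PipelineConfig:
    """All filtering thresholds, immutable, with the standard defaults.

    ``min_overlap == -1`` switches paired-end merging to plain concatenation
    for non-overlapping read designs.  ``min_homo_rep`` / ``terminal_region_len``
    set to ``None`` disable the corresponding indel correction.
    """

    min_read_count: int = 1000
    min_marker_count: int = 100
    n_sample: int = 10000
    min_overlap: int = 10
    min_asv_count: int = 5
    min_asv_freq: float = 0.001
    min_ident: float = 0.75
    min_ident_z: float = -3.0
    max_breakpoints: int = 3
    min_parent_ratio: float = 1.5
    max_sm_miss: float = 0.5
    max_marker_miss: float = 0.5
    min_homo_rep: Optional[int] = 3
    sample_med_He: float = 0.0
    n_alleles: int = 3
    var_maf: float = 0.001
    var_he: float = 0.001
    terminal_region_len: Optional[int] = 5
    max_expected_errors: float = 2.0
    denoise_alpha: float = 2.0
    denoise_d_max: int = 10
    max_mismatch: int = 0
    merge_max_mismatch: int = 0
    seed: int = 0

    def __post_init__(self):
        fractions = (
            "min_asv_freq", "min_ident", "max_sm_miss", "max_marker_miss",
            "sample_med_He", "var_maf", "var_he",
        )
        for name in fractions:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        counts = (
            "min_read_count", "min_marker_count", "n_sample", "min_asv_count",
            "max_breakpoints", "n_alleles", "max_mismatch", "merge_max_mismatch",
        )
        for name in counts:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (self.min_overlap >= 1 or self.min_overlap == -1):
            raise ConfigError(
                f"min_overlap must be >= 1 or -1, got {self.min_overlap}"
            )
        if self.min_homo_rep is not None and self.min_homo_rep < 1:
            raise ConfigError("min_homo_rep must be >= 1 or None")
        if self.terminal_region_len is not None and self.terminal_region_len < 0:
            raise ConfigError("terminal_region_len must be >= 0 or None")
        if self.max_expected_errors < 0:
            raise ConfigError("max_expected_errors must be >= 0")

    def replace(self, **overrides) -> "PipelineConfig":
        return load_config(overrides, base=self)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def load_config(overrides: Optional[Mapping] = None, base: Optional[PipelineConfig] = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from defaults plus overrides.

    Unknown keys raise :class:`ConfigError` rather than being ignored, so a
    typo in a parameter name can never silently fall back to the default.
    """
    overrides = dict(overrides or {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(overrides) - known)
    if unknown:
        raise ConfigError(f"unknown config parameter(s): {unknown}")
    if base is not None:
        merged = base.to_dict()
        merged.update(overrides)
        overrides = merged
    return PipelineConfig(**overrides)


LEDGER_STAGES = ["n_demux", "n_in", "n_out", "n_downsampled", "n_final"]


@dataclass
class RunLedger:
    """Read counts at each pipeline stage per (sample_id, marker_id).

    Within a row counts must be monotone non-increasing across stages:
    demultiplexed >= filter input >= filter output >= downsampled >= final.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        _require_columns(df, ["sample_id", "marker_id"] + LEDGER_STAGES, "run ledger")
        for a, b in zip(LEDGER_STAGES, LEDGER_STAGES[1:]):
            bad = df[df[a] < df[b]]
            if len(bad):
                row = bad.iloc[0]
                raise ValueError(
                    f"run ledger: {b} > {a} for ({row['sample_id']}, {row['marker_id']})"
                )
        if (df[LEDGER_STAGES[-1]] < 0).any():
            raise ValueError("run ledger: negative count")

    def write(self, path) -> None:
        write_table(self.data, path)


def write_table(df: pd.DataFrame, path) -> None:
    """Persist a stage table as TSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "marker_id": str})
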