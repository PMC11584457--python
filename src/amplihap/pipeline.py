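"""One-call orchestration of the full run and the demultiplexed entry point."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .annotate import annotate_seq_tbl
from .asv import build_seq_table
from .datamodel import (
    MarkerInfo,
    PipelineConfig,
    RunLedger,
    SampleManifest,
    write_table,
)
from .demux import demultiplex_reads
from .errors import PipelineError, EmptyResultError
from .readqc import downsample_reads, filter_trim
from .report import generate_report
from .seqfilter import sequence_filter

logger = logging.getLogger(__name__)


@dataclass
class RunResult:
    demultiplexed: pd.DataFrame
    flt_reads: pd.DataFrame
    sub_reads: pd.DataFrame
    seq_tbl: pd.DataFrame
    seq_ann_tbl: pd.DataFrame
    seq_flt_tbl: pd.DataFrame
    variant_table: pd.DataFrame
    ledger: RunLedger
    report_path: Optional[Path]


def _banner(text: str) -> None:
    logger.info("---- %s ----", text)


def _build_ledger(demux, flt, sub, final) -> RunLedger:
    base = demux[["sample_id", "marker_id", "n"]].rename(columns={"n": "n_demux"})
    f = flt[["sample_id", "marker_id", "n_in", "n_out"]]
    s = sub[["sample_id", "marker_id", "n"]].rename(columns={"n": "n_downsampled"})
    fin = (
        final.groupby(["sample_id", "marker_id"], as_index=False)["count"]
        .sum().rename(columns={"count": "n_final"})
    )
    df = base.merge(f, on=["sample_id", "marker_id"], how="left")
    df = df.merge(s, on=["sample_id", "marker_id"], how="left")
    df = df.merge(fin, on=["sample_id", "marker_id"], how="left")
    for col in ("n_in", "n_out", "n_downsampled", "n_final"):
        df[col] = df[col].fillna(0).astype(int)
    return RunLedger(df)


def run_from_demultiplexed(
    demultiplexed: pd.DataFrame,
    manifest: SampleManifest,
    markers: MarkerInfo,
    run_dir,
    config: Optional[PipelineConfig] = None,
    marker_trim: Optional[pd.DataFrame] = None,
    make_report: bool = True,
) -> RunResult:
    """Run every stage downstream of demultiplexing.

    ``demultiplexed`` must reference existing per-combination FASTQ pairs;
    dangling paths raise immediately with the offending list.
    """
    config = config or PipelineConfig()
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    if len(demultiplexed) == 0:
        raise EmptyResultError("run_from_demultiplexed: empty demultiplex table")
    dangling = [
        p
        for col in ("reads_1", "reads_2")
        for p in demultiplexed[col]
        if not Path(p).exists()
    ]
    if dangling:
        raise PipelineError(f"missing FASTQ file(s): {dangling}")

    _stage_sidecar(run_dir, config)

    _banner("filter and trim")
    flt_reads = filter_trim(demultiplexed, marker_trim, run_dir, config)
    _banner("downsampling")
    sub_reads = downsample_reads(flt_reads, run_dir, config)
    if len(sub_reads) == 0:
        raise EmptyResultError(
            "downsampling: every combination below min_read_count"
        )
    _banner("ASV estimation")
    seq_tbl = build_seq_table(sub_reads, run_dir, config)
    if len(seq_tbl) == 0:
        raise EmptyResultError("ASV estimation: no merged sequences")
    _banner("filtering haplotype sequence")
    seq_ann_tbl = annotate_seq_tbl(seq_tbl, markers, run_dir, config)
    seq_flt_tbl, variant_table = sequence_filter(
        seq_ann_tbl, manifest, markers, run_dir, run_dir / "vcf", config
    )
    ledger = _build_ledger(demultiplexed, flt_reads, sub_reads, seq_flt_tbl)
    ledger.write(run_dir / "read_tracking.tsv")

    report_path = None
    if make_report:
        _banner("generating report")
        report_path = generate_report(
            run_dir / "report" / "Report.html",
            manifest,
            markers,
            config,
            demultiplexed=demultiplexed,
            flt_reads=flt_reads,
            sub_reads=sub_reads,
            seq_ann_tbl=seq_ann_tbl,
            seq_flt_tbl=seq_flt_tbl,
            variant_table=variant_table,
            ledger=ledger,
        )
        logger.info('report saved to "%s"', report_path)
    return RunResult(
        demultiplexed, flt_reads, sub_reads, seq_tbl, seq_ann_tbl,
        seq_flt_tbl, variant_table, ledger, report_path,
    )


def process_run(
    reads_1,
    reads_2,
    manifest: SampleManifest,
    markers: MarkerInfo,
    run_dir,
    config: Optional[PipelineConfig] = None,
    marker_trim: Optional[pd.DataFrame] = None,
    make_report: bool = True,
) -> RunResult:
    """Run the complete pipeline from pooled FASTQ input to the report."""
    config = config or PipelineConfig()
    run_dir = Path(run_dir)
    for p in (reads_1, reads_2):
        if not Path(p).exists():
            raise PipelineError(f"input FASTQ not found: {p}")
    _banner("processing run")
    _banner("demultiplexing")
    demultiplexed = demultiplex_reads(
        reads_1, reads_2, manifest, markers, run_dir, config
    )
    if len(demultiplexed) == 0:
        raise EmptyResultError("demultiplexing: no read pair assigned")
    return run_from_demultiplexed(
        demultiplexed, manifest, markers, run_dir, config, marker_trim, make_report
    )


def _stage_sidecar(run_dir: Path, config: PipelineConfig) -> None:
    config.write_json(run_dir / "config.json")
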