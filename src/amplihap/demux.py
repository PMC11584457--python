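"""Assign read pairs to (sample, marker) combinations and trim technical bases.

Each sample carries a unique dual barcode (``barcode_fwd`` on read 1,
``barcode_rev`` on read 2) and each marker a unique primer pair directly
downstream of the barcode.  A pair is assigned when the forward read begins
with ``barcode_fwd + primer_fwd`` and the reverse read with
``barcode_rev + primer_rev`` of the same (sample, marker); both prefixes are
then trimmed.  Matching is exact by default (``max_mismatch = 0``), with an
optional per-element Hamming tolerance applied to barcode and primer
independently.  Orientation is fixed: no swap search is attempted.

Matching precedence is barcode first (selects the sample), then primer
(selects the marker); pairs with a valid barcode but no primer match count
as unassigned.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from ._fastq import read_fastq_pairs, write_fastq
from .datamodel import MarkerInfo, PipelineConfig, SampleManifest, write_table

logger = logging.getLogger(__name__)

DEMUX_COLUMNS = ["sample_id", "marker_id", "reads_1", "reads_2", "n", "sample", "info"]


def _hamming_le(a: str, b: str, k: int) -> bool:
    """True if Hamming(a, b) <= k; strings must be equal length."""
    if k == 0:
        return a == b
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > k:
                return False
    return True


def demultiplex_reads(
    reads_1,
    reads_2,
    manifest: SampleManifest,
    markers: MarkerInfo,
    out_dir,
    config: Optional[PipelineConfig] = None,
    write_undetermined: bool = False,
) -> pd.DataFrame:
    """Demultiplex a pooled read-pair file set into per-combination FASTQs.

    Returns the demultiplex table (sample_id, marker_id, reads_1, reads_2,
    n, sample, info) with one row per combination that received at least
    one pair; it is also written to ``<out_dir>/demultiplex.tsv`` and the
    trimmed pairs to ``<out_dir>/demultiplex/<sample>_<marker>_R{1,2}.fastq.gz``.
    """
    config = config or PipelineConfig()
    max_mm = config.max_mismatch
    out_dir = Path(out_dir)
    sub_dir = out_dir / "demultiplex"
    sub_dir.mkdir(parents=True, exist_ok=True)

    mdf = manifest.data
    kdf = markers.data
    bf_len = manifest.barcode_fwd_len
    br_len = manifest.barcode_rev_len
    barcode_map = {
        (r["barcode_fwd"], r["barcode_rev"]): r["sample_id"]
        for _, r in mdf.iterrows()
    }
    sample_meta = mdf.set_index("sample_id")[["sample", "info"]]
    primer_list = [
        (r["marker_id"], r["primer_fwd"], r["primer_rev"]) for _, r in kdf.iterrows()
    ]

    buffers: dict = {}
    counts: dict = {}
    undetermined = []
    total = 0

    for (t1, s1, q1), (t2, s2, q2) in read_fastq_pairs(reads_1, reads_2):
        total += 1
        sample_id = _match_sample(
            s1, s2, bf_len, br_len, barcode_map, mdf, max_mm
        )
        marker_id = None
        if sample_id is not None:
            for mid, pf, pr in primer_list:
                if _hamming_le(s1[bf_len : bf_len + len(pf)], pf, max_mm) and _hamming_le(
                    s2[br_len : br_len + len(pr)], pr, max_mm
                ):
                    assert marker_id is None, "ambiguous marker assignment"
                    marker_id = mid
                    trim1 = bf_len + len(pf)
                    trim2 = br_len + len(pr)
        if sample_id is None or marker_id is None:
            if write_undetermined:
                undetermined.append(((t1, s1, q1), (t2, s2, q2)))
            continue
        key = (sample_id, marker_id)
        buf = buffers.setdefault(key, ([], []))
        buf[0].append((t1, s1[trim1:], q1[trim1:]))
        buf[1].append((t2, s2[trim2:], q2[trim2:]))
        counts[key] = counts.get(key, 0) + 1

    rows = []
    for _, mrow in mdf.iterrows():
        for _, krow in kdf.iterrows():
            key = (mrow["sample_id"], krow["marker_id"])
            if key not in buffers:
                continue
            r1 = sub_dir / f"{key[0]}_{key[1]}_R1.fastq.gz"
            r2 = sub_dir / f"{key[0]}_{key[1]}_R2.fastq.gz"
            write_fastq(r1, buffers[key][0])
            write_fastq(r2, buffers[key][1])
            rows.append(
                {
                    "sample_id": key[0],
                    "marker_id": key[1],
                    "reads_1": str(r1),
                    "reads_2": str(r2),
                    "n": counts[key],
                    "sample": sample_meta.loc[key[0], "sample"],
                    "info": sample_meta.loc[key[0], "info"],
                }
            )

    if write_undetermined and undetermined:
        write_fastq(sub_dir / "undetermined_R1.fastq.gz", (p[0] for p in undetermined))
        write_fastq(sub_dir / "undetermined_R2.fastq.gz", (p[1] for p in undetermined))

    table = pd.DataFrame(rows, columns=DEMUX_COLUMNS)
    assigned = int(table["n"].sum()) if len(table) else 0
    logger.info("%d of %d reads demultiplexed successfully.", assigned, total)
    write_table(table, out_dir / "demultiplex.tsv")
    return table


def _match_sample(s1, s2, bf_len, br_len, barcode_map, mdf, max_mm):
    key = (s1[:bf_len], s2[:br_len])
    hit = barcode_map.get(key)
    if hit is not None or max_mm == 0:
        return hit
    matches = [
        r["sample_id"]
        for _, r in mdf.iterrows()
        if _hamming_le(key[0], r["barcode_fwd"], max_mm)
        and _hamming_le(key[1], r["barcode_rev"], max_mm)
    ]
    if len(matches) == 1:
        return matches[0]
    return None  # none, or ambiguous under mismatch tolerance
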