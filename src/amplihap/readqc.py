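"""Per-cycle quality profiling, quality filtering, and exact downsampling.

Quality filtering keeps a read pair iff neither read contains an ``N`` and
each read's expected error count (sum of 10^(-Q/10) over its bases, after
any positional truncation) is at most ``max_expected_errors``.  Both mates
are kept or dropped together, preserving pair synchrony.

Downsampling draws exactly ``n_sample`` pairs without replacement from
combinations that exceed it, using a PRNG stream keyed by
``(seed, sample_id, marker_id)`` so per-combination results do not depend
on table order.
"""

from __future__ import annotations

import zlib
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._fastq import expected_errors, read_fastq, read_fastq_pairs, write_fastq, PHRED_OFFSET
from .datamodel import MarkerInfo, PipelineConfig, write_table
from .errors import ValidationError


def quality_profile(demux: pd.DataFrame) -> dict:
    """Aggregate per-cycle quality over samples, per marker and direction.

    Returns ``{marker_id: {"fwd": DataFrame, "rev": DataFrame}}`` where each
    DataFrame is indexed by cycle (1-based) with one column per Phred score
    holding the proportion of reads at that score, plus a ``mean`` column.
    An empty combination yields a 0-cycle frame (flagged by being empty).
    """
    profiles: dict = {}
    for marker_id, grp in demux.groupby("marker_id", sort=True):
        out = {}
        for direction, col in (("fwd", "reads_1"), ("rev", "reads_2")):
            counts: dict = {}
            for path in grp[col]:
                for _, _, qual in read_fastq(path):
                    for cycle, ch in enumerate(qual, start=1):
                        q = ord(ch) - PHRED_OFFSET
                        counts[(cycle, q)] = counts.get((cycle, q), 0) + 1
            out[direction] = _profile_frame(counts)
        profiles[marker_id] = out
    return profiles


def _profile_frame(counts: dict) -> pd.DataFrame:
    if not counts:
        return pd.DataFrame(columns=["mean"]).rename_axis("cycle")
    cycles = sorted({c for c, _ in counts})
    scores = sorted({q for _, q in counts})
    mat = np.zeros((len(cycles), len(scores)))
    for (c, q), n in counts.items():
        mat[cycles.index(c), scores.index(q)] = n
    totals = mat.sum(axis=1, keepdims=True)
    props = mat / totals
    df = pd.DataFrame(props, index=pd.Index(cycles, name="cycle"), columns=scores)
    df["mean"] = (mat * np.array(scores)).sum(axis=1) / totals.ravel()
    return df


def filter_trim(
    demux: pd.DataFrame,
    marker_trim: Optional[pd.DataFrame],
    out_dir,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Quality-filter (and positionally truncate) each demultiplexed pair file.

    ``marker_trim``, when given, is a frame with columns
    (marker_id, trim_fwd, trim_rev): reads are truncated at those cycle
    positions before the expected-error test.  Returns the input table with
    new file paths plus ``n_in`` / ``n_out`` columns; also written to
    ``filtered_reads.tsv``.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    sub_dir = out_dir / "filter"
    sub_dir.mkdir(parents=True, exist_ok=True)

    trims = {}
    if marker_trim is not None and len(marker_trim):
        for _, r in marker_trim.iterrows():
            trims[str(r["marker_id"])] = (int(r["trim_fwd"]), int(r["trim_rev"]))

    rows = []
    for _, row in demux.iterrows():
        trim = trims.get(row["marker_id"])
        kept1, kept2 = [], []
        n_in = 0
        for (t1, s1, q1), (t2, s2, q2) in read_fastq_pairs(row["reads_1"], row["reads_2"]):
            n_in += 1
            if trim is not None:
                tf, tr = trim
                if tf > len(s1) or tr > len(s2):
                    raise ValidationError(
                        f"marker {row['marker_id']}: trim position beyond read length"
                    )
                s1, q1 = s1[:tf], q1[:tf]
                s2, q2 = s2[:tr], q2[:tr]
            if "N" in s1 or "N" in s2:
                continue
            if expected_errors(q1) > config.max_expected_errors:
                continue
            if expected_errors(q2) > config.max_expected_errors:
                continue
            kept1.append((t1, s1, q1))
            kept2.append((t2, s2, q2))
        r1 = sub_dir / f"{row['sample_id']}_{row['marker_id']}_R1.fastq.gz"
        r2 = sub_dir / f"{row['sample_id']}_{row['marker_id']}_R2.fastq.gz"
        write_fastq(r1, kept1)
        write_fastq(r2, kept2)
        out = row.to_dict()
        out.update(reads_1=str(r1), reads_2=str(r2), n_in=n_in, n_out=len(kept1))
        rows.append(out)

    table = pd.DataFrame(rows)
    write_table(table, out_dir / "filtered_reads.tsv")
    return table


def _combination_rng(seed: int, sample_id: str, marker_id: str) -> np.random.Generator:
    """Deterministic per-combination stream, independent of table order."""
    tag = zlib.crc32(f"{sample_id}\t{marker_id}".encode())
    return np.random.default_rng([seed, tag])


def sample_indices(n_total: int, n_keep: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform without-replacement draw of ``n_keep`` sorted indices."""
    idx = rng.choice(n_total, size=n_keep, replace=False)
    idx.sort()
    return idx


def downsample_reads(
    filtered: pd.DataFrame,
    out_dir,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Downsample each combination to at most ``n_sample`` pairs.

    Combinations with fewer than ``min_read_count`` surviving pairs are
    dropped (a threshold of 0 disables that); combinations above
    ``n_sample`` are sampled without replacement to exactly ``n_sample``.
    Output column ``n`` is ``min(n_out, n_sample)``.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    sub_dir = out_dir / "downsample"
    sub_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for _, row in filtered.iterrows():
        n_out = int(row["n_out"])
        if n_out < config.min_read_count:
            continue
        r1 = sub_dir / f"{row['sample_id']}_{row['marker_id']}_R1.fastq.gz"
        r2 = sub_dir / f"{row['sample_id']}_{row['marker_id']}_R2.fastq.gz"
        if n_out > config.n_sample:
            rng = _combination_rng(config.seed, row["sample_id"], row["marker_id"])
            keep = set(sample_indices(n_out, config.n_sample, rng).tolist())
            pairs = [
                p
                for i, p in enumerate(read_fastq_pairs(row["reads_1"], row["reads_2"]))
                if i in keep
            ]
            write_fastq(r1, (p[0] for p in pairs))
            write_fastq(r2, (p[1] for p in pairs))
            n = config.n_sample
        else:
            # pass-through: copy to keep the stage directory self-contained
            pairs = list(read_fastq_pairs(row["reads_1"], row["reads_2"]))
            write_fastq(r1, (p[0] for p in pairs))
            write_fastq(r2, (p[1] for p in pairs))
            n = n_out
        out = {
            "sample_id": row["sample_id"],
            "marker_id": row["marker_id"],
            "sample": row["sample"],
            "info": row["info"],
            "reads_1": str(r1),
            "reads_2": str(r2),
            "n_out": n_out,
            "n": n,
        }
        rows.append(out)

    table = pd.DataFrame(rows)
    write_table(table, out_dir / "subsampled_reads.tsv")
    return table
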