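"""Haplotype quality annotation: similarity, z-standardization, chimeras, status.

Each candidate haplotype is scored against its marker reference
(``ident``), that similarity is standardized *per marker* across the whole
dataset (``ident_z``), PCR chimeras are flagged by a parent:child abundance
and mosaic-tiling test, and every row receives a status label.  All rows
are retained with their status; filtering to passing rows happens
downstream.

Status semantics: exactly one failed check gives that check's label;
two or more give ``multiple``; none gives ``pass``.
"""

from __future__ import annotations

from itertools import combinations
from typing import List, Optional

import numpy as np
import pandas as pd

from .align import align_to_reference, project_to_reference
from .datamodel import MarkerInfo, PipelineConfig, write_table
from .errors import ValidationError

SEQ_ANN_COLUMNS = [
    "sample_id", "marker_id", "sequence", "count", "status",
    "sample", "info", "ident", "ident_z",
]


def standardize_ident(idents) -> np.ndarray:
    """Z-score a marker's similarity values with sample (n-1) sd.

    When the sd is zero (all values equal, or a single row) every z is 0.
    """
    x = np.asarray(idents, dtype=float)
    if len(x) < 2:
        return np.zeros_like(x)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def min_breakpoints(child: str, parent_a: str, parent_b: str) -> Optional[int]:
    """Minimal number of switch points tiling ``child`` from two parents.

    All three strings must live in the same column space (equal length).
    Returns ``None`` when some column of the child matches neither parent
    (no exact mosaic exists).  A child identical to a single parent needs 0
    switches.  The greedy scan (keep the running set of parents consistent
    with the segment so far; start a new segment when it empties) is optimal
    for this minimal-segmentation problem.
    """
    assert len(child) == len(parent_a) == len(parent_b)
    feasible = {0, 1}
    switches = 0
    started = False
    for c, a, b in zip(child, parent_a, parent_b):
        here = set()
        if c == a:
            here.add(0)
        if c == b:
            here.add(1)
        if not here:
            return None
        if not started:
            feasible = here
            started = True
            continue
        nxt = feasible & here
        if nxt:
            feasible = nxt
        else:
            switches += 1
            feasible = here
    return switches


def detect_chimeras(
    group: pd.DataFrame,
    ref: str,
    max_breakpoints: int,
    min_parent_ratio: float,
) -> List[bool]:
    """Flag chimeric rows within one (sample, marker) combination.

    A row is a chimera iff two parent rows exist in the same combination,
    each with count >= ``min_parent_ratio`` x the child count, whose mosaic
    (in reference column space) reproduces the child exactly with between 1
    and ``max_breakpoints`` switch points.
    """
    seqs = list(group["sequence"])
    counts = list(group["count"])
    proj = [project_to_reference(s, ref) for s in seqs]
    flags = [False] * len(seqs)
    for i in range(len(seqs)):
        parents = [
            j
            for j in range(len(seqs))
            if j != i and counts[j] >= min_parent_ratio * counts[i]
        ]
        if len(parents) < 2:
            continue
        for j, k in combinations(parents, 2):
            bp = min_breakpoints(proj[i], proj[j], proj[k])
            if bp is not None and 1 <= bp <= max_breakpoints:
                flags[i] = True
                break
    return flags


def annotate_seq_tbl(
    seq_tbl: pd.DataFrame,
    markers: MarkerInfo,
    out_dir=None,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Annotate the ASV table with ident, ident_z, and status labels.

    Fail conditions per row: combination read total < ``min_read_count``
    (low_sample_count); count < ``min_asv_count`` (low_asv_count);
    within-combination frequency < ``min_asv_freq`` (low_asv_freq);
    ident < ``min_ident`` (low_ident); ident_z < ``min_ident_z``
    (low_ident_z); mosaic test (chimera).
    """
    config = config or PipelineConfig()
    if len(seq_tbl) == 0:
        raise ValidationError("annotate_seq_tbl: empty sequence table")
    unknown = set(seq_tbl["marker_id"]) - set(markers.marker_ids)
    if unknown:
        raise ValidationError(f"markers absent from marker info: {sorted(unknown)}")

    df = seq_tbl.copy().reset_index(drop=True)
    refs = {m: markers.reference(m) for m in set(df["marker_id"])}
    df["ident"] = [
        align_to_reference(s, refs[m]).ident
        for s, m in zip(df["sequence"], df["marker_id"])
    ]
    df["ident_z"] = 0.0
    for marker_id, grp in df.groupby("marker_id"):
        df.loc[grp.index, "ident_z"] = standardize_ident(grp["ident"].to_numpy())

    combo_total = df.groupby(["sample_id", "marker_id"])["count"].transform("sum")

    chim = np.zeros(len(df), dtype=bool)
    for (_, marker_id), grp in df.groupby(["sample_id", "marker_id"]):
        flags = detect_chimeras(
            grp, refs[marker_id], config.max_breakpoints, config.min_parent_ratio
        )
        chim[grp.index] = flags

    statuses = []
    for i, row in df.iterrows():
        fails = []
        if combo_total.iloc[i] < config.min_read_count:
            fails.append("low_sample_count")
        if row["count"] < config.min_asv_count:
            fails.append("low_asv_count")
        if row["count"] / combo_total.iloc[i] < config.min_asv_freq:
            fails.append("low_asv_freq")
        if row["ident"] < config.min_ident:
            fails.append("low_ident")
        if row["ident_z"] < config.min_ident_z:
            fails.append("low_ident_z")
        if chim[i]:
            fails.append("chimera")
        if not fails:
            statuses.append("pass")
        elif len(fails) == 1:
            statuses.append(fails[0])
        else:
            statuses.append("multiple")
    df["status"] = statuses
    df = df[SEQ_ANN_COLUMNS]
    if out_dir is not None:
        from pathlib import Path

        write_table(df, Path(out_dir) / "seq_ann_tbl.tsv")
    return df
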