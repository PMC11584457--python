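"""Dereplication, denoising, and paired-end merging into an ASV table.

The denoiser is a greedy pass in the UNOISE2 family: uniques are visited
in descending abundance and a unique *u* is absorbed into an
already-accepted center *c* when all of the following hold at edit
distance ``d = edit_distance(u, c) <= d_max``:

1. skew: ``abundance(u) / abundance(c) <= beta(d) = 1 / 2**(alpha * d + 1)``
   — an error lineage is rare relative to its source template;
2. error-model plausibility: ``abundance(u)`` is consistent with the
   number of reads expected to mutate from *c* into exactly *u*'s sequence,
   ``Poisson(abundance(c) * (eps/3)**d)`` with the per-base substitution
   rate ``eps`` estimated from the distance-1 neighborhood of the most
   abundant unique (an explicit rate can be supplied instead).  A unique
   whose count is implausibly high for an error lineage
   (``P(X >= count) < p_new``) is a genuine variant and becomes a center
   even when the skew test alone would absorb it.

A small-count floor (default 3) absorbs near-singleton uniques into the
nearest center unconditionally, so a low-frequency true haplotype keeps
its own error tail.  Skew alone cannot separate a minor clone at ~0.1%
within-sample frequency (abundance ratio 1e-3) from a single-error child
(expected ratio eps/3); condition 2 is what preserves single-nucleotide
resolution down to that regime while still absorbing error reads, and it
tolerates indels because distances are Levenshtein.

Forward and reverse reads are denoised independently; each read pair then
votes for its (forward-center, reverse-center) pair, and center pairs with
at least ``min_asv_count`` votes are merged into full-length haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import edlib
import pandas as pd

from ._fastq import read_fastq_pairs
from .datamodel import PipelineConfig, write_table

logger = logging.getLogger(__name__)

SEQ_TBL_COLUMNS = ["sample_id", "marker_id", "sequence", "count", "status", "sample", "info"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class UniqueSet:
    """Exact-sequence uniques with abundances, sorted by descending abundance."""

    sequences: List[str]
    abundances: List[int]

    def __len__(self):
        return len(self.sequences)

    @property
    def total(self) -> int:
        return sum(self.abundances)


def _derep_one(seqs) -> UniqueSet:
    counts: Dict[str, int] = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return UniqueSet([s for s, _ in items], [n for _, n in items])


def dereplicate(reads_1, reads_2) -> Tuple[UniqueSet, UniqueSet]:
    """Collapse a synchronized pair of FASTQ files to per-direction uniques."""
    fwd, rev = [], []
    for (_, s1, _), (_, s2, _) in read_fastq_pairs(reads_1, reads_2):
        fwd.append(s1)
        rev.append(s2)
    return _derep_one(fwd), _derep_one(rev)


def beta(d: int, alpha: float) -> float:
    """Maximum child:parent abundance ratio at edit distance ``d``."""
    return 1.0 / 2.0 ** (alpha * d + 1.0)


def estimate_error_rate(uniques: UniqueSet) -> float:
    """Per-base substitution rate from the top unique's distance-1 children.

    The expected total abundance of single-edit neighbors of the dominant
    template is ``a_top * L * eps`` for read length L, so the ratio of
    observed neighbor abundance to ``a_top * L`` estimates ``eps``.  A
    co-occurring true variant at distance 1 inflates the estimate slightly,
    which only makes absorption more conservative where the variant is
    abundant enough not to need protection.
    """
    if len(uniques) < 2:
        return 0.0
    top = uniques.sequences[0]
    a_top = uniques.abundances[0]
    if a_top == 0 or len(top) == 0:
        return 0.0
    sigma = 0
    for s, a in zip(uniques.sequences[1:], uniques.abundances[1:]):
        res = edlib.align(s, top, task="distance", k=1)
        if res["editDistance"] == 1:
            sigma += a
    return sigma / (a_top * len(top))


def denoise(
    uniques: UniqueSet,
    alpha: float = 2.0,
    d_max: int = 10,
    error_rate: Optional[float] = None,
    p_new: float = 0.01,
    small_count_floor: int = 3,
) -> Tuple[UniqueSet, Dict[str, str]]:
    """Greedy abundance-skew + error-model denoising.

    Returns the denoised centers (with corrected abundances, re-sorted by
    descending abundance) and the absorption map ``sequence -> center``.
    A center can absorb a unique when the skew rule *and* the Poisson
    error-model plausibility both hold (see module docstring), or
    unconditionally when the unique's count is at most
    ``small_count_floor``.  Candidate centers are ranked by (edit distance,
    descending current abundance, lexicographic sequence); the first
    eligible one absorbs.  With ``error_rate`` unset it is estimated from
    the uniques themselves.
    """
    from scipy.stats import poisson

    if error_rate is None:
        error_rate = estimate_error_rate(uniques)
    mu = error_rate / 3.0  # rate of one specific substitution at one site

    centers: List[str] = []
    abundance: Dict[str, int] = {}
    assignment: Dict[str, str] = {}
    order = sorted(
        zip(uniques.sequences, uniques.abundances), key=lambda kv: (-kv[1], kv[0])
    )
    for seq, count in order:
        best = None  # (distance, -abundance, center)
        for c in centers:
            res = edlib.align(seq, c, task="distance", k=d_max)
            d = res["editDistance"]
            if d < 0:  # beyond d_max
                continue
            if count <= small_count_floor:
                eligible = True
            else:
                skew_ok = count / abundance[c] <= beta(d, alpha)
                lam = abundance[c] * mu**d
                plausible = poisson.sf(count - 1, lam) >= p_new
                eligible = skew_ok and plausible
            if eligible:
                key = (d, -abundance[c], c)
                if best is None or key < best:
                    best = key
        if best is None:
            centers.append(seq)
            abundance[seq] = count
            assignment[seq] = seq
        else:
            c = best[2]
            abundance[c] += count
            assignment[seq] = c
    items = sorted(abundance.items(), key=lambda kv: (-kv[1], kv[0]))
    out = UniqueSet([s for s, _ in items], [n for _, n in items])
    return out, assignment


def merge_pairs(fwd: str, rev: str, min_overlap: int, max_mismatch: int = 0) -> Optional[str]:
    """Merge a forward and a (sequencing-orientation) reverse sequence.

    With ``min_overlap == -1`` the reverse complement is simply concatenated
    (non-overlapping read design).  Otherwise the maximal suffix/prefix
    overlap of at least ``min_overlap`` bases with at most ``max_mismatch``
    mismatches is fused; ``None`` when no overlap qualifies.
    """
    rc = revcomp(rev)
    if min_overlap == -1:
        return fwd + rc
    for olen in range(min(len(fwd), len(rc)), min_overlap - 1, -1):
        a = fwd[len(fwd) - olen :]
        b = rc[:olen]
        if max_mismatch == 0:
            if a == b:
                return fwd + rc[olen:]
        else:
            mism = sum(x != y for x, y in zip(a, b))
            if mism <= max_mismatch:
                return fwd + rc[olen:]
    return None


def build_seq_table(
    downsampled: pd.DataFrame,
    out_dir=None,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Construct the amplicon sequence table from downsampled pair files.

    Per combination: dereplicate and denoise each direction, let each read
    pair vote for its (fwd-center, rev-center) pair, merge center pairs
    with >= ``min_asv_count`` votes, and aggregate identical merged
    sequences.  Rows start with status ``pass``.
    """
    config = config or PipelineConfig()
    rows = []
    for _, row in downsampled.iterrows():
        pairs = [
            (s1, s2)
            for (_, s1, _), (_, s2, _) in read_fastq_pairs(row["reads_1"], row["reads_2"])
        ]
        if not pairs:
            logger.info(
                "combination (%s, %s): no reads, omitted",
                row["sample_id"], row["marker_id"],
            )
            continue
        fwd_u = _derep_one(s for s, _ in pairs)
        rev_u = _derep_one(s for _, s in pairs)
        _, fwd_map = denoise(fwd_u, config.denoise_alpha, config.denoise_d_max)
        _, rev_map = denoise(rev_u, config.denoise_alpha, config.denoise_d_max)
        votes: Dict[Tuple[str, str], int] = {}
        for s1, s2 in pairs:
            key = (fwd_map[s1], rev_map[s2])
            votes[key] = votes.get(key, 0) + 1
        merged_counts: Dict[str, int] = {}
        for (fc, rc_), n in votes.items():
            if n < config.min_asv_count:
                continue
            merged = merge_pairs(fc, rc_, config.min_overlap, config.merge_max_mismatch)
            if merged is None:
                continue
            merged_counts[merged] = merged_counts.get(merged, 0) + n
        if not merged_counts:
            logger.info(
                "combination (%s, %s): zero merged sequences, omitted",
                row["sample_id"], row["marker_id"],
            )
            continue
        for seq, n in sorted(merged_counts.items(), key=lambda kv: (-kv[1], kv[0])):
            rows.append(
                {
                    "sample_id": row["sample_id"],
                    "marker_id": row["marker_id"],
                    "sequence": seq,
                    "count": n,
                    "status": "pass",
                    "sample": row["sample"],
                    "info": row["info"],
                }
            )
    table = pd.DataFrame(rows, columns=SEQ_TBL_COLUMNS)
    if out_dir is not None:
        from pathlib import Path

        write_table(table, Path(out_dir) / "seq_tbl.tsv")
    return table
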