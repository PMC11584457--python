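"""Global alignment of haplotypes to marker references.

Alignment is end-to-end Needleman-Wunsch with match +1, mismatch -1,
gap open -2, gap extend -1 (affine).  Percent identity counts identical
columns over the full alignment length, gaps included in the denominator,
so a 3-nt deletion against a 120-nt reference gives 117/120.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict

from Bio import Align

_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-1,
)


@dataclass(frozen=True)
class AlignmentResult:
    aligned_seq: str
    aligned_ref: str
    ident: float

    def __post_init__(self):
        assert len(self.aligned_seq) == len(self.aligned_ref)


@lru_cache(maxsize=65536)
def align_to_reference(seq: str, ref: str) -> AlignmentResult:
    """Globally align ``seq`` against ``ref`` and compute fraction identity."""
    if not seq or not ref:
        raise ValueError("align_to_reference requires nonempty sequences")
    aln = _aligner.align(seq, ref)[0]
    a, r = str(aln[0]), str(aln[1])
    ident = sum(x == y for x, y in zip(a, r)) / len(a)
    return AlignmentResult(a, r, ident)


def project_to_reference(seq: str, ref: str) -> str:
    """Render ``seq`` in reference coordinates: one character per reference
    base ('-' where the haplotype has a deletion; insertions are dropped).

    This gives every haplotype of a marker a common column space, which the
    chimera mosaic test and the variant caller operate in.
    """
    res = align_to_reference(seq, ref)
    out = []
    for a, r in zip(res.aligned_seq, res.aligned_ref):
        if r != "-":
            out.append(a)
    return "".join(out)


def mask_bases(seq: str, ref: str, replacements: Dict[int, str]) -> str:
    """Replace the haplotype base aligned to given reference offsets.

    ``replacements`` maps 0-based reference offsets to the base to put
    there.  Offsets where the haplotype has a deletion are skipped, and
    insertions are carried through untouched, so the sequence length never
    changes for substitution-only edits.
    """
    res = align_to_reference(seq, ref)
    out = []
    ref_pos = 0
    for a, r in zip(res.aligned_seq, res.aligned_ref):
        if r == "-":  # insertion in seq
            out.append(a)
            continue
        if a != "-":
            out.append(replacements.get(ref_pos, a))
        ref_pos += 1
    return "".join(out)
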