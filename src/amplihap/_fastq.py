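"""Thin FASTQ I/O helpers shared by the pipeline stages.

Reading goes through Biopython's ``FastqGeneralIterator`` (the fast path that
yields ``(title, sequence, quality)`` string triples); writing is plain
4-line records.  Files ending in ``.gz`` are transparently (de)compressed.
"""

from __future__ import annotations

import gzip
import io
import os
from contextlib import contextmanager
from typing import Iterable, Iterator, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import DesyncError

PHRED_OFFSET = 33

FastqRecord = Tuple[str, str, str]  # (title, sequence, quality string)


@contextmanager
def _open_text(path, mode: str):
    if str(path).endswith(".gz"):
        if mode == "w":
            # pin mtime so identical content gives byte-identical files
            with open(path, "wb") as raw:
                with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
                    with io.TextIOWrapper(gz, encoding="ascii") as fh:
                        yield fh
        else:
            with gzip.open(path, mode + "t") as fh:
                yield fh
    else:
        with open(path, mode) as fh:
            yield fh


def read_fastq(path) -> Iterator[FastqRecord]:
    """Yield ``(title, seq, qual)`` for every record in a FASTQ(.gz) file."""
    with _open_text(path, "r") as fh:
        yield from FastqGeneralIterator(fh)


def read_fastq_pairs(path_1, path_2) -> Iterator[Tuple[FastqRecord, FastqRecord]]:
    """Yield synchronized read pairs; raise :class:`DesyncError` on mismatch.

    Pair ids must agree up to the first whitespace and an optional trailing
    ``/1`` / ``/2`` suffix.
    """
    with _open_text(path_1, "r") as fh1, _open_text(path_2, "r") as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for rec1 in it1:
            try:
                rec2 = next(it2)
            except StopIteration:
                raise DesyncError(f"{path_2} has fewer records than {path_1}")
            if _pair_id(rec1[0]) != _pair_id(rec2[0]):
                raise DesyncError(
                    f"read id mismatch: {rec1[0]!r} vs {rec2[0]!r}"
                )
            yield rec1, rec2
        try:
            next(it2)
        except StopIteration:
            pass
        else:
            raise DesyncError(f"{path_1} has fewer records than {path_2}")


def _pair_id(title: str) -> str:
    name = title.split()[0]
    if name.endswith("/1") or name.endswith("/2"):
        name = name[:-2]
    return name


def write_fastq(path, records: Iterable[FastqRecord]) -> int:
    """Write records to a FASTQ(.gz) file; return the record count."""
    os.makedirs(os.path.dirname(os.fspath(path)) or ".", exist_ok=True)
    n = 0
    with _open_text(path, "w") as fh:
        for title, seq, qual in records:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def count_fastq(path) -> int:
    return sum(1 for _ in read_fastq(path))


def expected_errors(qual: str) -> float:
    """Sum of per-base error probabilities, 10^(-Q/10), for a quality string."""
    return sum(_EE_TABLE[ord(c) - PHRED_OFFSET] for c in qual)


_EE_TABLE = [10.0 ** (-q / 10.0) for q in range(94)]
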