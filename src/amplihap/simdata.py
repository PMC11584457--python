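"""Synthetic multiplexed amplicon datasets with known per-read truth.

The generator emulates a dual-barcoded Illumina amplicon run over defined
two-haplotype mixtures: for each (sample, marker) combination it draws each
read pair's source haplotype binomially from the mixture ratio, builds the
fragment ``barcode + primer + haplotype`` (and the reverse-complement
analogue on the mate), and emits fixed-length reads with a linear Phred
quality decay, per-base substitution/indel errors in the insert, and
configurable rates of PCR chimeras (two-haplotype mosaics with one interior
breakpoint) and spurious homopolymer indels.  Every simulated pair is
recorded in a truth table (source haplotype + artifact label), which is
sufficient to score demultiplexing, denoising, and chimera detection
exactly.

Technical bases (barcode and primer) are emitted error-free; sequencing
errors are confined to the insert.  Real runs accumulate errors in
technical bases too — that aspect (and ART-style empirical error profiles)
is deliberately not modelled.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._fastq import write_fastq, PHRED_OFFSET
from .asv import revcomp
from .datamodel import MarkerInfo, SampleManifest, write_table
from .errors import ValidationError

_BASES = "ACGT"

# -- built-in two-allele marker panel for the bundled five-sample mixture
#    design (two 120-nt P. falciparum surface-antigen amplicons, CSP and
#    TRAP, each with a reference allele and an alternate allele differing
#    by 1-2 substitutions; primer tails and reference fillers are synthetic)

CSP_REF = (
    "CCCAAATGCAAACCCAAATG"
    "ATTGTTTAGCCTTATACCTTTGTAGTTCTGCTTTAATCCTATCGTCACATAAGGACCGCC"
    "TTACACACATAGACTCTCCCTCCCGCCGTGCTCCCAAATT"
)
CSP_ALT = CSP_REF[:3] + "C" + CSP_REF[4:60] + "T" + CSP_REF[61:]  # CCCC... prefix
TRAP_REF = (
    "TGGGTGAACCATGCAGTACC"
    "CAGGAATGCTAAGCATGGTGGCAGCGTAGCCTAGACATTAACCCCGTTATGTGCCGGGCC"
    "ACTGATAGGCTTTTCGTTTTATGCTCTTGGCAAGTAGACG"
)
TRAP_ALT = TRAP_REF[:8] + "G" + TRAP_REF[9:]  # TGGGTGAAG... prefix

DATASET1_MARKERS = pd.DataFrame(
    {
        "marker_id": ["CSP", "TRAP"],
        "primer_fwd": ["GTGGAGTATGTCCGTAACT", "CTTCTACGTCTTACAAAGG"],
        "primer_rev": ["CTAGCATACTAGGCAGTAA", "CGTGATCGAAAGCATCGGC"],
        "seq": [CSP_REF, TRAP_REF],
        "chrom": ["Pf3D7_03_v3", "Pf3D7_13_v3"],
        "start": [222253, 1465085],
        "end": [222372, 1465204],
    }
)

DATASET1_MANIFEST = pd.DataFrame(
    {
        "sample_id": ["S01", "S02", "S03", "S04", "S05"],
        "barcode_fwd": ["ATCGCTAT", "GTGACGAA", "CTATTGCA", "CGATCGAT", "AGAGGGAC"],
        "barcode_rev": ["TCTAATGT", "TTACAGCA", "GTGCTAAT", "GCACTTGT", "GCAAGCGT"],
        "sample": [
            "3D7_Dd2_1_1", "3D7_Dd2_1_10", "3D7_Dd2_1_100",
            "3D7_Dd2_1_500", "3D7_Dd2_1_1000",
        ],
        "info": ["1_1", "1_10", "1_100", "1_500", "1_1000"],
    }
)

DATASET1_RATIOS = [(1, 1), (1, 10), (1, 100), (1, 500), (1, 1000)]

DATASET1_ALT_HAPLOTYPES = {"CSP": CSP_ALT, "TRAP": TRAP_ALT}


@dataclass(frozen=True)
class MixtureSpec:
    """Study conditions for a simulated run.

    ``markers`` rows are ``{marker_id, ref_haplotype, alt_haplotype}``;
    ``samples`` rows are ``{sample_id, ratio}`` with ratio the
    (ref : alt) mixing proportion, e.g. ``(1, 1000)`` for a 1:1000 minor
    reference clone.
    """

    markers: Tuple[dict, ...]
    samples: Tuple[dict, ...]
    reads_per_combination: int = 10000
    read_length: int = 120
    sub_error_rate: float = 0.001
    indel_error_rate: float = 0.0001
    chimera_rate: float = 0.002
    homopolymer_indel_rate: float = 0.001
    quality_model: Tuple[int, int] = (38, 20)
    seed: int = 0

    def __post_init__(self):
        for name in ("sub_error_rate", "indel_error_rate", "chimera_rate",
                     "homopolymer_indel_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for s in self.samples:
            a, b = s["ratio"]
            if a <= 0 or b <= 0:
                raise ValidationError(f"ratio components must be positive: {s['ratio']}")
        for m in self.markers:
            if m["ref_haplotype"] == m["alt_haplotype"]:
                raise ValidationError(
                    f"marker {m['marker_id']}: alt haplotype equals ref"
                )


@dataclass
class SimulatedRun:
    reads_1: Path
    reads_2: Path
    truth: pd.DataFrame
    manifest: SampleManifest
    markers: MarkerInfo
    spec: MixtureSpec


def _quality_string(q_start: int, q_end: int, length: int) -> str:
    qs = np.rint(np.linspace(q_start, q_end, length)).astype(int)
    return "".join(chr(q + PHRED_OFFSET) for q in qs)


def _homopolymer_runs(seq: str, min_len: int = 3) -> List[Tuple[int, int, str]]:
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j, seq[i]))
        i = j
    return runs


def _mutate(seq: str, rng: np.random.Generator, sub_rate: float, indel_rate: float) -> Tuple[str, bool]:
    """Apply per-base substitution and indel errors; return (seq, changed)."""
    n_sub = rng.binomial(len(seq), sub_rate)
    n_indel = rng.binomial(len(seq), indel_rate)
    if n_sub == 0 and n_indel == 0:
        return seq, False
    chars = list(seq)
    for _ in range(n_sub):
        i = int(rng.integers(0, len(chars)))
        old = chars[i]
        choices = [b for b in _BASES if b != old]
        chars[i] = choices[int(rng.integers(0, 3))]
    for _ in range(n_indel):
        i = int(rng.integers(0, len(chars)))
        if rng.random() < 0.5 and len(chars) > 1:
            del chars[i]
        else:
            chars.insert(i, _BASES[int(rng.integers(0, 4))])
    return "".join(chars), True


def simulate_dataset(
    spec: MixtureSpec,
    manifest: SampleManifest,
    markers: MarkerInfo,
    out_dir,
) -> SimulatedRun:
    """Write pooled reads_1/reads_2 FASTQ(.gz) files and a truth table.

    Fragments are ``barcode + primer + insert`` on the forward side and
    ``barcode_rev + primer_rev + revcomp(insert)`` on the reverse side,
    truncated to ``read_length``; read order is shuffled deterministically
    by the spec seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mdf = manifest.data.set_index("sample_id")
    kdf = markers.data.set_index("marker_id")
    marker_specs = {m["marker_id"]: m for m in spec.markers}

    reads1: List[Tuple[str, str, str]] = []
    reads2: List[Tuple[str, str, str]] = []
    truth_rows = []

    for srow in spec.samples:
        sample_id = srow["sample_id"]
        a, b = srow["ratio"]
        p_ref = a / (a + b)
        bc_f = mdf.loc[sample_id, "barcode_fwd"]
        bc_r = mdf.loc[sample_id, "barcode_rev"]
        for marker_id, mspec in marker_specs.items():
            pf = kdf.loc[marker_id, "primer_fwd"]
            pr = kdf.loc[marker_id, "primer_rev"]
            tech_f = bc_f + pf
            tech_r = bc_r + pr
            min_len = max(len(tech_f), len(tech_r)) + 10
            if spec.read_length < min_len:
                raise ValidationError(
                    f"read_length {spec.read_length} shorter than "
                    f"barcode+primer+10 ({min_len}) for marker {marker_id}"
                )
            rng = np.random.default_rng(
                [spec.seed, zlib.crc32(f"{sample_id}:{marker_id}".encode())]
            )
            hap_ref = mspec["ref_haplotype"]
            hap_alt = mspec["alt_haplotype"]
            n = spec.reads_per_combination
            from_ref = rng.random(n) < p_ref
            art_draw = rng.random(n)
            qual_f = _quality_string(*spec.quality_model, spec.read_length)
            qual_r = qual_f
            for idx in range(n):
                source = "ref" if from_ref[idx] else "alt"
                template = hap_ref if from_ref[idx] else hap_alt
                artifact = "clean"
                if art_draw[idx] < spec.chimera_rate:
                    other = hap_alt if from_ref[idx] else hap_ref
                    bp = int(rng.integers(1, len(template) - 1))
                    template = template[:bp] + other[bp:]
                    artifact = "chimera"
                elif art_draw[idx] < spec.chimera_rate + spec.homopolymer_indel_rate:
                    runs = _homopolymer_runs(template)
                    if runs:
                        s, e, base = runs[int(rng.integers(0, len(runs)))]
                        if rng.random() < 0.5:
                            template = template[:s] + base + template[s:]
                        else:
                            template = template[:s] + template[s + 1 :]
                        artifact = "homopolymer"
                ins_f, err_f = _mutate(
                    template, rng, spec.sub_error_rate, spec.indel_error_rate
                )
                ins_r, err_r = _mutate(
                    revcomp(template), rng, spec.sub_error_rate, spec.indel_error_rate
                )
                if artifact == "clean" and (err_f or err_r):
                    artifact = "error"
                s1 = (tech_f + ins_f)[: spec.read_length]
                s2 = (tech_r + ins_r)[: spec.read_length]
                rid = f"{sample_id}:{marker_id}:{idx}"
                reads1.append((rid, s1, qual_f[: len(s1)]))
                reads2.append((rid, s2, qual_r[: len(s2)]))
                truth_rows.append(
                    {
                        "read_id": rid,
                        "sample_id": sample_id,
                        "marker_id": marker_id,
                        "haplotype": source,
                        "artifact": artifact,
                    }
                )

    order = np.random.default_rng([spec.seed, 0x5EED]).permutation(len(reads1))
    reads1 = [reads1[i] for i in order]
    reads2 = [reads2[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order])

    r1 = out_dir / "reads_1.fastq.gz"
    r2 = out_dir / "reads_2.fastq.gz"
    write_fastq(r1, reads1)
    write_fastq(r2, reads2)
    write_table(truth, out_dir / "truth.tsv")
    return SimulatedRun(r1, r2, truth, manifest, markers, spec)


def make_dataset1_fixture(
    seed: int,
    out_dir,
    reads_per_combination: int = 10000,
    **spec_overrides,
) -> SimulatedRun:
    """Generate the bundled five-sample mixture design.

    Five samples at defined (ref : alt) ratios 1:1, 1:10, 1:100, 1:500,
    1:1000 across the two built-in 120-nt markers, 10,000 pairs per
    combination by default.  With a fixed seed, two invocations produce
    byte-identical FASTQs.
    """
    manifest = SampleManifest(DATASET1_MANIFEST.copy())
    markers = MarkerInfo(DATASET1_MARKERS.copy())
    spec = MixtureSpec(
        markers=tuple(
            {
                "marker_id": m,
                "ref_haplotype": markers.reference(m),
                "alt_haplotype": DATASET1_ALT_HAPLOTYPES[m],
            }
            for m in markers.marker_ids
        ),
        samples=tuple(
            {"sample_id": sid, "ratio": ratio}
            for sid, ratio in zip(manifest.sample_ids, DATASET1_RATIOS)
        ),
        reads_per_combination=reads_per_combination,
        seed=seed,
        **spec_overrides,
    )
    out_dir = Path(out_dir)
    run = simulate_dataset(spec, manifest, markers, out_dir)
    manifest.write(out_dir / "sample_manifest.csv")
    markers.write(out_dir / "marker_info.csv")
    return run
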