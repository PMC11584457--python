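import numpy as np
import pandas as pd
import pytest
import edlib
from scipy.stats import poisson

from amplihap import denoise, dereplicate, merge_pairs
from amplihap.asv import UniqueSet, beta, build_seq_table, estimate_error_rate, revcomp
from amplihap.datamodel import MarkerInfo, PipelineConfig, SampleManifest
from amplihap.simdata import (
    DATASET1_ALT_HAPLOTYPES,
    DATASET1_MANIFEST,
    DATASET1_MARKERS,
    MixtureSpec,
    simulate_dataset,
)

from conftest import write_fastq_pair


def test_dereplicate_counts_and_conservation(tmp_path):
    recs = [("a", "ACGT", "IIII", "TTTT", "IIII")] * 3 + [("b", "AAAA", "IIII", "TTTT", "IIII")]
    r1, r2 = write_fastq_pair(tmp_path, recs)
    fwd, rev = dereplicate(r1, r2)
    assert fwd.sequences == ["ACGT", "AAAA"] and fwd.abundances == [3, 1]
    assert fwd.total == 4 == rev.total  # abundance conservation
    assert rev.sequences == ["TTTT"] and rev.abundances == [4]


def test_denoise_absorbs_error_lineage_with_known_rate():
    """At a realistic error rate the distance-1 child of a deep center is an
    expected error lineage: skew 10/5000 <= beta(1)=1/8 and the count is
    Poisson-plausible, so it is absorbed and the center gains its reads."""
    center = "ACGTACGTACGTACGTACGT"
    child = "AAGTACGTACGTACGTACGT"
    u = UniqueSet([center, child], [5000, 10])
    out, assign = denoise(u, alpha=2.0, error_rate=0.006)
    assert out.sequences == [center] and out.abundances == [5010]
    assert assign[child] == center


def test_denoise_keeps_implausibly_abundant_variant():
    """The same child at a near-zero error rate cannot be an error lineage:
    it stays a center even though the skew test alone would absorb it."""
    center = "ACGTACGTACGTACGTACGT"
    child = "AAGTACGTACGTACGTACGT"
    u = UniqueSet([center, child], [5000, 10])
    out, assign = denoise(u, alpha=2.0, error_rate=1e-5)
    assert set(out.sequences) == {center, child}
    assert assign[child] == child


def test_denoise_retains_balanced_true_haplotypes():
    # two real haplotypes one substitution apart: ratio 2397/2481 = 0.966
    # far exceeds beta(1) = 0.125, so both stay centers
    a = "CCCAAATGCAAACCCAAATG"
    b = "CCCCAATGCAAACCCAAATG"
    u = UniqueSet([a, b], [2481, 2397])
    out, _ = denoise(u, error_rate=0.001)
    assert sorted(out.abundances, reverse=True) == [2481, 2397]
    assert set(out.sequences) == {a, b}


def test_denoise_tie_broken_by_abundance_then_sequence():
    # a small-count unique equidistant from two centers goes to the more
    # abundant; with equal abundance, to the lexicographically smaller
    c1 = "AAAAAAAAAA"
    c2 = "CCCCCCCCCC"
    child = "AAAAACCCCC"  # distance 5 from both
    u = UniqueSet([c1, c2, child], [100, 90, 2])
    _, assign = denoise(u, error_rate=0.0)
    assert assign[child] == c1
    u2 = UniqueSet([c1, c2, child], [100, 100, 2])
    _, assign2 = denoise(u2, error_rate=0.0)
    assert assign2[child] == c1  # lexicographic tie-break


def test_denoise_identity_without_errors():
    seqs = ["ACGTACGTACGTACGTACGTACGTACGT", "ACGAACGTACGTACGTACGTACGTACGT"]
    u = UniqueSet(seqs, [990, 10])
    out, assign = denoise(u, error_rate=0.0)
    assert out.sequences == seqs and out.abundances == [990, 10]
    assert all(assign[s] == s for s in seqs)


def _brute_force_denoise(uniques, alpha, d_max, error_rate, p_new, floor):
    """Independent reference implementation of the absorption rule applied
    in descending-abundance order."""
    mu = error_rate / 3.0
    order = sorted(zip(uniques.sequences, uniques.abundances), key=lambda kv: (-kv[1], kv[0]))
    abundance = {}
    assign = {}
    for seq, count in order:
        candidates = []
        for c in abundance:
            d = edlib.align(seq, c, task="distance", k=d_max)["editDistance"]
            if d < 0:
                continue
            ok_floor = count <= floor
            ok_rule = (
                count / abundance[c] <= 1.0 / 2.0 ** (alpha * d + 1.0)
                and poisson.sf(count - 1, abundance[c] * mu**d) >= p_new
            )
            if ok_floor or ok_rule:
                candidates.append((d, -abundance[c], c))
        if candidates:
            c = min(candidates)[2]
            abundance[c] += count
            assign[seq] = c
        else:
            abundance[seq] = count
            assign[seq] = seq
    return abundance, assign


@pytest.mark.parametrize("case_seed", range(12))
def test_denoise_matches_brute_force_oracle(case_seed):
    rng = np.random.default_rng(1000 + case_seed)
    n = int(rng.integers(2, 15))
    base = "".join(rng.choice(list("ACGT"), size=25))
    seqs = set()
    while len(seqs) < n:
        s = list(base)
        for _ in range(int(rng.integers(0, 4))):
            i = int(rng.integers(0, len(s)))
            s[i] = "ACGT"[int(rng.integers(0, 4))]
        seqs.add("".join(s))
    seqs = sorted(seqs)
    counts = [int(rng.integers(1, 5000)) for _ in seqs]
    u = UniqueSet(seqs, counts)
    rate = float(rng.choice([0.0, 0.001, 0.01]))
    out, assign = denoise(u, alpha=2.0, d_max=10, error_rate=rate)
    bf_ab, bf_assign = _brute_force_denoise(u, 2.0, 10, rate, 0.01, 3)
    assert dict(zip(out.sequences, out.abundances)) == bf_ab
    assert assign == bf_assign


def test_estimate_error_rate_from_neighborhood():
    center = "A" * 50
    children = ["C" + "A" * 49, "A" * 25 + "G" + "A" * 24]
    u = UniqueSet([center] + children, [10000, 30, 20])
    # sigma=50 over a_top * L = 10000*50 -> 1e-4
    assert estimate_error_rate(u) == pytest.approx(1e-4)
    assert estimate_error_rate(UniqueSet([center], [10])) == 0.0


@pytest.mark.parametrize(
    "fwd, rev, min_overlap, expected",
    [
        # revcomp(rev) == CGTACGGGGG: maximal exact overlap CGTAC (len 5)
        ("ACGTACGTAC", revcomp("CGTACGGGGG"), 5, "ACGTACGTACGGGGG"),
        ("ACGTACGTAC", revcomp("CGTACGGGGG"), 6, None),  # overlap 5 < 6
        ("ACGTACGTAC", revcomp("ACGTACGTAC"), 10, "ACGTACGTAC"),  # full overlap
    ],
)
def test_merge_pairs_overlap(fwd, rev, min_overlap, expected):
    assert merge_pairs(fwd, rev, min_overlap) == expected


def test_merge_pairs_concatenate_mode():
    fwd, rev = "ACGTACGTAC", "TTTTTGGGGG"
    merged = merge_pairs(fwd, rev, -1)
    assert merged == fwd + revcomp(rev)
    assert len(merged) == len(fwd) + len(rev)


def _simulate_single(tmp_path, ratio, n_reads, seed, **overrides):
    manifest = SampleManifest(DATASET1_MANIFEST.iloc[[0]].copy())
    markers = MarkerInfo(DATASET1_MARKERS[DATASET1_MARKERS["marker_id"] == "CSP"].copy())
    spec = MixtureSpec(
        markers=(
            {
                "marker_id": "CSP",
                "ref_haplotype": markers.reference("CSP"),
                "alt_haplotype": DATASET1_ALT_HAPLOTYPES["CSP"],
            },
        ),
        samples=({"sample_id": "S01", "ratio": ratio},),
        reads_per_combination=n_reads,
        seed=seed,
        **overrides,
    )
    return simulate_dataset(spec, manifest, markers, tmp_path), manifest, markers


def test_build_seq_table_recovers_balanced_mixture(tmp_path):
    """A 1:1 mixture at 5,000 pairs yields the two true haplotypes as the
    top rows with counts within 3 binomial SD of 2,500 each."""
    from amplihap import demultiplex_reads

    run, manifest, markers = _simulate_single(tmp_path, (1, 1), 5000, 21)
    demux = demultiplex_reads(run.reads_1, run.reads_2, manifest, markers, tmp_path / "d")
    demux = demux.assign(n_in=demux["n"], n_out=demux["n"])
    tbl = build_seq_table(demux, config=PipelineConfig())
    top2 = tbl.nlargest(2, "count")
    assert set(top2["sequence"]) == {markers.reference("CSP"), DATASET1_ALT_HAPLOTYPES["CSP"]}
    sd = np.sqrt(5000 * 0.25)
    assert all(abs(c - 2500) <= 3 * sd for c in top2["count"])
    assert tbl["count"].sum() <= 5000  # no merged-count inflation


def test_build_seq_table_single_haplotype(tmp_path):
    seq = "ACGTTGCATCCGATAGCTTGAACCGTATGGCTTAGACGTC"  # no internal repeats
    recs = [
        (f"r{i}", seq[:30], "I" * 30, revcomp(seq)[:30], "I" * 30) for i in range(40)
    ]
    r1, r2 = write_fastq_pair(tmp_path, recs)
    table = pd.DataFrame(
        {
            "sample_id": ["S01"], "marker_id": ["M1"],
            "reads_1": [str(r1)], "reads_2": [str(r2)],
            "sample": ["s"], "info": ["i"],
        }
    )
    tbl = build_seq_table(table, config=PipelineConfig())
    assert len(tbl) == 1
    assert tbl.iloc[0]["sequence"] == seq
    assert tbl.iloc[0]["count"] == 40
    assert tbl.iloc[0]["status"] == "pass"
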