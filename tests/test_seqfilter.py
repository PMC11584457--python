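import numpy as np
import pandas as pd
import pytest

from amplihap import (
    call_variants,
    clean_homopolymers,
    clean_terminal_indels,
    name_haplotypes_and_frequencies,
    sequence_filter,
)
from amplihap.align import align_to_reference
from amplihap.datamodel import MarkerInfo, PipelineConfig, SampleManifest
from amplihap.errors import EmptyResultError
from amplihap.seqfilter import apply_dataset_filters, dataset_median_he, mask_variants
from amplihap.simdata import CSP_REF

REF = "GGTCAAATGGTCAGGTCAGGTCAAGGTTCA"  # contains AAA run at 4-6


def test_homopolymer_insertion_reverted():
    # ref ...C AAA TG...: run length 3 >= 3; inserted A removed
    ref = "GGCAAATGGC"
    seq = "GGCAAAATGGC"
    assert clean_homopolymers(seq, ref, 3) == ref


def test_homopolymer_deletion_restored():
    ref = "GGCAAATGGC"
    seq = "GGCAATGGC"  # one A of the run deleted
    assert clean_homopolymers(seq, ref, 3) == ref


def test_short_run_not_corrected():
    ref = "GGCAATGGCA"  # AA run length 2 < 3
    seq = "GGCAAATGGCA"
    assert clean_homopolymers(seq, ref, 3) == seq


def test_homopolymer_none_disables():
    ref = "GGCAAATGGC"
    seq = "GGCAAAATGGC"
    assert clean_homopolymers(seq, ref, None) == seq


def test_homopolymer_correction_idempotent_and_identity():
    rng = np.random.default_rng(17)
    ref = CSP_REF
    assert clean_homopolymers(ref, ref, 3) == ref  # identity on error-free input
    for _ in range(150):
        s = list(ref)
        for _ in range(int(rng.integers(1, 3))):
            i = int(rng.integers(1, len(s) - 1))
            if rng.random() < 0.5:
                s.insert(i, "ACGT"[int(rng.integers(0, 4))])
            else:
                del s[i]
        seq = "".join(s)
        once = clean_homopolymers(seq, ref, 3)
        assert clean_homopolymers(once, ref, 3) == once


def test_terminal_indels_reverted_only_at_ends():
    ref = CSP_REF
    head_del = ref[0] + ref[3:]  # 2-nt deletion at alignment columns 2-3
    assert clean_terminal_indels(head_del, ref, 5) == ref
    interior_del = ref[:50] + ref[52:]  # same length deletion mid-sequence
    assert clean_terminal_indels(interior_del, ref, 5) == interior_del
    assert clean_terminal_indels(head_del, ref, None) == head_del  # disabled


def _rows(counts_by_sample, seqs, marker="CSP"):
    rows = []
    for sample, counts in counts_by_sample.items():
        for c, s in zip(counts, seqs):
            if c:
                rows.append(
                    {
                        "sample_id": sample, "marker_id": marker, "sequence": s,
                        "count": c, "status": "pass", "sample": sample, "info": "",
                    }
                )
    return pd.DataFrame(rows)


def test_call_variants_biallelic_site():
    ref = "ACGTACGTAC"
    alt = "ACGAACGTAC"
    tbl = _rows({"A": [500, 500]}, [ref, alt])
    v = call_variants(tbl, ref, "chr1", 101)
    assert len(v) == 1
    site = v.iloc[0]
    assert site["pos"] == 104 and site["ref"] == "T"
    assert site["maf"] == pytest.approx(0.5)
    assert site["he"] == pytest.approx(0.5)
    skew = call_variants(_rows({"A": [900, 100]}, [ref, alt]), ref, "chr1", 101)
    assert skew.iloc[0]["he"] == pytest.approx(0.18)
    assert skew.iloc[0]["maf"] == pytest.approx(0.1)


def test_call_variants_pooled_dataset_frequency():
    """Read-count-weighted pooling across samples: 3,026 reads of one CSP
    allele against 21,216 of the other give p ~ (0.125, 0.875), He ~ 0.219."""
    ref = "ACGTACGTAC"
    alt = "ACGAACGTAC"
    tbl = _rows(
        {"S01": [2481, 2397], "S02": [496, 4378], "S03": [40, 4778],
         "S04": [9, 4926], "S05": [0, 4737]},
        [ref, alt],
    )
    v = call_variants(tbl, ref, "c", 1)
    p_minor = 3026 / (3026 + 21216)
    assert v.iloc[0]["maf"] == pytest.approx(p_minor, abs=1e-9)
    assert v.iloc[0]["he"] == pytest.approx(2 * p_minor * (1 - p_minor), abs=1e-9)


def test_mask_variants_merges_and_preserves_length():
    ref = "ACGTACGTAC"
    rare = "ACGTACGTAT"  # alt at last base, dataset freq 5/10035
    tbl = _rows({"A": [10000, 30, 5]}, [ref, "ACGAACGTAC", rare])
    v = call_variants(tbl, ref, "c", 1)
    cfg = PipelineConfig(var_maf=0.001, var_he=0.001, n_alleles=3)
    out = mask_variants(tbl, v, ref, cfg, mask_active=True)
    # the rare terminal substitution is reverted to the reference and the
    # row merges into the reference row; 30/10035 = 0.0030 >= var_maf stays
    assert len(out) == 2
    merged = out[out["sequence"] == ref]
    assert int(merged["count"].iloc[0]) == 10005
    assert bool(merged["masked"].iloc[0])
    assert all(len(s) == len(ref) for s in out["sequence"])


def test_mask_variants_allele_cap():
    ref = "ACGTACGTAC"
    muts = ["CCGTACGTAC", "GCGTACGTAC", "TCGTACGTAC"]  # 4 alleles at site 0
    tbl = _rows({"A": [5000, 2000, 1500, 1000]}, [ref] + muts)
    v = call_variants(tbl, ref, "c", 1)
    assert v.iloc[0]["n_alleles"] == 4
    cfg = PipelineConfig(n_alleles=3)
    out = mask_variants(tbl, v, ref, cfg, mask_active=False)
    # all non-major alleles revert to the reference base and merge
    assert len(out) == 1
    assert out.iloc[0]["sequence"] == ref
    assert out.iloc[0]["count"] == 9500


def _manifest(samples):
    return SampleManifest(
        pd.DataFrame(
            {
                "sample_id": samples,
                "barcode_fwd": [f"{'ACGT'[i % 4]}CGTACGT" for i in range(len(samples))],
                "barcode_rev": [f"{'TGCA'[i % 4]}GCATGCA" for i in range(len(samples))],
                "sample": samples,
                "info": samples,
            }
        )
    )


def _two_markers(ref1, ref2):
    return MarkerInfo(
        pd.DataFrame(
            {
                "marker_id": ["M1", "M2"],
                "primer_fwd": ["AAAAA", "CCCCC"],
                "primer_rev": ["GGGGG", "TTTTT"],
                "seq": [ref1, ref2],
                "chrom": ["c1", "c2"],
                "start": [1, 1],
                "end": [len(ref1), len(ref2)],
            }
        )
    )


def test_dataset_filters_missingness_boundary():
    ref = "ACGTACGTAC"
    rows = pd.concat(
        [
            _rows({"A": [500]}, [ref], marker="M1"),
            _rows({"A": [500]}, [ref], marker="M2"),
            _rows({"B": [500]}, [ref], marker="M1"),  # B missing M2: missingness 0.5
        ]
    ).reset_index(drop=True)
    cfg = PipelineConfig(min_marker_count=100, max_sm_miss=0.5, max_marker_miss=0.5)
    out = apply_dataset_filters(rows, cfg, _manifest(["A", "B"]), _two_markers(ref, ref))
    assert set(out["sample_id"]) == {"A", "B"}  # 0.5 is not > 0.5


def test_dataset_filters_marker_count_threshold():
    ref = "ACGTACGTAC"
    rows = pd.concat(
        [
            _rows({"A": [99]}, [ref], marker="M1"),   # combination total 99 < 100
            _rows({"A": [500]}, [ref], marker="M2"),
        ]
    ).reset_index(drop=True)
    cfg = PipelineConfig(min_marker_count=100, max_sm_miss=1, max_marker_miss=1)
    out = apply_dataset_filters(rows, cfg, _manifest(["A"]), _two_markers(ref, ref))
    assert set(out["marker_id"]) == {"M2"}


def test_dataset_filters_disabled_at_one():
    ref = "ACGTACGTAC"
    rows = _rows({"A": [500]}, [ref], marker="M1")
    cfg = PipelineConfig(min_marker_count=0, max_sm_miss=1, max_marker_miss=1)
    out = apply_dataset_filters(rows, cfg, _manifest(["A", "B"]), _two_markers(ref, ref))
    assert len(out) == 1  # nothing dropped for missingness


def test_dataset_filters_empty_raises_with_stage():
    ref = "ACGTACGTAC"
    rows = _rows({"A": [10]}, [ref], marker="M1")
    cfg = PipelineConfig(min_marker_count=100)
    with pytest.raises(EmptyResultError, match="min_marker_count"):
        apply_dataset_filters(rows, cfg, _manifest(["A"]), _two_markers(ref, ref))


@pytest.mark.parametrize(
    "counts, expected",
    [
        ((2481, 2397), (0.509, 0.491)),
        ((63, 4805), (0.0129, 0.987)),
        ((5,), (1.0,)),
    ],
)
def test_within_sample_frequencies(counts, expected):
    ref = "ACGTACGTAC"
    seqs = [ref, "ACGAACGTAC"][: len(counts)]
    tbl = _rows({"A": list(counts)}, seqs)
    out = name_haplotypes_and_frequencies(tbl)
    got = sorted(out["frequency"])
    assert [float(f"{v:.3g}") for v in got] == sorted(expected)
    assert out.groupby(["sample_id", "marker_id"])["frequency"].sum().iloc[0] == pytest.approx(1.0, abs=1e-9)


def test_haplotype_naming_by_dataset_abundance():
    ref = "ACGTACGTAC"
    alt = "ACGAACGTAC"
    tbl = _rows({"A": [100, 900], "B": [50, 800]}, [ref, alt])
    out = name_haplotypes_and_frequencies(tbl)
    names = dict(zip(out["sequence"], out["haplotype"]))
    assert names[alt] == "CSP-1"  # 1700 total reads vs 150
    assert names[ref] == "CSP-2"


def test_dataset_median_he():
    ref = "ACGTACGTAC"
    alt = "ACGAACGTAC"
    tbl = _rows({"A": [500, 500], "B": [1000]}, [ref, alt])
    # sample A: He = 0.5; sample B: He = 0 -> median over samples 0.25
    assert dataset_median_he(tbl) == pytest.approx(0.25)


def test_sequence_filter_end_to_end_masking(small_run):
    """Full-stack check on the small synthetic run: final frequencies sum
    to one, every row passes, and masking never lowered ident."""
    flt = small_run["result"].seq_flt_tbl
    sums = flt.groupby(["sample_id", "marker_id"])["frequency"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)
    assert (flt["status"] == "pass").all()
    markers = small_run["sim"].markers
    for _, r in flt.iterrows():
        assert align_to_reference(r["sequence"], markers.reference(r["marker_id"])).ident == pytest.approx(r["ident"])
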