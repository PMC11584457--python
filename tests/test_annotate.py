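import itertools

import numpy as np
import pandas as pd
import pytest

from amplihap import annotate_seq_tbl, standardize_ident
from amplihap.align import align_to_reference, project_to_reference
from amplihap.annotate import detect_chimeras, min_breakpoints
from amplihap.datamodel import MarkerInfo, PipelineConfig
from amplihap.simdata import CSP_REF

REF = CSP_REF  # 120 nt


def test_identity_alignment():
    res = align_to_reference(REF, REF)
    assert res.ident == 1.0
    assert res.aligned_seq == REF


def test_single_substitution_identity():
    seq = REF[:50] + ("A" if REF[50] != "A" else "C") + REF[51:]
    assert align_to_reference(seq, REF).ident == pytest.approx(119 / 120)


def test_three_base_deletion_identity():
    seq = REF[:50] + REF[53:]
    # gap columns count in the denominator: 117 matching of 120 columns
    assert align_to_reference(seq, REF).ident == pytest.approx(117 / 120)


@pytest.mark.parametrize(
    "values, target, expected",
    [
        ([1.0] * 4 + [0.892] * 5, 1.0, 1.05),
        ([1.0] * 4 + [0.892] * 5, 0.892, -0.843),
        ([1.0] * 5 + [0.958] * 5, 1.0, 0.949),
        ([1.0] * 5 + [0.958] * 5, 0.958, -0.949),
    ],
)
def test_standardize_ident_reproduces_printed_values(values, target, expected):
    z = standardize_ident(values)
    got = z[values.index(target)]
    assert float(f"{got:.3g}") == expected


def test_standardize_single_row_is_zero():
    assert standardize_ident([0.9]).tolist() == [0.0]
    assert standardize_ident([0.9, 0.9, 0.9]).tolist() == [0.0, 0.0, 0.0]


def test_standardize_mean_zero_sd_one():
    rng = np.random.default_rng(3)
    x = rng.uniform(0.7, 1.0, size=37)
    z = standardize_ident(x)
    assert abs(z.mean()) < 1e-9
    assert abs(z.std(ddof=1) - 1.0) < 1e-9


def _chimera_frame(child_count):
    a = REF
    b = REF[:30] + ("G" if REF[30] != "G" else "T") + REF[31:90] + ("A" if REF[90] != "A" else "C") + REF[91:]
    child = a[:60] + b[60:]
    return pd.DataFrame(
        {
            "sequence": [a, b, child],
            "count": [1000, 900, child_count],
        }
    )


def test_chimera_positive_and_ratio_boundary():
    grp = _chimera_frame(20)
    flags = detect_chimeras(grp, REF, max_breakpoints=3, min_parent_ratio=1.5)
    assert flags == [False, False, True]  # ratios 50 and 45 >= 1.5, 1 breakpoint
    grp2 = _chimera_frame(700)
    flags2 = detect_chimeras(grp2, REF, max_breakpoints=3, min_parent_ratio=1.5)
    assert flags2 == [False, False, False]  # 900/700 = 1.29 < 1.5


def test_chimera_never_flags_dominant_row():
    grp = _chimera_frame(20)
    grp.loc[2, "count"] = 5000  # child now dominates every candidate parent
    flags = detect_chimeras(grp, REF, 3, 1.5)
    assert flags[2] is False or flags[2] == False  # noqa: E712


def _brute_force_min_breakpoints(child, a, b, max_bp):
    """Enumerate every segmentation with <= max_bp switch points."""
    n = len(child)
    best = None
    for k in range(0, max_bp + 1):
        for cuts in itertools.combinations(range(1, n), k):
            bounds = [0, *cuts, n]
            for first in (0, 1):
                ok = True
                for seg_i in range(len(bounds) - 1):
                    src = (a, b)[(first + seg_i) % 2]
                    lo, hi = bounds[seg_i], bounds[seg_i + 1]
                    if child[lo:hi] != src[lo:hi]:
                        ok = False
                        break
                if ok:
                    best = k if best is None else min(best, k)
        if best is not None:
            return best
    return None


@pytest.mark.parametrize("seed", range(10))
def test_min_breakpoints_matches_brute_force(seed):
    rng = np.random.default_rng(200 + seed)
    n = int(rng.integers(6, 16))
    a = "".join(rng.choice(list("ACGT"), n))
    b = "".join(rng.choice(list("ACGT"), n))
    # half the cases are genuine mosaics, half random strings
    if seed % 2 == 0:
        cuts = sorted(rng.choice(range(1, n), size=int(rng.integers(1, 3)), replace=False))
        child = ""
        prev, src = 0, 0
        for c in list(cuts) + [n]:
            child += (a, b)[src][prev:c]
            prev, src = c, 1 - src
    else:
        child = "".join(rng.choice(list("ACGT"), n))
    got = min_breakpoints(child, a, b)
    expected = _brute_force_min_breakpoints(child, a, b, max_bp=n)
    assert got == expected


def _markers_for(ref):
    return MarkerInfo(
        pd.DataFrame(
            {
                "marker_id": ["CSP"],
                "primer_fwd": ["GTGGA"],
                "primer_rev": ["CTAGC"],
                "seq": [ref],
                "chrom": ["c"],
                "start": [1],
                "end": [len(ref)],
            }
        )
    )


def _row(sample, count, seq):
    return {
        "sample_id": sample, "marker_id": "CSP", "sequence": seq,
        "count": count, "status": "pass", "sample": sample, "info": "",
    }


def test_annotate_status_assignment():
    alt = REF[:3] + "C" + REF[4:]
    rng = np.random.default_rng(99)
    far = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 120)])  # unrelated DNA
    assert align_to_reference(far, REF).ident < 0.75  # precondition
    tbl = pd.DataFrame(
        [
            _row("A", 4948, REF),
            _row("A", 5, alt),          # freq 5/4953 >= 0.001, count >= 5 -> pass
            _row("B", 9996, REF),
            _row("B", 4, alt),          # count < 5 AND freq < 0.001 -> multiple
            _row("C", 2000, far),       # low_ident only
        ]
    )
    cfg = PipelineConfig(min_read_count=1000, min_ident_z=-10)
    ann = annotate_seq_tbl(tbl, _markers_for(REF), config=cfg)
    assert list(ann["status"]) == ["pass", "pass", "pass", "multiple", "low_ident"]
    assert ann.iloc[4]["ident"] < 0.75


def test_annotate_low_sample_count():
    tbl = pd.DataFrame([_row("A", 400, REF)])
    ann = annotate_seq_tbl(tbl, _markers_for(REF), config=PipelineConfig())
    assert ann.iloc[0]["status"] == "low_sample_count"


def test_annotate_is_order_invariant():
    alt = REF[:3] + "C" + REF[4:]
    rows = [
        _row("A", 4948, REF), _row("A", 5, alt),
        _row("B", 9000, REF), _row("B", 900, alt),
    ]
    cfg = PipelineConfig()
    fwd = annotate_seq_tbl(pd.DataFrame(rows), _markers_for(REF), config=cfg)
    rev = annotate_seq_tbl(pd.DataFrame(rows[::-1]), _markers_for(REF), config=cfg)
    key = ["sample_id", "count"]
    merged = fwd.merge(rev, on=key, suffixes=("_f", "_r"))
    assert (merged["status_f"] == merged["status_r"]).all()
    assert np.allclose(merged["ident_z_f"], merged["ident_z_r"])


def test_annotate_unknown_marker_raises():
    tbl = pd.DataFrame([_row("A", 100, REF)]).assign(marker_id="NOPE")
    with pytest.raises(Exception, match="NOPE"):
        annotate_seq_tbl(tbl, _markers_for(REF), config=PipelineConfig())
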