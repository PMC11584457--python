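"""Final haplotype filtering: indel correction, variant masking, naming.

This stage takes the annotated table and produces the final haplotype
panel.  In order: (1) homopolymer and terminal indel correction against the
marker reference (the two dominant sources of spurious short-read indels);
(2) dataset-level filters (per-combination read totals, sample and marker
missingness); (3) variant calling in reference coordinates with
read-count-weighted allele frequencies; (4) masking of suspect variants
(allele-count cap always; MAF/He thresholds gated by the dataset-median-He
guard) by reverting the offending base to the reference; (5) haplotype
naming per marker and within-sample frequencies.  A per-marker VCF of the
final variants is written alongside.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import pysam

from .align import align_to_reference, mask_bases, project_to_reference
from .datamodel import MarkerInfo, PipelineConfig, SampleManifest, write_table
from .errors import EmptyResultError

logger = logging.getLogger(__name__)

SEQ_FLT_COLUMNS = [
    "sample_id", "marker_id", "sequence", "count", "masked", "status",
    "ident", "haplotype", "frequency", "sample", "info",
]


# ---------------------------------------------------------------------------
# indel correction

def _ref_runs(ref: str) -> List[Tuple[str, int]]:
    """Per reference position: (base of its homopolymer run, run length)."""
    runs = []
    i = 0
    while i < len(ref):
        j = i
        while j < len(ref) and ref[j] == ref[i]:
            j += 1
        runs.extend([(ref[i], j - i)] * (j - i))
        i = j
    return runs


def _walk_indels(seq: str, ref: str):
    """Yield alignment events: ('match', col, a, ref_pos) for aligned columns,
    ('ins', col_start, bases, ref_pos) and ('del', col_start, bases, ref_pos)
    for gap runs.  ``ref_pos`` is the 0-based reference offset at the event
    start (for insertions, the offset of the next reference base)."""
    res = align_to_reference(seq, ref)
    cols = list(zip(res.aligned_seq, res.aligned_ref))
    i = 0
    ref_pos = 0
    while i < len(cols):
        a, r = cols[i]
        if a != "-" and r != "-":
            yield ("match", i, a, ref_pos)
            ref_pos += 1
            i += 1
        elif r == "-":
            j = i
            bases = []
            while j < len(cols) and cols[j][1] == "-":
                bases.append(cols[j][0])
                j += 1
            yield ("ins", i, "".join(bases), ref_pos)
            i = j
        else:
            j = i
            bases = []
            while j < len(cols) and cols[j][0] == "-" and cols[j][1] != "-":
                bases.append(cols[j][1])
                j += 1
            yield ("del", i, "".join(bases), ref_pos)
            ref_pos += len(bases)
            i = j


def clean_homopolymers(seq: str, ref: str, min_homo_rep: Optional[int]) -> str:
    """Revert indels inside reference homopolymer runs.

    An insertion or deletion is reverted when its bases all equal the base
    of a reference homopolymer run of length >= ``min_homo_rep`` at the
    event's position.  Substitutions are untouched; ``None`` disables.
    """
    if min_homo_rep is None:
        return seq
    runs = _ref_runs(ref)
    out = []
    for kind, _, payload, ref_pos in _walk_indels(seq, ref):
        if kind == "match":
            out.append(payload)
        elif kind == "ins":
            base = payload[0]
            uniform = all(b == base for b in payload)
            in_run = any(
                0 <= p < len(ref) and runs[p][0] == base and runs[p][1] >= min_homo_rep
                for p in (ref_pos - 1, ref_pos)
            )
            if not (uniform and in_run):
                out.append(payload)
        else:  # deletion
            base = payload[0]
            uniform = all(b == base for b in payload)
            in_run = all(
                runs[p][0] == base and runs[p][1] >= min_homo_rep
                for p in range(ref_pos, ref_pos + len(payload))
            )
            if uniform and in_run:
                out.append(payload)  # restore the deleted reference bases
    return "".join(out)


def clean_terminal_indels(seq: str, ref: str, terminal_region_len: Optional[int]) -> str:
    """Revert indels whose alignment columns lie in a terminal window.

    An indel run entirely within ``terminal_region_len`` columns of either
    alignment end is reverted to the reference; interior indels are kept.
    ``None`` disables.
    """
    if terminal_region_len is None:
        return seq
    res = align_to_reference(seq, ref)
    total = len(res.aligned_seq)
    L = terminal_region_len
    out = []
    for kind, col, payload, _ in _walk_indels(seq, ref):
        if kind == "match":
            out.append(payload)
            continue
        end_col = col + len(payload)  # exclusive
        terminal = end_col <= L or col >= total - L
        if kind == "ins":
            if not terminal:
                out.append(payload)
        else:
            if terminal:
                out.append(payload)  # restore deleted reference bases
    return "".join(out)


# ---------------------------------------------------------------------------
# variant calling and masking

def call_variants(marker_rows: pd.DataFrame, ref: str, chrom: str = ".", start: int = 1) -> pd.DataFrame:
    """Column-wise variant calling in reference coordinates for one marker.

    Allele frequencies are read-count weighted over all rows (all samples
    where the marker passed).  Returns one row per polymorphic reference
    offset with alleles, frequencies, MAF (frequency of the most frequent
    non-major allele), and expected heterozygosity He = 1 - sum(p^2).
    Deletions appear as the '-' allele; insertions are not called.
    """
    seq_counts: Dict[str, int] = {}
    for _, r in marker_rows.iterrows():
        seq_counts[r["sequence"]] = seq_counts.get(r["sequence"], 0) + int(r["count"])
    total = sum(seq_counts.values())
    projections = {s: project_to_reference(s, ref) for s in seq_counts}
    records = []
    for offset in range(len(ref)):
        allele_counts: Dict[str, int] = {}
        for s, n in seq_counts.items():
            a = projections[s][offset]
            allele_counts[a] = allele_counts.get(a, 0) + n
        if len(allele_counts) < 2 and ref[offset] in allele_counts:
            continue
        freqs = {a: n / total for a, n in allele_counts.items()}
        ordered = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))
        major = ordered[0][0]
        maf = ordered[1][1] if len(ordered) > 1 else 0.0
        he = 1.0 - sum(p * p for p in freqs.values())
        records.append(
            {
                "marker_id": marker_rows["marker_id"].iloc[0],
                "chrom": chrom,
                "pos": start + offset,
                "offset": offset,
                "ref": ref[offset],
                "major": major,
                "alleles": ordered,
                "n_alleles": len(ordered),
                "maf": maf,
                "he": he,
            }
        )
    return pd.DataFrame(
        records,
        columns=["marker_id", "chrom", "pos", "offset", "ref", "major",
                 "alleles", "n_alleles", "maf", "he"],
    )


def flag_variants(var_tbl: pd.DataFrame, config: PipelineConfig, mask_active: bool) -> pd.Series:
    """Boolean per variant site: True when the site's minor alleles should
    be masked.  The allele-count cap always applies; the MAF and He
    thresholds only when ``mask_active``."""
    if len(var_tbl) == 0:
        return pd.Series([], dtype=bool)
    fail = var_tbl["n_alleles"] > config.n_alleles
    if mask_active:
        fail = fail | (var_tbl["maf"] < config.var_maf) | (var_tbl["he"] < config.var_he)
    return fail


def mask_variants(
    rows: pd.DataFrame,
    var_tbl: pd.DataFrame,
    ref: str,
    config: PipelineConfig,
    mask_active: bool,
) -> pd.DataFrame:
    """Revert minor alleles at failing variant sites to the reference base.

    At a failing site every allele except the major one is replaced by the
    reference base in the haplotypes that carry it (gap alleles are left,
    to keep masking substitution-only).  Haplotypes identical after masking
    are merged within each combination with counts summed.
    """
    fail = flag_variants(var_tbl, config, mask_active)
    failing_sites = var_tbl[fail] if len(var_tbl) else var_tbl
    # offset -> (major allele, ref base)
    site_info = {
        int(r["offset"]): (r["major"], r["ref"]) for _, r in failing_sites.iterrows()
    }
    out = rows.copy()
    new_seqs = []
    masked_flags = []
    for _, r in out.iterrows():
        proj = project_to_reference(r["sequence"], ref)
        repl = {}
        for offset, (major, ref_base) in site_info.items():
            a = proj[offset]
            if a == "-" or a == major or a == ref_base:
                continue
            repl[offset] = ref_base
        if repl:
            new_seqs.append(mask_bases(r["sequence"], ref, repl))
            masked_flags.append(True)
        else:
            new_seqs.append(r["sequence"])
            masked_flags.append(bool(r.get("masked", False)))
    out["sequence"] = new_seqs
    out["masked"] = masked_flags
    return _merge_identical(out)


def _merge_identical(rows: pd.DataFrame) -> pd.DataFrame:
    """Merge rows with identical (sample_id, marker_id, sequence)."""
    agg = {c: "first" for c in rows.columns if c not in ("count", "masked")}
    agg["count"] = "sum"
    if "masked" in rows.columns:
        agg["masked"] = "any"
    merged = (
        rows.groupby(["sample_id", "marker_id", "sequence"], as_index=False, sort=False)
        .agg({k: v for k, v in agg.items() if k not in ("sample_id", "marker_id", "sequence")})
    )
    return merged


# ---------------------------------------------------------------------------
# dataset-level filters

def apply_dataset_filters(
    rows: pd.DataFrame,
    config: PipelineConfig,
    manifest: SampleManifest,
    markers: MarkerInfo,
) -> pd.DataFrame:
    """Drop failing rows, thin combinations, then samples/markers by missingness.

    Missingness denominators are the full study design: all markers in the
    marker table for a sample's missingness, all samples in the manifest
    for a marker's.
    """
    out = rows[rows["status"] == "pass"].copy()
    if len(out) == 0:
        raise EmptyResultError("sequence_filter: no rows passed annotation")

    totals = out.groupby(["sample_id", "marker_id"])["count"].transform("sum")
    out = out[totals >= config.min_marker_count]
    if len(out) == 0:
        raise EmptyResultError(
            "sequence_filter: every combination below min_marker_count"
        )

    n_markers = len(markers.marker_ids)
    present = out.groupby("sample_id")["marker_id"].nunique()
    sm_miss = 1.0 - present / n_markers
    keep_samples = set(sm_miss[sm_miss <= config.max_sm_miss].index)
    out = out[out["sample_id"].isin(keep_samples)]
    if len(out) == 0:
        raise EmptyResultError("sequence_filter: all samples exceeded max_sm_miss")

    n_samples = len(manifest.sample_ids)
    present_m = out.groupby("marker_id")["sample_id"].nunique()
    mk_miss = 1.0 - present_m / n_samples
    keep_markers = set(mk_miss[mk_miss <= config.max_marker_miss].index)
    out = out[out["marker_id"].isin(keep_markers)]
    if len(out) == 0:
        raise EmptyResultError("sequence_filter: all markers exceeded max_marker_miss")
    return out.reset_index(drop=True)


def dataset_median_he(rows: pd.DataFrame) -> float:
    """Median over samples of each sample's median per-marker haplotype He."""
    sample_meds = []
    for _, sample_rows in rows.groupby("sample_id"):
        hes = []
        for _, combo in sample_rows.groupby("marker_id"):
            freqs = combo["count"] / combo["count"].sum()
            hes.append(1.0 - float((freqs**2).sum()))
        sample_meds.append(float(np.median(hes)))
    return float(np.median(sample_meds)) if sample_meds else 0.0


# ---------------------------------------------------------------------------
# naming, frequencies, orchestration

def name_haplotypes_and_frequencies(rows: pd.DataFrame) -> pd.DataFrame:
    """Name haplotypes per marker and compute within-sample frequencies.

    Per marker, distinct sequences are named ``<marker_id>-<k>`` with k
    assigned in descending total dataset read count (ties broken
    lexicographically by sequence).  Frequencies sum to 1 within each
    (sample_id, marker_id).
    """
    out = rows.copy()
    names: Dict[Tuple[str, str], str] = {}
    for marker_id, grp in out.groupby("marker_id"):
        totals = grp.groupby("sequence")["count"].sum()
        ordered = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
        for k, (seq, _) in enumerate(ordered, start=1):
            names[(marker_id, seq)] = f"{marker_id}-{k}"
    out["haplotype"] = [
        names[(m, s)] for m, s in zip(out["marker_id"], out["sequence"])
    ]
    combo_totals = out.groupby(["sample_id", "marker_id"])["count"].transform("sum")
    out["frequency"] = out["count"] / combo_totals
    return out


def sequence_filter(
    seq_ann_tbl: pd.DataFrame,
    manifest: SampleManifest,
    markers: MarkerInfo,
    out_dir=None,
    vcf_output_dir=None,
    config: Optional[PipelineConfig] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full post-annotation filtering stack.

    Returns ``(seq_flt_tbl, variant_table)``; the final table is also
    written as ``seq_flt_tbl.tsv`` and per-marker VCFs under
    ``vcf_output_dir`` when paths are given.
    """
    config = config or PipelineConfig()
    refs = {m: markers.reference(m) for m in markers.marker_ids}

    rows = seq_ann_tbl[seq_ann_tbl["status"] == "pass"].copy()
    if len(rows) == 0:
        raise EmptyResultError("sequence_filter: no pass rows in annotated table")

    corrected = []
    for _, r in rows.iterrows():
        s = clean_homopolymers(r["sequence"], refs[r["marker_id"]], config.min_homo_rep)
        s = clean_terminal_indels(s, refs[r["marker_id"]], config.terminal_region_len)
        corrected.append(s)
    rows["sequence"] = corrected
    rows["masked"] = False
    rows = _merge_identical(rows)

    rows = apply_dataset_filters(rows, config, manifest, markers)

    mask_active = dataset_median_he(rows) >= config.sample_med_He

    masked_parts = []
    var_parts = []
    for marker_id, grp in rows.groupby("marker_id", sort=True):
        mrow = markers.row(marker_id)
        var_tbl = call_variants(grp, refs[marker_id], mrow["chrom"], int(mrow["start"]))
        masked = mask_variants(grp, var_tbl, refs[marker_id], config, mask_active)
        masked_parts.append(masked)
        var_parts.append(var_tbl)
    rows = pd.concat(masked_parts, ignore_index=True)

    # final variant panel over the masked haplotypes, for the VCF and report
    final_vars = []
    for marker_id, grp in rows.groupby("marker_id", sort=True):
        mrow = markers.row(marker_id)
        final_vars.append(
            call_variants(grp, refs[marker_id], mrow["chrom"], int(mrow["start"]))
        )
    variant_table = (
        pd.concat(final_vars, ignore_index=True) if final_vars else pd.DataFrame()
    )

    rows["ident"] = [
        align_to_reference(s, refs[m]).ident
        for s, m in zip(rows["sequence"], rows["marker_id"])
    ]
    rows["status"] = "pass"
    rows = name_haplotypes_and_frequencies(rows)
    rows = rows.sort_values(
        ["sample_id", "marker_id", "haplotype"], kind="mergesort"
    ).reset_index(drop=True)
    rows = rows[SEQ_FLT_COLUMNS]

    if out_dir is not None:
        write_table(rows, Path(out_dir) / "seq_flt_tbl.tsv")
    if vcf_output_dir is not None:
        write_vcf(rows, variant_table, markers, manifest, vcf_output_dir)
    return rows, variant_table


def write_vcf(
    flt_rows: pd.DataFrame,
    variant_table: pd.DataFrame,
    markers: MarkerInfo,
    manifest: SampleManifest,
    vcf_dir,
) -> List[Path]:
    """Write one VCF 4.2 per marker with AF/MAF/HE INFO fields and one
    pseudo-sample column per study sample carrying allele read depths (AD).

    Deletion alleles are emitted as anchored indel records; substitution
    sites as plain SNV records.
    """
    vcf_dir = Path(vcf_dir)
    vcf_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for marker_id in sorted(set(variant_table["marker_id"])) if len(variant_table) else []:
        mrow = markers.row(marker_id)
        ref = mrow["seq"]
        start = int(mrow["start"])
        header = pysam.VariantHeader()
        header.add_line(f"##contig=<ID={mrow['chrom']}>")
        header.add_meta("INFO", items=[("ID", "AF"), ("Number", "A"), ("Type", "Float"),
                                       ("Description", "Alternate allele frequency")])
        header.add_meta("INFO", items=[("ID", "MAF"), ("Number", "1"), ("Type", "Float"),
                                       ("Description", "Minor allele frequency")])
        header.add_meta("INFO", items=[("ID", "HE"), ("Number", "1"), ("Type", "Float"),
                                       ("Description", "Expected heterozygosity")])
        header.add_meta("FORMAT", items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
                                         ("Description", "Read depth per allele")])
        sample_ids = manifest.sample_ids
        for sid in sample_ids:
            header.add_sample(sid)

        marker_rows = flt_rows[flt_rows["marker_id"] == marker_id]
        proj = {
            (r["sample_id"], r["sequence"]): project_to_reference(r["sequence"], ref)
            for _, r in marker_rows.iterrows()
        }
        path = vcf_dir / f"{marker_id}.vcf"
        vf = pysam.VariantFile(str(path), "w", header=header)
        site_rows = variant_table[variant_table["marker_id"] == marker_id]
        for _, site in site_rows.iterrows():
            offset = int(site["offset"])
            alleles = [a for a, _ in site["alleles"]]
            alts = [a for a in alleles if a != site["ref"]]
            has_del = "-" in alleles
            if has_del and offset == 0:
                logger.warning("%s: deletion allele at first base skipped in VCF", marker_id)
                continue
            if has_del:
                pos0 = offset - 1
                vref = ref[pos0 : offset + 1]
                valts = [ref[pos0] if a == "-" else ref[pos0] + a for a in alts]
            else:
                pos0 = offset
                vref = site["ref"]
                valts = alts
            freqs = dict(site["alleles"])
            rec = vf.new_record(
                contig=mrow["chrom"],
                start=start - 1 + pos0,
                alleles=tuple([vref] + valts),
            )
            rec.info["AF"] = tuple(round(freqs[a], 6) for a in alts)
            rec.info["MAF"] = float(site["maf"])
            rec.info["HE"] = float(site["he"])
            for sid in sample_ids:
                depths = {a: 0 for a in [site["ref"]] + alts}
                for _, r in marker_rows[marker_rows["sample_id"] == sid].iterrows():
                    a = proj[(r["sample_id"], r["sequence"])][offset]
                    if a in depths:
                        depths[a] += int(r["count"])
                rec.samples[sid]["AD"] = tuple(depths[a] for a in [site["ref"]] + alts)
            vf.write(rec)
        vf.close()
        paths.append(path)
    return paths
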