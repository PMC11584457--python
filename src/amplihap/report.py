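"""Summary metrics and the self-contained HTML run report.

The report is a single static HTML file: study tables, read tracking
through the pipeline, missingness, per-combination read counts, haplotype
counts, diversity metrics (expected heterozygosity He = 1 - sum(f^2) over
within-sample haplotype frequencies, SNP and haplotype counts), a
haplotype-vs-reference alignment view with SNP highlighting, a
neighbor-joining tree of major haplotypes (> 50% within-sample relative
abundance), and a PCA of samples on haplotype frequencies.  Figures are
embedded as base64 PNG; every number shown is recomputable from the stage
TSVs written next to the report.
"""

from __future__ import annotations

import base64
import html
import io
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Optional, Tuple

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .align import project_to_reference
from .datamodel import (
    LEDGER_STAGES,
    MarkerInfo,
    PipelineConfig,
    RunLedger,
    SampleManifest,
)

MAJOR_HAPLOTYPE_MIN_FREQ = 0.5


def diversity_metrics(final_tbl: pd.DataFrame, variant_table: Optional[pd.DataFrame] = None) -> dict:
    """Per-combination He and haplotype counts; per-marker SNP/haplotype counts."""
    if len(final_tbl) == 0:
        raise ValueError("diversity_metrics: empty final table")
    rows = []
    for (sid, mid), grp in final_tbl.groupby(["sample_id", "marker_id"]):
        freqs = grp["count"] / grp["count"].sum()
        rows.append(
            {
                "sample_id": sid,
                "marker_id": mid,
                "He": 1.0 - float((freqs**2).sum()),
                "n_haplotypes": len(grp),
            }
        )
    per_combination = pd.DataFrame(rows)
    marker_rows = []
    for mid, grp in final_tbl.groupby("marker_id"):
        n_snps = 0
        if variant_table is not None and len(variant_table):
            n_snps = int((variant_table["marker_id"] == mid).sum())
        marker_rows.append(
            {
                "marker_id": mid,
                "n_SNPs": n_snps,
                "n_unique_haplotypes": grp["sequence"].nunique(),
            }
        )
    return {"per_combination": per_combination, "per_marker": pd.DataFrame(marker_rows)}


def read_tracking(ledger: RunLedger) -> pd.DataFrame:
    """Stage-by-stage read counts with fractions of the demultiplexed input."""
    df = ledger.data.copy()
    for stage in LEDGER_STAGES:
        df[f"frac_{stage}"] = np.where(
            df["n_demux"] > 0, df[stage] / df["n_demux"], 0.0
        )
    return df


def haplotype_tree(final_tbl: pd.DataFrame, markers: MarkerInfo) -> Optional[str]:
    """Neighbor-joining newick tree over major haplotypes (freq > 0.5).

    Haplotypes are anchored to their marker reference (common column
    space); the distance between two leaves of the same marker is the
    proportion of differing reference columns, and 1.0 across markers
    (distinct loci share no columns).  Returns ``None`` (skip, with a
    report note) when fewer than three distinct major haplotypes exist.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    majors = final_tbl[final_tbl["frequency"] > MAJOR_HAPLOTYPE_MIN_FREQ]
    if len(majors) == 0:
        return None
    leaves = []
    for _, r in majors.iterrows():
        label = f"{r['sample']}_{r['marker_id']}_{r['haplotype']}"
        proj = project_to_reference(r["sequence"], markers.reference(r["marker_id"]))
        leaves.append((label, r["marker_id"], proj))
    if len({(m, p) for _, m, p in leaves}) < 3:
        return None
    n = len(leaves)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if leaves[i][1] != leaves[j][1]:
                d = 1.0
            else:
                a, b = leaves[i][2], leaves[j][2]
                d = sum(x != y for x, y in zip(a, b)) / len(a)
            dm[i, j] = dm[j, i] = d
    labels = [l for l, _, _ in leaves]
    tree = nj(DistanceMatrix(dm, labels))
    return str(tree).strip()


def pca(final_tbl: pd.DataFrame) -> Tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates from SVD of the centered haplotype-frequency matrix.

    Rows are samples, columns are (marker, haplotype) frequencies (absent
    haplotype = 0).  Returns (coordinates with PC1/PC2, explained-variance
    fractions).  Signs are fixed so the largest-magnitude loading of each
    component is positive.
    """
    mat = final_tbl.pivot_table(
        index="sample_id", columns="haplotype", values="frequency",
        aggfunc="sum", fill_value=0.0,
    ).sort_index()
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("pca requires >= 2 samples and >= 2 haplotype columns")
    x = mat.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for k in range(len(s)):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    coords = u * s
    total_var = (s**2).sum()
    explained = (s**2) / total_var if total_var > 0 else np.zeros_like(s)
    out = pd.DataFrame(
        {
            "sample_id": mat.index,
            "PC1": coords[:, 0],
            "PC2": coords[:, 1] if coords.shape[1] > 1 else 0.0,
        }
    ).reset_index(drop=True)
    return out, explained


# ---------------------------------------------------------------------------
# HTML assembly

def _fig_to_html(fig, title: str) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=110, bbox_inches="tight",
                metadata={"Software": "amplihap"})
    plt.close(fig)
    b64 = base64.b64encode(buf.getvalue()).decode()
    return f'<figure><img src="data:image/png;base64,{b64}" alt="{html.escape(title)}"/></figure>'


def _table_html(df: pd.DataFrame, max_rows: int = 200) -> str:
    shown = df.head(max_rows).copy()
    if "sequence" in shown.columns:
        shown["sequence"] = shown["sequence"].str.slice(0, 24) + "…"
    return shown.to_html(index=False, border=0, float_format=lambda v: f"{v:.4g}")


def _placeholder(name: str) -> str:
    return f"<p><em>Section unavailable: {html.escape(name)} table was not provided.</em></p>"


def _missingness_fig(final_tbl, manifest, markers):
    samples = manifest.sample_ids
    mids = markers.marker_ids
    mat = np.ones((len(samples), len(mids)))
    have = {(r["sample_id"], r["marker_id"]) for _, r in final_tbl.iterrows()}
    for i, s in enumerate(samples):
        for j, m in enumerate(mids):
            if (s, m) in have:
                mat[i, j] = 0.0
    fig, ax = plt.subplots(figsize=(1.2 + 0.7 * len(mids), 1.0 + 0.4 * len(samples)))
    ax.imshow(mat, cmap="Reds", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(len(mids)), mids, rotation=45, ha="right")
    ax.set_yticks(range(len(samples)), samples)
    ax.set_title("Missing (red) sample x marker combinations")
    return fig


def _alignment_view(final_tbl, markers) -> str:
    """Colored haplotype-vs-reference alignment, SNP columns highlighted."""
    parts = []
    colors = {"A": "#66c2a5", "C": "#8da0cb", "G": "#fc8d62", "T": "#e78ac3", "-": "#cccccc"}
    for mid in sorted(set(final_tbl["marker_id"])):
        ref = markers.reference(mid)
        grp = final_tbl[final_tbl["marker_id"] == mid]
        haps = (
            grp.groupby(["haplotype", "sequence"], as_index=False)["count"].sum()
            .sort_values("haplotype")
        )
        rows = [("reference", ref)]
        rows += [
            (r["haplotype"], project_to_reference(r["sequence"], ref))
            for _, r in haps.iterrows()
        ]
        snp_cols = {
            i for i in range(len(ref))
            if len({s[i] for _, s in rows}) > 1
        }
        body = []
        for name, seq in rows:
            cells = []
            for i, ch in enumerate(seq):
                if i in snp_cols:
                    style = f"background:{colors.get(ch, '#fff')};font-weight:bold"
                else:
                    style = "color:#999"
                cells.append(f'<span style="{style}">{ch}</span>')
            body.append(
                f'<div class="aln"><code>{html.escape(name):>12}</code> '
                f'<code>{"".join(cells)}</code></div>'
            )
        parts.append(f"<h4>{html.escape(mid)}</h4>" + "\n".join(body))
    return "\n".join(parts)


def generate_report(
    out_path,
    manifest: SampleManifest,
    markers: MarkerInfo,
    config: PipelineConfig,
    demultiplexed: Optional[pd.DataFrame] = None,
    flt_reads: Optional[pd.DataFrame] = None,
    sub_reads: Optional[pd.DataFrame] = None,
    seq_ann_tbl: Optional[pd.DataFrame] = None,
    seq_flt_tbl: Optional[pd.DataFrame] = None,
    variant_table: Optional[pd.DataFrame] = None,
    ledger: Optional[RunLedger] = None,
) -> Path:
    """Render the self-contained HTML report.

    Missing stage tables produce an explanatory placeholder in the
    corresponding section rather than an error.  Output is deterministic
    for identical inputs except for the timestamp line.
    """
    sections = []
    sections.append(("Sample manifest", _table_html(manifest.data)))
    sections.append(("Marker info", _table_html(markers.data)))

    if ledger is not None:
        track = read_tracking(ledger)
        fig, ax = plt.subplots(figsize=(7, 3.5))
        labels = [f"{r['sample_id']}:{r['marker_id']}" for _, r in track.iterrows()]
        x = np.arange(len(track))
        for stage in LEDGER_STAGES:
            ax.plot(x, track[stage], marker="o", label=stage)
        ax.set_xticks(x, labels, rotation=45, ha="right", fontsize=7)
        ax.set_ylabel("read pairs")
        ax.legend(fontsize=7)
        ax.set_title("Read tracking through the pipeline")
        sections.append(
            ("Read tracking", _fig_to_html(fig, "read tracking") + _table_html(track))
        )
    elif demultiplexed is not None:
        sections.append(("Read tracking", _table_html(demultiplexed)))
    else:
        sections.append(("Read tracking", _placeholder("demultiplex")))

    if seq_flt_tbl is not None and len(seq_flt_tbl):
        sections.append(
            ("Missingness", _fig_to_html(_missingness_fig(seq_flt_tbl, manifest, markers),
                                         "missingness"))
        )
        counts = seq_flt_tbl.pivot_table(
            index="sample_id", columns="marker_id", values="count",
            aggfunc="sum", fill_value=0,
        )
        fig, ax = plt.subplots(figsize=(5, 3))
        counts.plot.bar(ax=ax)
        ax.set_ylabel("final read pairs")
        ax.set_title("Per-combination read counts")
        sections.append(("Read counts", _fig_to_html(fig, "read counts")))

        hap_counts = (
            seq_flt_tbl.groupby(["sample_id", "marker_id"])["haplotype"]
            .nunique().unstack(fill_value=0)
        )
        fig, ax = plt.subplots(figsize=(5, 3))
        hap_counts.plot.bar(ax=ax)
        ax.set_ylabel("haplotypes detected")
        ax.set_title("Haplotypes per sample per marker")
        sections.append(("Haplotype counts", _fig_to_html(fig, "haplotype counts")))

        metrics = diversity_metrics(seq_flt_tbl, variant_table)
        sections.append(
            ("Diversity metrics",
             _table_html(metrics["per_combination"]) + _table_html(metrics["per_marker"]))
        )
        sections.append(("Haplotype alignment", _alignment_view(seq_flt_tbl, markers)))

        newick = haplotype_tree(seq_flt_tbl, markers)
        if newick is None:
            sections.append(
                ("Haplotype tree",
                 "<p><em>Fewer than three distinct major haplotypes; tree skipped.</em></p>")
            )
        else:
            tree_html = f"<pre>{html.escape(newick)}</pre>"
            try:
                from Bio import Phylo

                tree = Phylo.read(io.StringIO(newick), "newick")
                fig, ax = plt.subplots(figsize=(6, 0.6 + 0.35 * newick.count(",")))
                Phylo.draw(tree, axes=ax, do_show=False)
                tree_html += _fig_to_html(fig, "NJ tree")
            except Exception:  # tree drawing is cosmetic
                pass
            sections.append(("Haplotype tree", tree_html))

        try:
            coords, explained = pca(seq_flt_tbl)
            fig, ax = plt.subplots(figsize=(4.5, 4))
            ax.scatter(coords["PC1"], coords["PC2"])
            for _, r in coords.iterrows():
                ax.annotate(r["sample_id"], (r["PC1"], r["PC2"]), fontsize=8)
            ax.set_xlabel(f"PC1 ({explained[0]:.0%})")
            ax.set_ylabel(f"PC2 ({explained[1]:.0%})" if len(explained) > 1 else "PC2")
            ax.set_title("PCA of haplotype frequencies")
            sections.append(("PCA", _fig_to_html(fig, "PCA")))
        except ValueError as exc:
            sections.append(("PCA", f"<p><em>{html.escape(str(exc))}</em></p>"))

        sections.append(("Final haplotype table", _table_html(seq_flt_tbl)))
    else:
        for name in ("Missingness", "Diversity metrics", "Haplotype alignment",
                     "Haplotype tree", "PCA", "Final haplotype table"):
            sections.append((name, _placeholder("final haplotype")))

    if seq_ann_tbl is not None:
        status_counts = seq_ann_tbl["status"].value_counts().rename_axis("status").reset_index(name="n")
        sections.append(
            ("Annotation status", _table_html(status_counts) + _table_html(seq_ann_tbl))
        )

    cfg_rows = pd.DataFrame(
        sorted(config.to_dict().items()), columns=["parameter", "value"]
    )
    sections.append(("Configuration", _table_html(cfg_rows, max_rows=100)))

    stamp = datetime.now(timezone.utc).strftime("%Y-%m-%d %H:%M:%S UTC")
    body = "\n".join(
        f"<section><h2>{html.escape(name)}</h2>\n{content}</section>"
        for name, content in sections
    )
    doc = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Amplicon haplotyping report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; max-width: 1100px; }}
table {{ border-collapse: collapse; font-size: 12px; }}
td, th {{ padding: 2px 8px; border-bottom: 1px solid #ddd; text-align: left; }}
.aln code {{ font-size: 11px; white-space: nowrap; }}
section {{ margin-bottom: 2em; }}
</style></head>
<body>
<h1>Amplicon haplotyping report</h1>
<p class="timestamp">Generated: {stamp}</p>
{body}
</body></html>
"""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(doc)
    return out_path
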