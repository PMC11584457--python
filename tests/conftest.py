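import pandas as pd
import pytest

from amplihap import PipelineConfig, make_dataset1_fixture, process_run
from amplihap.datamodel import MarkerInfo, SampleManifest


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A complete small synthetic run: five mixture samples x two markers,
    1,200 read pairs per combination, plus the full pipeline result."""
    root = tmp_path_factory.mktemp("smallrun")
    sim = make_dataset1_fixture(7, root / "sim", reads_per_combination=1200)
    config = PipelineConfig(min_read_count=500, min_marker_count=100, seed=7)
    result = process_run(
        sim.reads_1, sim.reads_2, sim.manifest, sim.markers,
        root / "run", config, make_report=False,
    )
    return {"sim": sim, "config": config, "result": result, "run_dir": root / "run"}


@pytest.fixture()
def toy_manifest():
    return SampleManifest(
        pd.DataFrame(
            {
                "sample_id": ["S01", "S02"],
                "barcode_fwd": ["ATCGCTAT", "GTGACGAA"],
                "barcode_rev": ["TCTAATGT", "TTACAGCA"],
                "sample": ["mix_1_1", "mix_1_10"],
                "info": ["1_1", "1_10"],
            }
        )
    )


@pytest.fixture()
def toy_markers():
    return MarkerInfo(
        pd.DataFrame(
            {
                "marker_id": ["M1"],
                "primer_fwd": ["GTGGAGTATG"],
                "primer_rev": ["CTAGCATACT"],
                "seq": ["ACGTACGTACGTACGTACGTACGTACGTAC"],
                "chrom": ["chr1"],
                "start": [101],
                "end": [130],
            }
        )
    )


def write_fastq_pair(tmp_path, records):
    """records: list of (title, seq1, qual1, seq2, qual2)."""
    from amplihap._fastq import write_fastq

    r1 = tmp_path / "r1.fastq.gz"
    r2 = tmp_path / "r2.fastq.gz"
    write_fastq(r1, [(t, s1, q1) for t, s1, q1, _, _ in records])
    write_fastq(r2, [(t, s2, q2) for t, _, _, s2, q2 in records])
    return r1, r2
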