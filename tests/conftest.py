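import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import meripkit as mk

settings.register_profile(
    "ci",
    derandomize=True,
    database=None,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_cfg():
    return mk.SimConfig(seed=11)


@pytest.fixture(scope="session")
def transcriptome(sim_cfg):
    return mk.simulate_transcriptome(sim_cfg)


@pytest.fixture(scope="session")
def merip_table(sim_cfg, transcriptome):
    return mk.simulate_merip_counts(transcriptome, sim_cfg)


@pytest.fixture(scope="session")
def called_peaks(merip_table):
    return mk.call_peaks(merip_table)


@pytest.fixture()
def toy_gtf(tmp_path):
    """Three transcripts: plus-strand coding, minus-strand two-exon, short."""
    lines = [
        # txA: single exon 101-200 (GTF 1-based), CDS 151-180, plus strand
        'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "gA"; transcript_id "txA";',
        'chr1\tsrc\tCDS\t151\t180\t.\t+\t.\tgene_id "gA"; transcript_id "txA";',
        # txB: minus strand, two exons; the exon listed last in the file is
        # first in transcript order
        'chr1\tsrc\texon\t301\t350\t.\t-\t.\tgene_id "gB"; transcript_id "txB";',
        'chr1\tsrc\texon\t401\t460\t.\t-\t.\tgene_id "gB"; transcript_id "txB";',
        # txC: non-coding single exon
        'chr1\tsrc\texon\t601\t650\t.\t+\t.\tgene_id "gC"; transcript_id "txC";',
    ]
    path = tmp_path / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path


def random_model(seed: int) -> mk.TranscriptModel:
    """A small random multi-exon transcript model for property tests."""
    rng = np.random.default_rng(seed)
    n_exons = int(rng.integers(1, 5))
    lengths = rng.integers(5, 60, size=n_exons)
    strand = "+" if rng.random() < 0.5 else "-"
    intervals = []
    pos = int(rng.integers(0, 1000))
    for ln in lengths:
        intervals.append((pos, pos + int(ln)))
        pos += int(ln) + int(rng.integers(1, 50))
    exons = tuple(intervals if strand == "+" else intervals[::-1])
    total = int(lengths.sum())
    cds_start = int(rng.integers(0, total - 1))
    cds_end = int(rng.integers(cds_start + 1, total + 1))
    return mk.TranscriptModel(
        f"tx{seed}", f"g{seed}", "chrP", strand, exons, cds_start, cds_end
    )
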