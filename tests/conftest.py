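import numpy as np
import pandas as pd
import pytest

from retintron.annotation import IntronRecord, extract_introns, read_gtf
from retintron.quantify import build_ir_matrix
from retintron.simulate import SimulationConfig, make_genome, simulate_cohort


@pytest.fixture(scope="session")
def tiny_gtf(tmp_path_factory):
    """Two genes: a 3-exon plus-strand coding gene and a 2-exon minus-strand
    gene whose intron spans an exon of a third overlapping transcript."""
    path = tmp_path_factory.mktemp("anno") / "tiny.gtf"
    lines = [
        # gene A: exons [100,200), [300,420), [500,600) -> introns (200,300), (420,500)
        'chr1\tt\texon\t101\t200\t.\t+\t.\tgene_id "gA"; transcript_id "tA";',
        'chr1\tt\texon\t301\t420\t.\t+\t.\tgene_id "gA"; transcript_id "tA";',
        'chr1\tt\texon\t501\t600\t.\t+\t.\tgene_id "gA"; transcript_id "tA";',
        'chr1\tt\tCDS\t151\t200\t.\t+\t0\tgene_id "gA"; transcript_id "tA";',
        'chr1\tt\tCDS\t301\t420\t.\t+\t1\tgene_id "gA"; transcript_id "tA";',
        'chr1\tt\tCDS\t501\t550\t.\t+\t2\tgene_id "gA"; transcript_id "tA";',
        # gene B, minus strand: exons [1000,1100), [1300,1400)
        'chr1\tt\texon\t1001\t1100\t.\t-\t.\tgene_id "gB"; transcript_id "tB";',
        'chr1\tt\texon\t1301\t1400\t.\t-\t.\tgene_id "gB"; transcript_id "tB";',
        # gene C: single exon inside gene B's intron -> flags overlap
        'chr1\tt\texon\t1151\t1250\t.\t+\t.\tgene_id "gC"; transcript_id "tC";',
    ]
    path.write_text("\n".join(lines) + "\n")
    return str(path)


@pytest.fixture(scope="session")
def tiny_models(tiny_gtf):
    return read_gtf(tiny_gtf)


@pytest.fixture(scope="session")
def synthetic_genome():
    cfg = SimulationConfig(n_genes=8, uorf_starts=3)
    genome, models = make_genome(cfg, seed=11)
    return genome, models


def make_intron_records(introns):
    """(intron_id, length) tuples -> minimal IntronRecords on one contig."""
    recs, pos = [], 0
    for iid, L in introns:
        recs.append(IntronRecord(iid, "g", "t", "chrS", "+", pos, pos + L, 1, 1))
        pos += L + 50
    return recs


@pytest.fixture(scope="session")
def paired_cohort():
    """30-pair cohort, 100 introns, 10 planted DIRs of delta-psi 0.3."""
    cfg = SimulationConfig(n_pairs=30, depth=100.0)
    introns = [(f"i{k:03d}", 150) for k in range(100)]
    psi = {iid: 0.15 for iid, _ in introns}
    planted = {f"i{k:03d}": 0.3 for k in range(10)}
    summaries, truth = simulate_cohort(cfg, seed=21, introns=introns, psi_map=psi, planted_dirs=planted)
    matrix = build_ir_matrix(summaries, make_intron_records(introns))
    return matrix, truth
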