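"""Intron classes, positional features, NMD rule chain and uORF detection."""

import numpy as np
import pandas as pd
import pytest

from retintron.annotation import GeneModel, extract_introns
from retintron.features import (
    classify_intron,
    find_uorfs,
    gc_content,
    intron_sequence,
    predict_nmd,
    relative_gene_position,
    transcript_sequence,
)
from retintron.simulate import SimulationConfig, make_genome

# ---------------------------------------------------------------------------
# transcript construction helper: spliced parts + introns -> genome + model


def build_transcript(spliced: str, cuts, intron_seqs, cds=(None, None), strand="+"):
    """Assemble a one-transcript genome from a spliced sequence, cut
    positions (spliced coords) and intron sequences inserted there."""
    pre, prev, exon_tx, pos = [], 0, [], 0
    for k, c in enumerate(list(cuts) + [len(spliced)]):
        pre.append(spliced[prev:c])
        exon_tx.append((pos, pos + c - prev))
        pos += c - prev
        if k < len(cuts):
            pre.append(intron_seqs[k])
            pos += len(intron_seqs[k])
        prev = c
    genomic = "".join(pre)
    if strand == "+":
        genome = {"chrT": genomic}
        exons = exon_tx
    else:
        comp = genomic.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        genome = {"chrT": comp}
        exons = [(len(genomic) - e, len(genomic) - s) for s, e in exon_tx]
    model = GeneModel("gT", "txT", "chrT", strand, exons, cds_start=cds[0], cds_end=cds[1])
    return genome, model


def nmd_oracle(model, intron, genome):
    """Brute-force NMD restatement: build the retained mRNA explicitly,
    walk codons linearly, and compare the stop against the junction list."""
    spliced = transcript_sequence(model, genome)
    iseq = intron_sequence(model, intron, genome)
    lens = [e - s for s, e in model.exons]
    junctions_spliced = list(np.cumsum(lens))[:-1]
    p = junctions_spliced[intron.ordinal - 1]
    if p <= model.cds_start or p >= model.cds_end:
        return "no_NMD"
    if p - model.cds_start < 200:
        return "no_NMD"
    if intron.ordinal == len(junctions_spliced):
        return "no_NMD"
    mrna = spliced[:p] + iseq + spliced[p:]
    stop = None
    for i in range(model.cds_start, len(mrna) - 2, 3):
        if mrna[i : i + 3] in ("TAA", "TAG", "TGA"):
            stop = i
            break
    normal_stop = model.cds_end - 3 + len(iseq)
    if stop is None or stop >= normal_stop:
        return "no_NMD"
    retained_junctions = [
        q + len(iseq) if q > p else q
        for k, q in enumerate(junctions_spliced, start=1)
        if k != intron.ordinal
    ]
    if max(retained_junctions) - stop <= 55:
        return "no_NMD"
    return "NMD"


def _one_intron(model):
    recs = extract_introns([model])
    return {r.ordinal: r for r in recs}


CDS300 = "ATG" + "GCT" * 298 + "TAA"  # 900 nt, stop-free body


def test_utr_introns_escape_nmd():
    utr5, utr3 = "C" * 60, "G" * 100
    spliced = utr5 + CDS300 + utr3
    cds = (60, 60 + 900)
    # one intron in the 3'UTR, one mid-CDS so the 3'UTR one is not last
    genome, model = build_transcript(
        spliced, [60 + 450, 60 + 900 + 50], ["GT" + "C" * 96 + "AG"] * 2, cds
    )
    introns = _one_intron(model)
    call = predict_nmd(model, introns[2], genome)
    assert (call.verdict, call.reason) == ("no_NMD", "utr")
    assert introns[2].region == "3UTR"


def test_near_start_escape():
    spliced = "C" * 60 + CDS300 + "G" * 100
    cds = (60, 960)
    genome, model = build_transcript(
        spliced, [60 + 150, 60 + 600], ["GT" + "A" * 50 + "AG"] * 2, cds
    )
    call = predict_nmd(model, _one_intron(model)[1], genome)
    assert (call.verdict, call.reason) == ("no_NMD", "near_start")


def test_last_intron_escape():
    spliced = "C" * 60 + CDS300 + "G" * 100
    cds = (60, 960)
    genome, model = build_transcript(
        spliced, [60 + 300, 60 + 600], ["GT" + "A" * 50 + "AG"] * 2, cds
    )
    call = predict_nmd(model, _one_intron(model)[2], genome)
    assert (call.verdict, call.reason) == ("no_NMD", "last_intron")


def test_frame_preserving_stop_free_intron_is_no_ptc():
    spliced = "C" * 60 + CDS300 + "G" * 100
    cds = (60, 960)
    quiet = "GGC" * 20  # 60 nt, frame-preserving, no stop in any frame
    genome, model = build_transcript(
        spliced, [60 + 300, 60 + 600], [quiet, "GT" + "A" * 50 + "AG"], cds
    )
    call = predict_nmd(model, _one_intron(model)[1], genome)
    assert (call.verdict, call.reason) == ("no_NMD", "no_ptc")


def test_ptc_near_last_junction_escapes():
    # PTC right at the intron start; short downstream exon keeps the stop
    # within 55 nt of the last junction
    spliced = "C" * 60 + CDS300 + "G" * 100
    cds = (60, 960)
    p = 60 + 300  # (p - cds_start) % 3 == 0: TAA lands in frame
    genome, model = build_transcript(
        spliced, [p, p + 20], ["TAA" + "C" * 27, "GT" + "A" * 50 + "AG"], cds
    )
    call = predict_nmd(model, _one_intron(model)[1], genome)
    assert (call.verdict, call.reason) == ("no_NMD", "ptc_within_55")
    # distance: junction at p+20 shifts by 30 (intron len) -> 50 nt from PTC


def test_mid_cds_ptc_triggers_nmd():
    spliced = "C" * 60 + CDS300 + "G" * 100
    cds = (60, 960)
    p = 60 + 300
    genome, model = build_transcript(
        spliced, [p, p + 400], ["TAA" + "C" * 27, "GT" + "A" * 50 + "AG"], cds
    )
    call = predict_nmd(model, _one_intron(model)[1], genome)
    assert (call.verdict, call.reason) == ("NMD", "ptc_triggers")
    assert call.ptc_tx_pos == p


def test_predict_nmd_requires_cds():
    genome, model = build_transcript("A" * 200, [100], ["GT" + "C" * 46 + "AG"])
    with pytest.raises(ValueError, match="CDS"):
        predict_nmd(model, _one_intron(model)[1], genome)


def test_nmd_agrees_with_oracle_on_randomized_transcripts():
    """Rule chain vs brute-force mRNA-construction oracle, both strands."""
    n_checked = 0
    for seed in range(6):
        genome, models = make_genome(SimulationConfig(n_genes=12), seed=seed)
        introns = extract_introns(models)
        by_tx = {m.transcript_id: m for m in models}
        for r in introns:
            m = by_tx[r.transcript_id]
            call = predict_nmd(m, r, genome)
            assert call.verdict == nmd_oracle(m, r, genome), (seed, r.intron_id)
            n_checked += 1
    assert n_checked >= 200


def test_gc_content_values():
    assert gc_content("GCGC") == 1.0
    assert gc_content("ATAT") == 0.0
    assert gc_content("ACGT") == 0.5
    with pytest.raises(ValueError):
        gc_content("")


def test_relative_gene_position_convention(tiny_models):
    from retintron.annotation import IntronRecord

    mk = lambda o, n: IntronRecord(f"i{o}", "g", "t", "c", "+", 0, 10, o, n)
    assert relative_gene_position(mk(1, 4)) == 0.0
    assert relative_gene_position(mk(3, 5)) == 0.5
    assert relative_gene_position(mk(4, 4)) == 1.0
    assert relative_gene_position(mk(1, 2)) is None  # <3 introns excluded


def test_relative_positions_mirror_on_reverse_strand():
    """A minus-strand gene's introns span the same genomic gaps but the
    ordinal (hence relative position) runs the other way."""
    genome, models = make_genome(SimulationConfig(n_genes=6), seed=4)
    minus = [m for m in models if m.strand == "-"]
    assert minus
    for m in minus:
        recs = sorted(
            (r for r in extract_introns([m])), key=lambda r: r.start
        )
        n = len(recs)
        if n < 3:
            continue
        pos = [relative_gene_position(r) for r in recs]
        # genomic order ascending = transcript order descending on minus strand
        assert pos == sorted(pos, reverse=True)
        assert pos[0] == 1.0 and pos[-1] == 0.0


def test_relative_position_uniform_spacing():
    genome, models = make_genome(SimulationConfig(n_genes=4, exons_per_gene=(6, 6)), seed=8)
    for m in models:
        recs = sorted(extract_introns([m]), key=lambda r: r.ordinal)
        pos = [relative_gene_position(r) for r in recs]
        assert pos == pytest.approx(list(np.linspace(0, 1, len(recs))))


def test_classify_intron_rules():
    medians = pd.DataFrame(
        {"c1_t": [0.0, 0.2, 0.1], "c1_n": [0.0, 0.15, 0.1]},
        index=["a", "b", "c"],
    )
    up = pd.DataFrame({"direction": ["up"], "is_dir": [True]}, index=["c"])
    assert classify_intron("a", medians, {}) == "constitutive"
    assert classify_intron("b", medians, {"c1": up}) == "unregulated_retained"
    assert classify_intron("c", medians, {"c1": up}) == "dir_up"


def test_find_uorfs_enumeration():
    assert find_uorfs("CCCCCCCCC", 6) == []
    # one 1-codon uORF: ATG GCT TAA
    seq = "AA" + "ATG" + "GCT" + "TAA" + "CCC" + "ATGMAIN"
    assert find_uorfs(seq, seq.find("ATGMAIN")) == [(2, 8, 2)]
    # ATG without an in-frame stop is incomplete -> excluded by default
    seq2 = "ATGGGGGGG" + "ATGMAIN"
    assert find_uorfs(seq2, 9) == []
    assert find_uorfs(seq2, 9, include_incomplete=True)[0][0] == 0


def test_find_uorfs_matches_codon_walk_oracle():
    """Enumeration agrees with an independent frame-walk over random UTRs."""
    rng = np.random.default_rng(5)
    for _ in range(50):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        main = 250
        got = find_uorfs(seq, main)
        expected = []
        for i in range(main):  # every upstream ATG, first in-frame stop
            if seq[i : i + 3] != "ATG":
                continue
            for j in range(i, len(seq) - 2, 3):
                if seq[j : j + 3] in ("TAA", "TAG", "TGA"):
                    expected.append((i, j, (j - i) // 3))
                    break
        assert got == expected
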