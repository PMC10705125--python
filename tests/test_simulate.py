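"""Synthetic-data generators: determinism, construction guarantees, and
statistical contracts (Monte-Carlo checks at fixed seeds)."""

import numpy as np
import pandas as pd
import pytest

from retintron import features
from retintron.annotation import extract_introns, intron_tx_position
from retintron.quantify import ir_call
from retintron.simulate import (
    SimulationConfig,
    make_genome,
    simulate_cohort,
    simulate_sample,
    simulate_survival,
)


def test_make_genome_deterministic(tmp_path):
    cfg = SimulationConfig(n_genes=10)
    for name in ("a", "b"):
        make_genome(cfg, 1, str(tmp_path / f"{name}.fa"), str(tmp_path / f"{name}.gtf"))
    assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()
    assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()


def test_make_genome_rejects_bad_config():
    with pytest.raises(ValueError):
        make_genome(SimulationConfig(n_genes=0), 1)
    with pytest.raises(ValueError):
        make_genome(SimulationConfig(intron_length=(2, 10)), 1)


def test_intron_gc_tracks_target():
    genome, models = make_genome(SimulationConfig(n_genes=10, gc_target=0.8), seed=2)
    introns = extract_introns(models)
    gcs = [
        features.gc_content(genome[r.chrom][r.start : r.end])
        for r in introns
        if models[0].strand  # all introns; sense vs antisense GC is identical
    ]
    assert 0.75 <= np.mean(gcs) <= 0.85


def test_uorf_gene_plants_exact_start_count(synthetic_genome):
    genome, models = synthetic_genome
    m = next(x for x in models if x.gene_id == "gene_0")
    introns = [r for r in extract_introns(models) if r.gene_id == "gene_0"]
    first = next(r for r in introns if r.ordinal == 1)
    assert first.region == "5UTR"
    spliced = features.transcript_sequence(m, genome)
    iseq = features.intron_sequence(m, first, genome)
    p = intron_tx_position(m, 1)
    retained_utr = spliced[:p] + iseq + spliced[p : m.cds_start]
    assert retained_utr.count("ATG") == 3
    # and the spliced 5'UTR has none
    assert spliced[: m.cds_start].count("ATG") == 0


def test_splice_dinucleotides_canonical(synthetic_genome):
    genome, models = synthetic_genome
    for r in extract_introns(models):
        m = next(x for x in models if x.transcript_id == r.transcript_id)
        seq = features.intron_sequence(m, r, genome)
        assert seq.startswith("GT") and seq.endswith("AG")


def test_simulate_sample_degenerate_psi():
    introns = [("i0", 100)]
    s = simulate_sample(introns, {"i0": 0.0}, 100.0, seed=1)
    m, cov, j = s.intron_stats["i0"]
    assert m == 0 and 60 <= j <= 140
    # fully retained: junction reads starve, quantification goes missing
    s1 = simulate_sample(introns, {"i0": 1.0}, 100.0, seed=1)
    m1, cov1, j1 = s1.intron_stats["i0"]
    assert j1 < 4 and ir_call(m1, cov1, j1).state == "missing"
    with pytest.raises(ValueError):
        simulate_sample(introns, {"i0": 0.5}, 0.0, seed=1)
    with pytest.raises(KeyError):
        simulate_sample(introns, {}, 100.0, seed=1)


def test_irratio_consistency_as_depth_grows():
    introns = [(f"i{k}", 150) for k in range(150)]
    psi = 0.3
    errs = []
    for d in (30.0, 100.0, 300.0):
        s = simulate_sample(introns, {i: psi for i, _ in introns}, d, seed=9)
        vals = [v for v in (ir_call(*s.intron_stats[i]).as_float for i, _ in introns)
                if not np.isnan(v)]
        errs.append(abs(np.mean(vals) - psi))
    assert errs[-1] <= errs[0] + 0.01  # estimator tightens with depth
    assert errs[-1] <= 0.03


def test_cohort_truth_table_and_determinism():
    cfg = SimulationConfig(n_pairs=5)
    introns = [(f"i{k}", 100) for k in range(60)]
    psi = {i: 0.2 for i, _ in introns}
    planted = {f"i{k}": 0.3 for k in range(50)}
    s1, t1 = simulate_cohort(cfg, 7, introns=introns, psi_map=psi, planted_dirs=planted)
    s2, t2 = simulate_cohort(cfg, 7, introns=introns, psi_map=psi, planted_dirs=planted)
    s3, t3 = simulate_cohort(cfg, 8, introns=introns, psi_map=psi, planted_dirs=planted)
    assert int(t1["is_dir"].sum()) == 50
    pd.testing.assert_frame_equal(t1, t3)  # truth independent of realization
    assert s1[0].intron_stats == s2[0].intron_stats
    assert s1[0].intron_stats != s3[0].intron_stats
    assert len(s1) == 10 and {x.condition for x in s1} == {"tumor", "normal"}


def test_cohort_null_config_has_no_planted_effects():
    cfg = SimulationConfig(n_pairs=3)
    _, truth = simulate_cohort(cfg, 1)
    assert not truth["is_dir"].any()
    assert (truth["psi_tumor"] == truth["psi_normal"]).all()


def test_survival_event_fraction_matches_censoring():
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(rng.uniform(0, 0.5, size=(5, 500)),
                        index=[f"i{k}" for k in range(5)],
                        columns=[f"P{j}" for j in range(500)])
    surv = simulate_survival(vals, {}, h0=0.01, censor_frac=0.3, seed=4)
    assert 0.65 <= surv["event"].mean() <= 0.75
    assert (surv["time"] > 0).all()


def test_survival_recovers_planted_hazard():
    rng = np.random.default_rng(1)
    vals = pd.DataFrame(rng.uniform(0, 0.5, size=(3, 400)),
                        index=["a", "b", "c"], columns=[f"P{j}" for j in range(400)])
    surv = simulate_survival(vals, {"a": 1.0}, h0=0.01, censor_frac=0.0, seed=2)
    x = (vals.loc["a"] > vals.loc["a"].median()).astype(int)
    from lifelines import CoxPHFitter

    df = pd.concat([surv[["time", "event"]], x.rename("x")], axis=1)
    cph = CoxPHFitter().fit(df, "time", "event")
    assert np.exp(cph.params_["x"]) == pytest.approx(np.e, rel=0.25)


def test_survival_rejects_empty_matrix():
    with pytest.raises(ValueError):
        simulate_survival(pd.DataFrame(), {}, 0.01, 0.2, 1)


def test_sam_round_trip_matches_summary_model(tmp_path):
    """The SAM emission + reader path reproduces the evidence model."""
    from retintron.quantify import summarize_alignments
    from retintron.simulate import emit_sam

    genome, models = make_genome(SimulationConfig(n_genes=3), seed=6)
    introns = [r for r in extract_introns(models) if not r.known_exon_overlap][:6]
    psi = {r.intron_id: 0.4 for r in introns}
    sam = tmp_path / "toy.sam"
    emit_sam(genome, introns, psi, 50.0, seed=3, path=str(sam))
    summ = summarize_alignments(str(sam), introns, sample_id="toy")
    for r in introns:
        m, cov, j = summ.intron_stats[r.intron_id]
        v = ir_call(m, cov, j)
        if v.state == "value":
            assert abs(v.irratio - 0.4) < 0.2
    assert any(ir_call(*summ.intron_stats[r.intron_id]).state == "value" for r in introns)
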