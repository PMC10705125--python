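"""Synthetic data with planted ground truth.

Everything downstream of read alignment is testable without controlled-access
data by simulating the quantities the pipeline consumes:

* ``make_genome`` — a small genome (FASTA) plus a GENCODE-style GTF with
  multi-exon protein-coding genes, controllable intron GC content and
  length, and optionally a 5'UTR intron carrying a configurable number of
  upstream start codons (uORFs) in its retained form.
* ``simulate_sample`` — per-intron read evidence under a true retention
  fraction psi: intron base depth ~ Poisson(d*psi) i.i.d. per base and
  flanking-junction split reads ~ Poisson(d*(1-psi)), so the locus depth
  budget d is shared between the retained and spliced isoforms and the
  IRratio m/(m+J) is a consistent estimator of psi.
* ``simulate_cohort`` — paired tumor/normal samples with planted
  differential-retention effects and a per-patient random effect on
  logit(psi) (sd 0.3 by default) inducing within-pair correlation.
* ``simulate_survival`` — exponential event times with hazard
  h0*exp(sum beta_i * x_i), x_i the IR-high (median-split) indicator of
  intron i, under independent uniform censoring calibrated to a target
  censored fraction.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .summaries import AlignmentSummary

__all__ = [
    "SimulationConfig",
    "make_genome",
    "write_fasta",
    "write_gtf",
    "simulate_sample",
    "simulate_cohort",
    "simulate_survival",
    "emit_sam",
]

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]


@dataclass
class SimulationConfig:
    """Knobs for the synthetic genome and cohort generators."""

    n_genes: int = 20
    exons_per_gene: Tuple[int, int] = (4, 8)  # inclusive range
    intron_length: Tuple[int, int] = (80, 300)
    gc_target: float = 0.45  # intron-body GC fraction
    utr5_length: Tuple[int, int] = (100, 200)
    cds_codons: Tuple[int, int] = (100, 250)
    utr3_length: Tuple[int, int] = (150, 300)
    uorf_starts: int = 0  # ATGs planted in a 5'UTR intron of gene 0
    depth: float = 100.0  # mean locus depth d
    intergenic_fraction: float = 0.05  # intergenic/coding read ratio
    coding_reads: int = 1_000_000
    n_pairs: int = 30
    pair_effect_sd: float = 0.3  # sd of the patient effect on logit(psi)
    cancer_type: str = "SYN"


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _seq_without(rng: np.random.Generator, n: int, gc: float, forbidden: str) -> str:
    for _ in range(200):
        s = _random_seq(rng, n, gc)
        if forbidden not in s:
            return s
    raise RuntimeError("could not generate sequence avoiding motif")


def _coding_seq(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(len(_SENSE_CODONS), size=n_codons)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in codons) + "TAA"


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _uorf_intron(rng: np.random.Generator, length: int, gc: float, n_starts: int) -> str:
    """Intron sequence whose retained form adds exactly *n_starts* upstream
    ATGs, each opening a short in-frame ORF terminated within the intron."""
    core_len = length - 4 - 15 * n_starts
    if core_len < n_starts + 1:
        raise ValueError("intron too short for requested uORF starts")
    for _ in range(200):
        blocks = []
        for _ in range(n_starts):
            inner = "".join(_SENSE_CODONS[i] for i in rng.choice(len(_SENSE_CODONS), size=3))
            blocks.append("ATG" + inner + "TAA")
        # split ATG-free filler around the planted blocks
        cuts = np.sort(rng.choice(core_len - 1, size=n_starts, replace=False)) + 1 if n_starts else []
        filler = _seq_without(rng, core_len, gc, "ATG")
        parts, prev = [], 0
        for c in list(cuts) + [core_len]:
            parts.append(filler[prev:c])
            prev = c
        body = parts[0] + "".join(b + p for b, p in zip(blocks, parts[1:]))
        seq = "GT" + body + "AG"
        if seq.count("ATG") == n_starts:  # no accidental ATG across junctions
            assert len(seq) == length
            return seq
    raise RuntimeError("could not plant exact uORF start count")


def make_genome(
    config: SimulationConfig,
    seed: int,
    fasta_path: Optional[str] = None,
    gtf_path: Optional[str] = None,
) -> Tuple[Dict[str, str], List[GeneModel]]:
    """Generate a genome dict {chrom: sequence} and transcript models.

    Gene *i* lives on its own contig ``chr_gene_i``; every third gene is on
    the minus strand.  When ``config.uorf_starts > 0`` the first intron of
    gene 0 is placed inside the 5'UTR and carries that many upstream start
    codons.  Deterministic given *seed*; optionally writes FASTA/GTF.
    """
    if config.n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if config.intron_length[0] < 4:
        raise ValueError("introns must be at least 4 nt (splice dinucleotides)")
    rng = np.random.default_rng(seed)
    genome: Dict[str, str] = {}
    models: List[GeneModel] = []
    for gi in range(config.n_genes):
        chrom = f"chr_gene_{gi}"
        strand = "-" if gi % 3 == 2 else "+"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        utr5 = _seq_without(rng, int(rng.integers(*config.utr5_length)), 0.5, "ATG")
        cds = _coding_seq(rng, int(rng.integers(*config.cds_codons)))
        utr3 = _random_seq(rng, int(rng.integers(*config.utr3_length)), 0.5)
        spliced = utr5 + cds + utr3
        want_uorf = gi == 0 and config.uorf_starts > 0
        # distinct interior cut points, >=10 nt apart and away from the ends;
        # for the uORF gene only the first junction falls inside the 5'UTR
        n_cuts = n_ex - 1
        lo_cut = len(utr5) + 10 if want_uorf else 10
        while True:
            cuts = np.sort(rng.choice(np.arange(lo_cut, len(spliced) - 10), size=n_cuts, replace=False))
            if np.all(np.diff(cuts) >= 10):
                break
        if want_uorf:
            while True:
                c0 = int(rng.integers(10, len(utr5) - 5))
                if utr5[c0 - 2 : c0] != "AT":  # intron starts with G: avoid boundary ATG
                    break
            cuts[0] = c0
            cuts = np.sort(cuts)
        intron_seqs = []
        for k in range(n_cuts):
            L = int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
            if want_uorf and k == 0:
                L = max(L, 4 + 16 * config.uorf_starts + 4)
                intron_seqs.append(_uorf_intron(rng, L, config.gc_target, config.uorf_starts))
            else:
                intron_seqs.append("GT" + _random_seq(rng, L - 4, config.gc_target) + "AG")
        # assemble the pre-mRNA (transcript sense) and exon offsets within it
        pre, prev = [], 0
        exon_tx: List[Tuple[int, int]] = []  # within pre-mRNA, transcript sense
        pos = 0
        for k, c in enumerate(list(cuts) + [len(spliced)]):
            pre.append(spliced[prev:c])
            exon_tx.append((pos, pos + (c - prev)))
            pos += c - prev
            if k < n_cuts:
                pre.append(intron_seqs[k])
                pos += len(intron_seqs[k])
            prev = c
        pre_seq = "".join(pre)
        pad5 = _random_seq(rng, 100, 0.5)
        pad3 = _random_seq(rng, 100, 0.5)
        if strand == "+":
            genome[chrom] = pad5 + pre_seq + pad3
            exons_genomic = [(100 + s, 100 + e) for s, e in exon_tx]
        else:
            genome[chrom] = pad5 + _revcomp(pre_seq) + pad3
            glen = len(genome[chrom])
            exons_genomic = [(glen - 100 - e, glen - 100 - s) for s, e in exon_tx]
        models.append(
            GeneModel(
                gene_id=f"gene_{gi}",
                transcript_id=f"tx_{gi}",
                chrom=chrom,
                strand=strand,
                exons=exons_genomic,
                cds_start=len(utr5),
                cds_end=len(utr5) + len(cds),
                biotype="protein_coding",
            )
        )
    if fasta_path is not None:
        write_fasta(genome, fasta_path)
    if gtf_path is not None:
        write_gtf(models, genome, gtf_path)
    return genome, models


def write_fasta(genome: Dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(models: Sequence[GeneModel], genome: Dict[str, str], path: str) -> None:
    """Emit exon and CDS features (1-based inclusive, GENCODE-style attrs).

    The CDS features cover the transcript CDS bounds including the stop
    codon, matching how the parser derives transcript-level bounds.
    """
    with open(path, "w") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_type "{m.biotype}";'
            )
            for s, e in sorted(m.exons):
                fh.write(
                    f"{m.chrom}\tsynthetic\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.cds_start is not None:
                offs = m.exon_offsets()
                for (s, e), off in zip(m.exons, offs):
                    elen = e - s
                    lo = max(m.cds_start, off)
                    hi = min(m.cds_end, off + elen)
                    if lo >= hi:
                        continue
                    if m.strand == "+":
                        gs, ge = s + (lo - off), s + (hi - off)
                    else:
                        gs, ge = e - (hi - off), e - (lo - off)
                    fh.write(
                        f"{m.chrom}\tsynthetic\tCDS\t{gs + 1}\t{ge}\t.\t{m.strand}\t0\t{attrs}\n"
                    )


def simulate_sample(
    introns: Sequence,
    psi_map: Dict[str, float],
    depth: float,
    seed: int,
    *,
    config: Optional[SimulationConfig] = None,
    sample_id: str = "S1",
    keep_profiles: bool = False,
    **meta,
) -> AlignmentSummary:
    """Simulate one sample's per-intron evidence.

    *introns* is a sequence of objects with ``intron_id`` and ``length``
    (IntronRecord works) or of ``(intron_id, length)`` tuples.  psi must be
    defined for every intron.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    stats, profiles = {}, {}
    for rec in introns:
        iid, L = (rec.intron_id, rec.length) if hasattr(rec, "intron_id") else rec
        if iid not in psi_map:
            raise KeyError(f"psi undefined for intron {iid}")
        psi = float(psi_map[iid])
        if not 0.0 <= psi <= 1.0:
            raise ValueError(f"psi out of [0,1] for {iid}")
        prof = rng.poisson(depth * psi, size=int(L))
        junc = int(rng.poisson(depth * (1.0 - psi)))
        m = float(np.median(prof))
        cov = float(np.mean(prof >= 1))
        stats[iid] = (m, cov, junc)
        if keep_profiles:
            profiles[iid] = prof
    coding = cfg.coding_reads
    intergenic = int(rng.binomial(coding, cfg.intergenic_fraction))
    return AlignmentSummary(
        sample_id=sample_id,
        intergenic_reads=intergenic,
        coding_reads=coding,
        intron_stats=stats,
        profiles=profiles,
        **meta,
    )


def _logit_shift(psi: float, u: float) -> float:
    if psi <= 0.0 or psi >= 1.0:
        return psi
    z = np.log(psi / (1 - psi)) + u
    return float(1.0 / (1.0 + np.exp(-z)))


def simulate_cohort(
    config: SimulationConfig,
    seed: int,
    *,
    introns: Optional[Sequence[Tuple[str, int]]] = None,
    psi_map: Optional[Dict[str, float]] = None,
    planted_dirs: Optional[Dict[str, float]] = None,
    stranded: bool = False,
) -> Tuple[List[AlignmentSummary], pd.DataFrame]:
    """Paired tumor/normal cohort with planted differential retention.

    ``planted_dirs`` maps intron_id -> delta-psi (signed); tumor psi equals
    normal psi plus delta, clipped to [0,1].  Every patient gets a shared
    random effect on logit(psi) applied to both of their samples, so pairs
    are positively correlated.  Returns (summaries, truth table).
    """
    rng = np.random.default_rng(seed)
    if introns is None:
        introns = [
            (f"intron_{i:04d}", int(rng.integers(config.intron_length[0], config.intron_length[1] + 1)))
            for i in range(200)
        ]
    if psi_map is None:
        psi_map = {iid: 0.2 for iid, _ in introns}
    planted = planted_dirs or {}
    unknown = set(planted) - {iid for iid, _ in introns}
    if unknown:
        raise ValueError(f"planted DIRs for unknown introns: {sorted(unknown)[:3]}")
    truth = pd.DataFrame(
        {
            "intron_id": [iid for iid, _ in introns],
            "psi_normal": [psi_map[iid] for iid, _ in introns],
        }
    )
    truth["delta_psi"] = [planted.get(iid, 0.0) for iid in truth["intron_id"]]
    truth["psi_tumor"] = np.clip(truth["psi_normal"] + truth["delta_psi"], 0.0, 1.0)
    truth["is_dir"] = truth["delta_psi"] != 0.0
    truth = truth.set_index("intron_id")

    summaries: List[AlignmentSummary] = []
    for p in range(config.n_pairs):
        pid = f"P{p:03d}"
        u = rng.normal(0.0, config.pair_effect_sd)
        for cond, col in (("normal", "psi_normal"), ("tumor", "psi_tumor")):
            psis = {iid: _logit_shift(truth.loc[iid, col], u) for iid, _ in introns}
            summaries.append(
                simulate_sample(
                    introns,
                    psis,
                    config.depth,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    config=config,
                    sample_id=f"{pid}_{'T' if cond == 'tumor' else 'N'}",
                    cancer_type=config.cancer_type,
                    condition=cond,
                    pair_id=pid,
                    stranded=stranded,
                )
            )
    return summaries, truth


def simulate_survival(
    ir_values: pd.DataFrame,
    beta_map: Dict[str, float],
    h0: float,
    censor_frac: float,
    seed: int,
) -> pd.DataFrame:
    """Exponential survival times with hazards planted on IR-high status.

    For each intron in *beta_map*, patients whose IRratio exceeds the
    cohort median of that intron get log-hazard beta added.  Censoring
    times are Uniform(0, c) with c calibrated so the realized censored
    fraction matches *censor_frac*.  Returns a patient/time/event table.
    """
    if ir_values.shape[1] == 0 or ir_values.shape[0] == 0:
        raise ValueError("empty IR matrix")
    if not 0.0 <= censor_frac < 1.0:
        raise ValueError("censor_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    patients = list(ir_values.columns)
    eta = np.zeros(len(patients))
    for iid, beta in beta_map.items():
        row = ir_values.loc[iid].to_numpy(dtype=float)
        med = np.nanmedian(row)
        eta += float(beta) * (np.nan_to_num(row, nan=-np.inf) > med)
    T = rng.exponential(1.0 / (h0 * np.exp(eta)))
    if censor_frac == 0.0:
        time, event = T, np.ones(len(T), dtype=int)
    else:
        U = rng.uniform(size=len(T))
        lo, hi = 1e-9, float(T.max()) * 1e3
        for _ in range(200):  # bisect c so that mean(c*U < T) ~= censor_frac
            c = 0.5 * (lo + hi)
            frac = float(np.mean(c * U < T))
            if frac > censor_frac:
                lo = c
            else:
                hi = c
        C = 0.5 * (lo + hi) * U
        event = (T <= C).astype(int)
        time = np.minimum(T, C)
    return pd.DataFrame(
        {"patient_id": patients, "time": np.maximum(time, 1e-9), "event": event, "endpoint": "OS"}
    ).set_index("patient_id")


def emit_sam(
    genome: Dict[str, str],
    introns: Sequence,
    psi_map: Dict[str, float],
    depth: float,
    seed: int,
    path: str,
    flank: int = 10,
) -> None:
    """Write a tiny SAM realizing the per-intron evidence model.

    Intron depth is emitted as single-base reads (one per unit of depth at
    each intron base) and each junction read as a spliced alignment with an
    N-gap exactly spanning the intron.  Intended for small cases only, to
    exercise the alignment-reading path end to end.
    """
    if len(genome) > 10:
        raise ValueError("SAM emission is for tiny cases (<=10 contigs)")
    rng = np.random.default_rng(seed)
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom, seq in genome.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{len(seq)}")
    rid = 0
    for rec in introns:
        psi = float(psi_map[rec.intron_id])
        prof = rng.poisson(depth * psi, size=rec.length)
        for off in np.nonzero(prof)[0]:
            for _ in range(int(prof[off])):
                pos = rec.start + int(off)
                base = genome[rec.chrom][pos]
                lines.append(f"r{rid}\t0\t{rec.chrom}\t{pos + 1}\t60\t1M\t*\t0\t0\t{base}\t*")
                rid += 1
        for _ in range(int(rng.poisson(depth * (1.0 - psi)))):
            pos = rec.start - flank
            cigar = f"{flank}M{rec.length}N{flank}M"
            seq = genome[rec.chrom][pos : rec.start] + genome[rec.chrom][rec.end : rec.end + flank]
            lines.append(f"r{rid}\t0\t{rec.chrom}\t{pos + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*")
            rid += 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
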