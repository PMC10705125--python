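"""IRratio quantification with explicit decision rules.

The intron-retention ratio of one intron in one sample is

    IRratio = m / (m + J)

where ``m`` is the median read depth across the intron's bases and ``J``
the number of split reads across the intron's flanking exon-exon junction
(evidence for the spliced isoform).  The ratio is only trusted under a
chain of decision rules; otherwise the value is forced to zero (confidently
spliced) or to a missing state (undecidable):

1. fewer than 4 junction reads -> missing (isoform not shown expressed);
2. intron coverage (fraction of bases with depth >= 1) below 20% -> zero;
3. coverage above 70% AND median depth above 3 -> keep the ratio;
4. anything else -> missing.

Boundary semantics are strict, mirroring the rule wording: coverage exactly
0.20 or 0.70 and median depth exactly 3 give *missing*; the sample-QC
intergenic/coding ratio at exactly 0.10 passes; a whitelist maximum of
exactly 0.08 is excluded.

In the matrix representation used downstream a cell is a float where NaN
encodes the missing state, 0.0 the confident-zero state, and any positive
value a kept ratio (rule 3 forces kept ratios to be > 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import IntronRecord, read_matrix, write_matrix

__all__ = [
    "IRValue",
    "IRMatrix",
    "sample_qc",
    "ir_call",
    "compute_irratio",
    "build_ir_matrix",
    "count_retained",
    "build_whitelist",
]

MIN_JUNCTION_READS = 4
COVERAGE_ZERO_BELOW = 0.20
COVERAGE_VALUE_ABOVE = 0.70
MEDIAN_DEPTH_ABOVE = 3.0
QC_INTERGENIC_RATIO = 0.10
WHITELIST_THRESHOLD = 0.08
RETAINED_THRESHOLD = 0.1


@dataclass(frozen=True)
class IRValue:
    """Outcome of the rule chain for one (intron, sample) cell."""

    state: str  # {"value", "zero", "missing"}
    irratio: float  # 0.0 for zero state, NaN for missing
    median_depth: float
    coverage_fraction: float
    junction_reads: int

    def __post_init__(self):
        if self.state == "zero" and self.irratio != 0.0:
            raise ValueError("zero state must store irratio 0.0")
        if self.state == "value" and not (0.0 < self.irratio <= 1.0):
            raise ValueError("value state requires irratio in (0, 1]")

    @property
    def as_float(self) -> float:
        return np.nan if self.state == "missing" else self.irratio


def sample_qc(intergenic_reads: int, coding_reads: int) -> str:
    """Sample-level QC on the intergenic/coding read ratio.

    Returns "warn" when intergenic/coding exceeds 10% (strict); warned
    samples are excluded from every cohort.  ``coding_reads`` must be > 0.
    """
    if coding_reads <= 0:
        raise ValueError("coding_reads must be positive for sample QC")
    return "warn" if intergenic_reads / coding_reads > QC_INTERGENIC_RATIO else "pass"


def ir_call(median_depth: float, coverage_fraction: float, junction_reads: int) -> IRValue:
    """Apply the decision-rule chain to summary statistics of one intron."""
    if junction_reads < MIN_JUNCTION_READS:
        return IRValue("missing", np.nan, median_depth, coverage_fraction, junction_reads)
    if coverage_fraction < COVERAGE_ZERO_BELOW:
        return IRValue("zero", 0.0, median_depth, coverage_fraction, junction_reads)
    if coverage_fraction > COVERAGE_VALUE_ABOVE and median_depth > MEDIAN_DEPTH_ABOVE:
        r = median_depth / (median_depth + junction_reads)
        return IRValue("value", r, median_depth, coverage_fraction, junction_reads)
    return IRValue("missing", np.nan, median_depth, coverage_fraction, junction_reads)


def compute_irratio(depth_profile: Sequence[int], junction_reads: int) -> IRValue:
    """Quantify one intron from its per-base depth profile.

    Coverage is the fraction of intron bases with depth >= 1 and the depth
    statistic is the median over all intron bases.
    """
    prof = np.asarray(depth_profile)
    if prof.size == 0:
        raise ValueError("empty depth profile")
    m = float(np.median(prof))
    cov = float(np.mean(prof >= 1))
    return ir_call(m, cov, junction_reads)


class IRMatrix:
    """Introns x samples IRratio grid plus per-sample metadata.

    ``values`` is a float DataFrame (rows introns, columns samples) with
    NaN = missing, 0.0 = confident zero, >0 = kept ratio.  ``samples`` is a
    DataFrame indexed by sample_id with columns ``cancer_type``,
    ``condition`` ("tumor"/"normal"), ``pair_id`` and ``stranded``.
    """

    def __init__(self, values: pd.DataFrame, samples: Optional[pd.DataFrame] = None):
        if values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if values.index.duplicated().any():
            raise ValueError("duplicate intron ids")
        if samples is None:
            samples = pd.DataFrame(index=values.columns)
        if not samples.index.equals(values.columns):
            samples = samples.loc[values.columns]
        self.values = values
        self.samples = samples

    @property
    def intron_ids(self):
        return self.values.index

    @property
    def sample_ids(self):
        return self.values.columns

    def subset_samples(self, sample_ids) -> "IRMatrix":
        return IRMatrix(self.values[list(sample_ids)], self.samples.loc[list(sample_ids)])

    def to_tsv(self, values_path: str, samples_path: Optional[str] = None) -> None:
        write_matrix(self.values, values_path)
        if samples_path is not None:
            self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, values_path: str, samples_path: Optional[str] = None) -> "IRMatrix":
        values = read_matrix(values_path)
        samples = None
        if samples_path is not None:
            samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
            for col in ("stranded",):
                if col in samples.columns:
                    samples[col] = samples[col].astype(bool)
        return cls(values, samples)


def build_ir_matrix(summaries: Iterable, introns: Sequence[IntronRecord]) -> IRMatrix:
    """Quantify every (intron, sample) cell from alignment summaries.

    Introns flagged ``known_exon_overlap`` are excluded, as are samples
    whose intergenic/coding QC warns.  Rows and columns are sorted
    deterministically (intron canonical order; sample_id).
    """
    keep = [r for r in introns if not r.known_exon_overlap]
    keep.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand))
    cols, meta = {}, {}
    for s in sorted(summaries, key=lambda s: s.sample_id):
        if sample_qc(s.intergenic_reads, s.coding_reads) == "warn":
            continue
        col = np.full(len(keep), np.nan)
        for i, rec in enumerate(keep):
            stats = s.intron_stats.get(rec.intron_id)
            if stats is None:
                continue
            m, cov, j = stats
            col[i] = ir_call(m, cov, j).as_float
        cols[s.sample_id] = col
        meta[s.sample_id] = {
            "cancer_type": s.cancer_type,
            "condition": s.condition,
            "pair_id": s.pair_id,
            "stranded": s.stranded,
        }
    values = pd.DataFrame(cols, index=[r.intron_id for r in keep])
    samples = pd.DataFrame.from_dict(meta, orient="index").reindex(values.columns)
    return IRMatrix(values, samples)


def summarize_alignments(path: str, introns: Sequence[IntronRecord], sample_id: str = None, **meta):
    """Build an AlignmentSummary from a SAM/BAM file.

    Per-intron depth profiles are accumulated from the aligned blocks of
    every read; a junction read is a spliced alignment whose N-gap spans
    the intron's coordinates exactly.  Intergenic reads cannot be inferred
    from these toy alignments, so the QC counters are set to pass
    (intergenic 0 / coding = total reads).  Intended for the small SAM
    files the simulator emits; real cohorts use the TSV summary path.
    """
    import pysam

    from .summaries import AlignmentSummary

    mode = "rb" if str(path).endswith(".bam") else "r"
    depth: dict = {}
    junctions: dict = {}
    with pysam.AlignmentFile(str(path), mode) as fh:
        lengths = {name: fh.get_reference_length(name) for name in fh.references}
        for chrom in {r.chrom for r in introns}:
            depth[chrom] = np.zeros(lengths.get(chrom, 0), dtype=np.int32)
        n_reads = 0
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            n_reads += 1
            chrom = read.reference_name
            if chrom not in depth:
                continue
            for bs, be in read.get_blocks():
                depth[chrom][bs:be] += 1
            pos = read.reference_start
            for op, ln in read.cigartuples or []:
                if op in (0, 2, 7, 8):  # M, D, =, X consume reference
                    pos += ln
                elif op == 3:  # N: splice gap
                    junctions[(chrom, pos, pos + ln)] = junctions.get((chrom, pos, pos + ln), 0) + 1
                    pos += ln
    stats = {}
    for rec in introns:
        prof = depth[rec.chrom][rec.start : rec.end]
        j = junctions.get((rec.chrom, rec.start, rec.end), 0)
        v = compute_irratio(prof, j)
        stats[rec.intron_id] = (v.median_depth, v.coverage_fraction, j)
    return AlignmentSummary(
        sample_id=sample_id or str(path),
        intergenic_reads=0,
        coding_reads=max(n_reads, 1),
        intron_stats=stats,
        **meta,
    )


def count_retained(column: pd.Series, threshold: float = RETAINED_THRESHOLD) -> int:
    """Number of retained introns in one sample: kept ratios strictly above
    *threshold* (missing and confident-zero cells never count)."""
    return int((column > threshold).sum())


def build_whitelist(stranded_matrix: IRMatrix, threshold: float = WHITELIST_THRESHOLD) -> set:
    """Introns whose maximum kept ratio over stranded samples exceeds *threshold*.

    All samples in the matrix must be flagged stranded.  Zero and missing
    cells do not contribute to the maximum; an all-missing intron is
    excluded.
    """
    if stranded_matrix.values.shape[1] == 0:
        raise ValueError("whitelist requires at least one stranded sample")
    if "stranded" in stranded_matrix.samples.columns and not stranded_matrix.samples["stranded"].all():
        raise ValueError("whitelist matrix contains non-stranded samples")
    mx = stranded_matrix.values.max(axis=1, skipna=True)
    return set(mx.index[mx > threshold])
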