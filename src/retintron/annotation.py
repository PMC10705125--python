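"""Gene-model and intron I/O.

Coordinate conventions
----------------------
Internal coordinates are always 0-based half-open.  GTF input is 1-based
inclusive and converted on read; BED output is 0-based half-open (the BED
standard).  Exons of a :class:`GeneModel` are stored in transcript
orientation (5' to 3'), so for minus-strand transcripts the genomic start
coordinates are descending.

CDS bounds are *transcript-level*: offsets into the spliced mRNA, with
``cds_end`` exclusive and including the stop codon when the annotation
carries ``stop_codon`` features (or when the CDS itself ends in a stop).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "IntronRecord",
    "read_gtf",
    "extract_introns",
    "write_intron_bed",
    "read_intron_bed",
    "write_matrix",
    "read_matrix",
]


@dataclass
class GeneModel:
    """One transcript of one gene, with exon structure and optional CDS."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list  # [(start, end)] 0-based half-open, 5'->3' transcript order
    cds_start: Optional[int] = None  # spliced-transcript offset, inclusive
    cds_end: Optional[int] = None  # spliced-transcript offset, exclusive
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        if any(e <= s for s, e in self.exons):
            raise ValueError(f"{self.transcript_id}: empty or inverted exon")
        ordered = starts == sorted(starts) if self.strand == "+" else starts == sorted(starts, reverse=True)
        if not ordered:
            raise ValueError(
                f"{self.transcript_id}: exons not in transcript orientation for strand {self.strand}"
            )
        # non-overlap in genomic space
        giv = sorted(zip(starts, ends))
        for (s1, e1), (s2, e2) in zip(giv, giv[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.cds_start is not None:
            L = self.spliced_length
            if not (0 <= self.cds_start < self.cds_end <= L):
                raise ValueError(
                    f"{self.transcript_id}: CDS bounds ({self.cds_start},{self.cds_end}) "
                    f"outside spliced length {L}"
                )

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def exon_offsets(self) -> list:
        """Transcript-coordinate offset of each exon's 5' end."""
        offs, pos = [], 0
        for s, e in self.exons:
            offs.append(pos)
            pos += e - s
        return offs


@dataclass
class IntronRecord:
    intron_id: str
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open genomic
    end: int
    ordinal: int  # 1-based, 5'->3' along the transcript
    n_introns_in_gene: int
    known_exon_overlap: bool = False
    region: str = "noncoding"  # {5UTR, CDS, 3UTR, mixed, noncoding}

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.intron_id}: end must exceed start")
        if not (1 <= self.ordinal <= self.n_introns_in_gene):
            raise ValueError(f"{self.intron_id}: ordinal out of range")

    @property
    def length(self) -> int:
        return self.end - self.start


def _attr(feature, *names: str) -> Optional[str]:
    for n in names:
        if n in feature.attributes:
            return feature.attributes[n][0]
    return None


def read_gtf(path: str) -> list:
    """Parse a GTF (Ensembl/GENCODE dialect) into :class:`GeneModel` objects.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Transcript-level CDS bounds are derived from CDS (+ optional stop_codon)
    features.  Models are returned in a canonical order:
    (chrom, genomic start, transcript_id).
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            if len(line.rstrip("\n").split("\t")) < 9:
                raise ValueError(f"malformed GTF line {lineno} in {path}: expected 9 tab-separated fields")
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # noqa: BLE001 - gffutils raises bare exceptions
        raise ValueError(f"malformed GTF {path}: {exc}") from exc

    exons: dict = {}
    cds: dict = {}
    stops: dict = {}
    meta: dict = {}
    for ftype, store in (("exon", exons), ("CDS", cds), ("stop_codon", stops)):
        for f in db.features_of_type(ftype):
            tid = _attr(f, "transcript_id")
            if tid is None:
                raise ValueError(f"GTF {ftype} feature without transcript_id at line for {f.id}")
            store.setdefault(tid, []).append((f.start - 1, f.end))
            if tid not in meta:
                meta[tid] = (
                    _attr(f, "gene_id") or tid,
                    f.seqid,
                    f.strand,
                    _attr(f, "gene_biotype", "gene_type", "transcript_type") or "protein_coding",
                )

    models = []
    for tid, ex in exons.items():
        gene_id, chrom, strand, biotype = meta[tid]
        if strand not in ("+", "-"):
            raise ValueError(f"{tid}: GTF strand {strand!r} unsupported")
        ex = sorted(ex, reverse=(strand == "-"))
        cds_start = cds_end = None
        if tid in cds:
            segs = sorted(cds[tid]) + sorted(stops.get(tid, []))
            lo = min(s for s, _ in segs)
            hi = max(e for _, e in segs)
            tx = _genomic_to_tx(ex, strand)
            if strand == "+":
                cds_start, cds_end = tx(lo), tx(hi - 1) + 1
            else:
                cds_start, cds_end = tx(hi - 1), tx(lo) + 1
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=tid,
                chrom=chrom,
                strand=strand,
                exons=ex,
                cds_start=cds_start,
                cds_end=cds_end,
                biotype=biotype,
            )
        )
    models.sort(key=lambda m: (m.chrom, min(s for s, _ in m.exons), m.transcript_id))
    return models


def _genomic_to_tx(exons: Sequence, strand: str):
    """Map a genomic base position to its spliced-transcript offset."""

    def fn(g: int) -> int:
        off = 0
        for s, e in exons:
            if s <= g < e:
                return off + (g - s if strand == "+" else e - 1 - g)
            off += e - s
        raise ValueError(f"genomic position {g} not exonic")

    return fn


def intron_tx_position(model: GeneModel, ordinal: int) -> int:
    """Spliced-transcript offset of the junction spanned by intron *ordinal*."""
    offs = model.exon_offsets()
    return offs[ordinal - 1] + (model.exons[ordinal - 1][1] - model.exons[ordinal - 1][0])


def _region_for(model: GeneModel, ordinal: int) -> str:
    if model.cds_start is None:
        return "noncoding"
    p = intron_tx_position(model, ordinal)
    if p <= model.cds_start:
        return "5UTR"
    if p >= model.cds_end:
        return "3UTR"
    return "CDS"


def extract_introns(models: Iterable[GeneModel]) -> list:
    """Derive the deduplicated intron universe from transcript models.

    One intron per inter-exon gap per transcript; identical genomic
    intervals are deduplicated by (chrom, start, end, strand), keeping the
    record from the first transcript in canonical order.
    ``known_exon_overlap`` is set when the intron interval intersects any
    exon of any transcript in the annotation (those introns are excluded
    from quantification downstream).
    """
    models = sorted(models, key=lambda m: (m.chrom, min(s for s, _ in m.exons), m.transcript_id))
    trees: dict = {}
    for m in models:
        t = trees.setdefault(m.chrom, IntervalTree())
        for s, e in m.exons:
            t[s:e] = m.transcript_id

    records: dict = {}
    for m in models:
        giv = sorted((s, e) for s, e in m.exons)
        gaps = [(e1, s2) for (_, e1), (s2, _) in zip(giv, giv[1:])]
        n = len(gaps)
        if m.strand == "-":
            gaps = gaps[::-1]  # 5'->3' on the minus strand is descending genomic
        for i, (gs, ge) in enumerate(gaps, start=1):
            key = (m.chrom, gs, ge, m.strand)
            if key in records:
                continue
            overlap = any(not (iv.end <= gs or iv.begin >= ge) for iv in trees[m.chrom].overlap(gs, ge))
            records[key] = IntronRecord(
                intron_id=f"{m.chrom}:{gs}-{ge}:{m.strand}",
                gene_id=m.gene_id,
                transcript_id=m.transcript_id,
                chrom=m.chrom,
                strand=m.strand,
                start=gs,
                end=ge,
                ordinal=i,
                n_introns_in_gene=n,
                known_exon_overlap=overlap,
                region=_region_for(m, i),
            )
    return sorted(records.values(), key=lambda r: (r.chrom, r.start, r.end, r.strand))


def write_intron_bed(introns: Iterable[IntronRecord], path: str) -> None:
    """Write introns as BED6 (0-based half-open, strand in column 6)."""
    with open(path, "w") as fh:
        for r in introns:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.intron_id}\t.\t{r.strand}\n")


def read_intron_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "intron_id", "score", "strand"],
        dtype={"chrom": str},
    )
    if df["intron_id"].duplicated().any():
        raise ValueError(f"duplicate intron_id rows in {path}")
    return df


def write_matrix(df: pd.DataFrame, path: str) -> None:
    """Write an introns x samples matrix as TSV; missing cells become "NA"."""
    if df.index.duplicated().any():
        raise ValueError("duplicate intron_id rows")
    # pandas' default shortest-repr float formatting round-trips exactly
    df.to_csv(path, sep="\t", na_rep="NA", index_label="intron_id")


def read_matrix(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate intron_id rows in {path}")
    return df
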