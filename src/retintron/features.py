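"""Sequence features of retained introns.

Introns fall into four mutually exclusive classes for feature comparison:
constitutive (median IRratio 0 in tumor and normal across every cancer),
unregulated-retained (retained somewhere but never differential), and
up-/down-regulated DIRs.  For each intron we compute GC content, length,
relative gene position, an NMD-susceptibility call for the retained-intron
transcript, and upstream ORFs introduced by retention in a 5'UTR.

NMD rule chain
--------------
A retained intron in a protein-coding transcript is predicted to elicit
nonsense-mediated decay unless one of the following escapes fires, checked
in order: the intron lies in a 5' or 3' UTR; its 5' end is closer than
200 nt (spliced-transcript coordinates) to the start codon; it is the last
intron; translation of the intron-retained mRNA yields no premature stop;
or the premature stop lies within 55 nt upstream of the retained
transcript's last exon-exon junction.  All distances are measured on the
mRNA of the intron-retained molecule, because that is what the NMD
machinery surveys.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import GeneModel, IntronRecord, intron_tx_position

__all__ = [
    "NMDCall",
    "classify_intron",
    "gc_content",
    "intron_length",
    "relative_gene_position",
    "transcript_sequence",
    "intron_sequence",
    "predict_nmd",
    "find_uorfs",
]

NEAR_START_NT = 200
PTC_LAST_JUNCTION_NT = 55
_STOPS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class NMDCall:
    verdict: str  # {"NMD", "no_NMD"}
    reason: str  # {utr, near_start, last_intron, no_ptc, ptc_within_55, ptc_triggers}
    ptc_tx_pos: Optional[int] = None  # first base of the premature stop, IR-transcript coords

    def __post_init__(self):
        if (self.verdict == "NMD") != (self.reason == "ptc_triggers"):
            raise ValueError("verdict NMD iff reason ptc_triggers")


def classify_intron(
    intron_id: str,
    medians: pd.DataFrame,
    dir_tables: Dict[str, pd.DataFrame],
) -> str:
    """Assign one of the four feature classes to an intron.

    *medians* holds the intron's median IRratio per (cancer, condition)
    combination (any shape with one row per intron works; NaN entries are
    ignored).  DIR membership wins over the median-based classes.
    """
    directions = set()
    for table in dir_tables.values():
        if intron_id in table.index:
            row = table.loc[intron_id]
            if bool(row.get("is_dir", True)):
                directions.add(row["direction"])
    if directions == {"up"}:
        return "dir_up"
    if directions == {"down"}:
        return "dir_down"
    if len(directions) > 1:
        raise ValueError(f"{intron_id}: inconsistent DIR directions; drop upstream")
    med = medians.loc[intron_id] if intron_id in getattr(medians, "index", []) else medians
    vals = np.asarray(med, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size and np.all(vals == 0):
        return "constitutive"
    return "unregulated_retained"


def gc_content(sequence: str) -> float:
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    return (s.count("G") + s.count("C")) / len(s)


def intron_length(intron: IntronRecord) -> int:
    return intron.length


def relative_gene_position(intron: IntronRecord) -> Optional[float]:
    """Percentile rank of the intron along its gene, 0 at the 5'-most and
    1 at the 3'-most intron: (ordinal - 1) / (n - 1).  Genes with fewer
    than 3 introns are excluded (returns None)."""
    n = intron.n_introns_in_gene
    if n < 3:
        return None
    return (intron.ordinal - 1) / (n - 1)


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    if hasattr(genome, "get_seq"):  # pyfaidx.Fasta (1-based inclusive API)
        return str(genome.get_seq(chrom, start + 1, end)).upper()
    return genome[chrom][start:end].upper()


def transcript_sequence(model: GeneModel, genome) -> str:
    """Spliced mRNA sequence in transcript sense."""
    parts = []
    for s, e in model.exons:
        seq = _fetch(genome, model.chrom, s, e)
        parts.append(seq if model.strand == "+" else _revcomp(seq))
    return "".join(parts)


def intron_sequence(model: GeneModel, intron: IntronRecord, genome) -> str:
    seq = _fetch(genome, intron.chrom, intron.start, intron.end)
    return seq if model.strand == "+" else _revcomp(seq)


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _first_stop_from(seq: str, start: int) -> Optional[int]:
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in _STOPS:
            return i
    return None


def predict_nmd(model: GeneModel, intron: IntronRecord, genome) -> NMDCall:
    """Predict whether retaining *intron* in *model* elicits NMD.

    Requires an annotated CDS; the intron must belong to the transcript.
    See the module docstring for the escape chain.
    """
    if model.cds_start is None:
        raise ValueError(f"{model.transcript_id}: NMD prediction requires a CDS")
    if intron.ordinal > model.n_introns:
        raise ValueError(f"{intron.intron_id}: not an intron of {model.transcript_id}")
    p = intron_tx_position(model, intron.ordinal)  # junction offset, spliced coords
    if p <= model.cds_start or p >= model.cds_end:
        return NMDCall("no_NMD", "utr")
    if p - model.cds_start < NEAR_START_NT:
        return NMDCall("no_NMD", "near_start")
    if intron.ordinal == model.n_introns:
        return NMDCall("no_NMD", "last_intron")

    spliced = transcript_sequence(model, genome)
    iseq = intron_sequence(model, intron, genome)
    retained = spliced[:p] + iseq + spliced[p:]
    # start codon offset is unchanged: the intron lies downstream of it
    stop = _first_stop_from(retained, model.cds_start)
    normal_stop_retained = model.cds_end - 3 + len(iseq)
    if stop is None or stop >= normal_stop_retained:
        return NMDCall("no_NMD", "no_ptc")
    # junctions of the IR transcript: every original junction except the
    # retained one, shifted by the intron length when downstream of it
    offs = model.exon_offsets()
    junctions = []
    for k in range(1, model.n_introns + 1):
        if k == intron.ordinal:
            continue
        q = intron_tx_position(model, k)
        junctions.append(q + len(iseq) if q > p else q)
    last_junction = max(junctions)  # chain guarantees a downstream junction exists
    if last_junction - stop <= PTC_LAST_JUNCTION_NT:
        return NMDCall("no_NMD", "ptc_within_55", ptc_tx_pos=stop)
    return NMDCall("NMD", "ptc_triggers", ptc_tx_pos=stop)


def find_uorfs(
    utr_sequence: str,
    main_start_offset: int,
    include_incomplete: bool = False,
) -> List[Tuple[int, int, int]]:
    """Enumerate upstream ORFs in a 5'UTR (mRNA sense, retained intron
    included).

    Every ATG strictly upstream of *main_start_offset* is paired with its
    first in-frame stop codon; the stop may lie at or beyond the main
    start.  Returns (start_offset, stop_offset, length_codons) in
    ascending start order, where length counts the codons before the stop.
    ATGs with no in-frame stop before the end of the sequence are
    incomplete ORFs and excluded unless *include_incomplete*.
    """
    seq = utr_sequence.upper()
    out = []
    pos = seq.find("ATG")
    while 0 <= pos < main_start_offset:
        stop = _first_stop_from(seq, pos)
        if stop is not None:
            out.append((pos, stop, (stop - pos) // 3))
        elif include_incomplete:
            out.append((pos, -1, (len(seq) - pos) // 3))
        pos = seq.find("ATG", pos + 1)
    return out
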