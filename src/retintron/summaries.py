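"""Per-sample alignment summaries: the quantifier's input container.

An :class:`AlignmentSummary` carries, for one RNA-seq sample, the per-intron
evidence needed by the IRratio rule chain (median depth, coverage fraction,
flanking-junction split-read count) plus the sample-level intergenic/coding
read counts used for QC.  Summaries round-trip through a plain TSV with
``#key=value`` header lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["AlignmentSummary"]


@dataclass
class AlignmentSummary:
    sample_id: str
    stranded: bool = False
    cancer_type: str = "SYN"
    condition: str = "tumor"  # "tumor" | "normal"
    pair_id: Optional[str] = None
    intergenic_reads: int = 0
    coding_reads: int = 1
    # intron_id -> (median_depth, coverage_fraction, junction_reads)
    intron_stats: Dict[str, Tuple[float, float, int]] = field(default_factory=dict)
    # optional raw per-base depth profiles (kept by the simulator)
    profiles: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.coding_reads <= 0:
            raise ValueError("coding_reads must be positive")

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#sample_id={self.sample_id}\n")
            fh.write(f"#stranded={int(self.stranded)}\n")
            fh.write(f"#cancer_type={self.cancer_type}\n")
            fh.write(f"#condition={self.condition}\n")
            fh.write(f"#pair_id={self.pair_id if self.pair_id is not None else ''}\n")
            fh.write(f"#intergenic_reads={self.intergenic_reads}\n")
            fh.write(f"#coding_reads={self.coding_reads}\n")
            fh.write("intron_id\tmedian_depth\tcoverage_fraction\tjunction_reads\n")
            for iid in sorted(self.intron_stats):
                m, cov, j = self.intron_stats[iid]
                fh.write(f"{iid}\t{m!r}\t{cov!r}\t{j}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "AlignmentSummary":
        meta: Dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    break
                k, _, v = line[1:].rstrip("\n").partition("=")
                meta[k] = v
        df = pd.read_csv(path, sep="\t", comment="#")
        stats = {
            str(r.intron_id): (float(r.median_depth), float(r.coverage_fraction), int(r.junction_reads))
            for r in df.itertuples(index=False)
        }
        return cls(
            sample_id=meta["sample_id"],
            stranded=bool(int(meta.get("stranded", "0"))),
            cancer_type=meta.get("cancer_type", "SYN"),
            condition=meta.get("condition", "tumor"),
            pair_id=meta.get("pair_id") or None,
            intergenic_reads=int(meta.get("intergenic_reads", "0")),
            coding_reads=int(meta.get("coding_reads", "1")),
            intron_stats=stats,
        )
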