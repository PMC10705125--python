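"""Differential intron retention between paired tumor/normal samples.

A differentially retained intron (DIR) must show a paired Wilcoxon
signed-rank p-value below 0.05 *and* an absolute difference of median
IRratios (tumor minus normal) above 0.1.  Missing cells drop the whole
pair for that intron; confident-zero cells participate as 0.0.  DIRs are
further categorized by whether the intron is essentially spliced in one
condition: cancer-associated (median 0 in normal, > 0.1 in tumor),
normal-associated (the mirror image), or altered-level otherwise.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import IRMatrix

__all__ = [
    "call_dirs",
    "categorize_dir",
    "merge_dirs_pan_cancer",
    "matrix_prep",
    "ir_expression_correlation",
    "mutation_proximity",
]

logger = logging.getLogger(__name__)

P_THRESHOLD = 0.05
DELTA_THRESHOLD = 0.1
RETAINED_MEDIAN = 0.1
MAX_MISSING_RATE = 0.30


def _pair_columns(samples: pd.DataFrame) -> Sequence[Tuple[str, str]]:
    pairs = []
    for pid, grp in samples.groupby("pair_id", sort=True):
        conds = grp.groupby("condition").groups
        if "tumor" in conds and "normal" in conds:
            pairs.append((grp.index[grp["condition"] == "tumor"][0],
                          grp.index[grp["condition"] == "normal"][0]))
    return pairs


def call_dirs(
    matrix: IRMatrix,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
    whitelist: Optional[Set[str]] = None,
    *,
    alpha: float = P_THRESHOLD,
    min_delta: float = DELTA_THRESHOLD,
    min_pairs: int = 15,
    cancer_type: str = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """Test every (whitelisted) intron for differential retention.

    *pairs* is a list of (tumor_sample, normal_sample) column pairs; when
    omitted it is derived from the matrix metadata (``pair_id`` +
    ``condition``).  Returns one row per testable intron with columns
    p_value, median_tumor, median_normal, delta, direction, category,
    n_pairs and the boolean ``is_dir``; rows are sorted by intron_id so
    the result is invariant to sample column order.  With ``adjust=True``
    a Benjamini-Hochberg q-value replaces the raw p in the DIR rule
    (off by default, matching the unadjusted screening).
    """
    if pairs is None:
        pairs = _pair_columns(matrix.samples)
    if len(pairs) <= min_pairs:
        raise ValueError(f"need more than {min_pairs} tumor/normal pairs, got {len(pairs)}")
    tumor_cols = [t for t, _ in pairs]
    normal_cols = [n for _, n in pairs]
    values = matrix.values
    if whitelist is not None:
        values = values.loc[values.index.isin(whitelist)]
    values = values.sort_index()
    T = values[tumor_cols].to_numpy(dtype=float)
    N = values[normal_cols].to_numpy(dtype=float)
    rows = []
    for i, iid in enumerate(values.index):
        ok = ~np.isnan(T[i]) & ~np.isnan(N[i])
        if ok.sum() < 2:
            logger.info("intron %s skipped: %d usable pairs", iid, int(ok.sum()))
            continue
        t, n = T[i, ok], N[i, ok]
        diffs = t - n
        if np.all(diffs == 0):
            p = 1.0
        else:
            p = float(sps.wilcoxon(diffs, zero_method="wilcox", method="auto").pvalue)
        mt, mn = float(np.median(t)), float(np.median(n))
        delta = mt - mn
        rows.append(
            {
                "intron_id": iid,
                "cancer_type": cancer_type or "NA",
                "p_value": p,
                "median_tumor": mt,
                "median_normal": mn,
                "delta": delta,
                "direction": "up" if delta > 0 else "down",
                "n_pairs": int(ok.sum()),
            }
        )
    out = pd.DataFrame(rows).set_index("intron_id")
    if out.empty:
        out["is_dir"] = pd.Series(dtype=bool)
        out["category"] = pd.Series(dtype=object)
        return out
    pcol = out["p_value"]
    if adjust:
        from statsmodels.stats.multitest import multipletests

        pcol = pd.Series(multipletests(out["p_value"], method="fdr_bh")[1], index=out.index)
    out["is_dir"] = (pcol < alpha) & (out["delta"].abs() > min_delta)
    out["category"] = [
        categorize_dir(mn, mt) for mn, mt in zip(out["median_normal"], out["median_tumor"])
    ]
    return out


def categorize_dir(median_normal: float, median_tumor: float) -> str:
    """Cancer-associated: spliced in normal (median 0), retained in tumor
    (median > 0.1); normal-associated is the mirror; otherwise the
    retention level is altered but present in both."""
    if median_normal == 0 and median_tumor > RETAINED_MEDIAN:
        return "cancer_associated"
    if median_tumor == 0 and median_normal > RETAINED_MEDIAN:
        return "normal_associated"
    return "altered_level"


def merge_dirs_pan_cancer(
    dir_tables: Dict[str, pd.DataFrame],
    matrix: IRMatrix,
    max_missing: float = MAX_MISSING_RATE,
) -> list:
    """Merge per-cancer DIR tables into one pan-cancer feature list.

    Introns called in both directions in different cancers are dropped, as
    are introns missing in more than *max_missing* of all samples.
    """
    direction: Dict[str, Set[str]] = {}
    for table in dir_tables.values():
        hits = table[table["is_dir"]] if "is_dir" in table.columns else table
        for iid, d in zip(hits.index, hits["direction"]):
            direction.setdefault(iid, set()).add(d)
    consistent = sorted(iid for iid, ds in direction.items() if len(ds) == 1)
    missing_rate = matrix.values.isna().mean(axis=1)
    return [iid for iid in consistent if iid in missing_rate.index and missing_rate[iid] <= max_missing]


def matrix_prep(values: pd.DataFrame, max_missing: float = MAX_MISSING_RATE) -> pd.DataFrame:
    """Missing-rate filter + row-mean imputation, for embedding/model prep.

    Rows (introns) with a missing rate of *max_missing* or more are
    dropped (the filter keeps rates strictly below the threshold); the
    remaining missing cells are imputed with the row mean over observed
    entries.  Confident zeros are observations, not missing.
    """
    rate = values.isna().mean(axis=1)
    kept = values.loc[rate < max_missing].copy()
    means = kept.mean(axis=1, skipna=True)
    out = kept.T.fillna(means).T
    if out.isna().any().any():
        raise ValueError("rows with no observed values cannot be imputed")
    return out


def ir_expression_correlation(delta: pd.Series, log2fc: pd.Series) -> Tuple[float, float]:
    """Spearman correlation of DIR delta-median IRratio vs gene log2 fold
    change (genes matched on index).  Ties receive average ranks (scipy
    default); constant input is undefined and raises."""
    joined = pd.concat([delta, log2fc], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 paired observations")
    a, b = joined.iloc[:, 0], joined.iloc[:, 1]
    if a.nunique() == 1 or b.nunique() == 1:
        raise ValueError("correlation undefined for constant input")
    rho, p = sps.spearmanr(a, b)
    return float(rho), float(p)


def mutation_proximity(
    dirs: pd.DataFrame,
    variants: pd.DataFrame,
    window: int = 20,
) -> pd.DataFrame:
    """Flag DIRs with a somatic variant near either splice site.

    *dirs* needs columns chrom/start/end (0-based half-open intron
    coordinates); *variants* needs chrom/pos (0-based base position) and
    optionally sample_id.  A variant within *window* bp (inclusive, either
    side) of the first or last intronic base flags the DIR.  Returns the
    flagged (intron, variant) combinations.
    """
    hits = []
    for v in variants.itertuples(index=False):
        near = dirs[
            (dirs["chrom"] == v.chrom)
            & (
                ((dirs["start"] - window <= v.pos) & (v.pos <= dirs["start"] + window))
                | ((dirs["end"] - 1 - window <= v.pos) & (v.pos <= dirs["end"] - 1 + window))
            )
        ]
        for iid in near.index:
            hits.append(
                {
                    "intron_id": iid,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "sample_id": getattr(v, "sample_id", "NA"),
                }
            )
    return pd.DataFrame(hits, columns=["intron_id", "chrom", "pos", "sample_id"])
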