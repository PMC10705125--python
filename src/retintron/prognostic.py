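"""Survival analysis on intron retention.

Two layers: (1) per-intron screening — eligibility (valid IRratio in at
least half the patients, at least 5% of valid values above 0.1), then a
median-split univariate Cox regression restricted to patients with
IRratio > 0; and (2) a multi-intron prognostic signature — LASSO-penalized
Cox regression over introns with a missing rate below 20% (mean-imputed),
with the penalty chosen by cross-validated partial-likelihood deviance at
either the minimum (lambda.min) or the one-standard-error rule
(lambda.1se).  The intron-retention risk (IRR) of a patient is the sum of
IRratios weighted by the selected coefficients, and the cohort is split
into high/low risk at the median IRR.

The cross-validated deviance follows Verweij & van Houwelingen: for fold k,
-2 * (pl(beta_{-k}; all data) - pl(beta_{-k}; data without fold k)), with
Breslow handling of ties inside the penalized path (matching the path
solver) and Efron ties in the unpenalized univariate fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "prognostic_eligibility",
    "median_split_cox",
    "expression_survival",
    "IRRModel",
    "fit_irr",
    "km_logrank",
]

ELIGIBLE_VALID_FRAC = 0.50
ELIGIBLE_HIGH_FRAC = 0.05
ELIGIBLE_HIGH_IRRATIO = 0.1
EXPRESSION_MIN_TPM = 1.0
IRR_MAX_MISSING = 0.20


def prognostic_eligibility(row: pd.Series) -> bool:
    """Screen one intron: >= 50% of patients with a valid (non-missing)
    IRratio and >= 5% of those valid values above 0.1."""
    valid = row.dropna()
    if len(row) == 0 or len(valid) / len(row) < ELIGIBLE_VALID_FRAC:
        return False
    return (valid > ELIGIBLE_HIGH_IRRATIO).sum() / len(valid) >= ELIGIBLE_HIGH_FRAC


def _cox_on_groups(df: pd.DataFrame) -> Tuple[float, float]:
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return float(np.exp(cph.params_["group"])), float(cph.summary.loc["group", "p"])


def median_split_cox(row: pd.Series, survival: pd.DataFrame) -> Tuple[float, float, Tuple[int, int]]:
    """Univariate Cox on the IR-high vs IR-low median split.

    Restricted to patients with IRratio > 0; high = strictly above the
    median of the restricted values (ties go low).  Returns
    (hazard ratio of high vs low, Wald p, (n_low, n_high)).
    """
    joined = pd.concat([row.rename("ir"), survival[["time", "event"]]], axis=1, join="inner").dropna()
    joined = joined[joined["ir"] > 0]
    if len(joined) < 4:
        raise ValueError("too few patients with IRratio > 0")
    med = joined["ir"].median()
    joined["group"] = (joined["ir"] > med).astype(int)
    n_low = int((joined["group"] == 0).sum())
    n_high = int((joined["group"] == 1).sum())
    if n_low == 0 or n_high == 0:
        raise ValueError("degenerate median split (all values tied)")
    if joined["event"].sum() == 0:
        raise ValueError("no events among patients with IRratio > 0")
    hr, p = _cox_on_groups(joined[["time", "event", "group"]])
    return hr, p, (n_low, n_high)


def expression_survival(tpm_row: pd.Series, survival: pd.DataFrame) -> Optional[Tuple[float, float]]:
    """Median-split Cox on gene expression; genes with median <= 1 TPM are
    skipped (returns None)."""
    joined = pd.concat([tpm_row.rename("x"), survival[["time", "event"]]], axis=1, join="inner").dropna()
    if joined["x"].median() <= EXPRESSION_MIN_TPM:
        return None
    med = joined["x"].median()
    joined["group"] = (joined["x"] > med).astype(int)
    if joined["group"].nunique() < 2:
        raise ValueError("degenerate expression split")
    return _cox_on_groups(joined[["time", "event", "group"]])


@dataclass
class IRRModel:
    """LASSO-Cox intron-retention risk signature."""

    intron_ids: List[str]
    coefficients: np.ndarray  # on the original IRratio scale
    lambda_rule: str
    lambda_: float
    irr: pd.Series = field(default=None, repr=False)  # per-patient risk score
    cutoff: float = None  # median IRR

    def score(self, values: pd.DataFrame) -> pd.Series:
        """IRR = sum_i coef_i * IRratio_i per patient (columns)."""
        X = values.loc[self.intron_ids].to_numpy(dtype=float)
        return pd.Series(self.coefficients @ X, index=values.columns, name="irr")

    def groups(self, irr: Optional[pd.Series] = None) -> pd.Series:
        irr = self.irr if irr is None else irr
        return pd.Series(np.where(irr > self.cutoff, "high", "low"), index=irr.index)

    def to_json(self) -> dict:
        return {
            "intron_ids": list(self.intron_ids),
            "coefficients": [float(c) for c in self.coefficients],
            "lambda_rule": self.lambda_rule,
            "lambda": float(self.lambda_),
            "cutoff": float(self.cutoff),
        }


def _breslow_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    order = np.argsort(-time)  # decreasing time: cumulative sums give risk sets
    eta, time, event = eta[order], time[order], event[order]
    log_cum = np.logaddexp.accumulate(eta)
    # risk set for an event at t includes everyone with time >= t (ties share it)
    ll = 0.0
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d = event[i:j]
        if d.any():
            denom = log_cum[j - 1]
            ll += float(eta[i:j][d.astype(bool)].sum() - d.sum() * denom)
        i = j
    return ll


def _cv_deviance(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    alphas: np.ndarray,
    cv_folds: int,
    seed: int,
    l1_ratio: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-alpha CV deviance (mean, SE over folds), Verweij-van Houwelingen."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(time))
    folds = np.array_split(idx, cv_folds)
    y_all = Surv.from_arrays(event=event.astype(bool), time=time)
    dev = np.zeros((cv_folds, len(alphas)))
    for k, fold in enumerate(folds):
        mask = np.zeros(len(time), dtype=bool)
        mask[fold] = True
        est = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas, fit_baseline_model=False)
        y_tr = Surv.from_arrays(event=event[~mask].astype(bool), time=time[~mask])
        est.fit(X[~mask], y_tr)
        coefs = _coef_path(est, alphas)
        for a in range(len(alphas)):
            eta_all = X @ coefs[:, a]
            ll_full = _breslow_loglik(eta_all, time, event)
            ll_train = _breslow_loglik(eta_all[~mask], time[~mask], event[~mask])
            dev[k, a] = -2.0 * (ll_full - ll_train)
    return dev.mean(axis=0), dev.std(axis=0, ddof=1) / np.sqrt(cv_folds)


def _coef_path(est: CoxnetSurvivalAnalysis, alphas: np.ndarray) -> np.ndarray:
    """Coefficients at each requested alpha (features x alphas)."""
    fitted = np.asarray(est.alphas_)
    out = np.zeros((est.coef_.shape[0], len(alphas)))
    for a, alpha in enumerate(alphas):
        j = int(np.argmin(np.abs(fitted - alpha)))
        out[:, a] = est.coef_[:, j]
    return out


def fit_irr(
    values: pd.DataFrame,
    survival: pd.DataFrame,
    lambda_rule: str = "min",
    seed: int = 0,
    *,
    cv_folds: int = 10,
    max_missing: float = IRR_MAX_MISSING,
) -> IRRModel:
    """Fit the LASSO-Cox IRR signature.

    *values* is introns x patients (NaN = missing); introns with missing
    rate >= 20% are dropped and the rest mean-imputed.  Features are
    standardized internally; reported coefficients are rescaled to the
    original IRratio scale so the IRR score is a plain dot product with
    raw IRratios.
    """
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")
    surv = survival.loc[survival.index.intersection(values.columns)].dropna(subset=["time", "event"])
    if int(surv["event"].sum()) < 2:
        raise ValueError("need at least 2 events")
    vals = values[surv.index]
    rate = vals.isna().mean(axis=1)
    kept = vals.loc[rate < max_missing]
    if kept.shape[0] < 2:
        raise ValueError("need at least 2 candidate introns after missing-rate filter")
    kept = kept.T.fillna(kept.mean(axis=1, skipna=True)).T
    sd = kept.std(axis=1, ddof=1)
    nonconst = sd > 0
    if not nonconst.any():
        raise ValueError("all candidate introns are constant")
    kept = kept.loc[nonconst]
    sd = sd[nonconst]
    X = ((kept.T - kept.mean(axis=1)) / sd).to_numpy(dtype=float)
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy()

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=50, fit_baseline_model=False)
    path.fit(X, Surv.from_arrays(event=event.astype(bool), time=time))
    alphas = np.asarray(path.alphas_)
    mean_dev, se_dev = _cv_deviance(X, time, event, alphas, cv_folds, seed)
    i_min = int(np.argmin(mean_dev))
    if lambda_rule == "min":
        i_sel = i_min
    else:  # most parsimonious model within one SE of the minimum
        ok = mean_dev <= mean_dev[i_min] + se_dev[i_min]
        i_sel = int(np.flatnonzero(ok)[0])  # alphas_ are in decreasing order
    coef_std = path.coef_[:, i_sel]
    coef_orig = coef_std / sd.to_numpy()
    nz = coef_std != 0
    model = IRRModel(
        intron_ids=list(kept.index[nz]),
        coefficients=coef_orig[nz],
        lambda_rule=lambda_rule,
        lambda_=float(alphas[i_sel]),
    )
    if nz.any():
        model.irr = model.score(kept)
    else:
        model.irr = pd.Series(0.0, index=kept.columns, name="irr")
    model.cutoff = float(model.irr.median())
    return model


def km_logrank(
    groups: pd.Series,
    survival: pd.DataFrame,
) -> Tuple[Dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group, two-sided log-rank p, and the Cox
    hazard ratio of 'high' vs 'low' (or second vs first group level)."""
    joined = pd.concat([groups.rename("group"), survival[["time", "event"]]], axis=1, join="inner").dropna()
    levels = sorted(joined["group"].unique(), key=lambda g: (g != "low", g))
    if len(levels) != 2 or (joined["group"] == levels[0]).sum() == 0 or (joined["group"] == levels[1]).sum() == 0:
        raise ValueError("need exactly two nonempty groups")
    curves = {}
    for g in levels:
        sub = joined[joined["group"] == g]
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"], label=str(g))
        curves[g] = km.survival_function_.rename(columns={str(g): "survival"})
    a, b = (joined[joined["group"] == g] for g in levels)
    lr = logrank_test(a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"])
    joined["x"] = (joined["group"] == levels[1]).astype(int)  # high (or 2nd level) vs low
    cph = CoxPHFitter()
    cph.fit(joined[["time", "event", "x"]], duration_col="time", event_col="event")
    return curves, float(lr.p_value), float(np.exp(cph.params_["x"]))
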