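"""End-to-end orchestration with seeded reproducibility.

``run_pipeline`` executes the stages in dependency order —
simulate -> quantify -> whitelist -> dir -> features -> diagnose ->
prognosis — writing every artifact under one run directory together with a
serialized config and its hash.  One global seed fans out to per-stage
child seeds via sha256("{seed}:{stage}") mod 2^31, so any stage can be
re-run independently and two runs with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import annotation, differential, diagnostic, features, prognostic, quantify, simulate
from .quantify import IRMatrix
from .simulate import SimulationConfig

__all__ = ["PipelineConfig", "stage_seed", "run_pipeline", "make_demo", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "quantify", "whitelist", "dir", "features", "diagnose", "prognosis"]


@dataclass
class PipelineConfig:
    """Fully serializable pipeline configuration.

    Threshold defaults are the pipeline's standard decision rules; the
    simulation block controls the synthetic cohort.
    """

    seed: int = 42
    stages: List[str] = field(default_factory=lambda: list(STAGES))
    # synthetic cohort
    n_genes: int = 12
    n_pairs: int = 30
    depth: float = 100.0
    n_planted_dirs: int = 10
    delta_psi: float = 0.3
    psi_base: float = 0.15
    n_stranded: int = 4
    # modeling
    diagnose_repeats: int = 5
    diagnose_folds: int = 4
    lambda_rule: str = "min"
    censor_frac: float = 0.2
    survival_beta: float = 1.5

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage child seed (< 2^31) from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(h, 16) % (2**31 - 1)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str) -> Path:
    """Run the configured stages on a synthetic cohort; returns the run dir."""
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    _write_json(out / "config.json", {"config": asdict(config), "hash": cfg_hash})

    state: Dict[str, object] = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        logger.info("stage %s (seed %d)", stage, stage_seed(config.seed, stage))
        _STAGE_FN[stage](config, out, state)
    _write_json(out / "run.json", {"hash": cfg_hash, "stages": [s for s in STAGES if s in config.stages]})
    return out


def _require(state: dict, key: str, stage: str):
    if key not in state:
        raise RuntimeError(f"stage '{stage}' requires upstream artifact '{key}'; run its producing stage first")
    return state[key]


def _stage_simulate(config: PipelineConfig, out: Path, state: dict) -> None:
    seed = stage_seed(config.seed, "simulate")
    sim = SimulationConfig(
        n_genes=config.n_genes,
        n_pairs=config.n_pairs,
        depth=config.depth,
        uorf_starts=3,
    )
    genome, models = simulate.make_genome(sim, seed, str(out / "genome.fa"), str(out / "genes.gtf"))
    introns = annotation.extract_introns(models)
    annotation.write_intron_bed(introns, str(out / "introns.bed"))
    usable = [r for r in introns if not r.known_exon_overlap]
    rng = np.random.default_rng(seed + 1)
    planted_ids = [r.intron_id for r in usable[: config.n_planted_dirs]]
    psi_map = {r.intron_id: config.psi_base for r in usable}
    planted = {iid: config.delta_psi for iid in planted_ids}
    summaries, truth = simulate.simulate_cohort(
        sim, seed + 2, introns=[(r.intron_id, r.length) for r in usable],
        psi_map=psi_map, planted_dirs=planted,
    )
    # a stranded subset for the whitelist, drawn from the normal condition
    stranded, _ = simulate.simulate_cohort(
        SimulationConfig(n_genes=config.n_genes, n_pairs=config.n_stranded, depth=config.depth),
        seed + 3, introns=[(r.intron_id, r.length) for r in usable],
        psi_map=psi_map, planted_dirs={}, stranded=True,
    )
    truth.to_csv(out / "truth.tsv", sep="\t")
    state.update(genome=genome, models=models, introns=introns, usable=usable,
                 summaries=summaries, stranded_summaries=stranded, truth=truth)


def _stage_quantify(config: PipelineConfig, out: Path, state: dict) -> None:
    introns = _require(state, "introns", "quantify")
    matrix = quantify.build_ir_matrix(_require(state, "summaries", "quantify"), introns)
    matrix.to_tsv(str(out / "ir_matrix.tsv"), str(out / "ir_samples.tsv"))
    smat = quantify.build_ir_matrix(_require(state, "stranded_summaries", "quantify"), introns)
    smat.to_tsv(str(out / "ir_matrix_stranded.tsv"))
    state.update(matrix=matrix, stranded_matrix=smat)


def _stage_whitelist(config: PipelineConfig, out: Path, state: dict) -> None:
    smat = _require(state, "stranded_matrix", "whitelist")
    wl = quantify.build_whitelist(smat)
    (out / "whitelist.txt").write_text("".join(f"{i}\n" for i in sorted(wl)))
    state["whitelist"] = wl


def _stage_dir(config: PipelineConfig, out: Path, state: dict) -> None:
    matrix = _require(state, "matrix", "dir")
    wl = _require(state, "whitelist", "dir")
    dirs = differential.call_dirs(matrix, whitelist=wl, cancer_type="SYN")
    dirs.to_csv(out / "dirs.tsv", sep="\t")
    state["dirs"] = dirs


def _stage_features(config: PipelineConfig, out: Path, state: dict) -> None:
    genome = _require(state, "genome", "features")
    models = {m.transcript_id: m for m in _require(state, "models", "features")}
    dirs = _require(state, "dirs", "features")
    rows = []
    for rec in _require(state, "usable", "features"):
        seq = features.intron_sequence(models[rec.transcript_id], rec, genome)
        nmd = None
        if rec.region in ("CDS", "5UTR", "3UTR"):
            nmd = features.predict_nmd(models[rec.transcript_id], rec, genome)
        if rec.intron_id in dirs.index and dirs.loc[rec.intron_id, "is_dir"]:
            cls = "dir_up" if dirs.loc[rec.intron_id, "direction"] == "up" else "dir_down"
        else:
            cls = "unclassified"
        rows.append(
            {
                "intron_id": rec.intron_id,
                "class": cls,
                "gc": round(features.gc_content(seq), 6),
                "length": rec.length,
                "rel_pos": features.relative_gene_position(rec),
                "region": rec.region,
                "nmd": nmd.verdict if nmd else "NA",
                "nmd_reason": nmd.reason if nmd else "NA",
            }
        )
    table = pd.DataFrame(rows).set_index("intron_id")
    table.to_csv(out / "features.tsv", sep="\t")
    state["features"] = table


def _stage_diagnose(config: PipelineConfig, out: Path, state: dict) -> None:
    matrix = _require(state, "matrix", "diagnose")
    dirs = _require(state, "dirs", "diagnose")
    feats = differential.merge_dirs_pan_cancer({"SYN": dirs}, matrix)
    if not feats:
        logger.warning("no DIR features; skipping diagnostic model")
        return
    dense = differential.matrix_prep(matrix.values.loc[feats])
    run = diagnostic.DiagnosticRun(
        repeats=config.diagnose_repeats,
        folds=config.diagnose_folds,
        seed=stage_seed(config.seed, "diagnose"),
    )
    run = diagnostic.train_eval_cv(
        dense.T, matrix.samples["condition"], matrix.samples["pair_id"], run
    )
    _write_json(
        out / "diagnostic.json",
        {
            "pooled_auc": run.pooled_auc,
            "per_repeat_aucs": run.per_repeat_aucs,
            "n_features": len(feats),
            "confusion": run.confusion.tolist(),
        },
    )
    state["diagnostic"] = run


def _stage_prognosis(config: PipelineConfig, out: Path, state: dict) -> None:
    matrix = _require(state, "matrix", "prognosis")
    seed = stage_seed(config.seed, "prognosis")
    tumors = matrix.samples.index[matrix.samples["condition"] == "tumor"]
    vals = matrix.values[list(tumors)]
    truth = state.get("truth")
    beta_introns = [i for i in vals.index if truth is not None and truth.loc[i, "is_dir"]][:2]
    surv = simulate.simulate_survival(
        vals, {i: config.survival_beta for i in beta_introns}, h0=0.01,
        censor_frac=config.censor_frac, seed=seed,
    )
    surv.to_csv(out / "survival.tsv", sep="\t")
    eligible = vals.index[[prognostic.prognostic_eligibility(vals.loc[i]) for i in vals.index]]
    screen = []
    for iid in eligible:
        try:
            hr, p, (nl, nh) = prognostic.median_split_cox(vals.loc[iid], surv)
        except ValueError:
            continue
        screen.append({"intron_id": iid, "hr": hr, "p": p, "n_low": nl, "n_high": nh})
    pd.DataFrame(screen).to_csv(out / "prognostic_screen.tsv", sep="\t", index=False)
    model = prognostic.fit_irr(vals, surv, lambda_rule=config.lambda_rule, seed=seed)
    _write_json(out / "irr_model.json", model.to_json())
    if model.intron_ids and model.irr.nunique() > 1:
        curves, p, hr = prognostic.km_logrank(model.groups(), surv)
        km = pd.concat(
            [c.assign(group=g) for g, c in curves.items()]
        ).rename_axis("time").reset_index()
        km.to_csv(out / "km_curves.tsv", sep="\t", index=False)
        _write_json(out / "km_stats.json", {"logrank_p": p, "hr_high_vs_low": hr})
    state["irr_model"] = model


_STAGE_FN = {
    "simulate": _stage_simulate,
    "quantify": _stage_quantify,
    "whitelist": _stage_whitelist,
    "dir": _stage_dir,
    "features": _stage_features,
    "diagnose": _stage_diagnose,
    "prognosis": _stage_prognosis,
}


def make_demo(seed: int, outdir: str) -> Path:
    """Small end-to-end demo run; writes a manifest of headline numbers."""
    config = PipelineConfig(seed=seed)
    if config.n_genes <= 0:
        raise ValueError("demo requires at least one gene")
    out = run_pipeline(config, outdir)
    manifest = {"config_hash": config.hash(), "seed": seed}
    diag = json.loads((out / "diagnostic.json").read_text()) if (out / "diagnostic.json").exists() else {}
    manifest["pooled_auc"] = diag.get("pooled_auc")
    manifest["n_dirs"] = int(pd.read_csv(out / "dirs.tsv", sep="\t")["is_dir"].sum())
    if (out / "km_stats.json").exists():
        manifest.update(json.loads((out / "km_stats.json").read_text()))
    _write_json(out / "manifest.json", manifest)
    return out
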