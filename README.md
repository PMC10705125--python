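# retintron

Intron retention (IR) — an intron surviving splicing into the mature
transcript — is a comparatively neglected alternative-splicing outcome in
cancer transcriptomics, despite evidence that tumors shift retention
levels genome-wide and that individual events can silence tumor
suppressors or mark patient prognosis.  `retintron` is a tested, reusable
implementation of a pan-cancer IR analysis pipeline for bulk RNA-seq
cohorts with paired tumor/normal samples and survival follow-up.  It is
aimed at computational biologists who want the full chain — quantification
rules, differential calling, sequence characterization, and
diagnostic/prognostic modeling — as an importable library with a thin CLI,
plus a synthetic-data generator with planted ground truth so every stage
can be validated without access-controlled patient data.

## The quantities at the core

**IRratio.** For one intron in one sample,

```
IRratio = m / (m + J)
```

where *m* is the median read depth across the intron and *J* the number of
split reads spanning the intron's flanking exon–exon junction.  The ratio
estimates the retention fraction ψ, and is only trusted under decision
rules: at least 4 junction reads (otherwise missing); intron coverage
below 20% ⇒ confidently spliced (value 0); coverage above 70% *and* median
depth above 3 ⇒ keep the ratio; anything else ⇒ missing.  Samples with an
intergenic/coding read ratio above 10% are excluded, and analyses are
restricted to a *whitelist* of introns with max IRratio > 0.08 in
strand-specific samples.

**Differential retention (DIR).** Per cancer type, a paired Wilcoxon
signed-rank test on tumor−normal IRratio differences; a DIR requires
p < 0.05 and |Δ median IRratio| > 0.1, and is categorized as
cancer-associated (spliced in normal, retained in tumor), normal-associated
(the mirror), or altered-level.

**NMD prediction.** A retained intron in a coding transcript is predicted
to trigger nonsense-mediated decay unless it lies in a UTR, starts < 200 nt
from the start codon, is the last intron, produces no premature stop, or
the premature stop falls within 55 nt of the retained transcript's last
exon–exon junction.

**Models.** Diagnostic: a 500-tree random forest (mtry = 3) on merged DIR
features, scored by pooled out-of-fold AUC over repeated pair-aware 4-fold
cross-validation.  Prognostic: median-split univariate Cox per intron, and
a LASSO-penalized Cox signature whose intron-retention risk score
`IRR = Σ coefᵢ · IRratioᵢ` splits patients at the median into risk groups
compared by Kaplan–Meier/log-rank.

## Worked example

Run the full synthetic pipeline (genome → cohort → quantification →
whitelist → DIR calling → features → diagnostic → prognostic):

```
retintron run --seed 42 --out demo/
```

or from Python:

```python
from retintron.pipeline import PipelineConfig, make_demo
out = make_demo(42, "demo")
print((out / "manifest.json").read_text())
```

which prints (numbers produced by this exact command):

```json
{
  "config_hash": "a71352f331a00a5a",
  "hr_high_vs_low": 8.305885115580535,
  "logrank_p": 1.3215811695923287e-05,
  "n_dirs": 10,
  "pooled_auc": 1.0,
  "seed": 42
}
```

Reading: the simulated cohort (30 tumor/normal pairs, 12 genes) plants 10
differentially retained introns with Δψ = 0.3; all 10 are recovered as
DIRs (`n_dirs`), they separate tumor from normal perfectly under
cross-validation (`pooled_auc`), and the LASSO-Cox IRR signature built on
the tumor samples splits patients into risk groups with hazard ratio ≈ 8.3
and log-rank p ≈ 1.3 × 10⁻⁵ against the planted survival effect.  The run
directory also holds the IR matrix, the DIR table with categories, the
per-intron feature table (GC, length, relative position, NMD verdict), and
the serialized IRR model.

Individual stages are available as subcommands (`retintron introns`,
`quantify`, `whitelist`, `dir`, `diagnose`, `prognosis`); every artifact is
a plain TSV/JSON/BED file.

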