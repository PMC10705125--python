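# Methods

## Scope and data model

`retintron` implements an intron-retention (IR) analysis chain for bulk
RNA-seq cohorts: quantification of per-intron retention, differential
retention between paired tumor/normal samples, sequence characterization
of retained introns, and diagnostic/prognostic modeling.  The pipeline
does not realign reads; its input is either a per-sample summary TSV
(median intron depth, coverage fraction, flanking-junction split-read
count, intergenic/coding read counts) or, for small cases, a SAM/BAM file
from which those summaries are derived.

Internally all coordinates are 0-based half-open; GTF input (1-based
inclusive) is converted on read and BED output follows the BED standard.
Introns are defined per transcript as inter-exon gaps and deduplicated
genome-wide by (chrom, start, end, strand), keeping ordinal and region
annotation from the first transcript in canonical (chrom, start,
transcript id) order.  Introns that intersect any annotated exon are
flagged and excluded from quantification: a read inside such an interval
cannot distinguish retention from expression of the overlapping exon.
Transcript-level CDS bounds include the stop codon; GTFs that annotate
the stop separately (`stop_codon` features) are merged on read.

## IRratio and its decision rules

The retention ratio of an intron in a sample is `m / (m + J)` with *m*
the median per-base depth over the intron and *J* the split-read count
across the junction that skips it.  Both isoforms share the locus: depth
supports retention, junction reads support splicing, so the ratio
estimates the retention fraction ψ.  The rule chain:

1. `J < 4` → **missing** (no evidence the spliced isoform is expressed);
2. coverage (fraction of intron bases with depth ≥ 1) `< 0.20` → **0.0**
   (confidently spliced);
3. coverage `> 0.70` and `m > 3` → keep the ratio (necessarily > 0);
4. otherwise → **missing**.

Boundary semantics are strict everywhere (coverage exactly 0.20/0.70 and
median exactly 3 are missing; a sample QC ratio of exactly 0.10 passes; a
whitelist maximum of exactly 0.08 is excluded), mirroring the strict
wording of the rules ("less than", "above", "exceeded").  Coverage uses
depth ≥ 1 because the rules name no depth cutoff; this is the minimal
reading and is stated here deliberately.  In matrices a cell is a float:
NaN = missing, 0.0 = confident zero, positive = kept ratio.  Confident
zeros are observations (they enter medians, imputation means and
eligibility counts); missing cells are not.

Sample QC excludes samples whose intergenic/coding read ratio exceeds
10%.  The whitelist is computed on strand-specific samples only — on
unstranded libraries antisense transcription can masquerade as retention —
and keeps introns whose maximum kept ratio exceeds 0.08.

## Differential retention

Per intron, pairs with a missing value on either side are dropped; the
remaining tumor−normal differences enter a Wilcoxon signed-rank test
(zero differences dropped; exact null distribution when scipy's rule
permits, otherwise the continuity-corrected normal approximation).  The
phrase "paired Wilcoxon rank-sum" conventionally denotes the signed-rank
test; that reading is adopted here.  A DIR requires p < 0.05 (unadjusted;
a Benjamini–Hochberg switch exists but defaults off, matching the
screening design) and |Δ median| > 0.1.  Cohorts require more than 15
tumor/normal pairs.  Categories: cancer-associated iff median(normal) = 0
and median(tumor) > 0.1; normal-associated for the mirror; otherwise
altered-level.

Pan-cancer feature merging unions per-cancer DIR tables, drops introns
called in both directions in different cancers, and drops introns missing
in more than 30% of all samples.  Matrix preparation for embeddings and
classifiers keeps rows with missing rate strictly below 30% and imputes
remaining missing cells with the row mean over observed entries.

Mutation proximity flags a DIR when a variant lies within 20 bp
(inclusive, both intronic and exonic side) of the first or last intronic
base.  IR–expression coupling is measured as the Spearman correlation of
Δ median IRratio against log2 fold change from an externally supplied
differential-expression table (DE calling itself is out of scope).

## Sequence features and NMD

Intron classes are mutually exclusive: DIR-up / DIR-down (membership in
any cancer's DIR table; inconsistent directions are dropped upstream),
constitutive (median IRratio 0 in every cancer and condition),
unregulated-retained (nonzero somewhere, never differential).  GC content
and length are computed on the genomic intron sequence; relative gene
position is `(ordinal − 1) / (n − 1)` in transcript orientation, mapping
the 5′-most intron to 0 and the 3′-most to 1, with genes of fewer than 3
introns excluded.

NMD prediction operates on the intron-retained mRNA, because that is the
molecule surveilled.  All distances are spliced-transcript coordinates.
Escape conditions, in order: intron in a 5′/3′ UTR; intron 5′ end < 200 nt
downstream of the start codon; last intron; no premature stop before the
normal stop when translating the retained mRNA from the annotated start;
premature stop within 55 nt (inclusive) upstream of the retained
transcript's last exon–exon junction.  Otherwise the transcript is
predicted NMD-sensitive.  The premature-stop position is the first base of
the stop codon.  An independent brute-force oracle (explicit mRNA
construction plus linear codon scan) is kept in the test suite and the
acceptance script; the implementation must agree with it exactly on
randomized transcripts.

uORF detection pairs every ATG strictly upstream of the main start with
its first in-frame stop (which may lie beyond the main start).  ORF length
counts codons from the initiator ATG up to (excluding) the stop.  ATGs
with no in-frame stop before sequence end are "incomplete" and excluded by
default.

## Diagnostic model

A random forest with 500 trees and 3 candidate features per split,
evaluated by repeated 4-fold cross-validation (default 100 repeats).
Folds are partitions of tumor/normal *pairs*, so both members of a pair
share a fold; an assertion enforces this.  Whether the original protocol
respected pairing is unknowable from its description; enforcing it avoids
an optimistic bias, at the cost of a possible (small) difference from the
original numbers.  The pooled AUC is one AUC over all out-of-fold
probabilities concatenated across folds and repeats — the most literal
reading of "pooled" — with per-repeat AUCs retained for transparency.
Class imbalance is left unadjusted.  The feature-reduction curve shrinks
the feature set geometrically, n ← ceil(0.9·n), scoring each size by
5-fold CV misclassification; because ceil(0.9·n) = n for n ≤ 9, the
recursion stops when the size stops decreasing.

## Survival analysis

Eligibility per intron: valid (non-missing) IRratio in ≥ 50% of patients
and > 0.1 in ≥ 5% of the valid values.  The median-split Cox restricts to
patients with IRratio > 0, splits at the median of the restricted values
(ties to the low group — deterministic, and stated because the protocol
is silent), and fits a univariate Cox model (Efron ties, Wald p);
unadjusted p < 0.05 is the screening threshold.  The gene-expression
analog median-splits genes with median expression > 1 TPM.

The IRR signature: introns with missing rate < 20% are mean-imputed,
standardized, and fed to an L1-penalized Cox path (coordinate-descent
elastic net with l1_ratio = 1).  The penalty is chosen by 10-fold
cross-validated partial-likelihood deviance in the Verweij–van
Houwelingen form — for fold k, −2·[pl(β₋ₖ; all) − pl(β₋ₖ; without k)]
with Breslow tie handling, matching the path solver — at either the
deviance minimum (default) or the one-standard-error rule (sparsest model
within one SE).  Coefficients are rescaled to the raw IRratio scale so
`IRR = Σ coefᵢ · IRratioᵢ` is a plain dot product; patients split at the
median IRR (ties low), and groups are compared by Kaplan–Meier curves, a
two-sided log-rank test, and the Cox hazard ratio of high vs low.

## Synthetic data

The generator exists to give every stage a ground truth.  It emulates:

* **Genomes/annotation** — multi-exon protein-coding genes (4–8 exons by
  default) with GC-controllable introns of 80–300 bp carrying canonical
  GT…AG dinucleotides, stop-free CDS bodies, ATG-free 5′UTRs, and
  optionally a 5′UTR intron planting an exact number of upstream ATGs,
  each opening a short in-frame ORF (for uORF and NMD tests).
* **Read evidence** — per intron, base depth i.i.d. Poisson(d·ψ) and
  junction reads Poisson(d·(1−ψ)), so the locus depth budget d (default
  100, a realistic exonic depth for TCGA-scale libraries) is split by the
  retention fraction and IRratio is a consistent estimator of ψ.
  Extremes behave like real data: ψ = 1 starves the junction and the
  quantifier reports missing; ψ = 0 gives a zero call.
* **Cohorts** — paired tumor/normal samples (default 30 pairs, matching
  the smallest usable paired cohorts) with planted Δψ effects on chosen
  introns and a shared per-patient random effect on logit(ψ)
  (sd 0.3) inducing the within-pair correlation a paired test exploits.
* **Survival** — exponential event times with hazard h₀·exp(Σβ·x), x the
  IR-high median-split indicator, under uniform censoring whose scale is
  calibrated by bisection to a target censored fraction (default 20%).

What it does *not* emulate: read-level error and mappability, fragment
length, isoform competition beyond a single intron, covariate-dependent
censoring, batch effects.  Passing tests therefore demonstrate
correctness of the decision rules and estimators under the stated
generative model, not robustness to alignment artifacts in real cohorts.
A SAM emitter (single-base intron reads plus N-gapped junction reads)
exists solely to exercise the alignment-reading path on tiny cases; the
TSV summary path is the primary surface.

## Numerical and design choices

* Determinism: every stochastic call takes a seed; the pipeline derives
  per-stage child seeds as sha256("{seed}:{stage}") mod 2³¹, so stages are
  independently reproducible and a fixed-seed run is byte-identical.
* Problem sizes in the test and verification suites (cohorts of 30 pairs,
  hundreds to a thousand introns, 150–200 patients, 20-seed replications)
  are chosen to make the statistical checks sharp at desk scale: type-I
  rates are binomial with ~1000 trials, hazard-ratio recovery uses the
  median over 20 seeds, and permutation centering uses the mean over 20
  permutations (a single permutation AUC at n = 60 has sd ≈ 0.075).
* Degenerate inputs raise: empty depth profiles, zero coding reads,
  cohorts with too few pairs, splits with an empty group or no events,
  constant features in the penalized fit, empty matrices.
* Known limitations: no multiple-testing correction by default (by
  design, with a BH switch); the NMD rule ignores reinitiation and
  intron-containing 3′UTR junction effects beyond the 55-nt heuristic;
  the synthetic GTF uses one transcript per gene, so transcript-collapse
  behavior is exercised only by the dedicated annotation tests; maximum-
  entropy splice scores and conservation profiles are outside scope.
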