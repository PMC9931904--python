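# Methods

This note documents the statistical model, the conventions the package
fixes where published practice leaves room, and what the synthetic panel
does and does not emulate. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Mixed-model genome scan

Strain means `y` (n strains) are modeled as

    y = Xβ + g + ε,  g ~ N(0, σg² K),  ε ~ N(0, σe² I)

with `X` an intercept (null) or intercept + marker dosage (alternative).
Dosage codes the two founder alleles 0/1, heterozygotes 0.5, and unknown
calls as the column mean (RI strains are inbred, so heterozygous and
missing calls are rare edge cases, not the norm).

**Kinship.** K = WW′/m over column-centered dosages. Scans use
leave-one-chromosome-out (LOCO): the tested marker's chromosome is removed
from K so the random effect cannot absorb the very signal being tested.
The null model is refitted per LOCO kinship.

**Likelihood.** After eigendecomposition K = USU′ the ML likelihood
concentrates to a scalar function of δ = σe²/σg²; β and σg² have closed
forms given δ. δ is maximized on a 100-point log grid spanning
[1e−5, 1e5], then refined by golden-section/Brent to ~1e−9 relative
precision. Grid-boundary optima are flagged (`boundary`), not errors; a
near-constant trait is flagged `degenerate` with variances floored at
1e−12. Per-marker fits are vectorized across markers (closed-form 2×2
weighted normal equations at each δ), which keeps a 70-strain × 5,000-marker
scan under a second without approximating the per-marker δ optimum.

**Statistics.** LRS = 2(ℓ₁ − ℓ₀), clamped at 0 against optimizer jitter;
p = P(χ²₁ > LRS) computed via `chi2.logsf` so −log₁₀p survives LRS > 60;
LOD = LRS/4.61. Thresholds −log₁₀p 3.0/4.0 (suggestive/significant) are
configuration, not constants. MAF is computed on the dosage view over the
strains actually analyzed; markers below 0.05 are dropped before testing.

**ML, not REML.** The LRS/LOD conversion presumes likelihoods comparable
across models with different fixed effects, which REML likelihoods are not.
The cost is the usual slight finite-sample bias in variance estimates; the
type-I checks in the test suite (null markers significant at 4–5% for a
nominal 5%) show the resulting p-values are, if anything, mildly
conservative at n = 70. No claim of numeric identity with any external
scanner is made.

**p-value calibration and LD.** Markers within one RI chromosome sit on
long founder-block haplotypes, so per-scan p-values are strongly
dependent. The uniformity property test therefore samples approximately
independent markers (one per chromosome per seed) before applying a
Kolmogorov–Smirnov test; applying an i.i.d. test to thousands of correlated
p-values would reject for reasons unrelated to calibration.

## 1.5-LOD support intervals

One peak per chromosome (maximal LRS; ties go to the lowest Mb), emitted
only at or above the suggestive threshold. The interval walks outward to
the **last marker whose LOD is within 1.5 of the peak** (inner-marker
convention) — conservative relative to interpolating the crossing point.
On the drop scale LOD (not −log p) is used, as the name says. Widening the
drop can only widen intervals (tested property). Gene membership is by any
overlap between gene body and interval, 1-based inclusive Mb coordinates,
no strand.

## Expression, correlation, criteria

TPM: per-sample length-normalized rates scaled to sum to exactly 10⁶;
log2(TPM+1) for analysis. The mean-expression ≥ 2 criterion is applied on
whatever scale the matrix declares; the default pipeline applies it to
log2(TPM+1) values, because that is the scale panel expression datasets are
usually distributed on, but the threshold is equally usable on raw TPM via
the declared-scale mechanism — the two readings differ and neither is
asserted as canonical. The boundary is inclusive (mean exactly 2 passes).

Pearson correlation uses pairwise-complete strain means, p from the exact
t transform with n−2 df; |r| = 1 reports the smallest positive float and a
flag. The P < 0.05 criterion is **strict** and deliberately uncorrected
for multiple testing — it reproduces the nominal-significance convention
of candidate screening, and anyone using it on thousands of genes should
treat it as a screen, not an inference.

## Cis-eQTL rule

A gene is cis-regulated when the genome-wide maximum-LRS marker of its
expression scan exceeds LRS 14 (strict) and lies within
[start − 5 Mb, end + 5 Mb] on the gene's own chromosome. The window
anchors on the gene body, not the TSS. "Maximum LRS" is read genome-wide
(the panel-database convention); a `scope="local"` switch restricts the
maximum to the window for the alternative reading. LRS ties break toward
the marker nearest the gene midpoint. Because founder haplotype blocks are
tens of Mb long, the argmax can drift past the 5 Mb window even for a true
cis gene — the power tests quantify this (≈95% detection at a 1.5-SD
planted effect, 70 strains).

## Candidate scoring

Weights 1 (expression), 2 (coding variant), 2 (cis), 2 (correlation),
3 (functional relevance); total 0–10; selection at total ≥ 6 — one point
above the score-range midpoint of 5, so a selected gene must satisfy a
majority of the weighted evidence. A coding variant counts only in
{non-synonymous, frameshift, stop gain, stop loss}. Functional relevance
is a user-supplied gene list: database mining is irreproducible over time
and is out of scope by design. Ranking is total desc, then chromosome
order, then position; weights and cutoff are configurable.

## Synthetic panel

The generator emulates a two-founder RI family:

* **Genotypes** — per strain and chromosome, breakpoints ~
  Poisson((length_cM/100) × expansion), expansion default 4 (the classic
  sib-mating RI map inflation); alternating homozygous founder blocks;
  founder at the chromosome start is a fair coin, so expected MAF ≈ 0.5.
  Markers sit on a uniform grid (default 1,000/chromosome, 100 cM ≙ 200 Mb
  at the fixed 2 Mb/cM scale). An optional missingness knob introduces
  unknown calls.
* **Phenotype** — intercept 5.4 + Σ effect × dosage at the marker nearest
  each planted position + polygenic draw from the realized kinship scaled
  to h² (default 0.3) + i.i.d. noise sized to fill the unit variance
  budget (so planted effects are in phenotype-SD units and the effect
  equals the expected allele-group mean difference). Per-animal replicates
  (default 4/strain) are drawn around strain means and averaged, because
  the scan operates on strain means. Defaults (70 strains, 1 planted QTL
  of 1.5 SD) mirror a realistic well-powered panel study.
* **Expression** — per-gene baseline ~ N(5, 1.5²) on a log2(TPM+1)-like
  scale, clipped at 0; a 15% fraction of genes get an additive cis effect
  (default 1.5× the expression noise SD of 0.5) from the marker nearest
  the gene. Variant (13%) and functional (12%) memberships are independent
  sparse subsets, rates chosen to match the sparsity seen in candidate
  screens of this kind. Each planted QTL also gets one fully loaded
  "causal" gene centered on the QTL marker, with variant + functional
  membership and a floored baseline, so ground-truth recovery is
  well-defined.
* **Determinism** — every stage draws from its own `(seed, stream)`
  generator; identical configs are byte-identical on disk.

What it does **not** emulate: real BXD pedigrees or genotype files,
epistasis, dominance, sex or batch effects, X-chromosome dosage,
count-level sequencing noise, or LD structure beyond the founder-block
mosaic. Passing tests therefore demonstrate the correctness and
calibration of the *methods* under a faithful idealization, not the
re-derivation of any particular panel's published QTL coordinates (which
would require that panel's actual genotype and expression files).

## Problem sizes used in the checks

The test suite runs the power and calibration studies at 70 strains with
5 chromosomes × 200 markers (100 seeds for recovery, 50 for type-I), and
the end-to-end pipeline at 3 chromosomes × 120 markers with 150 genes —
sizes at which the binomial error bars on the pass criteria are already
far smaller than the margins being asserted. The default pipeline
configuration (5 × 1,000 markers, 2,000 genes) completes in well under a
minute on one core.
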