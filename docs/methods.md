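# Methods

This note records the models implemented in `repeatarch`, their
assumptions, the defaults that matter, what the synthetic cohort does and
does not emulate, and the numerical choices that were genuinely open.

## Annotation resolution and window statistics

Coordinates are 0-based half-open everywhere inside the package; GFF3
(1-based inclusive) is converted at the I/O boundary. Overlapping repeat
annotations are resolved by assigning every base to the highest-priority
covering feature — rDNA > known TE > simple repeats and low-complexity >
unknown repeats — with ties within a priority level broken by longer
element, then smaller start, then feature id, which makes resolution
deterministic. The ≤ 20 bp removal applies to the *post-trim fragment*,
not the original element: a long element reduced to a sliver by a
higher-priority overlap is treated as a likely false positive and
dropped. Resolution is idempotent and conserves covered bases up to that
filter (both properties are tested against a per-base painting oracle).

Window densities tile each chromosome from position 0 in fixed windows
(default 100 kb). Trailing short windows are kept, normalized by their
true width, and flagged `short_window` so downstream users can exclude
them; discarding them silently would throw away data. Gene distances use
the dialect of the standard closest-feature tool: overlap → 0, book-ended
→ 1, otherwise gap + 1. The per-window density regression (class density
on CDS density and the population-scaled recombination rate `4Ne r`) is
ordinary least squares with drop-one F tests; constant responses or
collinear predictors return a flagged degenerate fit with no p-values
rather than fragile numbers.

## Depth-based quantification

"Median genic coverage" is implemented as the median over genes of the
per-gene *mean* depth — the quantity a per-region depth summarizer
emits — rather than the median of per-base genic depth. The genome-size
estimator divides the genome-wide summed depth by this median; because
genes are on average single copy the ratio is a haploid genome length.
The estimator's main error source is the sampling noise of the genic
median: with the default 2,000-gene panel its standard error is ~0.3%,
and simulated recovery at 25× is accurate to well under 1% mean absolute
relative error.

Copy numbers are reported on both scales carried by `CopyNumberMatrix`:
the haploid ratio `rho` (single-copy ≈ 1) and `diploid = 2 rho`
(single-copy ≈ 2). Class bp abundances sum `rho × element length`, i.e.
they are haploid-genome bp totals, which is the scale on which the large
LTR classes come out near their expected tens of Mb; gene copy numbers
are reported diploid (the ATP-pathway locus spans roughly 2–14 copies).
Depths are never floored, capped or winsorized. CVs use `100·sd/mean`
with the n−1 variance; a zero-mean class yields an undefined CV and an
explicit flag instead of an infinity.

## The linear mixed model

The model is `y = X b + u + e` with `u ~ N(0, sg² K)`,
`e ~ N(0, se² I)`, and `K = W W'/p` from locus-centered (not
individual-centered) genotypes with mean imputation of missing dosages.
Estimation profiles the restricted likelihood over `lambda = sg²/se²`
after a single eigendecomposition of K: a 100-point grid on
`log10(lambda) ∈ [−5, 5]` followed by bounded scalar refinement to 1e−6.
Boundary optima are flagged. GLS at the optimum gives the fixed effects;
their covariance is conditional on the estimated lambda (no
degrees-of-freedom correction such as Satterthwaite — tests are Wald
chi-square, matching the chi-square reporting convention of the
analysis this package implements).

Factors use sum-to-zero contrasts so type III Wald tests are invariant to
level ordering; interactions are products of the coded columns and
require their main effects. Per-term semi-partial r² uses the
approximate-df form `(df·F)/(df·F + df_resid)` with `F = chi²/df` and
`df_resid = n − rank(X)`; this is an approximation to the
generalized-variance semi-partial R² and is documented as such. Marginal
and conditional R² follow the standard fixed-vs-fixed-plus-random
decomposition with the genetic variance scaled by the mean diagonal of K.
Least-squares means are predictions at the grand mean of continuous
covariates averaged with equal weight over the other factors' levels.
Rows with any missing response or covariate are dropped listwise with a
logged count.

Model presets: `abundance` (a repeat-class abundance on longitude,
latitude, sex, habitat, sex:habitat, ancestry), `phenotype` (a trait on
genome size plus the same terms), and `joint` (flowering time on the
z-scaled genome size, ATP-locus copy number and transformed polygenic
value). All fits include the kinship random effect.

## Association scans and the polygenic value

The genome-wide scans use the standard single-null-fit approximation:
variance components are estimated once under the covariate-only null,
and every feature is then tested by GLS under that fixed structure. This
is orders of magnitude faster than per-feature REML and is the default
of the widely used mixed-model GWA tools; an exact per-feature refit is
available behind `refit_variance=True`. The unstructured mode (no
kinship) uses the same fixed-scale convention with the residual variance
from the covariate-only fit, so a zero kinship matrix and "no kinship"
give identical results. Monomorphic features are skipped with a logged
count, not errored. No minor-allele-frequency filter is applied by
default. Benjamini–Hochberg q-values are computed by the step-up rule
exactly (tested against a brute-force oracle and an independent library
implementation); Bonferroni flags use `p ≤ alpha/m`.

The polygenic value is `2·Σ alpha_l p_l` over loci passing the 10% FDR
(configurable), with `p = dosage/2 ∈ {0, 0.5, 1}` and `alpha` the
scan-estimated effects — an in-sample score, as in the study design this
mirrors. Because the raw PGV can be negative, the joint model uses
log10(PGV + shift) z-scaled, where the shift is |min| plus 5% of the
value range. The 5% epsilon is a deliberate numerical choice: a
vanishing epsilon would place the minimum individual several
log10-decades below everyone else, a single point of extreme leverage
that can erase the PGV term from any regression it enters. Five percent
bounds the transformed span to ~1.3 decades while keeping the shift+log
contract.

Both the copy-number GWA and the SNP GWA are provided with and without
kinship control; the pipeline defaults to controlled for both.

## The synthetic cohort

The generator's defaults are the study conditions: 186 individuals from
17 paired agricultural/natural populations spanning latitudes 38–41°,
two admixing varietal ancestries whose mixture follows the latitudinal
gradient (logistic in latitude, Fst-like divergence 0.15), sexes 1:1,
20–35× coverage, a ~594 Mb genome (269 Mb single-copy plus 16 repeat
classes whose mean abundances put Ty3 at 86.8 Mb, Copia 59.0, Helitron
50.1, unknown-LTR 49.3, with realistic fills elsewhere). Per-class
abundance CVs (10–40%, rDNA highest) combine a shared per-individual
"repeat load" multiplier (CV 5%) with class-specific lognormal noise and
a few planted latitudinal clines; under these defaults genome sizes span
roughly 545–665 Mb, a ~20% spread. Region depths are gamma-Poisson with
an excess CV² of 0.01 beyond Poisson, reflecting the overdispersion of
real region-depth data; the genome-wide summed depth stays consistent
with the true genome size and base depth, so zero-noise mode inverts
exactly.

Flowering time is an exact sum of recorded components: intercept, genome
size at +0.08 days/Mb, sex (males −8.7 days), habitat and sex×habitat
terms, latitude/longitude/ancestry terms, the ATP-locus copy-number
effect, the polygenic effect, a kinship-structured random deviate
(sigma_g² = 4) and residual noise (sigma_e² = 4). The ATP-locus and
polygenic effect scales are calibrated at generation time so that those
components hold 20% and 35% of the realized phenotypic variance — the
shares the analysis is meant to recover. Growth rate is an analogous
trait with a small negative genome-size effect.

Two structural choices matter and are deliberate:

- **The ATP-locus copy number is clinal.** Its latent value combines a
  gamma-distributed component with a northward decline (−0.5 copies per
  degree) and a var. rudis ancestry loading (+3 copies per unit
  ancestry), so — like real large-effect CNVs in a structured species —
  part of its signal is absorbed by the kinship control rather than being
  an artificially orthogonal predictor.
- **The polygenic architecture is leading-locus heavy.** The 97 causal
  SNPs (drawn from common, weakly ancestry-aligned loci, since only
  structure-unconfounded effects are discoverable by a kinship-controlled
  scan) receive geometrically decaying variance shares (ratio 0.25).
  At n = 186 with a desk-scale SNP panel, a locus needs roughly p ≲ 1e−4
  to survive a 10% FDR, i.e. an individual variance share of several
  percent; an exchangeable many-tiny-effects architecture would leave the
  FDR-selection → PGV stage with nothing to select, and the detected
  architectures of flowering-time studies are in fact dominated by a few
  major loci over a polygenic tail. The decay is a config knob
  (`polygenic_decay`), as is every other generator parameter.

What the generator does **not** emulate: linkage disequilibrium between
SNPs (loci are drawn independently given ancestry), read-level artifacts
(mappability, GC bias, organellar contamination of the depth sum),
reference bias in repeat annotation, and selection. Passing tests
therefore validate the estimators and inference machinery under a
faithful generative model of the study design, not robustness to every
failure mode of real sequencing data.

Desk-scale sizes: the default SNP panel is 1,000 loci and the annotation
carries 250 elements per class plus 2,000 genes; real panels are orders
of magnitude larger, but these sizes preserve every statistical contrast
the pipeline tests while keeping the full run around a second. The
replicate studies used by the test suite shrink the annotation further
(40 elements per class, 400–600 genes) without changing cohort size.

## Pipeline and reproducibility

Stages (simulate → quantify → windows → abundance models → phenotype
models → GWA → PGV → joint model) run in dependency order; toggling off a
required upstream stage raises a dependency error naming both stages.
Intermediates are plain TSV/JSON/VCF/BED/GFF3. Everything is driven by
one master seed through independent substreams, so a rerun with the same
config reproduces every output exactly — including the REML optimizer,
which is deterministic. The report carries provenance (config hash, seed,
package and library versions). If no SNP passes the FDR threshold the
PGV stage fails loudly (the polygenic value is undefined) and retains all
upstream outputs rather than silently substituting something else.

In the pipeline's window regressions, gene density stands in for CDS
density (the synthetic annotation does not model exon structure), and
simulated repeat placement is uniform, so those regressions exercise the
machinery rather than recover a planted density gradient.

## Known limitations

- Wald chi-square tests are asymptotic; at small n they run slightly
  liberal (calibration is verified at n = 100 within [0.035, 0.065] at
  nominal 0.05).
- The semi-partial r² uses a residual-df approximation rather than the
  exact generalized-variance construction.
- The fixed-effect covariance ignores uncertainty in lambda.
- Single kinship kernel only; no Gaussian-process/spatial extensions, no
  non-Gaussian responses.
- The joint model's predictor ordering is a property of the calibrated
  generative shares; under seeds where the FDR selection captures only
  the top locus the PGV and ATP terms can come close.
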