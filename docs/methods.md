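# Methods

## Dosage model

A sample is modelled as two founder alleles $A$ and $B$ with copy counts
$c_A, c_B \geq 0$ ($c = 0$ only for the *5 whole-gene deletion, which
contributes no sequence). Allele-quantification signal is assumed
proportional to copy number, so the expected variant fraction at panel SNP
$s$ is

$$f_s(A, c_A, B, c_B) = \frac{c_A \mathbb{1}[s \in V_A] + c_B \mathbb{1}[s \in V_B]}{c_A + c_B},$$

where $V_X$ is the set of panel SNPs haplotype $X$ carries in variant
state. The panel covers the defining SNPs of *2 (2850C>T, rs16947),
*3 (2549delA), *4 (1846G>A), *6 (1707delT), *10 (100C>T), *17 (1023C>T)
and *41 (2988G>A). Haplotype content is restricted to this panel but uses
the standard nomenclature's full assignments — *4 = {100C>T, 1846G>A},
*17 = {1023C>T, 2850C>T}, *41 = {2850C>T, 2988G>A} — because the joint
dosage fit needs them: with *41 = {2988A} alone, a *1/*41 sample's 2850
signal would be misattributed to *2, and the shared 100C>T of *4/*10 is
resolved by whether a matching 1846 dose is present, not by subtraction
rules. *41 is keyed to rs28371725 (2988G>A); *36 is not separable from
*10 on this panel, so every *10-containing call carries a `star10_or_36`
flag.

## Ratio classification

At a heterozygous SNP the folded allelic ratio (major/minor percentage
quotient) is compared against a calibration table with per-class mean, SD,
minimum and maximum; defaults:

| copies | mean | SD | min | max |
|---|---|---|---|---|
| 2 | 0.97 | 0.07 | 0.85 | 1.06 |
| 3 | 1.83 | 0.16 | 1.60 | 2.20 |
| 4 | 2.76 | 0.39 | 2.42 | 3.20 |

The calibration publishes ranges, not decision rules, so boundaries are
the midpoints of the gaps between adjacent class ranges — 1.33 between
1:1 and 2:1, 2.31 between 2:1 and 3:1 — which is symmetric and
configurable. The acceptance ceiling is 3.7 (the 4-copy maximum plus
roughly one within-class SD, rounded up); ratios above it are flagged
`out_of_range`, ratios within 0.1 of a boundary `near_boundary`.
Classification always folds oriented ratios to ≥ 1 (the classifier must
not depend on which allele is labelled reference); an oriented
variant/reference mode is kept for reproducing calibration statistics,
where balanced heterozygotes average slightly below 1. A minor-allele
percentage below 5% is treated as a homozygous signal: no finite ratio is
reported because a ~100% peak is what one, two, or four identical copies
all look like. Percent pairs must sum to 100 ± 2 before rescaling;
larger discrepancies are input errors.

ΔΔCT conversion uses the comparative method, copies
$= R \cdot 2^{-\Delta\Delta C_T}$ with $R = 2$ reference copies; raw
values farther than 0.35 from an integer are flagged low-confidence.

## Diplotype search

The caller enumerates every founder pair from the allele table (including
*1/*1 and *5 pairs) and every copy split of each candidate total (each
non-deletion founder 1–3 copies; 3 supports the observed ×3
multiplications), scoring each configuration by the mean absolute
deviation between observed and expected variant fractions over the panel.
Candidate totals are the orthogonal assay's value when supplied, else {2}
∪ the totals implied by classifying each heterozygous SNP's ratio. The
search space is ~10² configurations, so exhaustive enumeration is exact
and fast; a property test keeps it equivalent to an independent naive
enumeration.

Ties and near-ties: configurations within +0.03 residual of the best are
kept as alternatives, and the call is flagged ambiguous when they disagree
on phenotype. Equal residuals break by parsimony — fewer distinct
non-reference founders, then fewer total copies, then lower star numbers,
then the more balanced split (so a homozygous total of 4 reads
`(A/A)x4` as 2+2). When the orthogonal total conflicts with the
ratio-implied total the orthogonal assay wins and a
`copy_number_conflict` flag plus a log warning record the disagreement.

Blind spots are flagged, not guessed: samples with no heterozygous panel
SNP are `homozygous_unquantifiable` (this covers *5 carriers, homozygotes
and homozygous multiplications — only the orthogonal total can resolve
them, and homozygous calls with totals above 2 render as `(A/A)xN`);
balanced n:n duplicated heterozygotes are indistinguishable from 1:1 by
quantification alone, so they are only called when the orthogonal total
forces them and are flagged ambiguous.

Pre-resolution phenotyping (`phenotype_before_resolution`) reproduces what
a genotype plus a bare total copy number supports: for a heterozygote with
more than two copies it enumerates single-founder amplifications (the
extra copies on one chromosome, the other founder staying at one copy) and
reports the candidate score/phenotype set. The balanced two-sided
alternative (e.g. 2+2 within a total of 4) is excluded there as it
requires independent duplications on both chromosomes; the full caller's
search space does include such splits when data support them.

## Activity scores and phenotypes

Per-copy activity values: 1 for *1 and *2; 0.5 for *10, *17, *41; 0 for
*3, *4, *5, *6. The score is the copy-weighted sum over both founders.
Phenotype bins: 0 → PM, 0.5 → IM, 1–2 inclusive → EM, strictly greater
than 2 → UM (a score of exactly 2 is EM). Scores must be non-negative
half-steps; with this allele set no score strictly between 0.5 and 1 can
arise. The allele and activity tables ship as YAML
(`pyrostar/data/default_model.yaml`) so other activity-score versions can
be loaded without code changes.

## Cohort statistics

Phenotype percentages are computed from counts and rounded
half-away-from-zero to one decimal (two where finer precision is wanted,
e.g. genotype frequencies). Hardy-Weinberg equilibrium is a Pearson χ²
with 1 df against expected counts from the observed allele frequencies,
computed per population label when labels exist and pooled otherwise;
monomorphic SNPs return statistic 0 / p 1 with a flag. Ratio statistics
use one-way ANOVA (scipy `f_oneway`), Tukey HSD at α = 0.05
(statsmodels), and Pearson correlation between copy number and ratio over
all samples. Degenerate inputs (single group, zero within-group variance)
fall back to descriptive statistics.

## Simulator

`simulate_cohort` draws founder pairs i.i.d. from a star-allele frequency
map (Hardy-Weinberg random mating), then duplicates (probability 0.03) or
triplicates (0.002) each non-deletion founder independently. Default
frequencies are those implied by the 218-sample validation cohort
(*1 0.374, *2 0.250, *4 0.149, *17 0.062, *41 0.057, *5 0.041, *10 0.041,
*3 0.018, *6 0.007); the rates are the same cohort's founder-slot rates.
The degenerate *5/*5 pair (no gene to assay) is redrawn.

Measurement noise is Gaussian on the percent scale, truncated to
[0, 100], with SD 2.0 percentage points by default — no error model is
published for the assay, so this is the minimal symmetric choice, with
the SD set by a delta-method match to the calibration dispersion: at the
2:1 fraction $p = 66.7$, $dr/dp = 100/(100-p)^2 \approx 0.09$, giving a
ratio SD of $2.0 \times 0.09 \approx 0.18$, bracketing the published
0.16. The orthogonal total is simulated as truth plus Gaussian raw noise
(SD 0.15) rounded to an integer, mirroring the ΔΔCT caller. Fixed seeds
give bit-identical cohorts. What the simulator does *not* emulate:
per-assay heteroscedasticity across the seven primer sets, pyrogram
peak-height artifacts, CYP2D7-hybrid cross-amplification, and more than
two founder haplotypes per sample — so passing tests demonstrate the
interpretation logic, not robustness to those instrument-level effects.

## Problem sizes and numerical choices

Property tests run 1000 random samples against the naive-enumeration
oracle; recovery tests use 400-sample cohorts at default noise; HWE
convergence uses 10⁴ samples with rare genotype categories lumped below
an expected count of 5; correlation checks use 500 samples per
copy-number class, where the analytic value from the calibration table
(equal groups) is r ≈ 0.948. Residual comparisons round at 1e-12 before
tie-breaking; percents are validated to [0, 100] at construction.

## Known limitations

Only the 7-SNP panel's nine alleles are modelled — no full haplotype
catalogue, no hybrid tandem structures (*68+*4-like), no read-level
phasing. Pre-resolution enumeration assumes at most one amplified founder.
Activity values outside the shipped table require a user-supplied config.
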