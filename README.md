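# pyrostar

CYP2D6 star-allele diplotype calling from pyrosequencing
allele-quantification data, with allele-specific copy-number resolution and
CPIC phenotype prediction.

## The problem

CYP2D6 metabolizes a large share of commonly prescribed drugs, and its gene
is structurally unstable: whole-gene deletions (*5), duplications and
multiplications are common. More than two functional copies makes a patient
an ultrarapid metabolizer (UM); zero functional copies a poor metabolizer
(PM). Conventional copy-number assays (TaqMan-style qPCR) report *how many*
gene copies a sample carries but not *which* of the two inherited alleles is
duplicated — and for a heterozygote like `*1/*17` with 3 total copies the
phenotype depends exactly on that: `*1x2/*17` scores 2.5 (UM) while
`*1/*17x2` scores 2 (EM).

Pyrosequencing allele quantification measures the percentage of each
nucleotide at a polymorphic position. Because signal is proportional to
copy number, the variant-allele fraction at a heterozygous defining SNP
reveals the copy split: ~50% for 1:1, ~67% for 2:1, ~75% for 3:1.
Equivalently the allelic ratio (major/minor percentage quotient) sits near
1, 2 or 3. `pyrostar` implements the full interpretation pipeline behind
this assay design:

- **Dosage model** — for a candidate diplotype with per-allele copy counts,
  the expected variant fraction at panel SNP $s$ is
  $f_s = \frac{\sum_i c_i \, \mathbb{1}[i \text{ carries } s]}{\sum_i c_i}$
  over the two founder alleles with copy counts $c_i$.
- **Ratio classifier** — measured allelic ratios are binned against a
  calibration table (means 0.97 / 1.83 / 2.76 with SD 0.07 / 0.16 / 0.39
  for 2 / 3 / 4 copies) into 1:1, 2:1, 3:1 splits.
- **Diplotype caller** — exhaustive search over founder pairs (from the
  7-SNP panel's allele table: *1, *2, *3, *4, *5, *6, *10, *17, *41) and
  copy splits, minimizing the mean absolute deviation between observed and
  expected fractions; identifies the duplicated allele and flags the
  assay's blind spots (homozygous samples, *5 carriers, *10-vs-*36).
- **Phenotype engine** — CPIC activity score
  $\mathrm{AS} = \sum_i c_i \, a_i$ with $a_i \in \{0, 0.5, 1\}$, mapped to
  PM (0), IM (0.5), EM (1–2), UM (> 2).
- **Cohort statistics** — genotype/phenotype frequency tables, per-SNP
  Hardy-Weinberg χ² tests, one-way ANOVA + Tukey HSD of ratios by
  copy-number class, Pearson correlation of ratio vs copy number.
- **Simulator** — HWE-structured cohorts with truncated-Gaussian percent
  noise calibrated to the ratio dispersion above, so the pipeline is
  testable end to end without instrument data.

Intended users: pharmacogenomics labs running allele-quantification CNV
assays, and anyone studying dosage-based allele-specific CNV calling.

## Worked example

The canonical ambiguous case — a `*1/*17` genotype with 3 total gene
copies, where the assay reads 65.3% T / 34.7% C at the *17-defining site:

```python
import pyrostar as ps

snps = {"rs28371706": 65.3, "rs16947": 65.3}  # *17 carries both
calls = tuple(
    ps.SNPQuantCall(snp, 100 - snps.get(snp, 0.0), snps.get(snp, 0.0))
    for snp in ps.AlleleModel.default().panel
)
sample = ps.SampleInput("demo", calls, total_copies=3)

call = ps.call_diplotype(sample)
pheno = ps.phenotype_for_sample(call)
print(call.best.render(), call.duplicated_allele,
      pheno.activity_score, pheno.phenotype)
# *1/*17x2 *17 2.0 EM

before = ps.phenotype_before_resolution("*1", "*17", 3)
print(sorted(before.candidate_scores), before.phenotype_label())
# [2.0, 2.5] EM|UM
```

Without quantification the sample is "EM or UM" (score 2 or 2.5); the
65.3/34.7 split (allelic ratio 1.88, a 2:1 class) shows the *variant*
allele is duplicated, so the resolved call is `*1/*17x2`, activity score
2.0, EM — not UM. The same pipeline is available from the shell:

```bash
pyrostar simulate --n 100 --seed 7 --out sheet.tsv --truth truth.tsv
pyrostar call --in sheet.tsv --out calls.tsv
pyrostar cohort-stats --calls calls.tsv --out summary.json
pyrostar ratio 34.7 65.3
# {"ratio": 1.882, "copy_split": "2:1", "implied_total_copies": 3, "flags": []}
```

## Limitations

Inherited from the assay itself: homozygous samples and *5 carriers give a
~100% single-allele signal, so their copy number cannot be quantified from
allele percentages alone (an orthogonal total, e.g. ΔΔCT-derived, resolves
them); balanced 2:2 duplications look like 1:1; *36 is indistinguishable
from *10 on the shared 100C>T. See `docs/methods.md` for the model details
and design choices.
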