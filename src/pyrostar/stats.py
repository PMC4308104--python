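"""Cohort-level statistics: frequency tables, HWE, ANOVA/Tukey, Pearson.

Reproduces the analysis layer of the validation study: genotype and
metabolizer-phenotype frequency tables for a called cohort, per-SNP
Hardy-Weinberg chi-squared tests (df = 1), one-way ANOVA with Tukey HSD
post-hoc comparisons of allelic ratios across copy-number classes, and the
Pearson correlation of ratio against copy number.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .model import AlleleConfiguration, AlleleModel, PhenotypeCall, PHENOTYPES, default_model

__all__ = [
    "CohortSummary",
    "HWEResult",
    "RatioClassStats",
    "RatioStatsByCopies",
    "summarize_cohort",
    "hwe_chi2",
    "ratio_stats",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (so 3.65 -> 3.7, not banker's 3.6)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class HWEResult:
    chi2: float
    p: float
    monomorphic: bool = False


@dataclass(frozen=True)
class CohortSummary:
    n: int
    genotype_counts: Mapping[str, int]
    phenotype_frequencies: Mapping[str, tuple[int, float]]  # phenotype -> (count, %)
    n_homozygous: int
    n_deletion_carriers: int
    hwe_results: Mapping[str, HWEResult] = field(default_factory=dict)

    def genotype_percent(self, genotype: str, ndigits: int = 1) -> float:
        return round_half_up(100.0 * self.genotype_counts.get(genotype, 0) / self.n, ndigits)


def summarize_cohort(
    calls: Sequence[tuple],
    model: Optional[AlleleModel] = None,
    percent_ndigits: int = 1,
) -> CohortSummary:
    """Frequency summary of a phenotyped cohort.

    ``calls`` holds ``(configuration, phenotype_call)`` or
    ``(configuration, phenotype_call, population_label)`` tuples.  Ambiguous
    calls count under their resolved phenotype; calls without one are
    excluded with a warning.  HWE is computed per population label when
    labels are present, pooled otherwise; per-SNP genotype classes derive
    from founder variant content (copy number ignored, deletion founders
    count as non-carriers).
    """
    model = model or default_model()
    if not calls:
        raise ValueError("empty cohort")

    genotype_counts: Counter[str] = Counter()
    phenotype_counts: Counter[str] = Counter()
    n_hom = 0
    n_del = 0
    per_pop_geno: dict[Optional[str], list[AlleleConfiguration]] = {}
    n_used = 0
    for entry in calls:
        config, pheno = entry[0], entry[1]
        label = entry[2] if len(entry) > 2 else None
        if not isinstance(config, AlleleConfiguration) or not isinstance(pheno, PhenotypeCall):
            raise TypeError("expected (AlleleConfiguration, PhenotypeCall[, label]) tuples")
        if pheno.phenotype not in PHENOTYPES:
            warnings.warn(f"excluding unresolved call {config.render()}", stacklevel=2)
            continue
        n_used += 1
        genotype_counts[config.render()] += 1
        phenotype_counts[pheno.phenotype] += 1
        if config.is_homozygous:
            n_hom += 1
        if "*5" in config.founders:
            n_del += 1
        per_pop_geno.setdefault(label, []).append(config)

    if n_used == 0:
        raise ValueError("no resolvable calls in cohort")

    phenotype_frequencies = {
        ph: (
            phenotype_counts.get(ph, 0),
            round_half_up(100.0 * phenotype_counts.get(ph, 0) / n_used, percent_ndigits),
        )
        for ph in PHENOTYPES
    }

    # pooled HWE unless multiple labelled strata exist
    strata = per_pop_geno if len(per_pop_geno) > 1 else {None: sum(per_pop_geno.values(), [])}
    hwe: dict[str, HWEResult] = {}
    for snp_id in model.panel:
        for label, configs in strata.items():
            counts = _genotype_class_counts(configs, snp_id, model)
            key = snp_id if label is None else f"{snp_id}:{label}"
            hwe[key] = hwe_chi2(counts)

    return CohortSummary(
        n=n_used,
        genotype_counts=dict(genotype_counts),
        phenotype_frequencies=phenotype_frequencies,
        n_homozygous=n_hom,
        n_deletion_carriers=n_del,
        hwe_results=hwe,
    )


def _genotype_class_counts(
    configs: Sequence[AlleleConfiguration], snp_id: str, model: AlleleModel
) -> tuple[int, int, int]:
    n_rr = n_rv = n_vv = 0
    for config in configs:
        carriers = sum(
            snp_id in model.allele(name).variant_snps for name in config.founders
        )
        if carriers == 0:
            n_rr += 1
        elif carriers == 1:
            n_rv += 1
        else:
            n_vv += 1
    return n_rr, n_rv, n_vv


def hwe_chi2(counts: tuple[int, int, int]) -> HWEResult:
    """Pearson chi-squared test for Hardy-Weinberg equilibrium (df = 1).

    ``counts`` are (hom-ref, het, hom-var) genotype counts at one SNP.
    Expected counts come from the observed allele frequencies; monomorphic
    SNPs (one allele absent) return statistic 0, p 1 with a flag.
    """
    n_rr, n_rv, n_vv = counts
    n = n_rr + n_rv + n_vv
    if n <= 0:
        raise ValueError("no genotypes observed")
    p = (2 * n_rr + n_rv) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return HWEResult(0.0, 1.0, monomorphic=True)
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, expected))
    return HWEResult(chi2, float(sps.chi2.sf(chi2, df=1)))


@dataclass(frozen=True)
class RatioClassStats:
    n: int
    mean: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class RatioStatsByCopies:
    classes: Mapping[int, RatioClassStats]
    anova_f: Optional[float]
    anova_p: Optional[float]
    tukey_significant: Optional[Mapping[tuple[int, int], bool]]
    pearson_r: Optional[float]
    pearson_p: Optional[float]


def ratio_stats(groups: Mapping[int, Sequence[float]], alpha: float = 0.05) -> RatioStatsByCopies:
    """Descriptive + inferential statistics of allelic ratios by copy number.

    One-way ANOVA across classes, Tukey HSD pairwise comparisons at
    ``alpha``, and Pearson correlation between copy number and ratio over
    all samples.  With fewer than two classes of >= 2 observations only the
    descriptive block is filled.
    """
    if not groups:
        raise ValueError("no ratio groups supplied")
    classes = {}
    for copies in sorted(groups):
        vals = np.asarray(list(groups[copies]), dtype=float)
        if vals.size == 0:
            raise ValueError(f"empty ratio group for {copies} copies")
        classes[copies] = RatioClassStats(
            n=int(vals.size),
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            min=float(vals.min()),
            max=float(vals.max()),
        )

    testable = {c: np.asarray(list(v), dtype=float) for c, v in groups.items() if len(v) >= 2}
    anova_f = anova_p = pearson_r = pearson_p = None
    tukey = None
    if len(testable) >= 2:
        anova_f, anova_p = (float(x) for x in sps.f_oneway(*testable.values()))
        values = np.concatenate(list(testable.values()))
        labels = np.concatenate([np.full(len(v), c) for c, v in testable.items()])
        if all(np.ptp(v) > 0 for v in testable.values()):
            # Tukey pairs come back in combinations order over sorted groups
            res = pairwise_tukeyhsd(values, labels, alpha=alpha)
            pairs = list(itertools.combinations(sorted(testable), 2))
            tukey = {pair: bool(rej) for pair, rej in zip(pairs, res.reject)}
        if np.ptp(values) > 0 and np.ptp(labels) > 0:
            pearson_r, pearson_p = (float(x) for x in sps.pearsonr(labels, values))

    return RatioStatsByCopies(
        classes=classes,
        anova_f=anova_f,
        anova_p=anova_p,
        tukey_significant=tukey,
        pearson_r=pearson_r,
        pearson_p=pearson_p,
    )
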