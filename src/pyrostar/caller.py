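"""Diplotype calling: fit copy-weighted star-allele pairs to allele fractions.

The engine enumerates every founder pair from the allele table (including
*1 and the *5 deletion) and every copy split compatible with the candidate
total copy numbers, predicts the noiseless variant fraction at each panel
SNP with the dosage model, and scores each configuration by the mean
absolute deviation from the observed fractions.  The minimizer is the call;
configurations within a small residual margin are kept as alternatives and
the call is flagged ambiguous if they disagree on phenotype.

Candidate totals come from an orthogonal copy-number assay when supplied
(TaqMan-style; it wins on conflict) and otherwise from classifying the
allelic ratios at heterozygous SNPs.  Samples with no heterozygous SNP are
flagged ``homozygous_unquantifiable``: allele quantification reads ~100%
there whether the sample has one (*5 carrier), two, or four identical
copies, so only the orthogonal total can resolve them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .cnv import (
    DEFAULT_HOM_THRESHOLD,
    RatioBinTable,
    SNPQuantCall,
    allelic_ratio,
    classify_ratio,
    default_bins,
)
from .model import (
    AlleleConfiguration,
    AlleleModel,
    PhenotypeCall,
    activity_score,
    default_model,
    expected_variant_fraction,
    phenotype_from_score,
    star_number,
)

__all__ = [
    "SampleInput",
    "DiplotypeCall",
    "call_diplotype",
    "identify_duplicated_allele",
    "phenotype_for_sample",
    "phenotype_before_resolution",
    "enumerate_configurations",
    "NoCallError",
]

logger = logging.getLogger(__name__)

#: alternatives are configurations within this residual of the best fit
DEFAULT_ALTERNATIVE_MARGIN = 0.03
#: per-founder tandem copies considered by the search (x3 multiplication)
DEFAULT_MAX_COPIES = 3


class NoCallError(ValueError):
    """No configuration is feasible for the sample's candidate totals."""


@dataclass(frozen=True)
class SampleInput:
    """One sample's panel quantification plus optional orthogonal data."""

    sample_id: str
    quant_calls: tuple[SNPQuantCall, ...]
    total_copies: Optional[int] = None
    population_label: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "quant_calls", tuple(self.quant_calls))
        seen = set()
        for call in self.quant_calls:
            if call.snp_id in seen:
                raise ValueError(f"{self.sample_id}: duplicate quant call for {call.snp_id}")
            seen.add(call.snp_id)
        if self.total_copies is not None and self.total_copies < 1:
            raise ValueError(f"{self.sample_id}: total_copies must be >= 1")


@dataclass(frozen=True)
class DiplotypeCall:
    sample_id: str
    best: AlleleConfiguration
    residual: float
    duplicated_allele: Optional[str]
    alternatives: tuple[tuple[AlleleConfiguration, float], ...] = ()
    flags: frozenset[str] = field(default_factory=frozenset)


def enumerate_configurations(
    total: int,
    model: AlleleModel,
    max_copies: int = DEFAULT_MAX_COPIES,
) -> list[AlleleConfiguration]:
    """All founder pairs and copy splits with the given total gene copies.

    Deletion founders (*5) contribute 0 copies, so a *5-carrying pair needs
    the other founder to supply the whole total; non-deletion founders get
    1..max_copies copies each.
    """
    names = sorted(model.alleles, key=star_number)
    configs: list[AlleleConfiguration] = []
    for a, b in itertools.combinations_with_replacement(names, 2):
        del_a = model.allele(a).is_deletion
        del_b = model.allele(b).is_deletion
        if del_a and del_b:
            continue
        range_a = (0,) if del_a else tuple(range(1, max_copies + 1))
        range_b = (0,) if del_b else tuple(range(1, max_copies + 1))
        seen = set()
        for ca in range_a:
            cb = total - ca
            if cb not in range_b:
                continue
            cfg = AlleleConfiguration(a, ca, b, cb).canonical()
            if cfg not in seen:
                seen.add(cfg)
                configs.append(cfg)
    return configs


def _residual(
    config: AlleleConfiguration,
    observed: Sequence[SNPQuantCall],
    model: AlleleModel,
) -> float:
    dev = 0.0
    for call in observed:
        expected = expected_variant_fraction(config, call.snp_id, model)
        dev += abs(call.percent_var / 100.0 - expected)
    return dev / len(observed)


def _tiebreak_key(config: AlleleConfiguration, residual: float) -> tuple:
    """Parsimony ordering among near-equal fits.

    Prefer fewer distinct non-reference founders, then fewer total copies,
    then lower star numbers, then the more balanced copy split (so a
    homozygous total of 4 reads 2+2, not 3+1).
    """
    non_ref = len({n for n in config.founders if n != "*1"})
    stars = (star_number(config.allele_a), star_number(config.allele_b))
    return (
        round(residual, 12),
        non_ref,
        config.total_copies,
        stars,
        abs(config.copies_a - config.copies_b),
    )


def call_diplotype(
    sample: SampleInput,
    model: Optional[AlleleModel] = None,
    bins: Optional[RatioBinTable] = None,
    max_copies: int = DEFAULT_MAX_COPIES,
    alternative_margin: float = DEFAULT_ALTERNATIVE_MARGIN,
    hom_threshold: float = DEFAULT_HOM_THRESHOLD,
) -> DiplotypeCall:
    """Call the best-fitting diplotype-with-copy-number for one sample."""
    model = model or default_model()
    bins = bins or default_bins()
    if not sample.quant_calls:
        raise ValueError(f"{sample.sample_id}: no quantification calls supplied")

    observed = tuple(c.normalized() for c in sample.quant_calls)
    het = [c for c in observed if c.is_heterozygous(hom_threshold)]

    flags: set[str] = set()
    ratio_totals: set[int] = set()
    for call in het:
        ratio = allelic_ratio(call, hom_threshold)
        if ratio is None:
            continue
        rc = classify_ratio(ratio, bins)
        if rc.implied_total_copies is not None:
            ratio_totals.add(rc.implied_total_copies)

    if sample.total_copies is not None:
        totals = {sample.total_copies}
        if ratio_totals and sample.total_copies not in ratio_totals:
            logger.warning(
                "%s: orthogonal total %d conflicts with ratio-implied %s; using orthogonal",
                sample.sample_id,
                sample.total_copies,
                sorted(ratio_totals),
            )
            flags.add("copy_number_conflict")
    else:
        totals = {2} | ratio_totals

    if not het:
        flags.add("homozygous_unquantifiable")

    scored: list[tuple[tuple, AlleleConfiguration, float]] = []
    for total in sorted(totals):
        for config in enumerate_configurations(total, model, max_copies):
            res = _residual(config, observed, model)
            scored.append((_tiebreak_key(config, res), config, res))
    if not scored:
        raise NoCallError(
            f"{sample.sample_id}: no feasible configuration for totals {sorted(totals)} "
            f"with max_copies={max_copies}"
        )
    scored.sort(key=lambda t: t[0])
    _, best, best_res = scored[0]
    alternatives = tuple(
        (cfg, res)
        for _, cfg, res in scored[1:]
        if res <= best_res + alternative_margin
    )

    if "*5" in best.founders:
        flags.add("deletion_carrier")
    if "*10" in best.founders:
        flags.add("star10_or_36")
    if "homozygous_unquantifiable" in flags and best.is_homozygous and best.total_copies > 2:
        best = replace(best, homozygous_total=best.total_copies)

    duplicated = _duplicated_founder(best)
    if (
        not best.is_homozygous
        and best.copies_a > 1
        and best.copies_a == best.copies_b
    ):
        # a balanced 2:2 duplication looks exactly like 1:1 to the assay
        flags.add("ambiguous")

    best_pheno = phenotype_from_score(activity_score(best, model))
    for cfg, _ in alternatives:
        if phenotype_from_score(activity_score(cfg, model)) != best_pheno:
            flags.add("ambiguous")
            break

    return DiplotypeCall(
        sample_id=sample.sample_id,
        best=best,
        residual=best_res,
        duplicated_allele=duplicated,
        alternatives=alternatives,
        flags=frozenset(flags),
    )


def _duplicated_founder(config: AlleleConfiguration) -> Optional[str]:
    ca, cb = config.copies_a, config.copies_b
    if ca > 1 and cb > 1:
        if ca == cb:
            return None
        return config.allele_a if ca > cb else config.allele_b
    if ca > 1:
        return config.allele_a
    if cb > 1:
        return config.allele_b
    return None


def identify_duplicated_allele(call: DiplotypeCall) -> Optional[str]:
    """Founder carrying the duplication/multiplication, if any.

    ``None`` for 1:1 configurations and for balanced n:n duplications
    (those are flagged ambiguous by the caller — the assay cannot orient
    them).  Unusable for homozygous-unquantifiable samples.
    """
    if "homozygous_unquantifiable" in call.flags:
        raise ValueError(
            f"{call.sample_id}: no heterozygous signal; duplicated allele undefined"
        )
    return _duplicated_founder(call.best)


def phenotype_for_sample(
    call: DiplotypeCall, model: Optional[AlleleModel] = None
) -> PhenotypeCall:
    """Activity score and metabolizer phenotype for a resolved call.

    Candidates include every alternative configuration within the residual
    margin; the call is ambiguous when they disagree on phenotype.
    """
    model = model or default_model()
    score = activity_score(call.best, model)
    phen = phenotype_from_score(score)
    scores = {score} | {activity_score(cfg, model) for cfg, _ in call.alternatives}
    phens = {phenotype_from_score(s) for s in scores}
    return PhenotypeCall(
        activity_score=score,
        phenotype=phen,
        ambiguous=len(phens) > 1,
        candidate_phenotypes=frozenset(phens),
        candidate_scores=frozenset(scores),
    )


def phenotype_before_resolution(
    allele_a: str,
    allele_b: str,
    total_copies: int,
    model: Optional[AlleleModel] = None,
) -> PhenotypeCall:
    """Phenotype from genotype + total copy number only (no quantification).

    This is what a conventional copy-number assay yields: the genotype names
    the two founders, the total says how many copies exist, but not which
    founder is amplified.  Every single-founder amplification consistent
    with the total is enumerated (the extra copies sit on one chromosome;
    the other founder keeps one copy) and the call is ambiguous when the
    candidates disagree on phenotype.
    """
    model = model or default_model()
    for name in (allele_a, allele_b):
        model.allele(name)

    def score(ca: int, cb: int) -> float:
        return activity_score(AlleleConfiguration(allele_a, ca, allele_b, cb), model)

    del_a = model.allele(allele_a).is_deletion
    del_b = model.allele(allele_b).is_deletion
    if del_a or del_b:
        # deletion carrier: the non-deleted founder holds the whole total
        ca = 0 if del_a else total_copies
        cb = 0 if del_b else total_copies
        candidates = {score(ca, cb)}
    elif allele_a == allele_b:
        candidates = {score(total_copies - total_copies // 2, total_copies // 2)}
    elif total_copies <= 2:
        candidates = {score(1, 1)}
    else:
        extra = total_copies - 1
        candidates = {score(extra, 1), score(1, extra)}

    phens = {phenotype_from_score(s) for s in candidates}
    ambiguous = len(phens) > 1
    rep = min(candidates)
    return PhenotypeCall(
        activity_score=rep,
        phenotype=phenotype_from_score(rep),
        ambiguous=ambiguous,
        candidate_phenotypes=frozenset(phens),
        candidate_scores=frozenset(candidates),
    )
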