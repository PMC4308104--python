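"""Published reference tables used for validation and simulator defaults.

Three small tables accompany the assay this package models:

* ``COHORT_GENOTYPE_ROWS`` — the 218-sample hypertension-trial validation
  cohort: every called genotype with its sample count and the published
  activity score / phenotype columns.
* ``CORIELL_GENOTYPES`` — the 19 Coriell Cell Repository reference samples
  with known copy number used to validate the allele-quantification assay.
  ``(A/A)xN`` marks homozygous samples whose total is unresolved.
* ``DUPLICATION_PANEL`` — the CNV-carrying samples whose phenotype
  prediction changes once the duplicated allele is identified: genotype,
  total copies, count, the candidate phenotypes/scores available *before*
  allele quantification (single-founder amplification assumed), and the
  resolved phenotype/score *after*.

These are inputs for tests and for the acceptance computations, and the
source of the simulator's default allele frequencies.
"""

from __future__ import annotations

from collections import Counter
from fractions import Fraction

from .model import parse_diplotype_string

__all__ = [
    "COHORT_GENOTYPE_ROWS",
    "CORIELL_GENOTYPES",
    "DUPLICATION_PANEL",
    "cohort_allele_frequencies",
    "expand_cohort",
]

# (genotype, n, published activity score, published phenotype)
COHORT_GENOTYPE_ROWS: tuple[tuple[str, int, float, str], ...] = (
    ("*3/*4", 2, 0.0, "PM"),
    ("*4/*4", 7, 0.0, "PM"),
    ("*4/*5", 1, 0.0, "PM"),
    ("*4/*6", 1, 0.0, "PM"),
    ("*3/*17", 1, 0.5, "IM"),
    ("*4/*10", 2, 0.5, "IM"),
    ("*4/*17", 1, 0.5, "IM"),
    ("*4/*41", 7, 0.5, "IM"),
    ("*5/*10", 1, 0.5, "IM"),
    ("*5/*17", 3, 0.5, "IM"),
    ("*1/*1", 30, 2.0, "EM"),
    ("*1/*2", 41, 2.0, "EM"),
    ("*1/*3", 5, 1.0, "EM"),
    ("*1/*4", 16, 1.0, "EM"),
    ("*1/*5", 7, 1.0, "EM"),
    ("*1/*6", 2, 1.0, "EM"),
    ("*1/*10", 6, 1.5, "EM"),
    ("*1/*17", 6, 1.5, "EM"),
    ("*1/*41", 8, 1.5, "EM"),
    ("*1x2/*4", 2, 2.0, "EM"),
    ("*1/*10x2", 1, 2.0, "EM"),
    ("*1/*17x2", 1, 2.0, "EM"),
    ("*2/*2", 11, 2.0, "EM"),
    ("*2/*4", 18, 1.0, "EM"),
    ("*2/*4x3", 1, 1.0, "EM"),
    ("*2/*5", 6, 1.0, "EM"),
    ("*2/*10", 4, 1.5, "EM"),
    ("*2/*17", 5, 1.5, "EM"),
    ("*2/*41", 5, 1.5, "EM"),
    ("*10/*17", 2, 1.0, "EM"),
    ("*10x2/*41", 1, 1.5, "EM"),
    ("*17/*17", 3, 1.0, "EM"),
    ("*17/*41", 2, 1.0, "EM"),
    ("*41/*41", 1, 1.0, "EM"),
    ("*1/*1x2", 2, 3.0, "UM"),
    ("*1x2/*2", 2, 3.0, "UM"),
    ("*1/*2x2", 2, 3.0, "UM"),
    ("*2x2/*10", 1, 2.5, "UM"),
    ("*2x2/*2", 1, 3.0, "UM"),
)

# Coriell Cell Repository reference samples with known copy number.
CORIELL_GENOTYPES: tuple[tuple[str, str], ...] = (
    ("NA18564", "*1/*10x2"),
    ("NA18532", "(*10/*10)x4"),
    ("NA18545", "(*10/*10)x4"),
    ("NA18944", "(*10/*10)x4"),
    ("NA18960", "(*10/*10)x4"),
    ("NA18603", "(*10/*10)x4"),
    ("NA18561", "(*10/*10)x4"),
    ("NA18959", "*2/*10x2"),
    ("NA18537", "*1/*10x2"),
    ("NA18542", "*1/*10x2"),
    ("NA18524", "*1/*10x3"),
    ("NA18526", "*1/*10x3"),
    ("NA18563", "*1/*10x2"),
    ("NA18947", "*1/*10x2"),
    ("GM17221", "*1x2/*2"),
    ("GM02016", "*2x2/*17"),
    ("GM17298", "(*1/*1)xN"),
    ("GM17232", "(*2/*2)xN"),
    ("GM17244", "*2/*4"),
)

# (resolved genotype, total copies, n, before-phenotypes, before-scores,
#  after-phenotype, after-score).  "Before" = genotype + total copy number
# only; "after" = duplicated allele identified by quantification.
DUPLICATION_PANEL: tuple[
    tuple[str, int, int, frozenset[str], frozenset[float], str, float], ...
] = (
    ("*1/*5", 1, 1, frozenset({"EM"}), frozenset({1.0}), "EM", 1.0),
    ("*2/*5", 1, 1, frozenset({"EM"}), frozenset({1.0}), "EM", 1.0),
    ("*1/*2", 2, 3, frozenset({"EM"}), frozenset({2.0}), "EM", 2.0),
    ("*1/*4", 2, 1, frozenset({"EM"}), frozenset({1.0}), "EM", 1.0),
    ("*2/*4", 2, 1, frozenset({"EM"}), frozenset({1.0}), "EM", 1.0),
    ("*2/*10", 2, 2, frozenset({"EM"}), frozenset({1.5}), "EM", 1.5),
    ("(*1/*1)x3", 3, 1, frozenset({"UM"}), frozenset({3.0}), "UM", 3.0),
    ("(*2/*2)x3", 3, 1, frozenset({"UM"}), frozenset({3.0}), "UM", 3.0),
    ("*1/*2x2", 3, 6, frozenset({"UM"}), frozenset({3.0}), "UM", 3.0),
    ("*1/*17x2", 3, 1, frozenset({"EM", "UM"}), frozenset({2.0, 2.5}), "EM", 2.0),
    ("*2/*4x2", 3, 1, frozenset({"EM"}), frozenset({1.0, 2.0}), "EM", 1.0),
    ("*1x2/*4", 3, 1, frozenset({"EM"}), frozenset({1.0, 2.0}), "EM", 2.0),
    ("*2x2/*17", 3, 1, frozenset({"EM", "UM"}), frozenset({2.0, 2.5}), "UM", 2.5),
    ("*1/*10x2", 3, 5, frozenset({"EM", "UM"}), frozenset({2.0, 2.5}), "EM", 2.0),
    ("*2/*10x2", 3, 2, frozenset({"EM", "UM"}), frozenset({2.0, 2.5}), "EM", 2.0),
    ("*1/*10x3", 4, 3, frozenset({"UM"}), frozenset({2.5, 3.5}), "UM", 2.5),
    ("(*10/*10)x4", 4, 6, frozenset({"EM"}), frozenset({2.0}), "EM", 2.0),
)


def expand_cohort(rows=COHORT_GENOTYPE_ROWS):
    """Yield one parsed configuration per sample (row repeated n times)."""
    for genotype, n, _score, _phen in rows:
        config = parse_diplotype_string(genotype)
        for _ in range(n):
            yield config


def cohort_allele_frequencies() -> dict[str, float]:
    """Founder-allele frequencies implied by the validation cohort.

    Each of the 218 samples contributes two founder slots (436 total);
    copy counts do not weight the frequency — a duplicated founder is
    still one inherited allele.
    """
    counts: Counter[str] = Counter()
    for config in expand_cohort():
        counts[config.allele_a] += 1
        counts[config.allele_b] += 1
    total = sum(counts.values())
    freqs = {name: Fraction(c, total) for name, c in counts.items()}
    return {name: float(f) for name, f in sorted(freqs.items())}
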