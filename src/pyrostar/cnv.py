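"""Allelic-ratio copy-number quantification and ΔΔCT conversion.

At a heterozygous defining SNP the quotient of the two allele percentages
(major over minor) tracks the per-chromosome copy split: ~1 for 1:1 (two
gene copies), ~2 for 2:1 (three copies), ~3 for 3:1 (four copies).  The
classifier bins a measured ratio against a calibration table of per-class
mean/SD/min/max; the default calibration is the validation-study table
(0.97±0.07 [0.85, 1.06], 1.83±0.16 [1.6, 2.2], 2.76±0.39 [2.42, 3.2]).

A near-100% signal means the sample is effectively homozygous at that SNP
and carries no copy-number information there (this is also why *5 carriers
and homozygous multiplications are invisible to allele quantification).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import load_default_config

__all__ = [
    "SNPQuantCall",
    "RatioCall",
    "RatioBinTable",
    "RatioClassSpec",
    "allelic_ratio",
    "classify_ratio",
    "copies_from_ddct",
    "DEFAULT_HOM_THRESHOLD",
    "PERCENT_SUM_TOLERANCE",
]

#: minor-allele percent below which a call is treated as a homozygous signal
DEFAULT_HOM_THRESHOLD = 5.0
#: |percent_ref + percent_var - 100| allowed before normalization refuses
PERCENT_SUM_TOLERANCE = 2.0


@dataclass(frozen=True)
class SNPQuantCall:
    """Measured reference/variant percentages at one panel SNP."""

    snp_id: str
    percent_ref: float
    percent_var: float

    def __post_init__(self):
        for p in (self.percent_ref, self.percent_var):
            if not 0.0 <= p <= 100.0:
                raise ValueError(f"{self.snp_id}: percent {p} outside [0, 100]")

    @property
    def minor_percent(self) -> float:
        return min(self.percent_ref, self.percent_var)

    @property
    def major_percent(self) -> float:
        return max(self.percent_ref, self.percent_var)

    def normalized(self, tolerance: float = PERCENT_SUM_TOLERANCE) -> "SNPQuantCall":
        """Rescale so the pair sums to exactly 100 (within ``tolerance``)."""
        total = self.percent_ref + self.percent_var
        if abs(total - 100.0) > tolerance:
            raise ValueError(
                f"{self.snp_id}: percents sum to {total:.2f}, outside 100±{tolerance}"
            )
        scale = 100.0 / total
        return SNPQuantCall(self.snp_id, self.percent_ref * scale, self.percent_var * scale)

    def is_heterozygous(self, hom_threshold: float = DEFAULT_HOM_THRESHOLD) -> bool:
        return self.minor_percent >= hom_threshold


@dataclass(frozen=True)
class RatioClassSpec:
    """Calibration for one copy-number class (n:1 split)."""

    copies: int
    mean: float
    sd: float
    min: float
    max: float


@dataclass(frozen=True)
class RatioCall:
    """A classified allelic ratio."""

    ratio: Optional[float]
    copy_split: str  # "1:1", "2:1", "3:1" or "unclassified"
    implied_total_copies: Optional[int]
    flags: frozenset[str] = field(default_factory=frozenset)


class RatioBinTable:
    """Per-class calibration plus the derived decision boundaries.

    Boundaries between adjacent classes sit at the midpoints of the gaps
    between the calibrated class ranges; ratios above ``upper_bound`` are
    out of range.  The table is configurable so a lab can recalibrate.
    """

    def __init__(
        self,
        classes: Sequence[RatioClassSpec],
        upper_bound: float = 3.7,
        near_margin: float = 0.1,
    ):
        self.classes = tuple(sorted(classes, key=lambda c: c.copies))
        if len(self.classes) < 1:
            raise ValueError("need at least one calibration class")
        self.upper_bound = float(upper_bound)
        self.near_margin = float(near_margin)
        self.boundaries = tuple(
            (lo.max + hi.min) / 2.0 for lo, hi in zip(self.classes, self.classes[1:])
        )
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise ValueError("decision boundaries must be strictly increasing")
        if self.boundaries and self.upper_bound <= self.boundaries[-1]:
            raise ValueError("upper_bound must exceed the last class boundary")

    @classmethod
    def from_dict(cls, cfg) -> "RatioBinTable":
        return cls(
            classes=[RatioClassSpec(**row) for row in cfg["classes"]],
            upper_bound=cfg.get("upper_bound", 3.7),
            near_margin=cfg.get("near_margin", 0.1),
        )

    @classmethod
    def default(cls) -> "RatioBinTable":
        return cls.from_dict(load_default_config()["ratio_bins"])


_DEFAULT_BINS: Optional[RatioBinTable] = None


def default_bins() -> RatioBinTable:
    global _DEFAULT_BINS
    if _DEFAULT_BINS is None:
        _DEFAULT_BINS = RatioBinTable.default()
    return _DEFAULT_BINS


def allelic_ratio(
    call: SNPQuantCall,
    hom_threshold: float = DEFAULT_HOM_THRESHOLD,
    oriented: bool = False,
) -> Optional[float]:
    """Allelic ratio at one SNP, or ``None`` for a homozygous signal.

    By default returns the folded major/minor quotient (>= 1), which is
    what the classifier consumes.  ``oriented=True`` returns variant/ref
    instead, useful for reproducing calibration statistics where balanced
    heterozygotes average slightly below 1.
    """
    call = call.normalized()
    if call.minor_percent < hom_threshold:
        return None
    if oriented:
        return call.percent_var / call.percent_ref
    return call.major_percent / call.minor_percent


def classify_ratio(ratio: float, bins: Optional[RatioBinTable] = None) -> RatioCall:
    """Assign a copy split (1:1 / 2:1 / 3:1) to a measured allelic ratio.

    Oriented ratios below 1 are folded to their reciprocal first.  Flags:
    ``near_boundary`` within ``near_margin`` of a decision boundary,
    ``out_of_range`` above the acceptance bound (left unclassified).
    """
    bins = bins or default_bins()
    if not (isinstance(ratio, (int, float)) and math.isfinite(ratio)) or ratio <= 0:
        raise ValueError(f"allelic ratio must be a positive finite number, got {ratio!r}")
    folded = ratio if ratio >= 1.0 else 1.0 / ratio

    flags = set()
    if any(abs(folded - b) <= bins.near_margin for b in bins.boundaries):
        flags.add("near_boundary")
    if folded > bins.upper_bound:
        flags.add("out_of_range")
        return RatioCall(ratio, "unclassified", None, frozenset(flags))

    idx = sum(folded >= b for b in bins.boundaries)
    spec = bins.classes[idx]
    split = f"{spec.copies - 1}:1"
    return RatioCall(ratio, split, spec.copies, frozenset(flags))


def copies_from_ddct(
    ddct: float, reference_copies: int = 2, confidence_margin: float = 0.35
) -> tuple[float, int, bool]:
    """Comparative ΔΔCT to copy number: raw = reference × 2^(−ΔΔCT).

    Returns ``(raw, rounded, low_confidence)``; a raw value farther than
    ``confidence_margin`` from its nearest integer is flagged low
    confidence, mirroring how real-time-PCR callers report uncertain
    copy-number estimates.
    """
    if reference_copies < 1:
        raise ValueError("reference_copies must be >= 1")
    raw = reference_copies * 2.0 ** (-ddct)
    rounded = int(round(raw))
    low_confidence = abs(raw - rounded) > confidence_margin
    return raw, rounded, low_confidence
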