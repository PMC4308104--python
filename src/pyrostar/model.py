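"""Star-allele model: panel definition, haplotypes, activity scores, phenotypes.

CYP2D6 star alleles are named haplotypes (*1 reference, *2, *3, ... *41)
defined by characteristic variants; a diplotype is the pair of haplotypes a
sample carries, optionally with per-allele copy counts when the gene is
deleted (*5) or duplicated/multiplicated (e.g. ``*1/*17x2``).  The CPIC
activity-score system assigns each functional gene copy a value (1 normal,
0.5 reduced, 0 none); the sum over all copies maps to a metabolizer
phenotype: poor (PM), intermediate (IM), extensive (EM) or ultrarapid (UM).

The default panel covers the seven SNPs that key the *2, *3, *4, *6, *10,
*17 and *41 haplotypes.  Haplotype content within the panel follows the
standard CYP2D6 nomenclature: *17 also carries 2850C>T and *41 is 2850C>T
plus 2988G>A, which is what lets a dosage model distinguish *1/*41 from a
*2-containing diplotype.  *36 shares 100C>T with *10 and cannot be
discriminated by this panel; *10 calls therefore mean "*10 or *36".
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Optional

import yaml

__all__ = [
    "PanelSNP",
    "StarAllele",
    "AlleleModel",
    "AlleleConfiguration",
    "PhenotypeCall",
    "DefinitionError",
    "DiplotypeParseError",
    "PHENOTYPES",
    "activity_score",
    "phenotype_from_score",
    "expected_variant_fraction",
    "parse_diplotype_string",
    "star_number",
]

PHENOTYPES = ("PM", "IM", "EM", "UM")

#: calls flagged "*10" may be *36; the panel cannot discriminate them
STAR10_OR_36_NOTE = "*10-or-*36"


class DefinitionError(KeyError):
    """An allele or SNP name is not in the model tables."""


class DiplotypeParseError(ValueError):
    """A star-nomenclature string does not match the accepted grammar."""

    def __init__(self, message: str, text: str, position: int):
        super().__init__(f"{message} in {text!r} at position {position}")
        self.text = text
        self.position = position


@dataclass(frozen=True)
class PanelSNP:
    """One assayed polymorphic position.

    ``var_base`` is ``-`` for single-base deletions (2549delA, 1707delT).
    """

    snp_id: str
    label: str
    ref_base: str
    var_base: str

    def __post_init__(self):
        if self.ref_base == self.var_base:
            raise ValueError(f"{self.snp_id}: ref and var base identical")


@dataclass(frozen=True)
class StarAllele:
    """A named haplotype with its panel-variant content and CPIC activity."""

    name: str
    variant_snps: frozenset[str]
    activity: float
    is_deletion: bool = False

    def __post_init__(self):
        if self.is_deletion and self.variant_snps:
            raise ValueError(f"{self.name}: a whole-gene deletion carries no panel variants")


def star_number(name: str) -> int:
    """Numeric part of a star name, for canonical ordering (*2 < *10)."""
    m = re.fullmatch(r"\*(\d+)", name)
    if m is None:
        raise DefinitionError(f"not a star-allele name: {name!r}")
    return int(m.group(1))


class AlleleModel:
    """Panel + haplotype + activity tables, loadable from YAML."""

    def __init__(self, panel: Iterable[PanelSNP], alleles: Iterable[StarAllele]):
        self.panel: dict[str, PanelSNP] = {}
        for snp in panel:
            if snp.snp_id in self.panel:
                raise ValueError(f"duplicate panel SNP {snp.snp_id}")
            self.panel[snp.snp_id] = snp
        self.alleles: dict[str, StarAllele] = {a.name: a for a in alleles}
        for allele in self.alleles.values():
            unknown = allele.variant_snps - self.panel.keys()
            if unknown:
                raise ValueError(f"{allele.name} references unknown SNPs {sorted(unknown)}")

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "AlleleModel":
        panel = [PanelSNP(**row) for row in cfg["panel"]]
        alleles = [
            StarAllele(
                name=name,
                variant_snps=frozenset(spec.get("variant_snps", [])),
                activity=float(spec["activity"]),
                is_deletion=bool(spec.get("is_deletion", False)),
            )
            for name, spec in cfg["alleles"].items()
        ]
        return cls(panel, alleles)

    @classmethod
    def from_yaml(cls, path) -> "AlleleModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "AlleleModel":
        return cls.from_dict(load_default_config())

    def allele(self, name: str) -> StarAllele:
        try:
            return self.alleles[name]
        except KeyError:
            raise DefinitionError(
                f"unknown star allele {name!r}; model defines {sorted(self.alleles)}"
            ) from None


_DEFAULT_CONFIG_CACHE: Optional[dict] = None


def load_default_config() -> dict:
    """Parsed contents of the packaged default model YAML (cached)."""
    global _DEFAULT_CONFIG_CACHE
    if _DEFAULT_CONFIG_CACHE is None:
        text = resources.files("pyrostar.data").joinpath("default_model.yaml").read_text()
        _DEFAULT_CONFIG_CACHE = yaml.safe_load(text)
    return _DEFAULT_CONFIG_CACHE


_DEFAULT_MODEL: Optional[AlleleModel] = None


def default_model() -> AlleleModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = AlleleModel.default()
    return _DEFAULT_MODEL


@dataclass(frozen=True)
class AlleleConfiguration:
    """An ordered founder pair with per-allele copy counts.

    ``copies_*`` count sequence-contributing gene copies; a *5 (whole-gene
    deletion) founder always has 0.  ``homozygous_total`` marks the
    "(A/A)xN" notation for homozygous samples whose total copy number comes
    from an orthogonal assay and whose per-chromosome split is unresolved;
    ``None`` total means the N itself is unknown ("(A/A)xN" literally).
    """

    allele_a: str
    copies_a: int
    allele_b: str
    copies_b: int
    homozygous_total: Optional[int] = None
    unresolved_total: bool = False

    def __post_init__(self):
        if self.copies_a < 0 or self.copies_b < 0:
            raise ValueError("copy counts must be non-negative")
        if self.copies_a + self.copies_b < 1:
            raise ValueError("a configuration needs at least one gene copy")
        if self.unresolved_total and self.allele_a != self.allele_b:
            raise ValueError("unresolved xN totals only apply to homozygous pairs")

    # -- derived views ---------------------------------------------------
    @property
    def total_copies(self) -> int:
        return self.copies_a + self.copies_b

    @property
    def founders(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)

    @property
    def is_homozygous(self) -> bool:
        return self.allele_a == self.allele_b

    def copies_of(self, name: str) -> int:
        return (self.copies_a if self.allele_a == name else 0) + (
            self.copies_b if self.allele_b == name else 0
        )

    def canonical(self) -> "AlleleConfiguration":
        """Sort sides by (star number, copies) so rendering is unique."""
        a = (star_number(self.allele_a), self.copies_a, self.allele_a)
        b = (star_number(self.allele_b), self.copies_b, self.allele_b)
        if a <= b:
            return self
        return replace(
            self,
            allele_a=self.allele_b,
            copies_a=self.copies_b,
            allele_b=self.allele_a,
            copies_b=self.copies_a,
        )

    def render(self) -> str:
        c = self.canonical()
        if c.homozygous_total is not None or c.unresolved_total:
            n = "N" if c.unresolved_total else str(c.homozygous_total)
            return f"({c.allele_a}/{c.allele_b})x{n}"

        def side(name: str, copies: int) -> str:
            if copies <= 1:  # *5 renders bare: its 0 copies are implied
                return name
            return f"{name}x{copies}"

        return f"{side(c.allele_a, c.copies_a)}/{side(c.allele_b, c.copies_b)}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class PhenotypeCall:
    """Activity score + metabolizer phenotype, with ambiguity annotations.

    When the duplicated allele cannot be assigned (genotype plus a total
    copy number only), ``candidate_scores``/``candidate_phenotypes`` hold
    every assignment possibility and ``ambiguous`` is set whenever the
    candidates disagree on phenotype.
    """

    activity_score: float
    phenotype: str
    ambiguous: bool = False
    candidate_phenotypes: frozenset[str] = field(default_factory=frozenset)
    candidate_scores: frozenset[float] = field(default_factory=frozenset)

    def phenotype_label(self) -> str:
        """``EM`` or, for ambiguous calls, the sorted ``EM|UM`` form."""
        if self.ambiguous and self.candidate_phenotypes:
            return "|".join(sorted(self.candidate_phenotypes, key=PHENOTYPES.index))
        return self.phenotype


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def activity_score(config: AlleleConfiguration, model: Optional[AlleleModel] = None) -> float:
    """CPIC activity score: sum of per-copy activity over all gene copies."""
    model = model or default_model()
    score = 0.0
    for name, copies in ((config.allele_a, config.copies_a), (config.allele_b, config.copies_b)):
        allele = model.allele(name)
        if allele.is_deletion and copies != 0:
            raise ValueError(f"{name} is a deletion and cannot contribute {copies} copies")
        score += copies * allele.activity
    return score


def phenotype_from_score(score: float) -> str:
    """Map an activity score to PM / IM / EM / UM.

    Bin edges: 0 -> PM, 0.5 -> IM, 1..2 inclusive -> EM, above 2 -> UM
    (score exactly 2 is EM; the EM/UM cut-off is strictly greater than 2).
    """
    if score < 0:
        raise ValueError(f"activity score must be non-negative, got {score}")
    if not math.isclose(score * 2, round(score * 2), abs_tol=1e-9):
        raise ValueError(f"activity score must be a multiple of 0.5, got {score}")
    if score == 0:
        return "PM"
    if score <= 0.5:
        return "IM"
    if score <= 2:
        return "EM"
    return "UM"


def expected_variant_fraction(
    config: AlleleConfiguration, snp_id: str, model: Optional[AlleleModel] = None
) -> float:
    """Noiseless variant-allele fraction the assay would read at one SNP.

    With per-copy signal, the variant percentage at a defining position is
    proportional to how many gene copies carry the variant: (copies carrying
    variant) / (total sequence-contributing copies).  Deletion founders
    contribute nothing; a configuration with zero contributing copies has no
    signal at all and raises.
    """
    model = model or default_model()
    if snp_id not in model.panel:
        raise DefinitionError(f"unknown panel SNP {snp_id!r}")
    total = 0
    variant = 0
    for name, copies in ((config.allele_a, config.copies_a), (config.allele_b, config.copies_b)):
        allele = model.allele(name)
        if allele.is_deletion:
            continue
        total += copies
        if snp_id in allele.variant_snps:
            variant += copies
    if total == 0:
        raise ValueError(f"{config.render()} has no sequence-contributing copies: signal undefined")
    return variant / total


_SIDE_RE = re.compile(r"(\*\d+)(?:[x×](\d+))?")
_BUNDLE_RE = re.compile(r"\((\*\d+)/(\*\d+)\)[x×](\d+|N)")


def parse_diplotype_string(text: str, model: Optional[AlleleModel] = None) -> AlleleConfiguration:
    """Parse star nomenclature (``*1/*17x2``, ``*1x2/*4``, ``(*10/*10)x4``).

    The parenthesised form marks a homozygous sample whose total copy
    number N came from an orthogonal assay (the allele-quantification signal
    cannot split it); ``(A/A)xN`` with a literal N means even the total is
    unknown.  Both '×' and 'x' are accepted.  Returns the canonical
    configuration; ``render(parse(text))`` is idempotent.
    """
    model = model or default_model()
    s = text.strip()
    if s.startswith("("):
        m = _BUNDLE_RE.fullmatch(s)
        if m is None:
            raise DiplotypeParseError("malformed homozygous-bundle notation", text, 0)
        a, b, n = m.groups()
        if a != b:
            raise DiplotypeParseError("bundle notation requires identical alleles", text, 1)
        model.allele(a)
        if n == "N":
            return AlleleConfiguration(a, 1, b, 1, unresolved_total=True).canonical()
        total = int(n)
        if total < 2:
            raise DiplotypeParseError("bundle total must be >= 2", text, s.index("x") + 1)
        return AlleleConfiguration(
            a, total - total // 2, b, total // 2, homozygous_total=total
        ).canonical()

    parts = s.split("/")
    if len(parts) != 2:
        raise DiplotypeParseError("expected exactly one '/'", text, len(s))

    def parse_side(part: str, offset: int) -> tuple[str, int]:
        m = _SIDE_RE.fullmatch(part)
        if m is None:
            raise DiplotypeParseError("malformed allele term", text, offset)
        name, mult = m.group(1), m.group(2)
        allele = model.allele(name)
        copies = int(mult) if mult else 1
        if mult is not None and copies < 2:
            raise DiplotypeParseError("explicit multiplier must be >= 2", text, offset)
        if allele.is_deletion:
            if mult is not None:
                raise DiplotypeParseError("*5 cannot carry a multiplier", text, offset)
            copies = 0
        return name, copies

    a, ca = parse_side(parts[0], 0)
    b, cb = parse_side(parts[1], len(parts[0]) + 1)
    return AlleleConfiguration(a, ca, b, cb).canonical()
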