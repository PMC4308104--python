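"""Synthetic cohort generation with the assay's noise structure.

The generator draws founder pairs under Hardy-Weinberg equilibrium from a
star-allele frequency map (defaults: the validation-cohort frequencies),
applies per-founder duplication/multiplication, and then emulates the two
measurements the caller consumes:

* allele-quantification percentages — the noiseless variant fraction from
  the dosage model plus truncated Gaussian noise in percentage points
  (default SD 2.0, chosen so the induced allelic-ratio dispersion brackets
  the published per-class calibration SDs 0.07/0.16/0.39);
* an orthogonal total copy number — the true total plus Gaussian noise on
  the raw scale (default SD 0.15), rounded like a ΔΔCT-based caller.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .caller import SampleInput
from .cnv import SNPQuantCall
from .datasets import cohort_allele_frequencies
from .model import AlleleConfiguration, AlleleModel, default_model, expected_variant_fraction

__all__ = ["SimulationConfig", "simulate_sample", "simulate_cohort", "sample_calibrated_ratios"]


def _default_frequencies() -> dict[str, float]:
    return cohort_allele_frequencies()


@dataclass
class SimulationConfig:
    """Cohort-generation parameters.

    ``duplication_rate``/``multiplication_rate`` are per-founder
    probabilities of carrying 2 resp. 3 tandem copies (mutually exclusive;
    defaults are the validation-cohort founder rates).  Deletions enter via
    the *5 frequency.
    """

    allele_frequencies: Mapping[str, float] = field(default_factory=_default_frequencies)
    duplication_rate: float = 0.03
    multiplication_rate: float = 0.002
    percent_noise_sd: float = 2.0
    taqman_raw_sd: float = 0.15
    n_samples: int = 218
    seed: int = 0

    def __post_init__(self):
        total = sum(self.allele_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies sum to {total}, not 1")
        for rate in (self.duplication_rate, self.multiplication_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.duplication_rate + self.multiplication_rate > 1.0:
            raise ValueError("duplication + multiplication rate exceeds 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def simulate_sample(
    truth: AlleleConfiguration,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str = "sim",
    model: Optional[AlleleModel] = None,
    with_total: bool = True,
) -> SampleInput:
    """Noisy panel quantification (and orthogonal total) for a known truth."""
    model = model or default_model()
    calls = []
    for snp_id in model.panel:
        frac = expected_variant_fraction(truth, snp_id, model)
        percent_var = 100.0 * frac + rng.normal(0.0, cfg.percent_noise_sd)
        percent_var = float(np.clip(percent_var, 0.0, 100.0))
        calls.append(SNPQuantCall(snp_id, 100.0 - percent_var, percent_var))
    total = None
    if with_total:
        raw = truth.total_copies + rng.normal(0.0, cfg.taqman_raw_sd)
        total = max(1, int(round(raw)))
    return SampleInput(
        sample_id=sample_id,
        quant_calls=tuple(calls),
        total_copies=total,
    )


def simulate_cohort(
    cfg: SimulationConfig,
    model: Optional[AlleleModel] = None,
    with_total: bool = True,
) -> list[tuple[SampleInput, AlleleConfiguration]]:
    """HWE cohort with hidden truths, for recovery scoring.

    Founder pairs are drawn independently from ``allele_frequencies``
    (Hardy-Weinberg random mating); each non-deletion founder is then
    duplicated or multiplicated with the configured rates.  The degenerate
    *5/*5 pair (no gene at all, nothing to assay) is redrawn.
    """
    model = model or default_model()
    names = sorted(cfg.allele_frequencies)
    probs = np.array([cfg.allele_frequencies[n] for n in names])
    if len(names) == 0:
        raise ValueError("empty allele frequency map")
    for name in names:
        model.allele(name)
    rng = np.random.default_rng(cfg.seed)

    def draw_copies(name: str) -> int:
        if model.allele(name).is_deletion:
            return 0
        u = rng.uniform()
        if u < cfg.multiplication_rate:
            return 3
        if u < cfg.multiplication_rate + cfg.duplication_rate:
            return 2
        return 1

    out = []
    i = 0
    while len(out) < cfg.n_samples:
        a, b = rng.choice(names, size=2, p=probs)
        if model.allele(a).is_deletion and model.allele(b).is_deletion:
            continue
        truth = AlleleConfiguration(a, draw_copies(a), b, draw_copies(b)).canonical()
        sample = simulate_sample(
            truth, cfg, rng, sample_id=f"sim{i:05d}", model=model, with_total=with_total
        )
        out.append((sample, truth))
        i += 1
    return out


def sample_calibrated_ratios(
    bins,
    n_per_class: int,
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Draw allelic ratios directly from a per-class Gaussian calibration.

    Useful for studying the ratio/copy-number relationship at the
    published dispersion without going through percent-space noise.
    """
    return {
        spec.copies: rng.normal(spec.mean, spec.sd, size=n_per_class)
        for spec in bins.classes
    }
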