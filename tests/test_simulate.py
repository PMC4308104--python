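"""Simulator: determinism, forward-model exactness, HWE structure,
and noise calibration against the published ratio dispersion."""

import numpy as np
import pytest
from scipy import stats as sps

from pyrostar import (
    SimulationConfig,
    activity_score,
    allelic_ratio,
    call_diplotype,
    parse_diplotype_string,
    phenotype_for_sample,
    sample_calibrated_ratios,
    simulate_cohort,
    simulate_sample,
)
from pyrostar.datasets import cohort_allele_frequencies


def test_same_seed_bit_identical_cohort():
    cfg = SimulationConfig(n_samples=25, seed=42)
    a = simulate_cohort(cfg)
    b = simulate_cohort(cfg)
    assert [(s.quant_calls, s.total_copies, t) for s, t in a] == [
        (s.quant_calls, s.total_copies, t) for s, t in b
    ]


def test_noiseless_forward_model_exact():
    cfg = SimulationConfig(percent_noise_sd=0.0, taqman_raw_sd=0.0)
    rng = np.random.default_rng(0)
    truth = parse_diplotype_string("*1/*2")
    sample = simulate_sample(truth, cfg, rng)
    by_snp = {c.snp_id: c.percent_var for c in sample.quant_calls}
    assert by_snp["rs16947"] == pytest.approx(50.0)
    assert sample.total_copies == 2

    truth = parse_diplotype_string("*1/*17x2")
    sample = simulate_sample(truth, cfg, rng)
    by_snp = {c.snp_id: c.percent_var for c in sample.quant_calls}
    assert by_snp["rs28371706"] == pytest.approx(200 / 3)
    assert by_snp["rs16947"] == pytest.approx(200 / 3)


def test_noiseless_simulate_call_round_trip_identity():
    """sd 0 simulation followed by calling recovers phenotype and
    duplicated allele for heterozygous configurations."""
    cfg = SimulationConfig(percent_noise_sd=0.0, taqman_raw_sd=0.0)
    rng = np.random.default_rng(0)
    for genotype in ("*1/*41", "*2/*10x2", "*1x2/*4", "*17/*41", "*4/*10"):
        truth = parse_diplotype_string(genotype)
        call = call_diplotype(simulate_sample(truth, cfg, rng))
        assert call.best == truth
        assert phenotype_for_sample(call).activity_score == activity_score(truth)
        assert call.residual == pytest.approx(0.0, abs=1e-12)


def test_degenerate_frequency_map_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(allele_frequencies={"*1": 0.7})


def test_monomorphic_cohort_all_homozygous_flagged():
    cfg = SimulationConfig(
        allele_frequencies={"*1": 1.0},
        duplication_rate=0.0,
        multiplication_rate=0.0,
        percent_noise_sd=0.0,  # finite noise can fake a low-level het signal
        n_samples=20,
        seed=3,
    )
    for sample, truth in simulate_cohort(cfg):
        assert truth.render() == "*1/*1"
        call = call_diplotype(sample)
        assert "homozygous_unquantifiable" in call.flags


def test_deletion_carrier_fraction_matches_hwe():
    freqs = dict(cohort_allele_frequencies())
    # rescale to put exactly 5% on *5
    scale = (1 - 0.05) / (1 - freqs["*5"])
    freqs = {k: v * scale for k, v in freqs.items()}
    freqs["*5"] = 0.05
    cfg = SimulationConfig(allele_frequencies=freqs, n_samples=4000, seed=9)
    carriers = sum("*5" in t.founders for _, t in simulate_cohort(cfg))
    expected = 2 * 0.05 * 0.95 + 0.05**2  # 9.75% under HWE
    assert carriers / 4000 == pytest.approx(expected, abs=0.015)


def test_cohort_genotypes_converge_to_hwe():
    """Founder-pair frequencies in a large simulated cohort fit the
    p^2 / 2pq / q^2 expectations (chi-squared GOF, alpha = 0.01)."""
    cfg = SimulationConfig(
        n_samples=10_000, seed=13, duplication_rate=0.0, multiplication_rate=0.0,
        percent_noise_sd=0.0, taqman_raw_sd=0.0,
    )
    pairs = simulate_cohort(cfg, with_total=False)
    names = sorted(cfg.allele_frequencies)
    freq = cfg.allele_frequencies
    observed = {}
    for _, truth in pairs:
        key = tuple(sorted(truth.founders))
        observed[key] = observed.get(key, 0) + 1
    # *5/*5 is redrawn by the generator; renormalize expectations over the rest
    expected = {}
    for i, a in enumerate(names):
        for b in names[i:]:
            if a == b == "*5":
                continue
            p = freq[a] * freq[b] * (1 if a == b else 2)
            expected[tuple(sorted((a, b)))] = p
    norm = sum(expected.values())
    expected = {k: v / norm * len(pairs) for k, v in expected.items()}
    # lump rare categories (expected < 5) to keep the chi-squared valid
    obs_l, exp_l, rare_o, rare_e = [], [], 0.0, 0.0
    for key, e in expected.items():
        o = observed.get(key, 0)
        if e >= 5:
            obs_l.append(o)
            exp_l.append(e)
        else:
            rare_o += o
            rare_e += e
    if rare_e > 0:
        obs_l.append(rare_o)
        exp_l.append(rare_e)
    exp_l = np.array(exp_l) * (sum(obs_l) / sum(exp_l))
    stat, p = sps.chisquare(obs_l, exp_l)
    assert p > 0.01


def test_percent_noise_induces_published_ratio_dispersion():
    """Delta method: sd 2.0 points at a 2/3 variant fraction gives ratio
    SD ~ 0.18, bracketing the published 3-copy calibration SD of 0.16."""
    cfg = SimulationConfig(percent_noise_sd=2.0)
    rng = np.random.default_rng(99)
    truth = parse_diplotype_string("*1/*17x2")
    ratios = []
    for _ in range(10_000):
        sample = simulate_sample(truth, cfg, rng, with_total=False)
        call = {c.snp_id: c for c in sample.quant_calls}["rs28371706"]
        r = allelic_ratio(call)
        if r is not None:
            ratios.append(r)
    sd = float(np.std(ratios, ddof=1))
    assert sd == pytest.approx(0.18, abs=0.03)


def test_calibrated_ratio_sampler_matches_spec(bins):
    rng = np.random.default_rng(5)
    groups = sample_calibrated_ratios(bins, 2000, rng)
    for spec in bins.classes:
        assert float(np.mean(groups[spec.copies])) == pytest.approx(spec.mean, abs=0.02)
        assert float(np.std(groups[spec.copies], ddof=1)) == pytest.approx(spec.sd, abs=0.02)
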