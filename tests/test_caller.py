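"""Diplotype-calling engine: worked examples, duplicated-allele logic,
pre-resolution ambiguity, and equivalence with a naive exhaustive oracle."""

import itertools

import numpy as np
import pytest

from pyrostar import (
    SampleInput,
    SNPQuantCall,
    call_diplotype,
    identify_duplicated_allele,
    phenotype_before_resolution,
    phenotype_for_sample,
)
from pyrostar.caller import enumerate_configurations

PANEL = (
    "rs16947",
    "rs35742686",
    "rs3892097",
    "rs5030655",
    "rs1065852",
    "rs28371706",
    "rs28371725",
)


class TestCallDiplotype:
    def test_balanced_heterozygote(self, noiseless_sample):
        call = call_diplotype(noiseless_sample("*1/*2"))
        assert call.best.render() == "*1/*2"
        assert call.duplicated_allele is None
        assert call.residual == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_variant_allele_from_worked_example(self, model):
        # the published 65.3/34.7 split at the *17 site, total 3 copies
        calls = []
        for snp_id in PANEL:
            if snp_id in ("rs28371706", "rs16947"):  # *17 carries both
                calls.append(SNPQuantCall(snp_id, 34.7, 65.3))
            else:
                calls.append(SNPQuantCall(snp_id, 100.0, 0.0))
        call = call_diplotype(SampleInput("ex", tuple(calls), total_copies=3))
        assert call.best.render() == "*1/*17x2"
        assert identify_duplicated_allele(call) == "*17"
        pheno = phenotype_for_sample(call)
        assert (pheno.activity_score, pheno.phenotype) == (2.0, "EM")

    def test_homozygous_multiplication_needs_orthogonal_total(self, noiseless_sample):
        call = call_diplotype(noiseless_sample("(*10/*10)x4"))
        assert "homozygous_unquantifiable" in call.flags
        assert call.best.render() == "(*10/*10)x4"
        assert phenotype_for_sample(call).activity_score == 2.0
        with pytest.raises(ValueError):
            identify_duplicated_allele(call)

    def test_deletion_carrier(self, noiseless_sample):
        call = call_diplotype(noiseless_sample("*1/*5"))
        assert call.best.render() == "*1/*5"
        assert "deletion_carrier" in call.flags
        assert phenotype_for_sample(call).activity_score == 1.0

    def test_shared_100ct_resolved_by_joint_dosage(self, noiseless_sample):
        # *4 explains matched 100C>T and 1846G>A; excess 100T implies *10
        call = call_diplotype(noiseless_sample("*4/*10"))
        assert call.best.render() == "*4/*10"
        assert "star10_or_36" in call.flags

    def test_total_copies_without_quantification_candidates(self, noiseless_sample):
        # no orthogonal total: candidate totals come from het-SNP ratios
        base = noiseless_sample("*1/*17x2")
        sample = SampleInput(base.sample_id, base.quant_calls, total_copies=None)
        call = call_diplotype(sample)
        assert call.best.render() == "*1/*17x2"

    def test_orthogonal_total_wins_on_conflict(self, noiseless_sample):
        # ratio says 3 copies but the orthogonal assay insists on 2
        sample = noiseless_sample("*1/*17x2", total_copies=2)
        call = call_diplotype(sample)
        assert call.best.total_copies == 2
        assert "copy_number_conflict" in call.flags

    def test_balanced_2_2_duplication_flagged_ambiguous(self, noiseless_sample):
        call = call_diplotype(noiseless_sample("*1x2/*2x2", total_copies=4))
        assert call.best.render() == "*1x2/*2x2"
        assert "ambiguous" in call.flags
        assert identify_duplicated_allele(call) is None

    def test_empty_quant_calls_rejected(self):
        with pytest.raises(ValueError):
            call_diplotype(SampleInput("x", ()))


class TestDuplicatedAllele:
    @pytest.mark.parametrize(
        "genotype, duplicated",
        [("*1/*17x2", "*17"), ("*1/*2", None), ("*2x2/*10", "*2"), ("*2/*4x3", "*4")],
    )
    def test_identification(self, genotype, duplicated, noiseless_sample):
        call = call_diplotype(noiseless_sample(genotype))
        assert identify_duplicated_allele(call) == duplicated


class TestPhenotypeBeforeResolution:
    def test_ambiguous_em_or_um(self):
        pheno = phenotype_before_resolution("*1", "*17", 3)
        assert pheno.ambiguous
        assert pheno.candidate_phenotypes == {"EM", "UM"}
        assert pheno.candidate_scores == {2.0, 2.5}
        assert pheno.phenotype_label() == "EM|UM"

    def test_unambiguous_duplication(self):
        pheno = phenotype_before_resolution("*1", "*2", 3)
        assert not pheno.ambiguous
        assert pheno.candidate_scores == {3.0}

    def test_score_ambiguity_without_phenotype_ambiguity(self):
        # both assignments are EM even though the scores differ
        pheno = phenotype_before_resolution("*2", "*4", 3)
        assert not pheno.ambiguous
        assert pheno.candidate_scores == {1.0, 2.0}

    def test_four_copy_heterozygote(self):
        pheno = phenotype_before_resolution("*1", "*10", 4)
        assert pheno.candidate_scores == {2.5, 3.5}
        assert pheno.candidate_phenotypes == {"UM"}

    def test_deletion_carrier_total_is_one_founder(self):
        pheno = phenotype_before_resolution("*2", "*5", 1)
        assert pheno.candidate_scores == {1.0}


# ---------------------------------------------------------------------------
# Independent oracle: naive exhaustive enumeration with its own variant table
# ---------------------------------------------------------------------------

ORACLE_VARIANTS = {
    "*1": set(),
    "*2": {"rs16947"},
    "*3": {"rs35742686"},
    "*4": {"rs1065852", "rs3892097"},
    "*5": None,  # deletion: no sequence contribution
    "*6": {"rs5030655"},
    "*10": {"rs1065852"},
    "*17": {"rs28371706", "rs16947"},
    "*41": {"rs16947", "rs28371725"},
}


def oracle_best(observed_fracs: dict, total: int):
    """Brute-force minimizer over every pair/split, independent of the
    production search: returns (min residual, set of argmin configs)."""
    best_res = None
    argmin = set()
    names = list(ORACLE_VARIANTS)
    for a, b in itertools.combinations_with_replacement(names, 2):
        if ORACLE_VARIANTS[a] is None and ORACLE_VARIANTS[b] is None:
            continue
        ca_range = [0] if ORACLE_VARIANTS[a] is None else [1, 2, 3]
        cb_range = [0] if ORACLE_VARIANTS[b] is None else [1, 2, 3]
        for ca in ca_range:
            cb = total - ca
            if cb not in cb_range:
                continue
            seq = ca + cb
            dev = 0.0
            for snp, obs in observed_fracs.items():
                var = (ca if ORACLE_VARIANTS[a] and snp in ORACLE_VARIANTS[a] else 0) + (
                    cb if ORACLE_VARIANTS[b] and snp in ORACLE_VARIANTS[b] else 0
                )
                dev += abs(obs - var / seq)
            res = dev / len(observed_fracs)
            key = _pair_key(a, ca, b, cb)
            if best_res is None or res < best_res - 1e-12:
                best_res, argmin = res, {key}
            elif abs(res - best_res) <= 1e-12:
                argmin.add(key)
    return best_res, argmin


def _pair_key(a, ca, b, cb):
    """Order-independent identity of an (allele, copies) founder pair."""
    return frozenset({(a, ca), (b, cb)}) if a != b else (a, tuple(sorted((ca, cb))))


def _production_key(config):
    return _pair_key(config.allele_a, config.copies_a, config.allele_b, config.copies_b)


def test_search_matches_naive_enumeration_on_random_samples():
    """The production search returns a global minimizer of the residual on
    1000 random noisy samples (oracle: independent full enumeration)."""
    rng = np.random.default_rng(20260926)
    names = [n for n in ORACLE_VARIANTS if n != "*5"]
    checked = 0
    for _ in range(1000):
        a, b = rng.choice(names, size=2)
        ca, cb = int(rng.integers(1, 4)), int(rng.integers(1, 4))
        total = ca + cb
        obs = {}
        calls = []
        for snp in PANEL:
            var = (ca if snp in ORACLE_VARIANTS[a] else 0) + (cb if snp in ORACLE_VARIANTS[b] else 0)
            pct = float(np.clip(100.0 * var / total + rng.normal(0, 2.0), 0, 100))
            obs[snp] = pct / 100.0
            calls.append(SNPQuantCall(snp, 100 - pct, pct))
        call = call_diplotype(SampleInput("r", tuple(calls), total_copies=total))
        best_res, argmin = oracle_best(obs, total)
        assert call.residual == pytest.approx(best_res, abs=1e-9)
        assert _production_key(call.best) in argmin
        checked += 1
    assert checked == 1000


def test_enumeration_covers_all_splits(model):
    configs = enumerate_configurations(3, model)
    rendered = {c.render() for c in configs}
    assert "*1/*2x2" in rendered and "*1x2/*2" in rendered
    assert "*1/*5" not in rendered  # *5 pairs only reach total via partner
    assert all(c.total_copies == 3 for c in configs)
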