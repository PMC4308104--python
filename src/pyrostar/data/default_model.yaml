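# Default CYP2D6 panel, haplotype definitions, CPIC activity values and
# allelic-ratio calibration. Positions follow the conventional CYP2D6
# gene numbering (M33388). Edit a copy and pass it via --config / from_yaml
# to load a different nomenclature or activity-score version.
panel:
  - {snp_id: rs16947,     label: "2850C>T",  ref_base: C, var_base: T}
  - {snp_id: rs35742686,  label: "2549delA", ref_base: A, var_base: "-"}
  - {snp_id: rs3892097,   label: "1846G>A",  ref_base: G, var_base: A}
  - {snp_id: rs5030655,   label: "1707delT", ref_base: T, var_base: "-"}
  - {snp_id: rs1065852,   label: "100C>T",   ref_base: C, var_base: T}
  - {snp_id: rs28371706,  label: "1023C>T",  ref_base: C, var_base: T}
  - {snp_id: rs28371725,  label: "2988G>A",  ref_base: G, var_base: A}

# variant_snps lists the panel positions each haplotype carries in variant
# state (full haplotype content restricted to the 7-SNP panel). activity is
# the CPIC per-functional-copy value: 1 normal, 0.5 reduced, 0 none.
alleles:
  "*1":  {variant_snps: [], activity: 1.0}
  "*2":  {variant_snps: [rs16947], activity: 1.0}
  "*3":  {variant_snps: [rs35742686], activity: 0.0}
  "*4":  {variant_snps: [rs1065852, rs3892097], activity: 0.0}
  "*5":  {variant_snps: [], activity: 0.0, is_deletion: true}
  "*6":  {variant_snps: [rs5030655], activity: 0.0}
  "*10": {variant_snps: [rs1065852], activity: 0.5}
  "*17": {variant_snps: [rs28371706, rs16947], activity: 0.5}
  "*41": {variant_snps: [rs16947, rs28371725], activity: 0.5}

# Allelic-ratio calibration per total gene copy number (heterozygous
# samples). Decision boundaries between classes are midpoints of the gaps
# between the calibrated class ranges; upper_bound caps acceptance above
# the 4-copy class.
ratio_bins:
  classes:
    - {copies: 2, mean: 0.97, sd: 0.07, min: 0.85, max: 1.06}
    - {copies: 3, mean: 1.83, sd: 0.16, min: 1.60, max: 2.20}
    - {copies: 4, mean: 2.76, sd: 0.39, min: 2.42, max: 3.20}
  upper_bound: 3.7
  near_margin: 0.1

noise:
  percent_noise_sd: 2.0
  taqman_raw_sd: 0.15
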