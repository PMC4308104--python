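"""Sample-sheet reading, call writing, and a minimal VCF export.

The primary exchange format is a long-form TSV sample sheet with one row
per (sample, panel SNP): columns ``sample_id``, ``snp_id``,
``percent_var`` and optionally ``percent_ref`` (imputed as
100 − percent_var when absent), ``total_copies`` and
``population_label``.  Calls are written as TSV or JSON with deterministic
ordering by sample id.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .caller import DiplotypeCall, SampleInput
from .cnv import PERCENT_SUM_TOLERANCE, SNPQuantCall
from .model import AlleleModel, PhenotypeCall, default_model

__all__ = [
    "read_sample_sheet",
    "write_calls",
    "write_sample_sheet",
    "write_vcf",
    "SampleSheetError",
]

CALL_COLUMNS = (
    "sample_id",
    "diplotype",
    "total_copies",
    "duplicated_allele",
    "activity_score",
    "phenotype",
    "flags",
)


class SampleSheetError(ValueError):
    """A sample sheet fails validation; message carries row numbers."""


def read_sample_sheet(
    path,
    model: Optional[AlleleModel] = None,
    tolerance: float = PERCENT_SUM_TOLERANCE,
) -> list[SampleInput]:
    """Parse and validate a TSV sample sheet into ``SampleInput`` records."""
    model = model or default_model()
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "snp_id": str})
    except pd.errors.EmptyDataError:
        raise SampleSheetError(f"{path}: empty sample sheet") from None
    required = {"sample_id", "snp_id", "percent_var"}
    missing = required - set(df.columns)
    if missing:
        raise SampleSheetError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise SampleSheetError(f"{path}: no data rows")

    errors: list[str] = []
    samples: dict[str, dict] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        snp_id = row["snp_id"]
        if snp_id not in model.panel:
            errors.append(
                f"line {line}: unknown snp_id {snp_id!r}; panel is {sorted(model.panel)}"
            )
            continue
        percent_var = float(row["percent_var"])
        percent_ref = row.get("percent_ref")
        if percent_ref is None or pd.isna(percent_ref):
            percent_ref = 100.0 - percent_var
        else:
            percent_ref = float(percent_ref)
        try:
            call = SNPQuantCall(snp_id, percent_ref, percent_var).normalized(tolerance)
        except ValueError as exc:
            errors.append(f"line {line}: {exc}")
            continue
        rec = samples.setdefault(
            row["sample_id"], {"calls": {}, "total_copies": None, "population_label": None}
        )
        if snp_id in rec["calls"]:
            errors.append(f"line {line}: duplicate ({row['sample_id']}, {snp_id})")
            continue
        rec["calls"][snp_id] = call
        if "total_copies" in df.columns and not pd.isna(row["total_copies"]):
            total = int(row["total_copies"])
            if rec["total_copies"] not in (None, total):
                errors.append(f"line {line}: conflicting total_copies for {row['sample_id']}")
            rec["total_copies"] = total
        if "population_label" in df.columns and not pd.isna(row["population_label"]):
            rec["population_label"] = str(row["population_label"])

    if errors:
        raise SampleSheetError(f"{path}: " + "; ".join(errors))

    return [
        SampleInput(
            sample_id=sid,
            quant_calls=tuple(rec["calls"][k] for k in sorted(rec["calls"])),
            total_copies=rec["total_copies"],
            population_label=rec["population_label"],
        )
        for sid, rec in sorted(samples.items())
    ]


def write_sample_sheet(samples: Sequence[SampleInput], path) -> None:
    """Inverse of :func:`read_sample_sheet` (round-trip safe)."""
    rows = []
    for s in sorted(samples, key=lambda s: s.sample_id):
        for call in s.quant_calls:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "snp_id": call.snp_id,
                    "percent_ref": call.percent_ref,
                    "percent_var": call.percent_var,
                    "total_copies": s.total_copies,
                    "population_label": s.population_label,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _call_record(call: DiplotypeCall, pheno: PhenotypeCall) -> dict:
    return {
        "sample_id": call.sample_id,
        "diplotype": call.best.render(),
        "total_copies": call.best.total_copies,
        "duplicated_allele": call.duplicated_allele or "",
        "activity_score": pheno.activity_score,
        "phenotype": pheno.phenotype_label(),
        "flags": ";".join(sorted(call.flags)),
    }


def write_calls(
    calls: Sequence[tuple[DiplotypeCall, PhenotypeCall]],
    path,
    format: str = "tsv",
) -> None:
    """Write phenotyped calls as TSV or JSON, ordered by sample id."""
    if not calls:
        raise ValueError("no calls to write")
    records = sorted(
        (_call_record(c, p) for c, p in calls), key=lambda r: r["sample_id"]
    )
    path = Path(path)
    if format == "tsv":
        pd.DataFrame(records, columns=list(CALL_COLUMNS)).to_csv(path, sep="\t", index=False)
    elif format == "json":
        path.write_text(json.dumps(records, indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'json')")


def write_vcf(
    sample: SampleInput,
    call: DiplotypeCall,
    path,
    model: Optional[AlleleModel] = None,
) -> None:
    """Minimal single-sample VCF 4.2 export of the panel genotypes.

    GT comes from founder variant content of the called configuration;
    the VAF FORMAT field carries the measured variant fraction.  Deletion
    variants are written as symbolic ``<DEL>`` alleles since the assay only
    reports per-base percentages, not flanking context.
    """
    model = model or default_model()
    observed = {c.snp_id: c for c in sample.quant_calls}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample.sample_id}",
    ]
    for snp in model.panel.values():
        pos = int("".join(ch for ch in snp.label if ch.isdigit()))
        alt = "<DEL>" if snp.var_base == "-" else snp.var_base
        carriers = [
            snp.snp_id in model.allele(name).variant_snps for name in call.best.founders
        ]
        gt = "/".join(str(int(c)) for c in sorted(carriers))
        vaf = ""
        if snp.snp_id in observed:
            vaf = f"{observed[snp.snp_id].percent_var / 100.0:.4f}"
        lines.append(
            f"22\t{pos}\t{snp.snp_id}\t{snp.ref_base}\t{alt}\t.\t.\t.\tGT:VAF\t{gt}:{vaf}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
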