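"""Readers and writers for per-sample genotype and phenotype tables.

Genotypes come in either as a multi-sample VCF (GT fields only are used) or
as a TSV matrix with one row per sample and one column per panel variant,
cells like ``T/C``, ``1/2`` or ``./.``. Both readers produce identical
:class:`SampleRecord` lists: panel variants absent from the input are
MISSING (``None``), input phase separators are ignored (phase is inferred
statistically downstream, never trusted from the input), and alleles are
translated to the catalog's symbol set.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .catalog import Catalog

logger = logging.getLogger(__name__)

__all__ = [
    "SampleRecord",
    "HPLC_LABELS",
    "normalize_hplc_label",
    "read_vcf",
    "read_genotype_table",
    "write_genotype_table",
    "read_phenotypes",
    "attach_phenotypes",
    "PhenotypeError",
]

#: Unordered genotype: pair of allele symbols, or None for MISSING.
Genotype = tuple[str, str] | None

MISSING: Genotype = None

#: Canonical HPLC diagnosis labels.
HPLC_LABELS = ("SS", "Sβ", "SD", "AS", "AA", "β-trait", "UNKNOWN")

#: Hematology variables carried on a sample (units in docs/methods.md).
HEMATOLOGY_VARS = ("hb", "rbc", "mcv", "mch", "mchc", "hbf", "hba")

# Percentage-scale variables, bounded [0, 100].
_PERCENT_VARS = ("hbf", "hba")

_HPLC_ALIASES = {
    "ss": "SS",
    "hbss": "SS",
    "sb": "Sβ",
    "sβ": "Sβ",
    "sbeta": "Sβ",
    "sbthal": "Sβ",
    "sβthal": "Sβ",
    "sbetathal": "Sβ",
    "sbeta0": "Sβ",
    "sbeta+": "Sβ",
    "hbsb": "Sβ",
    "sd": "SD",
    "hbsd": "SD",
    "as": "AS",
    "hbas": "AS",
    "aa": "AA",
    "hbaa": "AA",
    "btrait": "β-trait",
    "βtrait": "β-trait",
    "betatrait": "β-trait",
    "bthal trait": "β-trait",
    "bthaltrait": "β-trait",
    "βthaltrait": "β-trait",
    "betathaltrait": "β-trait",
}


class PhenotypeError(ValueError):
    """Raised for fatally malformed phenotype tables."""


@dataclass
class SampleRecord:
    """One patient: panel genotypes plus optional phenotype data."""

    sample_id: str
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    hplc_label: str = "UNKNOWN"
    hematology: dict[str, float] = field(default_factory=dict)
    age_years: float | None = None

    def genotype(self, variant_id: str) -> Genotype:
        return self.genotypes.get(variant_id)


def normalize_hplc_label(raw: str) -> str:
    """Map free-text HPLC diagnosis strings onto the canonical label set.

    Unknown strings normalize to ``UNKNOWN`` with a logged warning.
    """
    key = raw.strip().lower().replace("-", "").replace("_", "").replace(" ", "")
    key = key.replace("thal", "thal")  # no-op, kept for clarity of intent
    if key.endswith("thal"):
        key_b = key[: -len("thal")]
        if key_b in _HPLC_ALIASES:
            return _HPLC_ALIASES[key_b]
    if key in _HPLC_ALIASES:
        return _HPLC_ALIASES[key]
    if raw.strip() in HPLC_LABELS:
        return raw.strip()
    logger.warning("unrecognized HPLC label %r -> UNKNOWN", raw)
    return "UNKNOWN"


# ---------------------------------------------------------------------------
# Genotype matrix (TSV)
# ---------------------------------------------------------------------------

def _parse_cell(cell: str, symbols: tuple[str, str], where: str) -> Genotype:
    cell = cell.strip()
    if cell in ("", ".", "./.", ".|.", "NA"):
        return MISSING
    sep = "|" if "|" in cell else "/"
    parts = cell.split(sep)
    if len(parts) != 2 or not all(p in symbols for p in parts):
        logger.warning("unparseable genotype cell %r at %s -> MISSING", cell, where)
        return MISSING
    return _unordered(parts[0], parts[1])


def _unordered(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _open_text(path):
    """Open a path, or pass through a file-like object."""
    if hasattr(path, "read"):
        from contextlib import nullcontext

        return nullcontext(path)
    return open(path, newline="")


def read_genotype_table(path, catalog: Catalog) -> list[SampleRecord]:
    """Read a TSV genotype matrix (sample_id column + one column per variant).

    ``path`` may be a filesystem path or an open text handle.
    """
    samples: list[SampleRecord] = []
    with _open_text(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise ValueError(f"{path}: genotype table needs a 'sample_id' column")
        known = set(catalog.variants)
        for col in reader.fieldnames:
            if col != "sample_id" and col not in known:
                logger.warning("ignoring unknown genotype column %r", col)
        for row in reader:
            sid = row["sample_id"]
            rec = SampleRecord(sample_id=sid)
            for vid in catalog.variants:
                cell = row.get(vid)
                if cell is None:
                    rec.genotypes[vid] = MISSING
                    continue
                symbols = catalog.allele_symbols(vid)
                rec.genotypes[vid] = _parse_cell(cell, symbols, f"{sid}:{vid}")
            samples.append(rec)
    return samples


def write_genotype_table(
    samples: Iterable[SampleRecord], path: str | Path, catalog: Catalog
) -> None:
    """Write records as a TSV matrix readable by :func:`read_genotype_table`."""
    cols = catalog.panel_order
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["sample_id", *cols])
        for rec in samples:
            row = [rec.sample_id]
            for vid in cols:
                gt = rec.genotypes.get(vid)
                row.append("./." if gt is None else f"{gt[0]}/{gt[1]}")
            writer.writerow(row)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, catalog: Catalog) -> list[SampleRecord]:
    """Read panel genotypes for all samples of a VCF 4.x file.

    Records are matched to the panel by (chrom, pos, ref, alt) with a
    fallback on the ID column; non-panel records are ignored (count logged).
    An allele at a panel site that is not in the encoding map yields MISSING
    for that sample with a logged warning. Phase separators are ignored.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    records = {sid: SampleRecord(sample_id=sid) for sid in sample_ids}
    for rec in records.values():
        rec.genotypes = {vid: MISSING for vid in catalog.variants}

    by_site = {
        (v.chrom, v.pos, v.ref_allele, v.alt_allele): v.id
        for v in catalog.variants.values()
    }
    ignored = 0
    for var in vcf:
        vid = None
        for alt in var.ALT or [None]:
            key = (var.CHROM.removeprefix("chr"), var.POS, var.REF, alt)
            if key in by_site:
                vid = by_site[key]
                break
        if vid is None and var.ID in catalog.variants:
            vid = var.ID
        if vid is None:
            ignored += 1
            continue
        ref_sym, alt_sym = catalog.allele_symbols(vid)
        cat = catalog.variants[vid]
        allele_to_sym: dict[str, str] = {cat.ref_allele: ref_sym, cat.alt_allele: alt_sym}
        alleles = [var.REF, *(var.ALT or [])]
        for sid, gt in zip(sample_ids, var.genotypes):
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                continue  # missing GT stays MISSING
            try:
                syms = (allele_to_sym[alleles[a0]], allele_to_sym[alleles[a1]])
            except KeyError as exc:
                logger.warning(
                    "sample %s: allele %s at %s not in encoding map -> MISSING",
                    sid, exc.args[0], vid,
                )
                continue
            records[sid].genotypes[vid] = _unordered(*syms)
    if ignored:
        logger.info("ignored %d non-panel VCF records", ignored)
    return [records[sid] for sid in sample_ids]


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> dict[str, dict]:
    """Read a phenotype TSV: sample_id, hplc_label, age, and hematology.

    Returns ``{sample_id: {"hplc_label": ..., "age_years": ..., "hematology":
    {...}}}``. Duplicate sample ids are fatal; out-of-range values raise
    :class:`PhenotypeError`.
    """
    out: dict[str, dict] = {}
    with _open_text(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise PhenotypeError(f"{path}: phenotype table needs a 'sample_id' column")
        for row in reader:
            sid = row["sample_id"]
            if sid in out:
                raise PhenotypeError(f"duplicate sample_id {sid!r}")
            hema: dict[str, float] = {}
            for var in HEMATOLOGY_VARS:
                cell = (row.get(var) or "").strip()
                if cell in ("", "NA", "."):
                    continue
                val = float(cell)
                if math.isnan(val):
                    continue
                if val < 0:
                    raise PhenotypeError(f"{sid}: negative {var} value {val}")
                if var in _PERCENT_VARS and val > 100:
                    raise PhenotypeError(f"{sid}: {var} above 100% ({val})")
                hema[var] = val
            age_cell = (row.get("age") or row.get("age_years") or "").strip()
            age = float(age_cell) if age_cell not in ("", "NA", ".") else None
            if age is not None and age < 0:
                raise PhenotypeError(f"{sid}: negative age {age}")
            out[sid] = {
                "hplc_label": normalize_hplc_label(row.get("hplc_label", "")),
                "age_years": age,
                "hematology": hema,
            }
    return out


def attach_phenotypes(
    samples: list[SampleRecord], phenotypes: Mapping[str, dict]
) -> list[SampleRecord]:
    """Merge phenotype rows onto genotype records in place (and return them)."""
    for rec in samples:
        pheno = phenotypes.get(rec.sample_id)
        if pheno is None:
            continue
        rec.hplc_label = pheno["hplc_label"]
        rec.age_years = pheno["age_years"]
        rec.hematology = dict(pheno["hematology"])
    return samples


def write_phenotype_table(rows: Iterable[dict], path: str | Path) -> None:
    """Write phenotype rows (dicts with sample_id/hplc_label/age/hematology keys)."""
    cols = ["sample_id", "hplc_label", "age", *HEMATOLOGY_VARS]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(cols)
        for row in rows:
            writer.writerow([row.get(c, "") for c in cols])
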