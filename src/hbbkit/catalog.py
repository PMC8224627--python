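"""Variant panel for HBB-locus sickle cell diagnostics.

The catalog holds three things: the structural hemoglobin variants (HbS at
rs334, HbD-Punjab), the beta-thalassemia alleles with their functional class
(beta-0: no beta-globin output; beta-plus: reduced; beta-plus-plus: mildly
reduced), and the five haplotype-tag SNPs of the beta-globin gene cluster
together with the table of 5-symbol allele patterns that defines the
classical beta-S haplotypes (AI, SEN, BEN, BAN, CAM) and the named recurrent
atypical patterns (ATP-I/II/III).

The catalog is data, not code: it is loaded from a YAML config (a default
reproducing the panel ships with the package) and validated on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "VariantClass",
    "VariantDef",
    "TagSnpPanel",
    "HaplotypeTable",
    "Catalog",
    "CatalogError",
    "load_catalog",
    "save_catalog",
    "default_catalog_path",
    "variant_class",
]

#: Valid functional classes for a panel variant.
VARIANT_CLASSES = ("HBS", "HBD", "BETA0", "BETA_PLUS", "BETA_PLUS_PLUS", "TAG_SNP")

#: Classes that count as beta-thalassemia alleles.
BETA_THAL_CLASSES = ("BETA0", "BETA_PLUS", "BETA_PLUS_PLUS")

VariantClass = str


class CatalogError(ValueError):
    """Raised when a catalog config violates the panel invariants."""


@dataclass(frozen=True)
class VariantDef:
    """One panel variant.

    ``id`` is the rsID or legacy name ("rs334", "CD39"); ``hgvs`` the HBB
    c. notation, treated as an opaque key; ``pos`` is 1-based GRCh38.
    """

    id: str
    hgvs: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    var_class: VariantClass

    def __post_init__(self) -> None:
        if self.var_class not in VARIANT_CLASSES:
            raise CatalogError(f"{self.id}: unknown variant class {self.var_class!r}")
        if self.var_class in BETA_THAL_CLASSES and not self.hgvs:
            raise CatalogError(f"{self.id}: beta-thal entries require an HGVS string")
        if not self.ref_allele or not self.alt_allele:
            raise CatalogError(f"{self.id}: empty allele")

    @property
    def is_beta_thal(self) -> bool:
        return self.var_class in BETA_THAL_CLASSES


@dataclass(frozen=True)
class TagSnpPanel:
    """The five haplotype-tag SNPs in fixed pattern-column order.

    ``allele_encoding`` maps each SNP's physical alleles (as they appear in a
    VCF, reference strand) to the one-character symbols used in haplotype
    patterns; for rs3834466 the single T is symbol "1" and the TT duplication
    is symbol "2". This map is the only place strand/representation
    ambiguity is resolved.
    """

    snps: tuple[str, ...]
    allele_encoding: Mapping[str, Mapping[str, str]]

    def __post_init__(self) -> None:
        if len(self.snps) != 5:
            raise CatalogError(f"tag panel must have exactly 5 SNPs, got {len(self.snps)}")
        for snp in self.snps:
            enc = self.allele_encoding.get(snp)
            if enc is None:
                raise CatalogError(f"tag SNP {snp} has no allele encoding")
            if len(set(enc.values())) != 2:
                raise CatalogError(f"tag SNP {snp} must map exactly two symbols")

    def symbols(self, snp: str) -> tuple[str, ...]:
        """The two valid pattern symbols for ``snp``."""
        return tuple(dict.fromkeys(self.allele_encoding[snp].values()))

    def encode(self, snp: str, allele: str) -> str:
        """Translate a physical allele to its pattern symbol."""
        try:
            return self.allele_encoding[snp][allele]
        except KeyError:
            raise CatalogError(f"allele {allele!r} at {snp} not in encoding map") from None


@dataclass(frozen=True)
class HaplotypeTable:
    """Bijective map between canonical 5-symbol patterns and class labels."""

    patterns: Mapping[str, str]  # pattern -> label

    def __post_init__(self) -> None:
        if len(set(self.patterns.values())) != len(self.patterns):
            raise CatalogError("haplotype labels are not distinct")
        for pat in self.patterns:
            if len(pat) != 5:
                raise CatalogError(f"pattern {pat!r} is not 5 symbols long")

    @property
    def labels(self) -> Mapping[str, str]:
        """label -> pattern (inverse view)."""
        return {v: k for k, v in self.patterns.items()}


@dataclass(frozen=True)
class Catalog:
    """A validated variant panel."""

    variants: Mapping[str, VariantDef]
    tag_panel: TagSnpPanel
    haplotype_table: HaplotypeTable
    _by_hgvs: Mapping[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        hbs = [v for v in self.variants.values() if v.var_class == "HBS"]
        if len(hbs) != 1 or hbs[0].id != "rs334":
            raise CatalogError("catalog must contain exactly one HBS entry, rs334")
        tags = [v for v in self.variants.values() if v.var_class == "TAG_SNP"]
        if len(tags) != 5:
            raise CatalogError(f"catalog must contain exactly five TAG_SNP entries, got {len(tags)}")
        for snp in self.tag_panel.snps:
            if snp not in self.variants or self.variants[snp].var_class != "TAG_SNP":
                raise CatalogError(f"tag panel SNP {snp} missing from catalog")
        object.__setattr__(
            self,
            "_by_hgvs",
            {_norm_hgvs(v.hgvs): v.id for v in self.variants.values() if v.hgvs},
        )

    # -- lookups ---------------------------------------------------------

    def resolve(self, key: str) -> VariantDef:
        """Look up a variant by id or (whitespace-insensitive) HGVS string."""
        if key in self.variants:
            return self.variants[key]
        vid = self._by_hgvs.get(_norm_hgvs(key))
        if vid is not None:
            return self.variants[vid]
        raise KeyError(f"unknown variant {key!r}")

    @property
    def beta_thal_variants(self) -> list[VariantDef]:
        return [v for v in self.variants.values() if v.is_beta_thal]

    @property
    def hbd_variants(self) -> list[VariantDef]:
        return [v for v in self.variants.values() if v.var_class == "HBD"]

    @property
    def rs334(self) -> VariantDef:
        return self.variants["rs334"]

    def allele_symbols(self, variant_id: str) -> tuple[str, str]:
        """(ref_symbol, alt_symbol) used in genotype tables for a variant.

        Tag SNPs use their pattern symbols; all other variants use the
        physical allele strings themselves.
        """
        v = self.variants[variant_id]
        if v.var_class == "TAG_SNP":
            enc = self.tag_panel.allele_encoding[variant_id]
            return enc[v.ref_allele], enc[v.alt_allele]
        return v.ref_allele, v.alt_allele

    @property
    def panel_order(self) -> list[str]:
        """Canonical column order: rs334, HbD, beta-thal, then tag SNPs."""
        others = [
            v.id
            for v in self.variants.values()
            if v.var_class not in ("TAG_SNP", "HBS")
        ]
        return ["rs334", *others, *self.tag_panel.snps]


def _norm_hgvs(s: str) -> str:
    return "".join(s.split())


def default_catalog_path() -> Path:
    """Path of the packaged default panel config."""
    return Path(resources.files("hbbkit.data").joinpath("default_catalog.yaml"))  # type: ignore[arg-type]


def load_catalog(config_path: str | Path | None = None) -> Catalog:
    """Load and validate a catalog config (the packaged default if None)."""
    path = Path(config_path) if config_path is not None else default_catalog_path()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        variants: dict[str, VariantDef] = {}
        for rec in raw["variants"]:
            v = VariantDef(
                id=str(rec["id"]),
                hgvs=str(rec.get("hgvs", "") or ""),
                chrom=str(rec["chrom"]),
                pos=int(rec["pos"]),
                ref_allele=str(rec["ref"]),
                alt_allele=str(rec["alt"]),
                var_class=str(rec["class"]),
            )
            if v.id in variants:
                raise CatalogError(f"duplicate variant id {v.id!r}")
            variants[v.id] = v
        panel_raw = raw["tag_panel"]
        panel = TagSnpPanel(
            snps=tuple(str(s) for s in panel_raw["order"]),
            allele_encoding={
                str(snp): {str(a): str(sym) for a, sym in enc.items()}
                for snp, enc in panel_raw["encoding"].items()
            },
        )
        table = HaplotypeTable(
            patterns={str(p): str(lbl) for lbl, p in raw["haplotypes"].items()}
        )
        return Catalog(variants=variants, tag_panel=panel, haplotype_table=table)
    except (KeyError, TypeError) as exc:
        raise CatalogError(f"malformed catalog config {path}: {exc}") from exc


def save_catalog(catalog: Catalog, path: str | Path) -> None:
    """Write a catalog back to YAML (round-trips through load_catalog)."""
    doc = {
        "variants": [
            {
                "id": v.id,
                "hgvs": v.hgvs,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "class": v.var_class,
            }
            for v in catalog.variants.values()
        ],
        "tag_panel": {
            "order": list(catalog.tag_panel.snps),
            "encoding": {
                snp: dict(enc) for snp, enc in catalog.tag_panel.allele_encoding.items()
            },
        },
        "haplotypes": {lbl: pat for pat, lbl in catalog.haplotype_table.patterns.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def variant_class(catalog: Catalog, variant_id: str) -> VariantClass:
    """Functional class of a variant, looked up by id or HGVS string."""
    return catalog.resolve(variant_id).var_class
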