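"""Hemoglobin genotype calling from panel genotypes.

The decision rules implement the diagnostic logic of an HBB NGS panel:
rs334 (HbS) is read first, then the beta-thalassemia and HbD sites.

=========================  =======================================
rs334 / other sites        call
=========================  =======================================
hom alt                    SS (sickle cell anemia)
het + one het beta-thal    SB0 or SBP by the allele's class
                           (beta++ folds into SBP with a note)
het + het HbD              SD
het + nothing else         AS (carrier)
ref-hom + one het b-thal   BTRAIT
ref-hom + nothing          AA
anything else              UNRESOLVED with an explanatory note
=========================  =======================================

A compound heterozygote (rs334 het + beta-thal het) is assumed to carry the
two alleles in trans; the assumption is recorded in ``notes``. Samples with
more than one beta-thal allele, homozygous beta-thal, or S+D+beta-thal
combinations are never guessed at: they come back UNRESOLVED.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .catalog import Catalog
from .genotype_io import SampleRecord

__all__ = ["HbGenotypeCall", "CALL_LABELS", "call_hb_genotype", "genotype_counts",
           "display_label"]

#: NGS call labels. SB0 = S/beta-0-thal, SBP = S/beta-plus-thal (incl. beta++).
CALL_LABELS = ("AA", "AS", "SS", "SB0", "SBP", "SD", "BTRAIT", "UNRESOLVED")

#: Collapse NGS labels onto the HPLC label vocabulary for concordance tables.
_DISPLAY = {"SB0": "Sβ", "SBP": "Sβ", "BTRAIT": "β-trait"}


def display_label(call_label: str) -> str:
    """HPLC-comparable form of an NGS call label (SB0/SBP -> "Sβ")."""
    return _DISPLAY.get(call_label, call_label)


@dataclass
class HbGenotypeCall:
    """Result of calling one sample."""

    sample_id: str
    label: str
    beta_thal_variant: str | None = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in CALL_LABELS:
            raise ValueError(f"unknown call label {self.label!r}")
        needs_variant = self.label in ("SB0", "SBP", "BTRAIT")
        if needs_variant != (self.beta_thal_variant is not None):
            raise ValueError(
                f"{self.sample_id}: beta_thal_variant must be set iff label in "
                f"SB0/SBP/BTRAIT (label={self.label})"
            )


def _zygosity(gt, ref_sym: str, alt_sym: str) -> str | None:
    """'hom_ref' | 'het' | 'hom_alt' | None for MISSING."""
    if gt is None:
        return None
    n_alt = sum(1 for a in gt if a == alt_sym)
    return ("hom_ref", "het", "hom_alt")[n_alt]


def call_hb_genotype(sample: SampleRecord, catalog: Catalog) -> HbGenotypeCall:
    """Call one sample's hemoglobin genotype.

    Pure function of (genotypes, catalog); never raises on a valid
    :class:`SampleRecord` — uninterpretable combinations are UNRESOLVED.
    """
    sid = sample.sample_id
    rs334 = catalog.rs334
    s_zyg = _zygosity(
        sample.genotype("rs334"), rs334.ref_allele, rs334.alt_allele
    )
    if s_zyg is None:
        return HbGenotypeCall(sid, "UNRESOLVED", notes=["rs334 genotype missing"])

    # Tally beta-thal and HbD alleles (sorted for deterministic notes).
    bthal_het: list[str] = []
    bthal_hom: list[str] = []
    for v in sorted(catalog.beta_thal_variants, key=lambda v: v.id):
        zyg = _zygosity(sample.genotype(v.id), v.ref_allele, v.alt_allele)
        if zyg == "het":
            bthal_het.append(v.id)
        elif zyg == "hom_alt":
            bthal_hom.append(v.id)
    hbd_het = []
    hbd_hom = []
    for v in catalog.hbd_variants:
        zyg = _zygosity(sample.genotype(v.id), v.ref_allele, v.alt_allele)
        if zyg == "het":
            hbd_het.append(v.id)
        elif zyg == "hom_alt":
            hbd_hom.append(v.id)

    if bthal_hom or len(bthal_het) > 1 or hbd_hom:
        involved = sorted(bthal_hom + bthal_het + hbd_hom)
        return HbGenotypeCall(
            sid, "UNRESOLVED",
            notes=[f"uninterpretable beta-globin allele combination: {', '.join(involved)}"],
        )

    if s_zyg == "hom_alt":
        if bthal_het or hbd_het:
            return HbGenotypeCall(
                sid, "UNRESOLVED",
                notes=["rs334 homozygous plus additional beta-globin allele"],
            )
        return HbGenotypeCall(sid, "SS")

    if s_zyg == "het":
        if bthal_het and hbd_het:
            return HbGenotypeCall(
                sid, "UNRESOLVED", notes=["HbS + HbD + beta-thal allele combination"]
            )
        if bthal_het:
            vid = bthal_het[0]
            cls = catalog.variants[vid].var_class
            notes = ["HbS and beta-thal allele assumed in trans"]
            if cls == "BETA0":
                label = "SB0"
            else:
                label = "SBP"
                if cls == "BETA_PLUS_PLUS":
                    notes.append(f"{vid} is a beta++ allele (mild, near-AS phenotype)")
            return HbGenotypeCall(sid, label, beta_thal_variant=vid, notes=notes)
        if hbd_het:
            return HbGenotypeCall(sid, "SD")
        return HbGenotypeCall(sid, "AS")

    # rs334 hom-ref
    if hbd_het:
        return HbGenotypeCall(sid, "UNRESOLVED", notes=["HbD carrier without HbS"])
    if bthal_het:
        return HbGenotypeCall(sid, "BTRAIT", beta_thal_variant=bthal_het[0])
    return HbGenotypeCall(sid, "AA")


def genotype_counts(calls: list[HbGenotypeCall], collapse: bool = True) -> dict[str, int]:
    """Count calls per label.

    With ``collapse=True`` (default) SB0/SBP are merged into "Sβ" and BTRAIT
    shown as "β-trait", matching the HPLC vocabulary of diagnostic summary
    tables. Counts always sum to the cohort size.
    """
    if not calls:
        raise ValueError("empty cohort")
    labels = [display_label(c.label) if collapse else c.label for c in calls]
    return dict(Counter(labels))
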