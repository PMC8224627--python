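"""Synthetic SCD cohorts with the statistical structure of a Gulf-Arab
sickle cell study population.

Two generators live here:

* :func:`simulate_cohort` — a seeded stochastic generator. Each sample draws
  an Hb genotype class, beta-S / non-S gene-cluster haplotypes, a beta-thal
  mutation where the class requires one, hematology from per-group truncated
  normals, an HPLC label through a documented mislabeling process, and
  optional per-site missingness. A truth table records everything drawn so
  every pipeline stage can be checked against ground truth.

* :func:`paper_cohort_fixture` — a deterministic 240-patient cohort whose
  composition reproduces the reference study's printed tables: 154
  haplotyped SS patients with the published diplotype counts (100 AI/AI, 25
  AI/ATP, ...), 66 S/beta-thal patients with the published 13-mutation
  spectrum (10, 9, 8, 8, 8, 5, 5, 3, 3, 3, 2, 1, 1), 378 beta-S chromosomes
  of which 308 are AI (81.5%), and HPLC labels implementing the documented
  discordance flows (14 HPLC-Sβ patients that are SS by NGS, HPLC marginals
  184/54/2). Hematology is set to group means so summary tables are exactly
  reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import Catalog, load_catalog
from .genotype_io import (
    HEMATOLOGY_VARS,
    SampleRecord,
    attach_phenotypes,
    read_genotype_table,
)

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "paper_cohort_fixture",
    "to_sample_records",
    "DEFAULT_GENOTYPE_MIX",
    "DEFAULT_BS_HAPLOTYPE_FREQS",
    "DEFAULT_BETA_MUTATION_PROBS",
]

_CLASSES = ("SS", "SB0", "SBP", "SD", "AS", "AA", "BTRAIT")

_DISPLAY = {"SB0": "Sβ", "SBP": "Sβ", "BTRAIT": "β-trait"}

#: Published beta-thal mutation spectrum (legacy id -> patient count of 66).
MUTATION_SPECTRUM: tuple[tuple[str, int], ...] = (
    ("IVS-1, -25del", 10),
    ("IVS-II-1", 9),
    ("IVS-I-110", 8),
    ("IVS-I-1", 8),
    ("IVS-I-5", 8),
    ("CD39", 5),
    ("CD8", 5),
    ("CD8/9", 3),
    ("CD36/37", 3),
    ("CD31", 3),
    ("CD41/42", 2),
    ("IVS-I-6", 1),
    ("CD 82/83", 1),
)

#: Hb genotype class mix of the 240-patient cohort (NGS-confirmed classes).
DEFAULT_GENOTYPE_MIX: dict[str, float] = {
    "SS": 161 / 240,
    "SB0": 49 / 240,
    "SBP": 17 / 240,
    "SD": 4 / 240,
    "AS": 7 / 240,
    "AA": 1 / 240,
    "BTRAIT": 1 / 240,
}

#: Beta-S chromosome haplotype frequencies (AI 81.5%, atypical 6.9% split
#: over the three named recurrent patterns by their cohort proportions).
DEFAULT_BS_HAPLOTYPE_FREQS: dict[str, float] = {
    "AI": 0.815,
    "BEN": 0.058,
    "SEN": 0.024,
    "BAN": 0.013,
    "CAM": 0.021,
    "ATP-I": 0.040,
    "ATP-II": 0.017,
    "ATP-III": 0.012,
}

DEFAULT_BETA_MUTATION_PROBS: dict[str, float] = {
    vid: n / 66 for vid, n in MUTATION_SPECTRUM
}

# Cohort-wide hematology (mean, SD) per group; SS diplotype subgroups and
# S/beta-thal mutation subgroups override the base rows. Some published SDs
# are kept verbatim even where evidently misprinted (e.g. SS Hb 11.2+/-9.7);
# truncation at zero absorbs them and they are not test targets.
_SS_BASE = {"age": (13.3, 11.7), "hb": (11.2, 9.7), "rbc": (3.8, 0.9),
            "mcv": (80.6, 13.4), "mch": (27.2, 4.5), "mchc": (33.4, 1.4),
            "hbf": (22.6, 8.5), "hba": (0.0, 0.0)}
_SB_BASE = {"age": (11.2, 9.7), "hb": (10.7, 0.0), "rbc": (4.4, 0.8),
            "mcv": (69.5, 8.8), "mch": (22.4, 2.8), "mchc": (32.2, 1.6),
            "hbf": (24.7, 11.2)}

# SS subgroups keyed "SS:<diplotype>" (age, hb, mcv, mch, hbf published;
# rbc/mchc fall back to the SS base row).
_T5_ROWS: dict[str, dict[str, tuple[float, float]]] = {
    "AI/AI": {"age": (13.2, 11.8), "hb": (11.2, 7.5), "mcv": (81.0, 13.8),
              "mch": (27.5, 4.3), "hbf": (24.2, 7.9)},
    "AI/ATP": {"age": (15.0, 13.2), "hb": (9.9, 9.2), "mcv": (76.6, 12.1),
               "mch": (25.9, 4.6), "hbf": (21.0, 7.9)},
    "AI/BEN": {"age": (15.3, 13.7), "hb": (9.4, 1.5), "mcv": (86.1, 15.6),
               "mch": (29.0, 6.8), "hbf": (19.3, 11.5)},
    "AI/SEN": {"age": (12.1, 8.3), "hb": (10.7, 0.5), "mcv": (65.2, 4.1),
               "mch": (21.1, 1.4), "hbf": (15.2, 8.8)},
    "BEN/BEN": {"age": (6.4, 5.0), "hb": (8.9, 1.0), "mcv": (81.9, 8.5),
                "mch": (26.9, 4.0), "hbf": (16.8, 9.2)},
    "AI/BAN": {"age": (12.0, 12.2), "hb": (10.0, 0.4), "mcv": (90.2, 8.6),
               "mch": (29.8, 3.0), "hbf": (19.7, 5.1)},
    "CAM/CAM": {"age": (14.5, 4.9), "hb": (8.9, 0.1), "mcv": (89.5, 19.2),
                "mch": (29.2, 7.1), "hbf": (13.2, 2.0)},
    "SEN/SEN": {"age": (16.0, 7.1), "hb": (10.7, 1.1), "mcv": (85.2, 21.0),
                "mch": (29.2, 8.5), "hbf": (24.1, 11.0)},
    "BEN/CAM": {"age": (11.0, 0.0), "hb": (11.0, 0.0), "mcv": (78.6, 0.0),
                "mch": (26.0, 0.0), "hbf": (34.9, 0.0)},
    "BEN/ATP": {"age": (7.0, 0.0), "hb": (7.9, 0.0), "mcv": (76.0, 0.0),
                "mch": (24.0, 0.0), "hbf": (9.3, 0.0)},
    "AI/CAM": {"age": (2.0, 0.0), "hb": (9.7, 0.0), "mcv": (68.0, 0.0),
               "mch": (31.3, 0.0), "hbf": (22.6, 0.0)},
}

# S/beta-thal mutation subgroups keyed "Sβ:<legacy id>".
_T4_ROWS: dict[str, dict[str, tuple[float, float]]] = {
    "IVS-1, -25del": {"hb": (9.4, 1.7), "rbc": (4.6, 0.7), "mcv": (65.8, 3.6),
                      "mch": (20.5, 0.9), "mchc": (31.1, 0.7), "hbf": (29.6, 11.7)},
    "IVS-II-1": {"hb": (10.9, 1.5), "rbc": (4.8, 0.7), "mcv": (66.9, 2.4),
                 "mch": (22.6, 0.8), "mchc": (32.7, 1.6), "hbf": (33.5, 6.0)},
    "IVS-I-110": {"hb": (9.4, 1.1), "rbc": (4.2, 0.7), "mcv": (69.9, 5.6),
                  "mch": (22.5, 1.7), "mchc": (32.3, 1.2), "hbf": (12.6, 4.9)},
    "IVS-I-1": {"hb": (9.6, 1.6), "rbc": (4.3, 0.6), "mcv": (70.3, 8.4),
                "mch": (22.3, 1.7), "mchc": (31.6, 1.6), "hbf": (28.3, 9.9)},
    "IVS-I-5": {"hb": (9.2, 0.7), "rbc": (4.5, 0.8), "mcv": (67.4, 4.9),
                "mch": (21.4, 2.0), "mchc": (31.8, 1.6), "hbf": (20.6, 13.9)},
    "CD39": {"hb": (9.1, 0.9), "rbc": (3.6, 0.4), "mcv": (82.7, 16.0),
             "mch": (25.7, 5.0), "mchc": (31.5, 0.5), "hbf": (20.1, 12.9)},
    "CD8": {"hb": (9.2, 1.1), "rbc": (4.5, 0.7), "mcv": (61.3, 7.0),
            "mch": (20.8, 0.4), "mchc": (34.1, 1.8), "hbf": (32.3, 7.7)},
    "CD8/9": {"hb": (8.1, 0.9), "rbc": (3.7, 0.7), "mcv": (72.5, 2.7),
              "mch": (23.0, 0.9), "mchc": (31.6, 0.1), "hbf": (18.9, 1.7)},
    "CD36/37": {"hb": (8.4, 0.6), "rbc": (3.2, 0.6), "mcv": (63.4, 2.3),
                "mch": (24.3, 3.0), "mchc": (32.8, 1.4), "hbf": (14.2, 4.5)},
    "CD31": {"hb": (10.1, 1.8), "rbc": (4.9, 1.0), "mcv": (66.5, 2.1),
             "mch": (20.8, 0.4), "mchc": (31.3, 0.5), "hbf": (25.6, 2.7)},
    "CD41/42": {"hb": (11.6, 0.2), "rbc": (4.8, 0.5), "mcv": (76.8, 11.0),
                "mch": (24.4, 2.2), "mchc": (31.8, 1.7), "hbf": (33.9, 13.6)},
    "IVS-I-6": {"hb": (11.1, 0.0), "rbc": (5.1, 0.0), "mcv": (66.7, 0.0),
                "mch": (21.6, 0.0), "mchc": (32.4, 0.0), "hbf": (8.5, 0.0)},
    "CD 82/83": {"hb": (9.0, 0.0), "rbc": (4.2, 0.0), "mcv": (64.0, 0.0),
                 "mch": (21.3, 0.0), "mchc": (33.3, 0.0), "hbf": (15.4, 0.0)},
}

# Residual HbA per beta-plus mutation (mean, SD); beta-0 alleles leave none.
_DEFAULT_HBA_PARAMS: dict[str, tuple[float, float]] = {
    "IVS-I-110": (15.5, 6.2),
    "IVS-I-5": (0.0, 0.0),
    "IVS-I-6": (25.1, 0.0),
}

# Carrier / normal groups are not tabulated by the study; values are
# clinically plausible defaults (see docs/methods.md).
_OTHER_GROUPS: dict[str, dict[str, tuple[float, float]]] = {
    "AA": {"age": (12.0, 10.0), "hb": (13.2, 1.2), "rbc": (4.8, 0.4),
           "mcv": (86.0, 5.0), "mch": (29.0, 2.0), "mchc": (33.5, 1.0),
           "hbf": (0.5, 0.4), "hba": (96.5, 1.0)},
    "AS": {"age": (12.0, 10.0), "hb": (13.0, 1.3), "rbc": (4.9, 0.5),
           "mcv": (84.0, 6.0), "mch": (28.0, 2.0), "mchc": (33.3, 1.0),
           "hbf": (0.8, 0.6), "hba": (58.0, 3.0)},
    "SD": {"age": (12.0, 10.0), "hb": (10.5, 1.5), "rbc": (4.0, 0.7),
           "mcv": (80.0, 8.0), "mch": (26.0, 3.0), "mchc": (33.0, 1.2),
           "hbf": (12.0, 6.0), "hba": (0.0, 0.0)},
    "β-trait": {"age": (12.0, 10.0), "hb": (11.5, 1.2), "rbc": (5.5, 0.6),
                "mcv": (65.0, 5.0), "mch": (20.0, 2.0), "mchc": (31.0, 1.5),
                "hbf": (1.8, 1.0), "hba": (92.0, 2.0)},
}


def _default_hematology_params() -> dict[str, dict[str, tuple[float, float]]]:
    params: dict[str, dict[str, tuple[float, float]]] = {
        "SS": dict(_SS_BASE),
        "Sβ": dict(_SB_BASE),
    }
    for dip, row in _T5_ROWS.items():
        params[f"SS:{dip}"] = dict(row)
    for vid, row in _T4_ROWS.items():
        params[f"Sβ:{vid}"] = dict(row)
    for grp, row in _OTHER_GROUPS.items():
        params[grp] = dict(row)
    return params


#: HPLC mislabeling flows (true display label -> assigned HPLC label) with
#: per-sample Bernoulli probabilities implied by the documented discordance.
_DEFAULT_MISLABEL: dict[tuple[str, str], float] = {
    ("SS", "Sβ"): 14 / 161,
    ("Sβ", "SS"): 26 / 66,
    ("AS", "SS"): 1.0,
    ("AA", "SS"): 1.0,
    ("β-trait", "SS"): 1.0,
    ("SD", "SS"): 0.5,
}


@dataclass
class SimulationConfig:
    """All knobs of the stochastic cohort generator.

    Defaults encode the reference study conditions; probability vectors must
    sum to one and the seed is mandatory (same seed, same cohort).
    """

    n_samples: int = 240
    seed: int = 0
    genotype_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_MIX))
    bs_haplotype_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BS_HAPLOTYPE_FREQS))
    non_s_haplotype_freqs: dict[str, float] | None = None  # defaults to bs
    beta_mutation_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETA_MUTATION_PROBS))
    hematology_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_hematology_params)
    hba_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_HBA_PARAMS))
    mislabel: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_MISLABEL))
    missingness: float = 0.0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if not isinstance(self.seed, int):
            raise ValueError("seed is mandatory and must be an int")
        for name, vec in (
            ("genotype_mix", self.genotype_mix),
            ("bs_haplotype_freqs", self.bs_haplotype_freqs),
            ("beta_mutation_probs", self.beta_mutation_probs),
        ):
            if any(p < 0 for p in vec.values()) or not math.isclose(
                sum(vec.values()), 1.0, abs_tol=1e-9
            ):
                raise ValueError(f"{name} must be a probability vector summing to 1")
        if self.non_s_haplotype_freqs is not None and not math.isclose(
            sum(self.non_s_haplotype_freqs.values()), 1.0, abs_tol=1e-9
        ):
            raise ValueError("non_s_haplotype_freqs must sum to 1")
        unknown = set(self.genotype_mix) - set(_CLASSES)
        if unknown:
            raise ValueError(f"unknown genotype classes {sorted(unknown)}")
        for grp, row in self.hematology_params.items():
            for var, (mu, sd) in row.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {grp}/{var}")
        for flow, p in self.mislabel.items():
            if not 0 <= p <= 1:
                raise ValueError(f"mislabel probability out of range for {flow}")
        if not 0 <= self.missingness <= 1:
            raise ValueError("missingness must be in [0, 1]")


# ---------------------------------------------------------------------------
# Genotype construction shared by the simulator and the fixture
# ---------------------------------------------------------------------------

def _hom_ref_genotypes(catalog: Catalog) -> dict[str, tuple[str, str]]:
    out = {}
    for vid in catalog.variants:
        ref_sym, _ = catalog.allele_symbols(vid)
        out[vid] = (ref_sym, ref_sym)
    return out


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _build_genotypes(
    catalog: Catalog,
    klass: str,
    pattern1: str,
    pattern2: str,
    mutation: str | None,
) -> dict[str, tuple[str, str] | None]:
    """Panel genotypes of one sample given class, haplotype patterns and
    beta-thal mutation. ``pattern1`` is the beta-S chromosome for classes
    carrying one sickle allele."""
    g: dict[str, tuple[str, str] | None] = dict(_hom_ref_genotypes(catalog))
    for i, snp in enumerate(catalog.tag_panel.snps):
        g[snp] = _pair(pattern1[i], pattern2[i])
    rs = catalog.rs334
    if klass == "SS":
        g["rs334"] = _pair(rs.alt_allele, rs.alt_allele)
    elif klass in ("SB0", "SBP", "SD", "AS"):
        g["rs334"] = _pair(rs.ref_allele, rs.alt_allele)
    if mutation is not None:
        v = catalog.variants[mutation]
        ref_sym, alt_sym = catalog.allele_symbols(mutation)
        g[mutation] = _pair(ref_sym, alt_sym)
    if klass == "SD":
        hbd = catalog.hbd_variants[0]
        ref_sym, alt_sym = catalog.allele_symbols(hbd.id)
        g[hbd.id] = _pair(ref_sym, alt_sym)
    return g


def _diplotype_key(label1: str, label2: str) -> str:
    a, b = sorted(
        "ATP" if lbl.startswith("ATP") else lbl for lbl in (label1, label2)
    )
    # Print AI first when present: frequency convention of diplotype tables.
    if b == "AI" and a != "AI":
        a, b = b, a
    if a == "ATP" and b != "ATP":
        a, b = b, a
    return f"{a}/{b}"


def _hema_group_key(klass: str, dip_key: str | None, mutation: str | None) -> list[str]:
    """Lookup keys for hematology params, most specific first."""
    disp = _DISPLAY.get(klass, klass)
    keys = []
    if klass == "SS" and dip_key is not None:
        keys.append(f"SS:{dip_key}")
    if klass in ("SB0", "SBP") and mutation is not None:
        keys.append(f"Sβ:{mutation}")
    keys.append(disp)
    return keys


# ---------------------------------------------------------------------------
# Stochastic generator
# ---------------------------------------------------------------------------

def _draw_trunc(rng: np.random.Generator, mu: float, sd: float, upper: float) -> float:
    """Truncated-normal draw on [0, upper]; degenerate SD returns the mean."""
    if sd == 0:
        return mu
    a, b = (0.0 - mu) / sd, (upper - mu) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))


def simulate_cohort(
    config: SimulationConfig, catalog: Catalog | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (genotype table, phenotype table, truth table) frames.

    Deterministic given ``config.seed``. The genotype frame has the layout
    of :func:`hbbkit.genotype_io.read_genotype_table` input; the truth frame
    records the drawn class, diplotype, mutation and the mislabeling flip.
    """
    config.validate()
    catalog = catalog or load_catalog()
    rng = np.random.default_rng(config.seed)

    classes = list(config.genotype_mix)
    class_p = np.array([config.genotype_mix[c] for c in classes])
    bs_labels = list(config.bs_haplotype_freqs)
    bs_p = np.array([config.bs_haplotype_freqs[h] for h in bs_labels])
    ns_freqs = config.non_s_haplotype_freqs or config.bs_haplotype_freqs
    ns_labels = list(ns_freqs)
    ns_p = np.array([ns_freqs[h] for h in ns_labels])
    label_to_pattern = catalog.haplotype_table.labels
    mut_by_class = {
        "SB0": [(m, p) for m, p in config.beta_mutation_probs.items()
                if catalog.variants[m].var_class == "BETA0"],
        "SBP": [(m, p) for m, p in config.beta_mutation_probs.items()
                if catalog.variants[m].var_class in ("BETA_PLUS", "BETA_PLUS_PLUS")],
        "BTRAIT": list(config.beta_mutation_probs.items()),
    }

    geno_rows, pheno_rows, truth_rows = [], [], []
    for i in range(config.n_samples):
        sid = f"SIM{i + 1:05d}"
        klass = classes[rng.choice(len(classes), p=class_p)]

        def draw_hap(kind: str) -> str:
            if kind == "bs":
                return bs_labels[rng.choice(len(bs_labels), p=bs_p)]
            return ns_labels[rng.choice(len(ns_labels), p=ns_p)]

        if klass == "SS":
            lab1, lab2 = draw_hap("bs"), draw_hap("bs")
        elif klass in ("SB0", "SBP", "SD", "AS"):
            lab1, lab2 = draw_hap("bs"), draw_hap("ns")
        else:
            lab1, lab2 = draw_hap("ns"), draw_hap("ns")
        pat1, pat2 = label_to_pattern[lab1], label_to_pattern[lab2]

        mutation = None
        if klass in mut_by_class:
            muts, probs = zip(*mut_by_class[klass])
            p = np.array(probs) / sum(probs)
            mutation = muts[rng.choice(len(muts), p=p)]

        genotypes = _build_genotypes(catalog, klass, pat1, pat2, mutation)
        if config.missingness > 0:
            for vid in genotypes:
                if rng.random() < config.missingness:
                    genotypes[vid] = None

        dip_key = _diplotype_key(lab1, lab2)
        hema: dict[str, float] = {}
        for var in HEMATOLOGY_VARS:
            mu_sd = None
            for key in _hema_group_key(klass, dip_key, mutation):
                row = config.hematology_params.get(key)
                if row and var in row:
                    mu_sd = row[var]
                    break
            if var == "hba" and klass == "SBP" and mutation is not None:
                mu_sd = config.hba_params.get(mutation, (0.0, 0.0))
            elif var == "hba" and klass == "SB0":
                mu_sd = (0.0, 0.0)
            if mu_sd is None:
                continue
            upper = 100.0 if var in ("hbf", "hba") else np.inf
            hema[var] = round(_draw_trunc(rng, *mu_sd, upper), 2)
        age_row = None
        for key in _hema_group_key(klass, dip_key, mutation):
            row = config.hematology_params.get(key)
            if row and "age" in row:
                age_row = row["age"]
                break
        age = round(_draw_trunc(rng, *age_row, np.inf), 1) if age_row else None

        true_disp = _DISPLAY.get(klass, klass)
        hplc = true_disp
        flipped = False
        for (src, dst), p in config.mislabel.items():
            if src == true_disp and rng.random() < p:
                hplc = dst
                flipped = True
                break

        geno_rows.append(_genotype_row(sid, genotypes, catalog))
        pheno_rows.append({"sample_id": sid, "hplc_label": hplc,
                           "age": age, **hema})
        truth_rows.append({
            "sample_id": sid,
            "true_hb_genotype": klass,
            "true_diplotype": dip_key,
            "true_haplotypes": f"{lab1}|{lab2}",
            "true_beta_mutation": mutation or "",
            "hplc_label_assigned": hplc,
            "flip_applied": flipped,
        })

    cols = ["sample_id", *catalog.panel_order]
    return (
        pd.DataFrame(geno_rows, columns=cols),
        pd.DataFrame(pheno_rows, columns=["sample_id", "hplc_label", "age",
                                          *HEMATOLOGY_VARS]),
        pd.DataFrame(truth_rows),
    )


def _genotype_row(sid, genotypes, catalog) -> dict[str, str]:
    row = {"sample_id": sid}
    for vid in catalog.panel_order:
        gt = genotypes.get(vid)
        row[vid] = "./." if gt is None else f"{gt[0]}/{gt[1]}"
    return row


# ---------------------------------------------------------------------------
# Deterministic reference cohort
# ---------------------------------------------------------------------------

# (diplotype label pair, count) for the 154 haplotyped SS patients.
_SS_DIPLOTYPES: tuple[tuple[tuple[str, str], int], ...] = (
    (("AI", "AI"), 100),
    (("AI", "ATP-I"), 15),
    (("AI", "ATP-II"), 6),
    (("AI", "ATP-III"), 4),
    (("AI", "BEN"), 9),
    (("AI", "SEN"), 5),
    (("BEN", "BEN"), 4),
    (("AI", "BAN"), 4),
    (("CAM", "CAM"), 2),
    (("SEN", "SEN"), 2),
    (("BEN", "CAM"), 1),
    (("BEN", "ATP-I"), 1),
    (("AI", "CAM"), 1),
)

# Beta-S haplotype of the 66 S/beta-thal patients: the last four get the
# rarer backgrounds so that the beta-S chromosome table totals 378 with the
# published label counts (AI 308, BEN 22, SEN 9, BAN 5, CAM 8, ATP 26).
_SB_NON_AI: tuple[str, ...] = ("BEN", "BEN", "BAN", "CAM")

# The seven AS carriers: four haplotyped (S chromosome on AI x2, BEN, CAM),
# three with failed tag genotyping.
_AS_HAPLOTYPED: tuple[str, ...] = ("AI", "AI", "BEN", "CAM")


def _fixture_hema(group_keys: list[str], params, extra=None) -> dict[str, float]:
    """Group means as the hematology values (deterministic fixture)."""
    hema = {}
    for var in HEMATOLOGY_VARS:
        for key in group_keys:
            row = params.get(key)
            if row and var in row:
                hema[var] = row[var][0]
                break
    if extra:
        hema.update(extra)
    return hema


def paper_cohort_fixture(
    catalog: Catalog | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic 240-patient cohort reproducing the published tables.

    Composition (NGS-confirmed classes): 161 SS (154 haplotypable with the
    published diplotype counts, 7 with failed tag genotyping), 66 S/beta-thal
    with the published mutation spectrum, 4 SD, 7 AS, 1 AA, 1 beta-trait.
    HPLC labels implement the documented discordance (marginals 184 SS /
    54 Sβ / 2 SD; 14 HPLC-Sβ are SS by NGS). Hematology equals group means.

    Note: the source tables disagree on the S/beta-thal count (68 in the
    genotype distribution table vs 66 in the mutation spectrum); the fixture
    follows the mutation spectrum and the 378-chromosome haplotype
    arithmetic, which are mutually consistent.
    """
    catalog = catalog or load_catalog()
    params = _default_hematology_params()
    label_to_pattern = catalog.haplotype_table.labels
    missing_tags = list(catalog.tag_panel.snps[:3])

    geno_rows, pheno_rows = [], []
    counter = 0

    def add(klass, lab1, lab2, mutation, hplc, hema, age, unhaplotyped=False):
        nonlocal counter
        counter += 1
        sid = f"P{counter:03d}"
        pat1, pat2 = label_to_pattern[lab1], label_to_pattern[lab2]
        genotypes = _build_genotypes(catalog, klass, pat1, pat2, mutation)
        if unhaplotyped:
            for snp in missing_tags:
                genotypes[snp] = None
        geno_rows.append(_genotype_row(sid, genotypes, catalog))
        pheno_rows.append({"sample_id": sid, "hplc_label": hplc,
                           "age": age, **hema})

    # --- SS patients -----------------------------------------------------
    n_ss_mislabeled = 0
    for (lab1, lab2), n in _SS_DIPLOTYPES:
        dip_key = _diplotype_key(lab1, lab2)
        hema = _fixture_hema([f"SS:{dip_key}", "SS"], params)
        age = params.get(f"SS:{dip_key}", params["SS"]).get(
            "age", params["SS"]["age"]
        )[0]
        for _ in range(n):
            # The 14 false-positive Sβ diagnoses sit on AI/AI SS patients.
            if lab1 == lab2 == "AI" and n_ss_mislabeled < 14:
                hplc = "Sβ"
                n_ss_mislabeled += 1
            else:
                hplc = "SS"
            add("SS", lab1, lab2, None, hplc, hema, age)
    ss_base = _fixture_hema(["SS"], params)
    for _ in range(7):  # SS with failed tag genotyping
        add("SS", "AI", "AI", None, "SS", ss_base, params["SS"]["age"][0],
            unhaplotyped=True)

    # --- S/beta-thal patients -------------------------------------------
    sb_index = 0
    n_sb = sum(n for _, n in MUTATION_SPECTRUM)
    for vid, n in MUTATION_SPECTRUM:
        cls = catalog.variants[vid].var_class
        klass = "SB0" if cls == "BETA0" else "SBP"
        hema = _fixture_hema([f"Sβ:{vid}", "Sβ"], params)
        hema.pop("age", None)
        if klass == "SBP":
            hema["hba"] = _DEFAULT_HBA_PARAMS.get(vid, (0.0, 0.0))[0]
        else:
            hema["hba"] = 0.0
        age = params["Sβ"]["age"][0]
        for _ in range(n):
            # First 26 of the 66 were read as SS on HPLC.
            hplc = "SS" if sb_index < 26 else "Sβ"
            # The last four carry the rarer non-AI beta-S backgrounds.
            pos_from_end = n_sb - sb_index
            bs_label = (
                _SB_NON_AI[-pos_from_end] if pos_from_end <= len(_SB_NON_AI) else "AI"
            )
            add(klass, bs_label, bs_label, vid, hplc, hema, age)
            sb_index += 1

    # --- SD, AS, AA, beta-trait -----------------------------------------
    for k in range(4):
        add("SD", "AI", "AI", None, "SD" if k < 2 else "SS",
            _fixture_hema(["SD"], params), params["SD"]["age"][0],
            unhaplotyped=True)
    as_hema = _fixture_hema(["AS"], params)
    as_age = params["AS"]["age"][0]
    for k in range(7):
        if k < len(_AS_HAPLOTYPED):
            add("AS", _AS_HAPLOTYPED[k], _AS_HAPLOTYPED[k], None, "SS",
                as_hema, as_age)
        else:
            add("AS", "AI", "AI", None, "SS", as_hema, as_age, unhaplotyped=True)
    add("AA", "AI", "AI", None, "SS", _fixture_hema(["AA"], params),
        params["AA"]["age"][0])
    add("BTRAIT", "AI", "AI", "IVS-I-110", "SS", _fixture_hema(["β-trait"], params),
        params["β-trait"]["age"][0])

    cols = ["sample_id", *catalog.panel_order]
    geno = pd.DataFrame(geno_rows, columns=cols)
    pheno = pd.DataFrame(
        pheno_rows, columns=["sample_id", "hplc_label", "age", *HEMATOLOGY_VARS]
    )
    return geno, pheno


# ---------------------------------------------------------------------------
# Frame -> SampleRecord bridge
# ---------------------------------------------------------------------------

def to_sample_records(
    genotypes: pd.DataFrame, phenotypes: pd.DataFrame | None, catalog: Catalog
) -> list[SampleRecord]:
    """Parse simulator/fixture frames through the standard table readers,
    guaranteeing byte-for-byte equivalence with the TSV round trip."""
    import io as _io

    buf = _io.StringIO()
    genotypes.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    records = read_genotype_table(buf, catalog)
    if phenotypes is not None:
        from .genotype_io import read_phenotypes

        buf = _io.StringIO()
        phenotypes.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        attach_phenotypes(records, read_phenotypes(buf))
    return records
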