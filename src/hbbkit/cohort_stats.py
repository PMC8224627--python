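"""Cohort-level diagnostic and descriptive statistics.

Covers the reporting layer of the pipeline: the HPLC-vs-NGS confusion
matrix and concordance metrics for the S/beta-thal diagnosis, the
beta-thalassemia mutation spectrum, hematology summaries per group, the
diplotype frequency table for haplotyped SS patients, and a one-way ANOVA
of HbF across haplotype groups.

Two concordance conventions are implemented and always reported together.
The "paper" convention, common in diagnostic re-evaluation studies, scales
both metrics by the molecularly confirmed positive count: sensitivity =
(HPLC positives) / (NGS positives) and false-positive rate = (HPLC
positives not confirmed by NGS) / (NGS positives). The "standard"
convention is the textbook cross-tab arithmetic with NGS as truth:
sensitivity = TP/(TP+FN), FPR = FP/(FP+TN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import SampleRecord
from .hb_caller import HbGenotypeCall, display_label
from .haplotyper import DiplotypeCall
from .util import percent

__all__ = [
    "ConfusionMatrix",
    "ConcordanceMetrics",
    "build_confusion",
    "concordance_metrics",
    "concordance_from_marginals",
    "genotype_proportion",
    "mutation_frequency_table",
    "diplotype_table",
    "group_summary",
    "anova_hbf",
]


@dataclass
class ConfusionMatrix:
    """Cross-tabulation of HPLC labels (rows) against NGS calls (columns)."""

    labels: tuple[str, ...]
    cells: pd.DataFrame  # index = HPLC, columns = NGS

    @property
    def row_totals(self) -> pd.Series:
        return self.cells.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.cells.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.cells.to_numpy().sum())


@dataclass
class ConcordanceMetrics:
    """Sensitivity / false-positive rate for one target label, in percent."""

    target_label: str
    convention: str  # "paper" | "standard"
    sensitivity: float | None
    false_positive_rate: float | None
    numerators: dict[str, int] = field(default_factory=dict)
    denominators: dict[str, int] = field(default_factory=dict)


def build_confusion(
    hplc_labels: Mapping[str, str], ngs_calls: Iterable[HbGenotypeCall]
) -> ConfusionMatrix:
    """Cross-tabulate HPLC labels against (collapsed) NGS call labels.

    Both inputs must cover exactly the same samples; a sample present on one
    side only is fatal, listing the offenders.
    """
    ngs = {c.sample_id: display_label(c.label) for c in ngs_calls}
    only_hplc = sorted(set(hplc_labels) - set(ngs))
    only_ngs = sorted(set(ngs) - set(hplc_labels))
    if only_hplc or only_ngs:
        raise ValueError(
            f"sample sets differ: HPLC-only {only_hplc}, NGS-only {only_ngs}"
        )
    sids = sorted(hplc_labels)
    rows = [hplc_labels[s] for s in sids]
    cols = [ngs[s] for s in sids]
    labels = tuple(dict.fromkeys([*rows, *cols]))
    tab = pd.crosstab(pd.Series(rows, name="hplc"), pd.Series(cols, name="ngs"))
    tab = tab.reindex(index=labels, columns=labels, fill_value=0)
    return ConfusionMatrix(labels=labels, cells=tab)


def genotype_proportion(count: int, total: int) -> float:
    """Share of a genotype group in the cohort, in percent (half-up, 1 dp)."""
    return percent(count, total)


def concordance_from_marginals(
    hplc_positive: int,
    ngs_positive: int,
    false_positive: int,
    target_label: str = "Sβ",
) -> ConcordanceMetrics:
    """"Paper"-convention metrics straight from marginal counts.

    ``false_positive`` is the number of HPLC target-positives not confirmed
    by NGS. Both metrics are scaled by the NGS-confirmed positive count.
    """
    if ngs_positive == 0:
        return ConcordanceMetrics(target_label, "paper", None, None,
                                  denominators={"ngs_positive": 0})
    return ConcordanceMetrics(
        target_label=target_label,
        convention="paper",
        sensitivity=percent(hplc_positive, ngs_positive),
        false_positive_rate=percent(false_positive, ngs_positive),
        numerators={"sensitivity": hplc_positive,
                    "false_positive_rate": false_positive},
        denominators={"sensitivity": ngs_positive,
                      "false_positive_rate": ngs_positive},
    )


def concordance_metrics(
    matrix: ConfusionMatrix, target: str = "Sβ", convention: str = "paper"
) -> ConcordanceMetrics:
    """Concordance metrics for ``target`` under the chosen convention.

    Zero denominators leave the affected metric as None (flagged by
    omission from ``numerators``/``denominators``).
    """
    if target not in matrix.labels:
        raise ValueError(f"target label {target!r} not in matrix")
    cells = matrix.cells
    hplc_pos = int(matrix.row_totals.get(target, 0))
    ngs_pos = int(matrix.col_totals.get(target, 0))
    tp = int(cells.loc[target, target])
    if convention == "paper":
        return concordance_from_marginals(
            hplc_pos, ngs_pos, hplc_pos - tp, target_label=target
        )
    if convention != "standard":
        raise ValueError(f"unknown convention {convention!r}")
    fn = ngs_pos - tp
    fp = hplc_pos - tp
    tn = matrix.total - tp - fn - fp
    sens = percent(tp, tp + fn) if (tp + fn) else None
    fpr = percent(fp, fp + tn) if (fp + tn) else None
    m = ConcordanceMetrics(target, "standard", sens, fpr)
    if sens is not None:
        m.numerators["sensitivity"] = tp
        m.denominators["sensitivity"] = tp + fn
    if fpr is not None:
        m.numerators["false_positive_rate"] = fp
        m.denominators["false_positive_rate"] = fp + tn
    return m


def mutation_frequency_table(hb_calls: Iterable[HbGenotypeCall]) -> pd.DataFrame:
    """Beta-thal mutation spectrum among S/beta-thal compound heterozygotes.

    Counts each SB0/SBP call's mutation; percents are on the number of
    S/beta-thal patients. Rows are ordered by descending count, then by
    variant id for determinism. Columns: variant_id, n, percent.
    """
    sb = [c for c in hb_calls if c.label in ("SB0", "SBP")]
    if not sb:
        raise ValueError("no S/beta-thal calls in cohort")
    counts: dict[str, int] = {}
    for c in sb:
        counts[c.beta_thal_variant] = counts.get(c.beta_thal_variant, 0) + 1
    total = len(sb)
    rows = [
        {"variant_id": vid, "n": n, "percent": percent(n, total)}
        for vid, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows)


def diplotype_table(
    diplotypes: Mapping[str, DiplotypeCall],
    hb_calls: Iterable[HbGenotypeCall],
    group_label: str = "SS",
) -> pd.DataFrame:
    """Diplotype frequency table for haplotyped patients of one Hb genotype.

    Pairs are keyed by their unordered class labels with all atypical
    haplotypes pooled as "ATP" (e.g. "AI/ATP"); the member with the larger
    cohort count is printed first. Percents are on the number of haplotyped
    patients of the group. Columns: diplotype, n, percent.
    """
    wanted = {c.sample_id for c in hb_calls if c.label == group_label}
    pairs: dict[tuple[str, str], int] = {}
    for sid, dip in diplotypes.items():
        if sid not in wanted:
            continue
        labels = tuple(
            "ATP" if h.label.startswith("ATP") else h.label for h in dip.pair
        )
        key = tuple(sorted(labels))
        pairs[key] = pairs.get(key, 0) + 1
    if not pairs:
        raise ValueError(f"no haplotyped {group_label} samples")
    total = sum(pairs.values())
    # Order haplotype names within a pair by overall chromosome abundance.
    chrom_counts: dict[str, int] = {}
    for (a, b), n in pairs.items():
        chrom_counts[a] = chrom_counts.get(a, 0) + n
        chrom_counts[b] = chrom_counts.get(b, 0) + n
    rows = []
    for key, n in sorted(pairs.items(), key=lambda kv: (-kv[1], kv[0])):
        a, b = sorted(key, key=lambda lbl: (-chrom_counts[lbl], lbl))
        rows.append(
            {"diplotype": f"{a}/{b}", "n": n, "percent": percent(n, total)}
        )
    return pd.DataFrame(rows)


def group_summary(
    samples: Iterable[SampleRecord],
    grouping: Mapping[str, str],
    variables: Sequence[str] = ("age", "hb", "rbc", "mcv", "mch", "mchc", "hbf"),
) -> pd.DataFrame:
    """Per-group n, mean and SD of age and hematology variables.

    ``grouping`` maps sample_id -> group label; samples without a group or
    without hematology are skipped. SD uses the sample convention (n-1) and
    is absent (NaN) for single-patient groups, matching how cohort tables
    print bare values for n = 1. Groups are ordered by descending n.
    """
    records = []
    for rec in samples:
        grp = grouping.get(rec.sample_id)
        if grp is None:
            continue
        row: dict[str, object] = {"group": grp}
        for var in variables:
            if var == "age":
                row["age"] = rec.age_years
            else:
                row[var] = rec.hematology.get(var)
        records.append(row)
    if not records:
        return pd.DataFrame(columns=["group", "n"])
    df = pd.DataFrame(records)
    out_rows = []
    for grp, sub in df.groupby("group"):
        row: dict[str, object] = {"group": grp, "n": len(sub)}
        for var in variables:
            vals = sub[var].dropna().astype(float)
            row[f"{var}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{var}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        out_rows.append(row)
    out = pd.DataFrame(out_rows).sort_values(
        ["n", "group"], ascending=[False, True], ignore_index=True
    )
    return out


def anova_hbf(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of HbF across haplotype groups.

    Requires at least two groups with at least two observations each
    (degenerate groups are reported by name). Returns (F, p). When all
    observations are identical the F statistic is 0 and p is 1.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    bad = sorted(name for name, vals in groups.items() if len(vals) < 2)
    if bad:
        raise ValueError(f"groups with fewer than two observations: {bad}")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if all(np.ptp(np.concatenate(arrays)) == 0 for _ in [0]):
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)
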