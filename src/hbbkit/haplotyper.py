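"""Beta-S gene-cluster haplotyping: EM phasing, classification, HWE.

Phasing is the Excoffier–Slatkin style EM for multilocus haplotype
frequencies from unphased genotypes. The five tag SNPs are phased jointly
with rs334 as a sixth site, so that for S/beta-thal compound heterozygotes
and AS carriers the chromosome carrying the sickle allele is identified
statistically — without that, "which haplotype is the beta-S one" is
uncomputable for anything but SS homozygotes.

E-step: each sample distributes posterior mass over the ordered haplotype
pairs compatible with its unphased genotypes, proportional to
``f(h1) * f(h2)``; missing sites are marginalized by summing over both
symbols. M-step: frequencies are the expected haplotype counts over ``2n``
chromosomes. The likelihood is non-decreasing every iteration, which the
test suite asserts on random cohorts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .catalog import Catalog, HaplotypeTable
from .genotype_io import SampleRecord
from .hb_caller import HbGenotypeCall
from .util import percent

logger = logging.getLogger(__name__)

__all__ = [
    "Haplotype",
    "DiplotypeCall",
    "FrequencyEstimate",
    "HweResult",
    "BsAssignment",
    "classify_haplotype",
    "em_frequencies",
    "em_phase",
    "assign_bs_haplotypes",
    "chromosome_frequencies",
    "hwe_test",
    "genotype_counts_for_variant",
]

# An allele configuration of one chromosome across the phased sites.
_Hap = tuple[str, ...]


@dataclass(frozen=True)
class Haplotype:
    """A classified chromosome: 5-symbol tag pattern plus rs334 state."""

    pattern: str
    s_allele: bool
    label: str


@dataclass
class DiplotypeCall:
    """Maximum-posterior phased haplotype pair for one sample.

    ``pair`` is ordered lexicographically for determinism; ``alternatives``
    lists the remaining compatible unordered pairs with their posteriors
    (all posteriors sum to 1 over pair + alternatives).
    """

    sample_id: str
    pair: tuple[Haplotype, Haplotype]
    posterior: float
    alternatives: list[tuple[tuple[Haplotype, Haplotype], float]] = field(
        default_factory=list
    )


@dataclass
class FrequencyEstimate:
    """EM haplotype-frequency estimate over the phased sites."""

    frequencies: dict[_Hap, float]
    log_likelihood: float
    n_iterations: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)


@dataclass
class HweResult:
    """One-locus Hardy-Weinberg chi-square test (1 df, no correction)."""

    variant_id: str
    genotype_counts: tuple[int, int, int]  # hom-ref, het, hom-alt
    chi2: float
    p_value: float
    flags: list[str] = field(default_factory=list)


@dataclass
class BsAssignment:
    """Beta-S chromosomes contributed by one sample to frequency tables."""

    sample_id: str
    haplotypes: list[Haplotype]
    ambiguous: bool = False
    reason: str | None = None


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_haplotype(pattern: str, table: HaplotypeTable) -> str:
    """Class label for a 5-symbol pattern.

    Canonical patterns map to their classical label; any other valid pattern
    gets the fallback name ``ATP(<pattern>)`` (atypical, never silently
    merged). Invalid symbols raise, naming the offending SNP position.
    """
    n_sites = len(next(iter(table.patterns)))
    if len(pattern) != n_sites:
        raise ValueError(f"pattern {pattern!r} must have {n_sites} symbols")
    for i in range(n_sites):
        valid = {p[i] for p in table.patterns}
        if pattern[i] not in valid:
            raise ValueError(
                f"invalid symbol {pattern[i]!r} at tag SNP position {i + 1} "
                f"(valid: {sorted(valid)})"
            )
    return table.patterns.get(pattern, f"ATP({pattern})")


# ---------------------------------------------------------------------------
# EM core (generic over sites)
# ---------------------------------------------------------------------------

def _compatible_ordered_pairs(
    genotype: Sequence[tuple[str, str] | None],
    site_symbols: Sequence[Sequence[str]],
) -> list[tuple[_Hap, _Hap]]:
    """All ordered haplotype pairs compatible with one unphased genotype.

    A known het site contributes both orientations; a known hom site one;
    a missing site contributes all four symbol combinations (marginalized).
    """
    per_site: list[list[tuple[str, str]]] = []
    for gt, symbols in zip(genotype, site_symbols):
        if gt is None:
            per_site.append([(x, y) for x in symbols for y in symbols])
        else:
            a, b = gt
            if a not in symbols or b not in symbols:
                raise ValueError(f"genotype symbol {gt} not in site alphabet {symbols}")
            per_site.append([(a, b)] if a == b else [(a, b), (b, a)])
    pairs = []
    for combo in itertools.product(*per_site):
        h1 = tuple(x for x, _ in combo)
        h2 = tuple(y for _, y in combo)
        pairs.append((h1, h2))
    return pairs


def em_frequencies(
    genotypes: Sequence[Sequence[tuple[str, str] | None]],
    site_symbols: Sequence[Sequence[str]],
    max_iter: int = 1000,
    tol: float = 1e-8,
    restarts: int = 1,
    seed: int | None = None,
) -> tuple[FrequencyEstimate, list[dict[tuple[_Hap, _Hap], float]]]:
    """EM haplotype-frequency estimation from unphased genotypes.

    Returns the frequency estimate plus, per sample, the posterior over
    compatible *unordered* pairs (keys ordered lexicographically). The
    deterministic default (one restart) initializes uniformly over the
    haplotypes compatible with the cohort; extra restarts draw Dirichlet
    initial points from ``seed`` and keep the highest-likelihood solution.
    """
    if len(genotypes) == 0:
        raise ValueError("at least one sample is required")

    sample_pairs = [_compatible_ordered_pairs(g, site_symbols) for g in genotypes]
    hap_index: dict[_Hap, int] = {}
    for pairs in sample_pairs:
        for h1, h2 in pairs:
            hap_index.setdefault(h1, len(hap_index))
            hap_index.setdefault(h2, len(hap_index))
    haps = list(hap_index)
    H = len(haps)
    n = len(genotypes)
    idx = [
        (np.array([hap_index[h1] for h1, _ in pairs]),
         np.array([hap_index[h2] for _, h2 in pairs]))
        for pairs in sample_pairs
    ]

    def run(f0: np.ndarray) -> tuple[np.ndarray, list[float], int, bool]:
        f = f0.copy()
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            counts = np.zeros(H)
            loglik = 0.0
            for i1, i2 in idx:
                w = f[i1] * f[i2]
                z = w.sum()
                if z <= 0:
                    # All mass vanished (can happen transiently with sparse
                    # inits); fall back to uniform weights for this sample.
                    w = np.ones_like(w)
                    z = w.sum()
                else:
                    loglik += np.log(z)
                w /= z
                np.add.at(counts, i1, w)
                np.add.at(counts, i2, w)
            f_new = counts / (2 * n)
            trace.append(loglik)
            if np.max(np.abs(f_new - f)) < tol:
                f = f_new
                converged = True
                break
            f = f_new
        return f, trace, it, converged

    inits = [np.full(H, 1.0 / H)]
    if restarts > 1:
        rng = np.random.default_rng(seed)
        inits += [rng.dirichlet(np.ones(H)) for _ in range(restarts - 1)]

    best = None
    for f0 in inits:
        f, trace, it, conv = run(f0)
        if best is None or trace[-1] > best[1][-1]:
            best = (f, trace, it, conv)
    f, trace, it, conv = best

    # Per-sample posterior over unordered pairs at the final frequencies.
    posteriors: list[dict[tuple[_Hap, _Hap], float]] = []
    for pairs, (i1, i2) in zip(sample_pairs, idx):
        w = f[i1] * f[i2]
        z = w.sum()
        w = w / z if z > 0 else np.full_like(w, 1.0 / len(w))
        post: dict[tuple[_Hap, _Hap], float] = {}
        for (h1, h2), wk in zip(pairs, w):
            key = (h1, h2) if h1 <= h2 else (h2, h1)
            post[key] = post.get(key, 0.0) + float(wk)
        posteriors.append(post)

    freqs = {h: float(f[hap_index[h]]) for h in haps}
    est = FrequencyEstimate(
        frequencies=freqs,
        log_likelihood=float(trace[-1]),
        n_iterations=it,
        converged=conv,
        loglik_trace=[float(x) for x in trace],
    )
    return est, posteriors


# ---------------------------------------------------------------------------
# Cohort-level phasing over the tag panel + rs334
# ---------------------------------------------------------------------------

def em_phase(
    samples: Iterable[SampleRecord],
    catalog: Catalog,
    max_iter: int = 1000,
    tol: float = 1e-8,
    restarts: int = 1,
    seed: int | None = None,
    max_missing_tags: int = 2,
) -> tuple[FrequencyEstimate, dict[str, DiplotypeCall], dict[str, str]]:
    """Phase a cohort over the 5 tag SNPs plus rs334.

    Samples missing more than ``max_missing_tags`` tag-SNP genotypes are
    excluded (logged), emulating a "successfully haplotyped" subset; the
    rest have missing sites marginalized in the E-step. Returns the
    frequency estimate, per-sample maximum-posterior diplotype calls (ties
    broken toward the lexicographically smallest pattern pair), and the
    excluded samples with reasons.
    """
    panel = catalog.tag_panel
    rs334 = catalog.rs334
    site_ids = [*panel.snps, "rs334"]
    site_symbols: list[tuple[str, ...]] = [
        panel.symbols(s) for s in panel.snps
    ] + [(rs334.ref_allele, rs334.alt_allele)]

    kept: list[SampleRecord] = []
    excluded: dict[str, str] = {}
    genotypes = []
    for rec in samples:
        gts = [rec.genotype(vid) for vid in site_ids]
        n_missing_tags = sum(1 for g in gts[:-1] if g is None)
        if n_missing_tags > max_missing_tags:
            excluded[rec.sample_id] = f"missing {n_missing_tags} tag SNP genotypes"
            continue
        bad = next(
            (
                (vid, g)
                for vid, g, syms in zip(site_ids, gts, site_symbols)
                if g is not None and any(a not in syms for a in g)
            ),
            None,
        )
        if bad is not None:
            excluded[rec.sample_id] = f"invalid genotype {bad[1]} at {bad[0]}"
            continue
        kept.append(rec)
        genotypes.append(gts)
    for sid, why in excluded.items():
        logger.info("excluded from haplotyping: %s (%s)", sid, why)
    if not kept:
        raise ValueError("no samples left to phase")

    est, posteriors = em_frequencies(
        genotypes, site_symbols, max_iter=max_iter, tol=tol,
        restarts=restarts, seed=seed,
    )

    table = catalog.haplotype_table
    s_alt = rs334.alt_allele

    def to_hap(h: _Hap) -> Haplotype:
        pattern = "".join(h[:-1])
        return Haplotype(
            pattern=pattern, s_allele=(h[-1] == s_alt),
            label=classify_haplotype(pattern, table),
        )

    calls: dict[str, DiplotypeCall] = {}
    for rec, post in zip(kept, posteriors):
        # Sort by posterior (desc), then lexicographically for determinism.
        ranked = sorted(post.items(), key=lambda kv: (-kv[1], kv[0]))
        (h1, h2), p = ranked[0]
        calls[rec.sample_id] = DiplotypeCall(
            sample_id=rec.sample_id,
            pair=(to_hap(h1), to_hap(h2)),
            posterior=p,
            alternatives=[((to_hap(a), to_hap(b)), q) for (a, b), q in ranked[1:]],
        )
    return est, calls, excluded


# ---------------------------------------------------------------------------
# Beta-S chromosome assignment and frequencies
# ---------------------------------------------------------------------------

def assign_bs_haplotypes(
    diplotypes: Mapping[str, DiplotypeCall],
    hb_calls: Iterable[HbGenotypeCall],
    ambiguity_tol: float = 1e-6,
) -> list[BsAssignment]:
    """Which chromosomes of each sample carry the sickle allele.

    SS samples contribute both chromosomes; S-compound samples (SB0/SBP, SD)
    and AS carriers contribute exactly the phased chromosome bearing the
    rs334 sickle allele; AA / beta-trait / unresolved samples contribute
    none. A sample whose top two phase configurations are within
    ``ambiguity_tol`` posterior of each other is flagged AMBIGUOUS and
    excluded from frequency tables (logged).
    """
    out: list[BsAssignment] = []
    for call in hb_calls:
        dip = diplotypes.get(call.sample_id)
        if dip is None:
            continue
        if call.label in ("AA", "BTRAIT", "UNRESOLVED"):
            out.append(BsAssignment(call.sample_id, []))
            continue
        if dip.alternatives and dip.posterior - dip.alternatives[0][1] < ambiguity_tol:
            logger.warning(
                "sample %s: phase ambiguity (posterior %.6f vs %.6f) -> AMBIGUOUS",
                call.sample_id, dip.posterior, dip.alternatives[0][1],
            )
            out.append(
                BsAssignment(call.sample_id, [], ambiguous=True,
                             reason="posterior phase ambiguity")
            )
            continue
        h1, h2 = dip.pair
        if call.label == "SS":
            out.append(BsAssignment(call.sample_id, [h1, h2]))
        else:  # SB0 / SBP / SD / AS: exactly one chromosome carries S
            s_chroms = [h for h in (h1, h2) if h.s_allele]
            if len(s_chroms) != 1:
                out.append(
                    BsAssignment(call.sample_id, [], ambiguous=True,
                                 reason="phased rs334 dose inconsistent with call")
                )
                continue
            out.append(BsAssignment(call.sample_id, s_chroms))
    return out


def chromosome_frequencies(
    assignments: Iterable[BsAssignment],
) -> dict[str, tuple[int, float]]:
    """Per-label beta-S chromosome counts and percents (of all counted).

    Atypical labels (ATP-I/II/III and ATP(<pattern>)) are pooled as "ATP",
    the convention of cohort frequency tables. Percents are half-up to one
    decimal; counts sum to the total number of beta-S chromosomes.
    """
    counts: dict[str, int] = {}
    for a in assignments:
        if a.ambiguous:
            continue
        for h in a.haplotypes:
            label = "ATP" if h.label.startswith("ATP") else h.label
            counts[label] = counts.get(label, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no beta-S chromosomes to tabulate")
    return {
        lbl: (c, percent(c, total))
        for lbl, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    }


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

def hwe_test(
    genotype_counts: tuple[int, int, int], variant_id: str = ""
) -> HweResult:
    """1-df chi-square HWE test of (hom-ref, het, hom-alt) counts.

    Expectations are ``p^2, 2pq, q^2`` from the sample allele frequencies;
    no continuity correction. Monomorphic sites return chi2=0, p=1 with a
    MONOMORPHIC flag; any expected cell below 5 raises a SMALL_COUNTS flag
    (the chi-square approximation is then unreliable).
    """
    hr, het, ha = genotype_counts
    if min(hr, het, ha) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = hr + het + ha
    if n == 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * hr + het) / (2 * n)
    q = 1.0 - p
    flags: list[str] = []
    if p == 0.0 or q == 0.0:
        return HweResult(variant_id, genotype_counts, 0.0, 1.0, ["MONOMORPHIC"])
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    if expected.min() < 5:
        flags.append("SMALL_COUNTS")
    observed = np.array([hr, het, ha], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(variant_id, genotype_counts, chi2, p_value, flags)


def genotype_counts_for_variant(
    samples: Iterable[SampleRecord], catalog: Catalog, variant_id: str
) -> tuple[int, int, int]:
    """(hom-ref, het, hom-alt) counts for one panel variant (MISSING skipped)."""
    v = catalog.variants[variant_id]
    ref_sym, alt_sym = catalog.allele_symbols(variant_id)
    hr = het = ha = 0
    for rec in samples:
        gt = rec.genotype(variant_id)
        if gt is None:
            continue
        n_alt = sum(1 for a in gt if a == alt_sym)
        if n_alt == 0:
            hr += 1
        elif n_alt == 1:
            het += 1
        else:
            ha += 1
    return hr, het, ha
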