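# Methods

This note documents the models, conventions and numerical choices behind
`hbbkit`, and what the synthetic cohorts do and do not establish about real
data.

## Variant catalog

The panel is configuration, not code (`src/hbbkit/data/default_catalog.yaml`):
the HbS variant (rs334), HbD-Punjab (c.364G>C — the only common HbD allele
in the Gulf region; other HbD alleles can be added in config), thirteen
β-thalassemia alleles with a functional class, and the five haplotype-tag
SNPs with their allele→symbol encoding. Classes are β⁰ (no β-globin
output), β⁺ (reduced), β⁺⁺ (mildly reduced). IVS-I-6 (c.92+6T>C) is classed
β⁺⁺ on phenotypic grounds — carriers present near-AS severity — though some
tabulations list it as plain β⁺; the class is data and can be edited.
IVS-II-1 is recorded with its HGVS string `c.315+1G>T` verbatim even though
legacy literature writes the substitution as G→A; the id and HGVS string
are opaque keys, and alleles follow the HGVS form.

Genomic coordinates (GRCh38) are carried only for VCF record matching,
which additionally falls back on the ID column; no classification logic
reads a position, so a coordinate error cannot change a call. The allele
encoding table is the single audited point where strand/representation
ambiguity is resolved (notably rs7482144, reported as C>T or G>A depending
on strand, and rs3834466, where the shorter allele T is symbol "1" and the
TT duplication "2").

## Genotype calling

Calls are a pure function of the genotype map and the catalog. The rules
(README table) assume a sample heterozygous for both rs334 and a β-thal
allele carries them in trans — true compound heterozygosity. HbS-in-cis
alleles are not represented in the populations this panel targets; the
assumption is recorded in the call's notes so downstream users can see it.
Combinations outside the rule table return UNRESOLVED with an explanatory
note rather than a guess, because a silent wrong call would contaminate the
concordance statistics.

## EM phasing

Haplotype frequencies are estimated by the standard EM for multilocus
haplotypes from unphased genotypes. Sites: the five tag SNPs plus rs334.
Including rs334 is a deliberate modeling choice — for Sβ-thal and AS
samples the question "which chromosome carries S" is otherwise
unanswerable, and β^S^-chromosome frequency tables require it.

Numerical choices:

* **Initialization** — uniform over the haplotypes compatible with the
  cohort; one restart by default, so the default run is fully
  deterministic. Extra restarts (Dirichlet starts from a seed) are exposed
  for rugged likelihoods.
* **Convergence** — max |Δf| < 1e-8 or 1000 iterations. The log-likelihood
  is non-decreasing by construction; the test suite asserts it on random
  cohorts.
* **Missing data** — missing sites are marginalized in the E-step (both
  symbols allowed per chromosome). Samples missing more than two tag-SNP
  genotypes are excluded with a logged reason, mirroring how panel studies
  report a "successfully haplotyped" subset; exclusion thresholds are
  arguments, not constants.
* **Tie-breaking** — the reported diplotype is the maximum-posterior
  unordered pair; exact ties resolve to the lexicographically smallest
  pattern pair. A sample whose top two configurations are within 1e-6
  posterior is flagged AMBIGUOUS in β^S^ assignment and left out of
  frequency tables with a warning.

Classification is table lookup on the 5-symbol pattern. Only CCCG2, TTCG2
and TCCG2 carry the ATP-I/II/III names; any other non-canonical pattern is
reported as `ATP(<pattern>)` and never merged silently. "CAR" is accepted
as a synonym of BAN in inputs; output uses BAN.

## Hardy–Weinberg testing

Per-variant 1-df χ² of observed genotype counts against p², 2pq, q² from
the sample allele frequencies, no continuity correction; p-value from the
upper tail. An exact test is a non-goal. Monomorphic sites return χ²=0,
p=1 flagged MONOMORPHIC; any expected cell below 5 raises a SMALL_COUNTS
flag since the χ² approximation is then unreliable. Note that in a disease
cohort rs334 and haplotype-tagging sites are strongly selected and are not
expected to sit in HWE; the flags report, they do not filter.

## Concordance conventions

Diagnostic re-evaluation studies commonly scale both agreement metrics by
the molecularly confirmed positive count: sensitivity = HPLC⁺/NGS⁺,
false-positive rate = (HPLC⁺ not confirmed)/NGS⁺. This "paper" convention
is the default; the textbook cross-tab convention (sensitivity =
TP/(TP+FN), FPR = FP/(FP+TN), NGS as truth) is always computed alongside,
and every metric carries its numerator and denominator so nothing is
hidden behind a percentage. Percents print one decimal, rounded half-up; a
k-row percent column can therefore drift from 100 by up to 0.05·k.

Summary tables use sample SD (n−1); single-patient groups report no SD,
matching how cohort tables print bare values for n = 1. ANOVA of HbF is
one-way fixed-effects on raw values; no multiple-testing correction is
applied because single tests are reported.

## Synthetic cohorts

`simulate_cohort` emulates, per sample: genotype class from a categorical
mix (defaults: the NGS-confirmed distribution of a 240-patient Gulf cohort
— 67% SS, 27.5% Sβ-thal, plus SD/AS/AA/β-trait singletons); two
gene-cluster haplotypes (β^S^ chromosomes from the published frequencies —
AI 0.815, BEN 0.058, SEN 0.024, BAN 0.013, CAM 0.021, atypicals 0.069
split ATP-I 0.040 / ATP-II 0.017 / ATP-III 0.012 by their cohort
proportions; non-S chromosomes default to the same distribution, as the
study populations provide no separate estimate); one β-thal allele for
Sβ/β-trait samples from the 13-allele spectrum restricted to the class;
hematology from independent truncated normals per group (diplotype-specific
for SS, mutation-specific for Sβ, with base-group fallback); residual HbA
for Sβ⁺ samples per mutation (IVS-I-110 15.5±6.2%, IVS-I-5 0, IVS-I-6
25.1%); an HPLC label through independent Bernoulli mislabel flows
(defaults implied by the documented discordance counts, e.g. true-Sβ→HPLC-SS
at 26/66); and per-site missingness (default 0 — haplotyping failure is
modeled explicitly by the reference cohort instead). Same seed, same
cohort, byte for byte.

Known limitations of the generator, hence of what green tests show about
real data: hematology variables are drawn independently (the sources print
only means ± SD, no covariances — real MCV/MCH are strongly correlated);
linkage is modeled only across the six phased sites; mislabeling is
independent per sample rather than driven by HbA2 levels; and a few
published dispersions are kept verbatim even where they are evident
misprints (SS Hb 11.2±9.7, AI/AI Hb 11.2±7.5 g/dL), absorbed by truncation
at zero and excluded from targets. Carrier/normal group hematology (AA, AS,
SD, β-trait) is not tabulated by the source studies; defaults are
clinically plausible values fixed once in `synthetic_cohort.py`.

`paper_cohort_fixture` is the deterministic counterpart: 240 patients whose
composition reproduces the published tables exactly — 154 haplotypable SS
with the printed diplotype counts, 66 Sβ-thal with the printed mutation
spectrum, 378 β^S^ chromosomes with the printed label counts (AI 308 =
81.5%), HPLC marginals 184/54/2 with the 14 documented false-positive Sβ
diagnoses — with hematology set to group means so summary tables are
exactly reproducible. Two source-table tensions are resolved in the
fixture's composition: the genotype-distribution table's Sβ count (68)
disagrees with the mutation spectrum (66 patients) and with the
378-chromosome arithmetic (154×2 + 70); the fixture follows the latter
two, which are mutually consistent, carrying 161 SS instead of 159. The
printed marginals also force discordance flows beyond the documented ones;
the completion chosen keeps the documented false-positive count (14) exact
and assigns the remaining flow to HPLC-SS rows. Single-S backgrounds in the
fixture are tag-homozygous, so their phase is identifiable by construction;
heterozygous SS diplotypes are resolved by the EM through the cohort's
strong AI anchor.

## Problem sizes

Default test and acceptance runs use the 240-patient reference cohort,
simulated cohorts of 100–5,000 samples, 3-site EM-vs-oracle cohorts of
14–16 samples, and 1,000-replicate ANOVA calibration; these sizes give
stable statistics (binomial/normal SEs well inside the asserted bounds)
while keeping any single check in seconds.
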