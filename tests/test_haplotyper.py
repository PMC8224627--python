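import numpy as np
import pytest
from hypothesis import given, strategies as st

import hbbkit as hk
from hbbkit.haplotyper import BsAssignment, DiplotypeCall, Haplotype

from _oracles import maximize_likelihood

BINARY_SITES_3 = [("A", "a"), ("B", "b"), ("C", "c")]


def random_genotypes(rng, n, site_symbols, freqs=None, missing_p=0.0):
    """Draw unphased genotypes from random haplotype frequencies."""
    haps = [tuple(s[i] for s, i in zip(site_symbols, combo))
            for combo in np.ndindex(*[len(s) for s in site_symbols])]
    if freqs is None:
        freqs = rng.dirichlet(np.ones(len(haps)))
    out = []
    for _ in range(n):
        h1 = haps[rng.choice(len(haps), p=freqs)]
        h2 = haps[rng.choice(len(haps), p=freqs)]
        g = []
        for a, b in zip(h1, h2):
            if rng.random() < missing_p:
                g.append(None)
            else:
                g.append(tuple(sorted((a, b))))
        out.append(g)
    return out


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

class TestClassify:
    @pytest.mark.parametrize(
        "pattern,label",
        [
            ("TTCA2", "AI"),
            ("TTCA1", "SEN"),
            ("TTCG1", "BEN"),
            ("CCCG1", "BAN"),
            ("TCAG1", "CAM"),
            ("CCCG2", "ATP-I"),
            ("TTCG2", "ATP-II"),
            ("TCCG2", "ATP-III"),
        ],
    )
    def test_canonical_patterns(self, catalog, pattern, label):
        assert hk.classify_haplotype(pattern, catalog.haplotype_table) == label

    def test_novel_pattern_gets_fallback_name(self, catalog):
        assert hk.classify_haplotype("TCAG2", catalog.haplotype_table) == "ATP(TCAG2)"

    def test_invalid_symbol_names_the_site(self, catalog):
        with pytest.raises(ValueError, match="position 5"):
            hk.classify_haplotype("TTCA3", catalog.haplotype_table)

    def test_bijection_on_canonical_patterns(self, catalog):
        table = catalog.haplotype_table
        seen = {hk.classify_haplotype(p, table) for p in table.patterns}
        assert seen == set(table.patterns.values())
        assert len(seen) == 8


# ---------------------------------------------------------------------------
# EM phasing
# ---------------------------------------------------------------------------

class TestEm:
    def test_homozygous_cohort_is_allele_counting(self):
        """With no phase ambiguity, posteriors are 1 and frequencies are
        direct chromosome counts."""
        g = [
            [("A", "A"), ("B", "B")],
            [("A", "A"), ("B", "B")],
            [("a", "a"), ("b", "b")],
        ]
        est, posts = hk.em_frequencies(g, [("A", "a"), ("B", "b")])
        assert est.converged
        assert est.frequencies[("A", "B")] == pytest.approx(4 / 6)
        assert est.frequencies[("a", "b")] == pytest.approx(2 / 6)
        for post in posts:
            assert max(post.values()) == pytest.approx(1.0)

    def test_single_het_site_equals_allele_counting(self):
        """Samples with at most one het site have no phase ambiguity, so EM
        must equal direct allele counting exactly."""
        g = [
            [("A", "a"), ("B", "B")],
            [("A", "A"), ("B", "b")],
            [("A", "A"), ("B", "B")],
        ]
        est, _ = hk.em_frequencies(g, [("A", "a"), ("B", "b")])
        assert est.frequencies[("A", "B")] == pytest.approx(4 / 6, abs=1e-9)
        assert est.frequencies[("a", "B")] == pytest.approx(1 / 6, abs=1e-9)
        assert est.frequencies[("A", "b")] == pytest.approx(1 / 6, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_likelihood_maximization(self, seed):
        """EM solution attains the simplex-optimized maximum likelihood
        (independent SLSQP oracle) within 1e-4 on small 3-site cohorts."""
        rng = np.random.default_rng(seed)
        g = random_genotypes(rng, 14, BINARY_SITES_3)
        est, _ = hk.em_frequencies(g, BINARY_SITES_3, restarts=5, seed=seed)
        oracle_freqs, oracle_ll = maximize_likelihood(g, BINARY_SITES_3, seed=seed)
        assert est.log_likelihood == pytest.approx(oracle_ll, abs=1e-4)
        for hap, f in oracle_freqs.items():
            assert est.frequencies.get(hap, 0.0) == pytest.approx(f, abs=1e-3)

    @given(st.integers(0, 10_000))
    def test_loglik_monotone_and_posteriors_normalized(self, seed):
        rng = np.random.default_rng(seed)
        g = random_genotypes(rng, 12, BINARY_SITES_3, missing_p=0.1)
        est, posts = hk.em_frequencies(g, BINARY_SITES_3)
        trace = np.array(est.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)
        assert sum(est.frequencies.values()) == pytest.approx(1.0, abs=1e-9)
        for post in posts:
            assert sum(post.values()) == pytest.approx(1.0, abs=1e-9)

    def test_order_invariance(self, catalog, reference_cohort):
        """Cohort frequencies do not depend on sample input order."""
        fwd, _, _ = hk.em_phase(reference_cohort[:80], catalog)
        rev, _, _ = hk.em_phase(list(reversed(reference_cohort[:80])), catalog)
        for hap, f in fwd.frequencies.items():
            assert rev.frequencies.get(hap, 0.0) == pytest.approx(f, abs=1e-6)

    def test_excessive_missingness_excludes_sample(self, catalog, reference_cohort):
        _, dips, excluded = hk.em_phase(reference_cohort, catalog)
        # 7 SS + 4 SD + 3 AS tag-genotyping failures in the reference cohort
        assert len(excluded) == 14
        assert len(dips) == 226
        assert all("missing" in why for why in excluded.values())


# ---------------------------------------------------------------------------
# Beta-S assignment and chromosome frequencies
# ---------------------------------------------------------------------------

def _hap(pattern, s, catalog):
    return Haplotype(pattern, s, hk.classify_haplotype(pattern, catalog.haplotype_table))


class TestBsAssignment:
    def test_contributions_by_genotype_class(self, catalog):
        ai_s = _hap("TTCA2", True, catalog)
        atp_s = _hap("CCCG2", True, catalog)
        ai_ns = _hap("TTCA2", False, catalog)
        dips = {
            "ss": DiplotypeCall("ss", (ai_s, atp_s), 1.0),
            "sb": DiplotypeCall("sb", (ai_ns, ai_s), 1.0),
            "aa": DiplotypeCall("aa", (ai_ns, ai_ns), 1.0),
        }
        calls = [
            hk.HbGenotypeCall("ss", "SS"),
            hk.HbGenotypeCall("sb", "SB0", beta_thal_variant="CD39"),
            hk.HbGenotypeCall("aa", "AA"),
        ]
        assigns = {a.sample_id: a for a in hk.assign_bs_haplotypes(dips, calls)}
        assert [h.label for h in assigns["ss"].haplotypes] == ["AI", "ATP-I"]
        assert [h.s_allele for h in assigns["sb"].haplotypes] == [True]
        assert assigns["sb"].haplotypes[0].label == "AI"
        assert assigns["aa"].haplotypes == []

    def test_phase_ambiguity_is_flagged_and_excluded(self, catalog):
        ai = _hap("TTCA2", True, catalog)
        ben = _hap("TTCG1", True, catalog)
        tie = DiplotypeCall(
            "x", (ai, ai), 0.5, alternatives=[((ben, ben), 0.5)]
        )
        calls = [hk.HbGenotypeCall("x", "SS")]
        (a,) = hk.assign_bs_haplotypes({"x": tie}, calls)
        assert a.ambiguous
        with pytest.raises(ValueError):
            hk.chromosome_frequencies([a])

    def test_single_ss_sample_frequencies(self, catalog):
        ai = _hap("TTCA2", True, catalog)
        assigns = [BsAssignment("s", [ai, ai])]
        assert hk.chromosome_frequencies(assigns) == {"AI": (2, 100.0)}


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

class TestHwe:
    def test_exact_proportions_give_zero(self):
        res = hk.hwe_test((25, 50, 25))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_no_hets_matches_direct_formula(self):
        """(50, 0, 50): p=q=1/2, expected (25, 50, 25); chi-square evaluated
        directly from the definition."""
        obs = np.array([50, 0, 50])
        exp = np.array([25.0, 50.0, 25.0])
        expected_chi2 = float(((obs - exp) ** 2 / exp).sum())
        res = hk.hwe_test((50, 0, 50))
        assert res.chi2 == pytest.approx(expected_chi2)  # = 100
        assert res.p_value < 1e-20

    def test_monomorphic_site_flagged(self):
        res = hk.hwe_test((100, 0, 0))
        assert res.chi2 == 0.0 and res.p_value == 1.0
        assert "MONOMORPHIC" in res.flags

    @given(st.tuples(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)))
    def test_outputs_well_formed(self, counts):
        if sum(counts) == 0:
            with pytest.raises(ValueError):
                hk.hwe_test(counts)
            return
        res = hk.hwe_test(counts)
        assert res.chi2 >= 0
        assert 0 <= res.p_value <= 1

    def test_small_expected_cells_flagged(self):
        res = hk.hwe_test((3, 2, 1))
        assert "SMALL_COUNTS" in res.flags

    def test_counts_from_reference_cohort(self, catalog, reference_cohort):
        counts = hk.genotype_counts_for_variant(reference_cohort, catalog, "rs334")
        # 161 SS hom-alt, 66+4+7 = 77 het, 2 hom-ref (AA, beta-trait)
        assert counts == (2, 77, 161)
        res = hk.hwe_test(counts, "rs334")
        assert 0 <= res.p_value <= 1
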