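import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import hbbkit as hk
from hbbkit.util import percent


def _calls(labels):
    out = []
    for i, lbl in enumerate(labels):
        variant = "CD39" if lbl in ("SB0", "SBP", "BTRAIT") else None
        out.append(hk.HbGenotypeCall(f"S{i}", lbl, beta_thal_variant=variant))
    return out


class TestConfusion:
    def test_perfect_agreement_is_diagonal(self):
        calls = _calls(["SS", "SS", "AA", "SB0"])
        hplc = {c.sample_id: hk.hb_caller.display_label(c.label) for c in calls}
        m = hk.build_confusion(hplc, calls)
        cells = m.cells.to_numpy()
        assert cells.sum() == 4
        assert np.trace(cells) == 4

    def test_sample_mismatch_is_fatal(self):
        calls = _calls(["SS"])
        with pytest.raises(ValueError, match="S0"):
            hk.build_confusion({"OTHER": "SS"}, calls)

    def test_permutation_invariance(self):
        calls = _calls(["SS", "SB0", "AA", "SS"])
        hplc = {"S0": "Sβ", "S1": "SS", "S2": "AA", "S3": "SS"}
        m1 = hk.build_confusion(hplc, calls)
        m2 = hk.build_confusion(hplc, list(reversed(calls)))
        assert m1.cells.loc[m2.cells.index, m2.cells.columns].equals(m2.cells)

    def test_reference_cohort_marginals(self, reference_cohort, reference_calls):
        """HPLC marginals reproduce the published 184/54/2 split; NGS
        marginals follow the mutation-spectrum-consistent composition."""
        hplc = {s.sample_id: s.hplc_label for s in reference_cohort}
        m = hk.build_confusion(hplc, reference_calls)
        assert m.total == 240
        assert m.row_totals["SS"] == 184
        assert m.row_totals["Sβ"] == 54
        assert m.row_totals["SD"] == 2
        assert m.col_totals["Sβ"] == 66
        assert m.col_totals["AS"] == 7
        # the 14 documented false-positive Sβ diagnoses are SS by NGS
        assert m.cells.loc["Sβ", "SS"] == 14


class TestConcordance:
    def test_published_marginals_reproduce_printed_rates(self):
        """54 HPLC-Sβ, 68 NGS-Sβ, 14 false positives -> 79.4% sensitivity and
        20.6% false-positive rate under the 'paper' convention."""
        m = hk.concordance_from_marginals(54, 68, 14)
        assert m.sensitivity == 79.4
        assert m.false_positive_rate == 20.6
        assert m.numerators["sensitivity"] == 54
        assert m.denominators["sensitivity"] == 68

    def test_diagonal_matrix_is_perfect_under_both_conventions(self):
        calls = _calls(["SB0", "SB0", "SS", "AA"])
        hplc = {c.sample_id: hk.hb_caller.display_label(c.label) for c in calls}
        matrix = hk.build_confusion(hplc, calls)
        for conv in ("paper", "standard"):
            m = hk.concordance_metrics(matrix, "Sβ", conv)
            assert m.sensitivity == 100.0
            assert m.false_positive_rate == 0.0

    @given(st.lists(st.sampled_from(["SS", "Sβ", "AA"]), min_size=4, max_size=40))
    def test_standard_convention_matches_cell_arithmetic(self, hplc_labels):
        rng = np.random.default_rng(len(hplc_labels))
        ngs_labels = [
            str(rng.choice(["SS", "SB0", "AA"])) for _ in hplc_labels
        ]
        calls = _calls(ngs_labels)
        hplc = {c.sample_id: l for c, l in zip(calls, hplc_labels)}
        matrix = hk.build_confusion(hplc, calls)
        if "Sβ" not in matrix.labels:
            return
        m = hk.concordance_metrics(matrix, "Sβ", "standard")
        tp = sum(h == "Sβ" and hk.hb_caller.display_label(n) == "Sβ"
                 for h, n in zip(hplc_labels, ngs_labels))
        fn = sum(h != "Sβ" and hk.hb_caller.display_label(n) == "Sβ"
                 for h, n in zip(hplc_labels, ngs_labels))
        fp = sum(h == "Sβ" and hk.hb_caller.display_label(n) != "Sβ"
                 for h, n in zip(hplc_labels, ngs_labels))
        tn = len(hplc_labels) - tp - fn - fp
        if tp + fn:
            assert m.sensitivity == percent(tp, tp + fn)
        if fp + tn:
            assert m.false_positive_rate == percent(fp, fp + tn)

    def test_zero_denominator_flagged_as_undefined(self):
        calls = _calls(["SS", "AA"])
        hplc = {"S0": "Sβ", "S1": "AA"}
        matrix = hk.build_confusion(hplc, calls)
        m = hk.concordance_metrics(matrix, "Sβ", "paper")
        assert m.sensitivity is None and m.false_positive_rate is None


class TestMutationTable:
    def test_counts_and_percents(self):
        calls = []
        for i in range(10):
            calls.append(hk.HbGenotypeCall(f"a{i}", "SB0", beta_thal_variant="IVS-1, -25del"))
        for i in range(56):
            calls.append(hk.HbGenotypeCall(f"b{i}", "SBP", beta_thal_variant="IVS-I-110"))
        table = hk.mutation_frequency_table(calls)
        top = table[table.variant_id == "IVS-1, -25del"].iloc[0]
        assert top.n == 10
        assert top.percent == percent(10, 66) == 15.2

    def test_single_sbeta_sample(self):
        calls = _calls(["SB0"])
        table = hk.mutation_frequency_table(calls)
        assert list(table.percent) == [100.0]

    def test_percent_column_sums_to_100_within_rounding(self, reference_calls):
        table = hk.mutation_frequency_table(reference_calls)
        assert table.n.sum() == 66
        # each 1-decimal half-up rounding moves a row by at most 0.05
        assert abs(table.percent.sum() - 100.0) <= 0.05 * len(table)


class TestGroupSummary:
    def _samples(self):
        recs = []
        for i, hbf in enumerate([20.0, 24.0, 28.0]):
            recs.append(hk.SampleRecord(
                sample_id=f"g1_{i}", hematology={"hbf": hbf, "hb": 9.0},
                age_years=10 + i,
            ))
        recs.append(hk.SampleRecord(sample_id="solo", hematology={"hbf": 8.5},
                                    age_years=4))
        return recs

    def test_mean_sd_and_singleton_rows(self):
        recs = self._samples()
        grouping = {r.sample_id: ("A" if r.sample_id.startswith("g1") else "B")
                    for r in recs}
        out = hk.group_summary(recs, grouping)
        a = out[out.group == "A"].iloc[0]
        assert a.n == 3
        assert a.hbf_mean == pytest.approx(24.0)
        assert a.hbf_sd == pytest.approx(np.std([20, 24, 28], ddof=1))
        b = out[out.group == "B"].iloc[0]
        assert b.n == 1
        assert b.hbf_mean == 8.5
        assert np.isnan(b.hbf_sd)  # single-patient rows print bare values
        assert list(out.group) == ["A", "B"]  # ordered by descending n

    def test_identical_patients_have_zero_sd(self):
        recs = [hk.SampleRecord(sample_id=f"s{i}", hematology={"hb": 9.9})
                for i in range(2)]
        out = hk.group_summary(recs, {"s0": "G", "s1": "G"}, variables=("hb",))
        assert out.iloc[0].hb_sd == 0.0

    def test_recovers_known_normal_mean(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(24.2, 7.9, size=400)
        recs = [hk.SampleRecord(sample_id=f"s{i}", hematology={"hbf": v})
                for i, v in enumerate(vals)]
        out = hk.group_summary(recs, {r.sample_id: "AI/AI" for r in recs},
                               variables=("hbf",))
        se = 7.9 / np.sqrt(400)
        assert abs(out.iloc[0].hbf_mean - 24.2) < 3 * se


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        groups = {"A": [5.0, 5.0, 5.0], "B": [5.0, 5.0]}
        f, p = hk.anova_hbf(groups)
        assert f == 0.0 and p == 1.0

    def test_two_groups_equal_pooled_t_squared(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(20, 5, 12), rng.normal(24, 5, 12)
        f, p_f = hk.anova_hbf({"A": a, "B": b})
        t, p_t = sps.ttest_ind(a, b)  # pooled-variance two-sample t
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_degenerate_group_named_in_error(self):
        with pytest.raises(ValueError, match="B"):
            hk.anova_hbf({"A": [1.0, 2.0], "B": [3.0]})

    def test_reference_cohort_hbf_not_significant(self, reference_cohort,
                                                  reference_calls,
                                                  reference_phasing):
        """HbF means across AI-carrying and SEN-carrying haplotype groups
        (group hematology equals group means in the reference cohort)."""
        _, dips, _ = reference_phasing
        ss = {c.sample_id for c in reference_calls if c.label == "SS"}
        by_group: dict[str, list[float]] = {}
        hbf = {s.sample_id: s.hematology.get("hbf") for s in reference_cohort}
        for sid, dip in dips.items():
            if sid not in ss:
                continue
            labels = sorted(h.label for h in dip.pair)
            if not any(l in ("AI", "SEN") for l in labels):
                continue
            key = "/".join("ATP" if l.startswith("ATP") else l for l in labels)
            if hbf[sid] is not None:
                by_group.setdefault(key, []).append(hbf[sid])
        by_group = {k: v for k, v in by_group.items() if len(v) >= 2}
        f, p = hk.anova_hbf(by_group)
        assert f >= 0 and 0 <= p <= 1
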