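"""Frequency comparison, differentiation screen, Fisher exact and BH-FDR."""

from __future__ import annotations

import random
from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxcohort import datasets
from pgxcohort.popcompare import (
    CompareError,
    bh_adjust,
    compare_allele_frequencies,
    compare_phenotype_frequencies,
    fisher_exact_2x2,
    screen_differentiated_variants,
)


def oracle_fisher(a, n_a, b, n_b):
    """Independent two-sided Fisher oracle via exact Fraction enumeration."""

    def choose(n, k):
        return Fraction(factorial(n), factorial(k) * factorial(n - k))

    k, n = a + b, n_a + n_b
    denom = choose(n, n_a)
    probs = {}
    for x in range(max(0, k - n_b), min(k, n_a) + 1):
        probs[x] = choose(k, x) * choose(n - k, n_a - x) / denom
    obs = probs[a]
    return float(sum(p for p in probs.values() if p <= obs))


@pytest.fixture(scope="module")
def all_rows(annotations):
    high = datasets.load_af_table("high")
    low = datasets.load_af_table("low")
    both = pd.concat([high, low], ignore_index=True)
    study = both.rename(columns={"af_study": "alt_freq"}).drop(columns=["af_ref"])
    ref = both.rename(columns={"af_ref": "alt_freq"}).drop(columns=["af_study"])
    rows, skipped = compare_allele_frequencies(study, ref, annotations)
    assert skipped == []
    return rows


class TestCompareAlleleFrequencies:
    def test_published_deltas(self, all_rows):
        by_rsid = {r.rsid: r for r in all_rows}
        assert by_rsid["rs396991"].delta == pytest.approx(0.211, abs=1e-12)
        assert by_rsid["rs2359612"].delta == pytest.approx(-0.114, abs=1e-12)

    def test_identical_tables_give_zero_delta_unit_ratio(self, annotations):
        table = datasets.load_af_table("high").rename(columns={"af_study": "alt_freq"})
        table = table.drop(columns=["af_ref"])
        rows, _ = compare_allele_frequencies(table, table.copy(), annotations)
        assert rows
        for r in rows:
            assert r.delta == 0.0
            assert r.ratio == pytest.approx(1.0)

    def test_swap_negates_delta_and_inverts_ratio(self, annotations):
        high = datasets.load_af_table("high")
        study = high.rename(columns={"af_study": "alt_freq"}).drop(columns=["af_ref"])
        ref = high.rename(columns={"af_ref": "alt_freq"}).drop(columns=["af_study"])
        fwd, _ = compare_allele_frequencies(study, ref, annotations)
        rev, _ = compare_allele_frequencies(ref, study, annotations)
        f = {r.rsid: r for r in fwd}
        for r in rev:
            assert r.delta == pytest.approx(-f[r.rsid].delta)
            if r.ratio and f[r.rsid].ratio:
                assert r.ratio == pytest.approx(1.0 / f[r.rsid].ratio)

    def test_swapped_ref_alt_is_harmonized(self, annotations):
        study = pd.DataFrame(
            [{"chrom": "1", "pos": 10, "rsid": "rs396991", "gene": "FCGR3A",
              "ref": "A", "alt": "C", "alt_freq": 0.6}]
        )
        ref = study.assign(ref="C", alt="A", alt_freq=0.3)
        rows, _ = compare_allele_frequencies(study, ref, annotations)
        assert rows[0].af_ref == pytest.approx(0.7)

    def test_strand_ambiguous_swap_is_dropped(self, annotations):
        study = pd.DataFrame(
            [{"chrom": "1", "pos": 10, "rsid": "rs396991", "gene": "FCGR3A",
              "ref": "A", "alt": "T", "alt_freq": 0.6}]
        )
        ref = study.assign(ref="T", alt="A", alt_freq=0.3)
        with pytest.warns(UserWarning, match="ambiguous"):
            rows, skipped = compare_allele_frequencies(study, ref, annotations)
        assert rows == []
        assert "rs396991" in skipped

    def test_absent_variant_is_skipped_not_fatal(self, annotations):
        study = pd.DataFrame([{"rsid": "rs396991", "alt_freq": 0.5}])
        ref = pd.DataFrame([{"rsid": "rs_other", "alt_freq": 0.5}])
        rows, skipped = compare_allele_frequencies(study, ref, annotations)
        assert rows == []
        assert "rs396991" in skipped


class TestScreen:
    def test_published_tier_counts(self, all_rows):
        report = screen_differentiated_variants(all_rows)
        assert len(report.high_abs) == 13
        assert len(report.high_up) == 5
        assert len(report.low_up) == 24
        assert len(report.low_down) == 0

    def test_below_threshold_high_evidence_row_excluded(self):
        from pgxcohort.popcompare import FrequencyComparison

        row = FrequencyComparison(
            chrom="1", pos=1, rsid="rsX", gene="G", ref="A", alt="G",
            af_study=0.549, af_ref=0.5, delta=0.049, ratio=1.098,
            evidence_level="1A",
        )
        report = screen_differentiated_variants([row])
        assert not report.high_abs and not report.high_up

    def test_toy_low_evidence_partition(self):
        from pgxcohort.popcompare import FrequencyComparison

        rows = [
            FrequencyComparison("1", i, f"rs{i}", "G", "A", "G",
                                0.5 + d, 0.5, d, None, "3")
            for i, d in enumerate([0.25, 0.12, -0.15, 0.05])
        ]
        report = screen_differentiated_variants(rows)
        assert sorted(r.delta for r in report.low_up) == [0.12, 0.25]
        assert [r.delta for r in report.low_down] == [-0.15]

    def test_raising_cutoffs_never_grows_a_tier(self, all_rows):
        loose = screen_differentiated_variants(all_rows, high_cut=0.05, high_up_cut=0.10)
        tight = screen_differentiated_variants(all_rows, high_cut=0.10, high_up_cut=0.15)
        assert len(tight.high_abs) <= len(loose.high_abs)
        assert len(tight.high_up) <= len(loose.high_up)


class TestFisher:
    def test_identical_proportions_give_p_one(self):
        assert fisher_exact_2x2(5, 10, 5, 10) == 1.0

    def test_agrees_with_enumeration_oracle(self):
        rng = random.Random(1234)
        for _ in range(200):
            n_a, n_b = rng.randint(1, 40), rng.randint(1, 40)
            a, b = rng.randint(0, n_a), rng.randint(0, n_b)
            assert fisher_exact_2x2(a, n_a, b, n_b) == pytest.approx(
                oracle_fisher(a, n_a, b, n_b), abs=1e-12
            )

    def test_agrees_with_scipy_on_large_tables(self):
        from scipy.stats import fisher_exact as scipy_fisher

        rng = random.Random(7)
        for _ in range(25):
            n_a, n_b = rng.randint(400, 900), rng.randint(400, 900)
            a, b = rng.randint(0, n_a), rng.randint(0, n_b)
            ours = fisher_exact_2x2(a, n_a, b, n_b)
            ref = scipy_fisher([[a, n_a - a], [b, n_b - b]]).pvalue
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_type_i_error_calibration_under_the_null(self):
        rng = np.random.default_rng(2024)
        n = 1500
        hits = 0
        trials = 2000
        for _ in range(trials):
            p0 = rng.uniform(0.1, 0.5)
            a = rng.binomial(n, p0)
            b = rng.binomial(n, p0)
            if fisher_exact_2x2(int(a), n, int(b), n) < 0.05:
                hits += 1
        assert 0.03 <= hits / trials <= 0.07

    def test_invalid_tables_rejected(self):
        with pytest.raises(CompareError):
            fisher_exact_2x2(1, 0, 1, 10)
        with pytest.raises(CompareError):
            fisher_exact_2x2(11, 10, 1, 10)


class TestBH:
    def test_single_p_is_its_own_q(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_ps_are_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(99)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 30))
            ours = bh_adjust(p.tolist())
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(ours, ref, atol=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=25))
    def test_q_dominates_p_and_preserves_order(self, p):
        q = bh_adjust(p)
        assert all(qi >= pi - 1e-15 for qi, pi in zip(q, p))
        order = np.argsort(p, kind="mergesort")
        q_sorted = np.asarray(q)[order]
        assert (np.diff(q_sorted) >= -1e-15).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(CompareError):
            bh_adjust([0.5, 1.5])


class TestComparePhenotypeFrequencies:
    def _summary(self, counts, n):
        from pgxcohort.profiler import CohortSummary

        return CohortSummary(
            cohort_size=n,
            gene_phenotypes={
                g: {p: (c, c / n) for p, c in per.items()} for g, per in counts.items()
            },
            fraction_ge1=0.0,
            mean_drugs=0.0,
            drug_risk={},
            drugs_over_threshold=[],
            risk_threshold=0.4,
        )

    def test_equal_frequencies_give_p_one(self):
        summary = self._summary({"G": {"X": 856}}, 1577)
        ref = pd.DataFrame(
            [{"gene": "G", "phenotype": "X", "frequency": 856 / 1577, "n_ref": 1577}]
        )
        out = compare_phenotype_frequencies(summary, ref)
        assert out[0].p_value == pytest.approx(1.0)
        assert out[0].q_value >= out[0].p_value

    def test_degenerate_zero_counts_give_p_one(self):
        summary = self._summary({"G": {"X": 0}}, 100)
        ref = pd.DataFrame(
            [{"gene": "G", "phenotype": "X", "frequency": 0.0, "n_ref": 100}]
        )
        assert compare_phenotype_frequencies(summary, ref)[0].p_value == 1.0

    def test_random_tables_match_oracle(self):
        rng = random.Random(5)
        for _ in range(30):
            n_s, n_r = rng.randint(20, 120), rng.randint(20, 120)
            c_s, c_r = rng.randint(0, n_s), rng.randint(0, n_r)
            summary = self._summary({"G": {"X": c_s}}, n_s)
            ref = pd.DataFrame(
                [{"gene": "G", "phenotype": "X", "frequency": c_r / n_r, "n_ref": n_r}]
            )
            out = compare_phenotype_frequencies(summary, ref)
            assert out[0].p_value == pytest.approx(
                oracle_fisher(c_s, n_s, c_r, n_r), abs=1e-12
            )

    def test_missing_reference_size_rejected(self):
        summary = self._summary({"G": {"X": 5}}, 10)
        ref = pd.DataFrame(
            [{"gene": "G", "phenotype": "X", "frequency": 0.5, "n_ref": np.nan}]
        )
        with pytest.raises(CompareError, match="n_ref"):
            compare_phenotype_frequencies(summary, ref)
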