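import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from founder_tracer.datamodel import MISSING, GenotypeMatrix
from founder_tracer import qc

from oracles import hwe_exact_oracle


def gm_from_calls(calls: np.ndarray, chrom: str = "1") -> GenotypeMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": 1000 + 1000 * np.arange(m),
            "id": [f"v{j}" for j in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix([f"S{i}" for i in range(n)], variants, calls)


def random_gm(rng, n, m, missing_rate=0.0):
    freqs = rng.uniform(0.05, 0.95, m)
    calls = rng.binomial(2, freqs, size=(n, m)).astype(np.int8)
    if missing_rate:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    return gm_from_calls(calls)


class TestMissingness:
    def test_variant_above_threshold_removed(self):
        calls = np.zeros((10, 2), dtype=np.int8)
        calls[0, 0] = MISSING  # 10% missing > 5%
        out, report = qc.filter_missingness(gm_from_calls(calls))
        assert out.n_variants == 1
        assert report.steps[0]["removed_variants"] == 1

    def test_fully_observed_unchanged(self, rng):
        gm = random_gm(rng, 12, 30)
        out, report = qc.filter_missingness(gm)
        assert out.n_variants == 30 and out.n_samples == 12
        assert np.array_equal(out.calls, gm.calls)

    def test_removal_set_matches_bruteforce_recount(self, rng):
        gm = random_gm(rng, 40, 80, missing_rate=0.04)
        th = qc.QcThresholds(max_variant_missing=0.05, max_sample_missing=0.2)
        out, _ = qc.filter_missingness(gm, th)
        expect_kept = [
            v
            for j, v in enumerate(gm.variants["id"])
            if sum(gm.calls[i, j] == MISSING for i in range(gm.n_samples))
            / gm.n_samples
            < 0.05
        ]
        assert out.variants["id"].tolist() == expect_kept

    def test_empty_result_is_an_error(self):
        calls = np.full((4, 3), MISSING, dtype=np.int8)
        calls[0] = 0
        with pytest.raises(qc.QcError, match="empty"):
            qc.filter_missingness(gm_from_calls(calls))


class TestHweExact:
    @pytest.mark.parametrize(
        "counts", [(2, 4, 2), (0, 4, 0), (10, 1, 7), (1, 1, 1), (0, 0, 12)]
    )
    def test_matches_rational_enumeration(self, counts):
        expected = float(hwe_exact_oracle(*counts))
        assert qc.hwe_exact_test(*counts) == pytest.approx(expected, rel=1e-9)

    def test_monomorphic_is_one(self):
        assert qc.hwe_exact_test(5, 0, 0) == 1.0

    def test_invalid_counts_error(self):
        with pytest.raises(qc.QcError):
            qc.hwe_exact_test(-1, 2, 0)
        with pytest.raises(qc.QcError):
            qc.hwe_exact_test(0, 0, 0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.integers(0, 18), st.integers(0, 18), st.integers(0, 18)
    )
    def test_enumeration_agreement_property(self, a, b, c):
        if a + b + c == 0:
            return
        expected = float(hwe_exact_oracle(a, b, c))
        assert qc.hwe_exact_test(a, b, c) == pytest.approx(expected, rel=1e-9)
        assert 0 < qc.hwe_exact_test(a, b, c) <= 1


class TestHweFilter:
    def test_realized_threshold_is_alpha_over_n(self, rng):
        gm = random_gm(rng, 50, 1000)
        _, report = qc.hwe_filter(gm, qc.QcThresholds(hwe_alpha=0.05))
        assert report.steps[0]["params"]["realized_threshold"] == pytest.approx(5e-5)

    def test_extreme_het_excess_removed(self, rng):
        gm = random_gm(rng, 100, 50)
        calls = gm.calls.copy()
        calls[:, 7] = 1  # every sample heterozygous
        gm = gm_from_calls(calls)
        out, _ = qc.hwe_filter(gm)
        assert "v7" not in out.variants["id"].tolist()

    def test_null_data_rarely_removed(self, rng):
        gm = random_gm(rng, 200, 400)
        out, _ = qc.hwe_filter(gm)
        assert gm.n_variants - out.n_variants <= 1


class TestMafFilter:
    def test_singleton_removed(self):
        calls = np.zeros((100, 2), dtype=np.int8)
        calls[0, 0] = 1  # MAF 0.005
        calls[:50, 1] = 1
        out, _ = qc.maf_filter(gm_from_calls(calls))
        assert out.variants["id"].tolist() == ["v1"]

    def test_exactly_at_threshold_retained(self):
        calls = np.zeros((100, 1), dtype=np.int8)
        calls[0, 0] = 2  # MAF exactly 0.01: strict "lower than" keeps it
        out, _ = qc.maf_filter(gm_from_calls(calls))
        assert out.n_variants == 1

    def test_removal_matches_bruteforce(self, rng):
        gm = random_gm(rng, 60, 120, missing_rate=0.05)
        out, _ = qc.maf_filter(gm, qc.QcThresholds(min_maf=0.1))
        expect = []
        for j, v in enumerate(gm.variants["id"]):
            obs = [c for c in gm.calls[:, j] if c != MISSING]
            p = sum(obs) / (2 * len(obs))
            if not min(p, 1 - p) < 0.1:
                expect.append(v)
        assert out.variants["id"].tolist() == expect


class TestLdPrune:
    def test_duplicate_pair_loses_one(self, rng):
        gm = random_gm(rng, 50, 2)
        calls = gm.calls.copy()
        calls[:, 1] = calls[:, 0]
        kept, report = qc.ld_prune(gm_from_calls(calls))
        assert len(kept) == 1
        assert report.steps[0]["removed_variants"] == 1

    def test_independent_variants_survive(self, rng):
        gm = random_gm(rng, 100, 60)
        th = qc.QcThresholds(ld_r2=0.5)
        kept, _ = qc.ld_prune(gm, th)
        assert len(kept) == 60

    def test_postcondition_no_kept_pair_above_threshold(self, rng):
        # correlated blocks: each variant copies its predecessor with noise
        n, m = 80, 60
        calls = np.empty((n, m), dtype=np.int8)
        calls[:, 0] = rng.binomial(2, 0.5, n)
        for j in range(1, m):
            copy = rng.random(n) < 0.9
            calls[:, j] = np.where(copy, calls[:, j - 1], rng.binomial(2, 0.5, n))
        gm = gm_from_calls(calls)
        th = qc.QcThresholds(ld_window=20, ld_step=5, ld_r2=0.2)
        kept, _ = qc.ld_prune(gm, th)
        kept_idx = [j for j, v in enumerate(gm.variants["id"]) if v in set(kept)]
        # exhaustive within-window check over the kept set
        for w_start in range(0, m, th.ld_step):
            window = [j for j in kept_idx if w_start <= j < w_start + th.ld_window]
            for x in range(len(window)):
                for y in range(x + 1, len(window)):
                    r2 = qc.dosage_r2(gm.calls[:, window[x]], gm.calls[:, window[y]])
                    assert r2 <= th.ld_r2 + 1e-12

    def test_window_of_one_is_noop(self, rng):
        gm = random_gm(rng, 30, 1)
        kept, _ = qc.ld_prune(gm)
        assert kept == gm.variants["id"].tolist()


def test_full_stack_is_deterministic(rng):
    gm = random_gm(rng, 60, 150, missing_rate=0.03)
    th = qc.QcThresholds(ld_window=25, ld_step=5, ld_r2=0.3)
    out1, kept1, rep1 = qc.run_qc(gm, th)
    out2, kept2, rep2 = qc.run_qc(gm, th)
    assert kept1 == kept2
    assert rep1.to_dict() == rep2.to_dict()
    assert np.array_equal(out1.calls, out2.calls)
    rep1.check_consistency()
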