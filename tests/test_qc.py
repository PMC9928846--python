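"""Quality control: allele frequency, exact HWE test, filter pipeline."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gremlkit import (DegenerateDataError, GenotypeMatrix, SNPInfo,
                      ValidationError, allele_frequency, apply_qc,
                      hwe_exact_test)
from tests.conftest import make_genotypes


def hwe_enumeration_oracle(a, b, c):
    """Exact-probability full enumeration of the conditional HWE test.

    Independent route: P(h) built directly from factorial Fractions,
    tail summed over all heterozygote counts with P(h') <= P(h_obs).
    """
    n = a + b + c
    n1 = min(2 * a + b, 2 * c + b)
    n2 = 2 * n - n1
    f = math.factorial
    probs = {}
    for h in range(n1 % 2, n1 + 1, 2):
        x, z = (n1 - h) // 2, (n2 - h) // 2
        probs[h] = Fraction(f(n) * f(n1) * f(n2) * 2 ** h,
                            f(x) * f(h) * f(z) * f(2 * n))
    p_obs = probs[b]
    return float(min(sum(p for p in probs.values() if p <= p_obs), 1))


class TestAlleleFrequency:
    @pytest.mark.parametrize("counts,expected", [
        ((0, 10, 0), 0.5),      # all heterozygotes
        ((10, 0, 0), 0.0),      # monomorphic for a1
        ((57, 14, 50), (14 + 100) / 242),
    ])
    def test_known_values(self, counts, expected):
        assert allele_frequency(counts) == pytest.approx(expected, abs=1e-15)

    def test_all_missing_errors(self):
        with pytest.raises(DegenerateDataError):
            allele_frequency((0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            allele_frequency((-1, 2, 3))


class TestHWEExact:
    def test_degenerate_support(self):
        # monomorphic: a single configuration consistent with allele counts
        assert hwe_exact_test((10, 0, 0)) == 1.0

    @pytest.mark.parametrize("counts", [(25, 50, 25), (57, 14, 50),
                                        (3, 5, 2), (0, 2, 98)])
    def test_matches_enumeration(self, counts):
        assert hwe_exact_test(counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 60), st.integers(0, 60), st.integers(0, 60))
    def test_enumeration_property(self, a, b, c):
        if a + b + c == 0:
            return
        assert hwe_exact_test((a, b, c)) == pytest.approx(
            hwe_enumeration_oracle(a, b, c), abs=1e-12)

    def test_large_n_path_is_consistent(self):
        # log-space path (n > 500) agrees with exact arithmetic
        counts = (300, 290, 110)
        exact = hwe_enumeration_oracle(*counts)
        assert hwe_exact_test(counts) == pytest.approx(exact, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            hwe_exact_test((1, -2, 3))


def qc_oracle(gm, maf_min, hwe_min, call_min, mind_max):
    """Loop-based re-implementation of the filter cascade."""
    d = gm.dosages
    keep_ind = []
    for j in range(d.shape[0]):
        row = d[j]
        if (row == -1).sum() / d.shape[1] <= mind_max:
            keep_ind.append(j)
    d = d[keep_ind]
    keep_snp, reasons = [], {}
    for i in range(d.shape[1]):
        col = d[:, i]
        called = col[col != -1]
        call_rate = called.size / d.shape[0]
        if call_rate < call_min:
            reasons[gm.snps[i].snp_id] = "geno"
            continue
        if called.size:
            freq = (np.sum(called == 1) + 2 * np.sum(called == 2)) \
                / (2 * called.size)
            if min(freq, 1 - freq) < maf_min:
                reasons[gm.snps[i].snp_id] = "maf"
                continue
            counts = tuple(int((called == k).sum()) for k in (0, 1, 2))
            if hwe_enumeration_oracle(*counts) < hwe_min:
                reasons[gm.snps[i].snp_id] = "hwe"
                continue
        keep_snp.append(i)
    return keep_ind, keep_snp, reasons


class TestApplyQC:
    def _matrix_with_rare_snp(self):
        # 50 individuals; snp0 has MAF 0.04, others are balanced
        rng = np.random.default_rng(7)
        d = (rng.random((50, 5)) < 0.5).astype(np.int8) \
            + (rng.random((50, 5)) < 0.5).astype(np.int8)
        d[:, 0] = 0
        d[:4, 0] = 1  # freq 4/100 = 0.04
        ids = [("f", f"i{j}") for j in range(50)]
        snps = [SNPInfo(f"s{i}") for i in range(5)]
        return GenotypeMatrix(ids, snps, d)

    def test_single_maf_failure(self):
        gm = self._matrix_with_rare_snp()
        out, report = apply_qc(gm, hwe_p_min=0.0, snp_call_rate_min=0.0)
        assert report.n_snps_out == report.n_snps_in - 1
        assert report.removal_reasons == {"s0": "maf"}
        assert "s0" not in out.snp_ids

    def test_disabled_thresholds_are_identity(self, rng):
        gm = make_genotypes(rng, n=30, m=40, missing_rate=0.2)
        out, report = apply_qc(gm, maf_min=0.0, hwe_p_min=0.0,
                               snp_call_rate_min=0.0, ind_missing_max=1.0)
        np.testing.assert_array_equal(out.dosages, gm.dosages)
        assert report.removal_reasons == {}

    def test_matches_loop_oracle_on_random_matrix(self, rng):
        gm = make_genotypes(rng, n=50, m=200, missing_rate=0.08)
        out, report = apply_qc(gm)
        keep_ind, keep_snp, reasons = qc_oracle(gm, 0.05, 1e-3, 0.90, 0.10)
        assert out.individual_ids == [gm.individual_ids[j] for j in keep_ind]
        assert out.snp_ids == [gm.snps[i].snp_id for i in keep_snp]
        snp_reasons = {k: v for k, v in report.removal_reasons.items()
                       if v != "mind"}
        assert snp_reasons == reasons

    def test_idempotent_and_survivors_pass_thresholds(self, rng):
        gm = make_genotypes(rng, n=60, m=150, missing_rate=0.05)
        out, _ = apply_qc(gm)
        again, report2 = apply_qc(out)
        np.testing.assert_array_equal(again.dosages, out.dosages)
        assert report2.removal_reasons == {}
        # exhaustive threshold check on survivors
        for i in range(out.n_snps):
            col = out.dosages[:, i]
            called = col[col != -1]
            freq = (np.sum(called == 1) + 2 * np.sum(called == 2)) \
                / (2 * called.size)
            counts = tuple(int((called == k).sum()) for k in (0, 1, 2))
            assert called.size / out.n_individuals >= 0.90
            assert min(freq, 1 - freq) >= 0.05
            assert hwe_exact_test(counts) >= 1e-3

    def test_all_removed_raises(self):
        d = np.zeros((20, 3), dtype=np.int8)  # every SNP monomorphic: MAF 0
        gm = GenotypeMatrix([("f", f"i{j}") for j in range(20)],
                            [SNPInfo(f"s{i}") for i in range(3)], d)
        with pytest.raises(DegenerateDataError):
            apply_qc(gm)
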