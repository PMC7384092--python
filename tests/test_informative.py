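"""Unit and property tests for het calling, the exact binomial test, BH, and
informative-SNP selection.  Oracles are independent enumerations (exact
integer arithmetic for the binomial tail, an O(m^2) literal transcription of
the step-up definition for BH)."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lohmap.model import ALT, REF, ConfigError, DataError, Thresholds
from lohmap.informative import (
    assign_retained_allele,
    bh_adjust,
    binom_two_sided_p_vec,
    binomial_two_sided_p,
    call_het_snps,
    select_informative,
)
from lohmap.simulate import H1, LohSpec, SimConfig, simulate_patient


def binom_p_oracle(k: int, n: int) -> float:
    """Exact two-sided p by enumeration: sum of P[X = j] over all outcomes j
    no more likely than k, computed with integer arithmetic."""
    pk = comb(n, k)
    total = sum(comb(n, j) for j in range(n + 1) if comb(n, j) <= pk)
    return float(Fraction(total, 2**n))


def bh_oracle(ps):
    """Literal step-up definition: q(i) = min_{j >= rank(i)} m * p(j) / j."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: (ps[i], i))
    q = [0.0] * m
    for rank0, i in enumerate(order):
        q[i] = min(1.0, min(m * ps[order[j]] / (j + 1) for j in range(rank0, m)))
    return q


class TestBinomialTest:
    def test_center_is_one(self):
        assert binomial_two_sided_p(10, 20) == 1.0

    def test_frozen_k27_n30(self):
        # 2 * (C(30,27)+C(30,28)+C(30,29)+C(30,30)) / 2^30
        expected = 2 * (4060 + 435 + 30 + 1) / 2**30
        assert binomial_two_sided_p(27, 30) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(8.430e-6, rel=1e-3)

    def test_frozen_k0_n11(self):
        assert binomial_two_sided_p(0, 11) == pytest.approx(2 / 2048, rel=1e-12)

    def test_validation(self):
        with pytest.raises(DataError):
            binomial_two_sided_p(5, 0)
        with pytest.raises(DataError):
            binomial_two_sided_p(-1, 10)
        with pytest.raises(DataError):
            binomial_two_sided_p(11, 10)

    @pytest.mark.parametrize("n", [1, 2, 7, 11, 24, 37, 60])
    def test_oracle_equivalence(self, n):
        for k in range(n + 1):
            assert binomial_two_sided_p(k, n) == pytest.approx(
                binom_p_oracle(k, n), abs=1e-12
            )

    def test_vectorized_matches_scalar(self):
        k = np.array([0, 3, 10, 27])
        n = np.array([11, 20, 20, 30])
        vec = binom_two_sided_p_vec(k, n)
        for i in range(len(k)):
            assert vec[i] == pytest.approx(binomial_two_sided_p(int(k[i]), int(n[i])))

    def test_symmetry(self):
        for n in (10, 25, 41):
            for k in range(n + 1):
                assert binomial_two_sided_p(k, n) == pytest.approx(
                    binomial_two_sided_p(n - k, n), abs=1e-14
                )


class TestBHAdjust:
    def test_frozen_example(self):
        q = bh_adjust([0.001, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.004, 0.04, 0.04, 0.5])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_equal_unchanged(self):
        q = bh_adjust([0.2] * 7)
        assert np.allclose(q, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(DataError):
            bh_adjust([-0.1])

    def test_empty(self):
        assert bh_adjust([]).size == 0

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=60,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle(self, ps):
        assert np.allclose(bh_adjust(ps), bh_oracle(ps), atol=1e-12)

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=2,
            max_size=40,
        ),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariance(self, ps, rnd):
        idx = list(range(len(ps)))
        rnd.shuffle(idx)
        q = bh_adjust(ps)
        q_perm = bh_adjust([ps[i] for i in idx])
        assert np.allclose([q[i] for i in idx], q_perm, atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(5)
        ps = rng.uniform(size=100)
        assert np.all(bh_adjust(ps) >= ps - 1e-15)


def _frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "normal_ref", "normal_alt"]
    )


class TestCallHetSnps:
    def test_center_of_window_kept(self):
        df = _frame([("chr18", 100, "A", "G", 6, 6)])
        het = call_het_snps(df, "normal", Thresholds())
        assert len(het) == 1
        assert het.normal_vaf.iloc[0] == pytest.approx(0.5)

    def test_depth_bound_strict(self):
        df = _frame([("chr18", 100, "A", "G", 5, 5)])  # depth exactly 10
        assert len(call_het_snps(df, "normal", Thresholds())) == 0

    def test_vaf_outside_window(self):
        df = _frame([("chr18", 100, "A", "G", 35, 15)])  # VAF 0.3
        assert len(call_het_snps(df, "normal", Thresholds())) == 0

    def test_vaf_window_inclusive(self):
        df = _frame([("chr18", 100, "A", "G", 12, 8), ("chr18", 200, "C", "T", 8, 12)])
        het = call_het_snps(df, "normal", Thresholds())  # VAF exactly 0.4 / 0.6
        assert len(het) == 2

    def test_zero_depth_no_error(self):
        df = _frame([("chr18", 100, "A", "G", 0, 0)])
        assert len(call_het_snps(df, "normal", Thresholds())) == 0


class TestAssignRetainedAllele:
    def test_ref_majority(self):
        assert assign_retained_allele(40, 5) == REF

    def test_alt_majority(self):
        assert assign_retained_allele(5, 40) == ALT

    def test_tie_rejected(self):
        with pytest.raises(DataError):
            assign_retained_allele(12, 12)


def _two_sample_frame(n, tumor_ref, tumor_alt, normal_ref=15, normal_alt=15):
    return pd.DataFrame(
        {
            "chrom": ["chr18"] * n,
            "pos": np.arange(1, n + 1) * 1000,
            "ref": ["A"] * n,
            "alt": ["G"] * n,
            "normal_ref": [normal_ref] * n,
            "normal_alt": [normal_alt] * n,
            "tumor_ref": tumor_ref,
            "tumor_alt": tumor_alt,
        }
    )


class TestSelectInformative:
    def test_tumor_depth_bound_strict(self):
        df = _two_sample_frame(1, [5], [5])  # tumor depth exactly 10
        het = call_het_snps(df, "normal", Thresholds())
        res = select_informative(df, "tumor", het, Thresholds())
        assert res.counts["n_tested"] == 0
        assert res.counts["n_informative"] == 0

    def test_missing_tumor_is_config_error(self):
        df = _frame([("chr18", 100, "A", "G", 15, 15)])
        het = call_het_snps(df, "normal", Thresholds())
        with pytest.raises(ConfigError):
            select_informative(df, "tumor", het, Thresholds())

    @pytest.mark.parametrize(
        "mode,n,expect_retained",
        [("WGS", 999, False), ("WGS", 1000, True), ("WES", 99, False), ("WES", 100, True)],
    )
    def test_retention_threshold_semantics(self, mode, n, expect_retained):
        # every SNP is an extreme imbalance -> all become informative
        df = _two_sample_frame(n, [60] * n, [0] * n)
        thr = Thresholds(mode=mode)
        het = call_het_snps(df, "normal", thr)
        res = select_informative(df, "tumor", het, thr)
        assert res.counts["n_informative"] == n
        assert res.retained is expect_retained

    def test_pure_tumor_nearly_all_informative(self):
        cfg = SimConfig(
            seed=11, n_tumors=1, purities=(1.0,), loh_specs=(LohSpec.whole(H1),),
            n_snps=2800, n_bins=30,
        )
        sim = simulate_patient(cfg)
        thr = Thresholds()
        het = call_het_snps(sim.depths, "normal", thr)
        assert len(het) >= 2000
        res = select_informative(sim.depths, "T1", het, thr)
        assert res.counts["n_informative"] / res.counts["n_tested"] >= 0.99
        assert res.retained

    def test_monotonicity_in_min_depth_and_alpha(self):
        cfg = SimConfig(
            seed=12, n_tumors=1, purities=(0.5,), loh_specs=(LohSpec.whole(H1),),
            n_snps=1500, n_bins=30,
        )
        sim = simulate_patient(cfg)
        tested, informative = [], []
        for min_depth in (10, 20, 30):
            thr = Thresholds(min_depth=min_depth)
            het = call_het_snps(sim.depths, "normal", thr)
            res = select_informative(sim.depths, "T1", het, thr)
            tested.append(res.counts["n_tested"])
        assert tested == sorted(tested, reverse=True)
        for alpha in (0.1, 0.05, 0.01):
            thr = Thresholds(fdr_alpha=alpha)
            het = call_het_snps(sim.depths, "normal", thr)
            res = select_informative(sim.depths, "T1", het, thr)
            informative.append(res.counts["n_informative"])
        assert informative == sorted(informative, reverse=True)

    def test_retained_allele_is_argmax_everywhere(self):
        cfg = SimConfig(
            seed=13, n_tumors=2, purities=(0.6, 0.8),
            loh_specs=(LohSpec.whole(H1), LohSpec.whole(H1)), n_snps=1500, n_bins=30,
        )
        sim = simulate_patient(cfg)
        thr = Thresholds()
        het = call_het_snps(sim.depths, "normal", thr)
        for t in ("T1", "T2"):
            res = select_informative(sim.depths, t, het, thr)
            inf = res.informative
            expected = np.where(inf.ref_count > inf.alt_count, REF, ALT)
            assert (inf.retained_allele == expected).all()
            assert (inf.q_value < thr.fdr_alpha).all()
            assert (inf.q_value >= inf.p_value - 1e-15).all()

    def test_null_calibration_small(self):
        """No-LOH tumors: BH controls the familywise error under the global
        null, so few replicates should yield any informative SNP."""
        hits = 0
        reps = 120
        for seed in range(reps):
            cfg = SimConfig(
                seed=seed, n_tumors=1, purities=(0.0,), loh_specs=(LohSpec.whole(H1),),
                n_snps=1000, n_bins=30,
            )
            sim = simulate_patient(cfg)
            thr = Thresholds()
            het = call_het_snps(sim.depths, "normal", thr)
            res = select_informative(sim.depths, "T1", het, thr)
            if res.counts["n_informative"] > 0:
                hits += 1
        se = np.sqrt(0.1 * 0.9 / reps)
        assert hits / reps <= 0.1 + 3 * se
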