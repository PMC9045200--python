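"""Signed-fold arithmetic, SD-of-ratio, tests, BH, classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ribotide.diffte import (
    bh_adjust,
    classify,
    compute_gene_stats,
    fold_change,
    round_signed_fold,
    sd_of_ratio,
    signed_fold,
    signed_to_ratio,
    summarize,
    te_fold_change,
    translation_efficiency,
    welch_log2_test,
)


class TestSignedFold:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(0.4, -2.5), (1.0, 1.0), (2.5, 2.5), (0.25, -4.0)],
    )
    def test_values(self, ratio, expected):
        assert signed_fold(ratio) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            signed_fold(0.0)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_antisymmetry(self, r):
        if not np.isclose(r, 1.0):
            assert signed_fold(r) == pytest.approx(-signed_fold(1 / r))

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_ratio_round_trip(self, r):
        assert signed_to_ratio(signed_fold(r)) == pytest.approx(r)


class TestFoldChange:
    @pytest.mark.parametrize(
        "mut,wt,expected", [(10, 10, 1.0), (25, 10, 2.5), (10, 25, -2.5)]
    )
    def test_values(self, mut, wt, expected):
        assert fold_change(mut, wt) == pytest.approx(expected)

    def test_zero_mean_undefined(self):
        assert np.isnan(fold_change(0.0, 10.0))
        assert np.isnan(fold_change(10.0, 0.0))


class TestTranslationEfficiency:
    @pytest.mark.parametrize(
        "rpf,mrna,expected", [(100, 50, 2.0), (50, 100, 0.5), (0, 50, 0.0)]
    )
    def test_values(self, rpf, mrna, expected):
        assert translation_efficiency(rpf, mrna) == pytest.approx(expected)

    def test_zero_mrna_undefined(self):
        assert np.isnan(translation_efficiency(10.0, 0.0))


class TestTeFoldChange:
    @pytest.mark.parametrize(
        "fc_mrna,fc_rpf,expected",
        [
            (-2.5, -10.0, -4.0),
            (-4.3, -8.5, -2.0),
            (2.0, 2.0, 1.0),
            (1.1, 3.0, 2.7),
        ],
    )
    def test_rounded_values(self, fc_mrna, fc_rpf, expected):
        assert round_signed_fold(te_fold_change(fc_rpf, fc_mrna)) == expected

    def test_nan_propagates(self):
        assert np.isnan(te_fold_change(float("nan"), -2.0))

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(min_value=0.05, max_value=20),
        st.floats(min_value=0.05, max_value=20),
    )
    def test_ratio_scale_consistency(self, r_mrna, r_te):
        """TE ratio x mRNA ratio == RPF ratio, exactly, through the signed
        folds (the multiplicative decomposition RPF = mRNA x TE)."""
        r_rpf = r_mrna * r_te
        fc_m, fc_r = signed_fold(r_mrna), signed_fold(r_rpf)
        fc_te = te_fold_change(fc_r, fc_m)
        assert signed_to_ratio(fc_te) * signed_to_ratio(fc_m) == \
            pytest.approx(signed_to_ratio(fc_r), rel=1e-9)


class TestSdOfRatio:
    def test_proportional_vectors_annihilate(self):
        wt = np.array([3.0, 5.0, 9.0])
        res = sd_of_ratio(2 * wt, wt)
        assert res.value == 0.0

    def test_hand_derived_case(self):
        res = sd_of_ratio((4, 5, 6), (2, 2, 2))
        assert res.value == pytest.approx(0.5)
        assert not res.radicand_clipped

    def test_needs_replicates(self):
        with pytest.raises(ValueError):
            sd_of_ratio([1.0], [2.0])

    def test_monte_carlo_against_resampling_oracle(self):
        """The formula (applied to the sampling distribution of the group
        means) agrees with the empirical SD of the ratio of means over
        10,000 resampled triplicate pairs within 15%."""
        rng = np.random.default_rng(12)
        n, reps = 3, 10_000
        sigma_k, sigma_w, rho = 0.25, 0.20, 0.6
        cov = [
            [sigma_k**2, rho * sigma_k * sigma_w],
            [rho * sigma_k * sigma_w, sigma_w**2],
        ]
        logs = rng.multivariate_normal([1.0, 0.0], cov, size=(reps, n))
        k = np.exp(logs[:, :, 0])
        w = np.exp(logs[:, :, 1])
        ratios = k.mean(axis=1) / w.mean(axis=1)
        empirical = ratios.std(ddof=1)

        # formula evaluated with the population moments of the means
        def lognorm_moments(mu, sigma):
            m = np.exp(mu + sigma**2 / 2)
            v = (np.exp(sigma**2) - 1) * m**2
            return m, v

        m_k, v_k = lognorm_moments(1.0, sigma_k)
        m_w, v_w = lognorm_moments(0.0, sigma_w)
        cov_kw = m_k * m_w * (np.exp(rho * sigma_k * sigma_w) - 1)
        radicand = (v_k / m_k**2 + v_w / m_w**2
                    - 2 * cov_kw / (m_k * m_w)) / n
        predicted = (m_k / m_w) * np.sqrt(radicand)
        assert predicted == pytest.approx(empirical, rel=0.15)


class TestWelch:
    def test_identical_groups(self):
        assert welch_log2_test([4, 4, 4], [4, 4, 4]) == 1.0

    def test_separated_groups(self):
        rng = np.random.default_rng(1)
        a = 1 + rng.normal(0, 1e-3, 3)
        b = 8 + rng.normal(0, 1e-3, 3)
        assert welch_log2_test(a, b) < 0.01

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            welch_log2_test([1.0], [2.0])


def _bh_oracle(p):
    """Brute-force BH step-up from the definition."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running_min = min(running_min, n * p[idx] / rank)
        q[idx] = running_min
    return q


class TestBhAdjust:
    def test_hand_evaluated(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_and_equal_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.random(rng.integers(1, 12))
            np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p),
                                       atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(4)
        p = rng.random(30)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()


class TestClassifyAndSummarize:
    def _stats(self, fc_mrna, fc_rpf, q=0.01):
        n = len(fc_mrna)
        table = pd.DataFrame(
            {
                "fc_mrna": fc_mrna,
                "fc_rpf": fc_rpf,
                "fc_te": [te_fold_change(r, m)
                          for r, m in zip(fc_rpf, fc_mrna)],
            },
            index=[f"g{i}" for i in range(n)],
        )
        for metric in ("mrna", "rpf", "te"):
            table[f"q_{metric}"] = q
            table[f"class_{metric}"] = classify(
                table[f"fc_{metric}"], table[f"q_{metric}"]
            )
        return table

    def test_all_unit_folds_unaffected(self):
        table = self._stats([1.0] * 5, [1.0] * 5)
        summary = summarize(table)
        assert all(summary[f"n_{d}_{m}"] == 0
                   for d in ("up", "down") for m in ("mrna", "rpf", "te"))

    def test_identical_folds_give_r_squared_one(self):
        fc = [2.0, -3.0, 1.5, -1.2, 4.0]
        summary = summarize(self._stats(fc, fc))
        assert summary["r_squared_rpf_vs_mrna"] == pytest.approx(1.0)

    def test_cutoffs_respected(self):
        table = self._stats([2.5, -2.5, 1.5], [2.5, -2.5, 1.5])
        assert list(table["class_mrna"]) == ["up", "down", "unchanged"]


def test_planted_te_effect_detected(default_run):
    """The strong translationally attenuated gene lands in the TE-down set
    of the genome-wide analysis (simulation oracle, fixed seed)."""
    report = default_run["report"]
    cadb = default_run["roles"]["cadB_like"]
    assert cadb in report["te_down_genes"]
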