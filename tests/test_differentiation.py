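import itertools

import numpy as np
import pandas as pd
import pytest

from ssrpop.core_data import DataError, GenotypeMatrix
from ssrpop.differentiation import (
    AlleleSizeProfile,
    allele_size_trend_test,
    amova,
    _amova_components,
    _mismatch_sq,
    fst,
    pairwise_mean,
    standardized_allele_size,
)


def _panel(rows, labels):
    calls = np.array(rows)
    acc = [f"a{i}" for i in range(calls.shape[0])]
    g = GenotypeMatrix(acc, [f"L{j}" for j in range(calls.shape[1])], calls)
    return g, pd.Series(labels, index=acc)


def brute_force_theta(samples_per_pop: list[np.ndarray]) -> float:
    """Independent Weir-Cockerham theta for one haploid locus: explicit
    indicator-variable ANOVA written out longhand."""
    sizes = [len(s) for s in samples_per_pop]
    N = sum(sizes)
    r = len(samples_per_pop)
    nc = (N - sum(n * n for n in sizes) / N) / (r - 1)
    alleles = sorted(set(np.concatenate(samples_per_pop)))
    num = den = 0.0
    for a in alleles:
        p = [np.mean(s == a) for s in samples_per_pop]
        pbar = sum(n * pi for n, pi in zip(sizes, p)) / N
        msa = sum(n * (pi - pbar) ** 2 for n, pi in zip(sizes, p)) / (r - 1)
        msw = sum(n * pi * (1 - pi) for n, pi in zip(sizes, p)) / (N - r)
        sa = (msa - msw) / nc
        num += sa
        den += sa + msw
    return num / den


class TestFst:
    def test_fixed_difference_gives_theta_one(self):
        g, labels = _panel([[100], [100], [100], [104], [104], [104]],
                           ["P1"] * 3 + ["P2"] * 3)
        res = fst(g, labels)
        assert res.per_locus["theta"].iloc[0] == pytest.approx(1.0)

    def test_identical_frequencies_clamped_to_zero(self):
        g, labels = _panel(
            [[100], [104], [100], [104], [100], [104], [100], [104]],
            ["P1"] * 4 + ["P2"] * 4)
        res = fst(g, labels)
        assert res.per_locus["theta_raw"].iloc[0] <= 0
        assert res.per_locus["theta"].iloc[0] == 0.0

    def test_matches_brute_force_on_toy_table(self):
        rng = np.random.default_rng(3)
        a = rng.choice([100, 104, 108], size=12, p=[0.6, 0.3, 0.1])
        b = rng.choice([100, 104, 108], size=9, p=[0.1, 0.2, 0.7])
        g, labels = _panel([[v] for v in np.concatenate([a, b])],
                           ["P1"] * 12 + ["P2"] * 9)
        res = fst(g, labels)
        assert res.per_locus["theta_raw"].iloc[0] == pytest.approx(
            brute_force_theta([a, b]), rel=1e-10)

    def test_multilocus_is_ratio_of_summed_components(self, two_pop_panel):
        g, _, truth, _ = two_pop_panel
        res = fst(g, truth.labels)
        assert 0.1 < res.multi_locus < 0.6  # divergence F=0.3 regime
        pw = res.pairwise
        assert pw.shape == (2, 2)
        assert pw.loc["POP1", "POP2"] == pw.loc["POP2", "POP1"]

    def test_pairwise_mean_matches_hand_mean(self):
        m = pd.DataFrame([[np.nan, 0.2, 0.4], [0.2, np.nan, 0.6],
                          [0.4, 0.6, np.nan]], index=list("abc"),
                         columns=list("abc"))
        assert pairwise_mean(m) == pytest.approx((0.2 + 0.4 + 0.6) / 3)

    def test_single_population_rejected(self):
        g, labels = _panel([[100], [104]], ["P1", "P1"])
        with pytest.raises(DataError):
            fst(g, labels)


class TestAmova:
    def test_no_differentiation(self):
        g, labels = _panel(
            [[100, 90], [104, 92], [100, 90], [104, 92],
             [100, 90], [104, 92], [100, 90], [104, 92]],
            ["P1"] * 4 + ["P2"] * 4)
        res = amova(g, labels, permutations=200, seed=0)
        assert res.pct_among == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.5

    def test_full_fixation(self):
        g, labels = _panel(
            [[100, 90]] * 4 + [[104, 92]] * 4, ["P1"] * 4 + ["P2"] * 4)
        res = amova(g, labels, permutations=200, seed=0)
        assert res.pct_among == pytest.approx(100.0, abs=1e-9)

    def test_components_match_brute_force_partition(self):
        g, labels = _panel(
            [[100, 90], [100, 92], [104, 90], [104, 92], [108, 90], [108, 92]],
            ["P1"] * 3 + ["P2"] * 3)
        res = amova(g, labels, permutations=10, seed=0)
        # independent sums-of-squares computation
        d2 = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                d2[i, j] = sum(g.calls[i, l] != g.calls[j, l] for l in range(2))
        ss_total = d2[np.triu_indices(6, 1)].sum() / 6
        ss_within = (d2[:3, :3][np.triu_indices(3, 1)].sum() / 3
                     + d2[3:, 3:][np.triu_indices(3, 1)].sum() / 3)
        ms_among = (ss_total - ss_within) / 1
        ms_within = ss_within / 4
        sigma_w = ms_within
        sigma_a = (ms_among - ms_within) / 3.0  # n0 = 3 for balanced 3+3
        assert res.sigma_among == pytest.approx(sigma_a, rel=1e-10)
        assert res.sigma_within == pytest.approx(sigma_w, rel=1e-10)

    def test_percentages_sum_to_100(self, two_pop_panel):
        g, _, truth, _ = two_pop_panel
        sub = g.subset(accessions=g.accessions[:20])
        res = amova(sub, truth.labels.iloc[:20], permutations=50, seed=1)
        assert res.pct_among + res.pct_within == pytest.approx(100.0)

    def test_permutation_p_within_ci_of_exact_enumeration(self):
        g, labels = _panel(
            [[100, 90], [100, 90], [104, 92], [104, 92], [100, 92], [104, 90]],
            ["P1"] * 3 + ["P2"] * 3)
        d2 = _mismatch_sq(g, np.arange(6))
        obs = _amova_components(d2, labels.to_numpy())[2]
        lab = labels.to_numpy()
        exact_hits = sum(
            _amova_components(d2, np.array(perm))[2] >= obs - 1e-12
            for perm in itertools.permutations(lab)
        )
        p_exact = exact_hits / 720
        res = amova(g, labels, permutations=400, seed=5)
        se = np.sqrt(p_exact * (1 - p_exact) / 400)
        assert abs(res.p_value - p_exact) < 1.96 * se + 1 / 400 + 1e-9

    def test_permutation_count_validated(self, two_pop_panel):
        g, _, truth, _ = two_pop_panel
        with pytest.raises(DataError):
            amova(g, truth.labels, permutations=0)


class TestStandardizedAlleleSize:
    def test_grand_mean_zero_on_complete_data(self, two_pop_panel):
        g, _, truth, _ = two_pop_panel
        profile = standardized_allele_size(g, truth.labels)
        assert profile.scores.mean() == pytest.approx(0.0, abs=1e-9)

    def test_two_size_locus_split_between_pops(self):
        g, labels = _panel([[150], [150], [160], [160]],
                           ["P1", "P1", "P2", "P2"])
        profile = standardized_allele_size(g, labels)
        # z-scores of {150,150,160,160} are -1,-1,+1,+1 (population sd)
        assert profile.scores.tolist() == pytest.approx([-1, -1, 1, 1])
        means = profile.by_subpop.set_index("subpopulation")["mean"]
        assert means["P1"] == pytest.approx(-1.0)
        assert means["P2"] == pytest.approx(1.0)

    def test_zero_variance_locus_excluded(self):
        g, labels = _panel([[150, 100], [150, 104], [150, 108]],
                           ["P1", "P1", "P2"])
        profile = standardized_allele_size(g, labels)
        # only the polymorphic second locus contributes
        z = (np.array([100, 104, 108]) - 104) / np.std([100, 104, 108])
        assert profile.scores.tolist() == pytest.approx(z.tolist())


class TestTrendTest:
    def test_identical_groups_t_zero_p_one(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        scores = pd.Series(vals, index=[f"a{i}" for i in range(6)])
        profile = AlleleSizeProfile(scores=scores, by_subpop=pd.DataFrame())
        labels = pd.Series(["P1"] * 3 + ["P2"] * 3, index=scores.index)
        res = allele_size_trend_test(profile, labels, "P1")
        row = res.iloc[0]
        assert row["t"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_value"] == pytest.approx(1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(0, 1, 50)
        cmp_ = rng.normal(5, 1, 50)
        scores = pd.Series(np.concatenate([ref, cmp_]),
                           index=[f"a{i}" for i in range(100)])
        labels = pd.Series(["P1"] * 50 + ["P2"] * 50, index=scores.index)
        profile = AlleleSizeProfile(scores=scores, by_subpop=pd.DataFrame())
        res = allele_size_trend_test(profile, labels, "P1")
        assert res.iloc[0]["p_value"] < 0.01
        assert res.iloc[0]["t"] > 0  # comparison minus reference

    def test_five_comparisons_against_reference(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(0, 1, 60),
                           index=[f"a{i}" for i in range(60)])
        labels = pd.Series(sum([[f"POP{k}"] * 10 for k in range(1, 7)], []),
                           index=scores.index)
        profile = AlleleSizeProfile(scores=scores, by_subpop=pd.DataFrame())
        res = allele_size_trend_test(profile, labels, "POP1")
        assert len(res) == 5
        assert res["p_value"].between(0, 1).all()
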