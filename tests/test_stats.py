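"""Rank tests, multiplicity correction and ddCt — each against an
independent formula, enumeration, or library oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy import stats as sps

from dcip.simulate import generate_qpcr_plate
from dcip.stats import (
    ddct,
    dunn_pairwise,
    holm_sidak,
    kruskal_wallis,
    one_sample_t_vs_one,
)


class TestKruskalWallis:
    def test_all_identical_observations_give_h_zero_p_one(self):
        res = kruskal_wallis({"a": [5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_hand_computed_two_group_value(self):
        # groups {1,2,3} vs {4,5,6}: rank sums 6 and 15,
        # H = 12/(6*7) * (36/3 + 225/3) - 3*7 = 27/7
        res = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert res.statistic == pytest.approx(27.0 / 7.0, abs=1e-12)
        assert res.statistic == pytest.approx(3.857, abs=1e-3)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            groups = {
                "a": rng.normal(0, 1, 8),
                "b": rng.normal(0.5, 1, 6),
                "c": rng.normal(1, 2, 7),
            }
            mine = kruskal_wallis(groups)
            ref = sps.kruskal(*groups.values())
            assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert mine.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_ties_match_scipy(self):
        groups = {"a": [1, 1, 2, 3], "b": [2, 2, 3, 3], "c": [1, 3, 3]}
        mine = kruskal_wallis(groups)
        ref = sps.kruskal(*groups.values())
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)

    def test_permutation_agrees_with_chi2_at_small_n(self):
        rng = np.random.default_rng(1)
        groups = {"a": rng.normal(0, 1, 4), "b": rng.normal(1.5, 1, 4)}
        chi2 = kruskal_wallis(groups, method="chi2")
        perm = kruskal_wallis(groups, method="permutation")
        assert perm.method == "permutation"
        # chi-squared is an approximation; require agreement, not equality
        assert perm.pvalue == pytest.approx(chi2.pvalue, abs=0.12)

    def test_permutation_p_is_exact_tail_fraction(self):
        groups = {"a": [1.0, 2.0], "b": [3.0, 4.0]}
        res = kruskal_wallis(groups, method="permutation")
        # brute force over all C(4,2)=6 assignments
        pooled = [1.0, 2.0, 3.0, 4.0]
        h_obs = kruskal_wallis(groups).statistic
        count = 0
        for combo in itertools.combinations(range(4), 2):
            rest = [i for i in range(4) if i not in combo]
            h = kruskal_wallis(
                {"a": [pooled[i] for i in combo], "b": [pooled[i] for i in rest]}
            ).statistic
            if h >= h_obs - 1e-12:
                count += 1
        assert res.pvalue == pytest.approx(count / 6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_wallis({"a": [1.0], "b": []})

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        groups = {"a": rng.uniform(1, 2, 6), "b": rng.uniform(1.5, 3, 5)}
        before = kruskal_wallis(groups)
        after = kruskal_wallis({k: np.exp(v) for k, v in groups.items()})
        assert before.statistic == pytest.approx(after.statistic, rel=1e-12)


def _dunn_oracle(groups):
    """Textbook Dunn z for every pair, recomputed independently."""
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[k], float) for k in names])
    ranks = sps.rankdata(pooled)
    n = pooled.size
    mean_rank = {}
    start = 0
    for k in names:
        sz = len(groups[k])
        mean_rank[k] = ranks[start:start + sz].mean()
        start += sz
    _, counts = np.unique(pooled, return_counts=True)
    ties = float(np.sum(counts**3 - counts))
    a = n * (n + 1) / 12.0 - ties / (12.0 * (n - 1))
    out = {}
    for g1, g2 in itertools.combinations(names, 2):
        se = np.sqrt(a * (1 / len(groups[g1]) + 1 / len(groups[g2])))
        out[(g1, g2)] = (mean_rank[g1] - mean_rank[g2]) / se
    return out


class TestDunn:
    def test_identical_groups_give_z_zero_p_one(self):
        res = dunn_pairwise({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res["z"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_two_group_direction_consistent_with_rank_sum(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 10)
        b = rng.normal(2, 1, 10)
        res = dunn_pairwise({"a": a, "b": b})
        u_p = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert res["z"].iloc[0] < 0  # a ranks below b
        assert (res["pvalue"].iloc[0] < 0.05) == (u_p < 0.05)

    def test_three_groups_match_formula_oracle(self):
        rng = np.random.default_rng(4)
        groups = {
            "a": rng.normal(0, 1, 7).tolist(),
            "b": rng.normal(1, 1, 5).tolist(),
            "c": rng.normal(2, 1, 6).tolist(),
        }
        res = dunn_pairwise(groups).set_index(["group1", "group2"])
        oracle = _dunn_oracle(groups)
        for pair, z in oracle.items():
            assert res.loc[pair, "z"] == pytest.approx(z, rel=1e-12)
            assert res.loc[pair, "pvalue"] == pytest.approx(2 * sps.norm.sf(abs(z)), rel=1e-12)

    def test_unadjusted_by_default_with_optional_holm_sidak(self):
        rng = np.random.default_rng(5)
        groups = {k: rng.normal(i, 1, 6) for i, k in enumerate("abc")}
        plain = dunn_pairwise(groups)
        assert "pvalue_adjusted" not in plain.columns
        adj = dunn_pairwise(groups, p_adjust="holm-sidak")
        assert (adj["pvalue_adjusted"] >= adj["pvalue"] - 1e-15).all()


class TestOneSampleT:
    def test_symmetric_about_one_gives_t_zero(self):
        res = one_sample_t_vs_one([0.9, 1.1])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_matches_closed_form(self):
        vals = np.array([1.2, 1.25, 1.15, 1.2])
        res = one_sample_t_vs_one(vals)
        t = (vals.mean() - 1.0) / (vals.std(ddof=1) / np.sqrt(vals.size))
        assert res.statistic == pytest.approx(t, rel=1e-12)

    def test_p_matches_numeric_t_density_integration(self):
        vals = np.array([1.05, 0.9, 1.3, 1.1, 0.95])
        res = one_sample_t_vs_one(vals)
        df = vals.size - 1
        tail, _ = integrate.quad(lambda x: sps.t.pdf(x, df), abs(res.statistic), np.inf)
        assert res.pvalue == pytest.approx(2 * tail, rel=1e-8)

    def test_degenerate_zero_sd(self):
        with pytest.warns(UserWarning, match="zero variance"):
            res = one_sample_t_vs_one([1.2, 1.2, 1.2, 1.2])
        assert res.degenerate and res.pvalue == 0.0
        with pytest.warns(UserWarning):
            res1 = one_sample_t_vs_one([1.0, 1.0])
        assert res1.pvalue == 1.0


class TestHolmSidak:
    def test_single_p_unchanged(self):
        assert holm_sidak([0.03])[0] == pytest.approx(0.03)

    def test_two_p_closed_form(self):
        adj = holm_sidak([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99**2)
        assert adj[0] == pytest.approx(0.0199)

    def test_dominance_and_monotonicity(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, 12)
        adj = holm_sidak(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(0, 0.5, 8)
        _, ref, _, _ = multipletests(p, method="holm-sidak")
        assert np.allclose(holm_sidak(p), ref)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak([0.5, 1.2])


def _ct_table(folds, noise=0.0, n=4, seed=0):
    return generate_qpcr_plate(
        ["SAND1"] + list(folds), folds, "SAND1", ct_noise_sd=noise, n_replicates=n, seed=seed
    )


class TestDdct:
    def test_identical_groups_give_fold_one(self):
        table = _ct_table({"G1": 1.0, "G2": 1.0})
        res = ddct(table, "SAND1")
        assert np.allclose(res.summary["fold_change"], 1.0)

    def test_fold_half_from_plus_one_ct(self):
        table = _ct_table({"G1": 0.5})
        res = ddct(table, "SAND1")
        row = res.summary.set_index("gene").loc["G1"]
        assert row["ddct"] == pytest.approx(1.0, abs=1e-12)
        assert row["fold_change"] == pytest.approx(0.5, abs=1e-12)

    def test_reference_gene_fold_is_exactly_one(self):
        table = _ct_table({"G1": 0.42, "G2": 2.06}, noise=0.3, seed=3)
        res = ddct(table, "SAND1")
        assert res.summary.set_index("gene").loc["SAND1", "fold_change"] == 1.0

    def test_global_per_sample_ct_shift_cancels(self):
        table = _ct_table({"G1": 0.42, "G2": 2.06}, noise=0.2, seed=4)
        res1 = ddct(table, "SAND1")
        shifted = table.copy()
        offsets = {s: i * 1.7 for i, s in enumerate(shifted["sample"].unique())}
        shifted["ct"] = shifted["ct"] + shifted["sample"].map(offsets)
        res2 = ddct(shifted, "SAND1")
        assert np.allclose(
            res1.summary["fold_change"], res2.summary["fold_change"], rtol=1e-10
        )

    def test_technical_replicates_averaged_first(self):
        table = _ct_table({"G1": 2.0})
        collapsed = table.groupby(["sample", "group", "gene"], as_index=False)["ct"].mean()
        res1 = ddct(table, "SAND1")
        res2 = ddct(collapsed, "SAND1")
        assert np.allclose(res1.summary["fold_change"], res2.summary["fold_change"])

    def test_missing_reference_names_the_sample(self):
        table = _ct_table({"G1": 1.0})
        broken = table[~((table["sample"] == "treated_2") & (table["gene"] == "SAND1"))]
        with pytest.raises(ValueError, match="treated_2"):
            ddct(broken, "SAND1")

    def test_missing_control_group_rejected(self):
        table = _ct_table({"G1": 1.0})
        with pytest.raises(ValueError, match="control group"):
            ddct(table[table["group"] == "treated"], "SAND1")

    def test_noisy_recovery_of_reported_fold_changes(self):
        """Plates simulated with the observed ARR6/AS2/CLV3-style fold
        changes are recovered within the replicate t-interval."""
        folds = {"ARR6": 0.42, "AS2": 0.36, "CLV3": 2.06}
        table = _ct_table(folds, noise=0.2, n=4, seed=11)
        res = ddct(table, "SAND1")
        treated = res.per_sample[res.per_sample["group"] == "treated"]
        for gene, true_fold in folds.items():
            dd = treated.loc[treated["gene"] == gene, "ddct"].to_numpy()
            ci = sps.t.interval(0.95, dd.size - 1, loc=dd.mean(),
                                scale=dd.std(ddof=1) / np.sqrt(dd.size))
            lo, hi = 2.0 ** (-ci[1]), 2.0 ** (-ci[0])
            assert lo <= true_fold <= hi
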