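"""Rank-based statistical battery: Kruskal-Wallis, Dunn, BH-FDR, Spearman."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sbmpet.stats import (
    bh_fdr,
    dunn_posthoc,
    kruskal_wallis,
    run_cognition_analysis,
    run_group_analysis,
    spearman,
    validate_metadata,
)

from _oracles import bh_stepup_reject


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        # ranks 1..9 in three groups of three: H = 12/(9*10) * sum(Rg^2/3) - 3*10 = 7.2
        values = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
        groups = np.repeat(["a", "b", "c"], 3)
        h, df, p = kruskal_wallis(values, groups)
        assert h == pytest.approx(7.2, abs=1e-10)
        assert df == 2

    def test_invariant_to_subject_permutation(self, rng):
        values = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        perm = rng.permutation(30)
        h1, _, p1 = kruskal_wallis(values, groups)
        h2, _, p2 = kruskal_wallis(values[perm], groups[perm])
        assert h1 == pytest.approx(h2, abs=1e-12) and p1 == pytest.approx(p2, abs=1e-12)

    def test_invariant_to_monotone_transform(self, rng):
        values = rng.normal(size=24)
        groups = np.repeat(["a", "b", "c"], 8)
        h1, _, _ = kruskal_wallis(values, groups)
        h2, _, _ = kruskal_wallis(np.exp(values), groups)
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_all_identical_is_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            h, df, p = kruskal_wallis(np.ones(9), np.repeat(["a", "b", "c"], 3))
        assert (h, p) == (0.0, 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis(np.arange(4.0), np.array(["a", "a", "a", "a"]))


class TestDunn:
    def test_identical_groups_null(self):
        res = dunn_posthoc(np.ones(9), np.repeat(["a", "b", "c"], 3))
        assert all(r["p"] == pytest.approx(1.0) for r in res)

    def test_separated_groups_hand_formula(self):
        # pooled ranks 1..6, mean ranks 1.5/3.5/5.5, var base n(n+1)/12 = 3.5
        values = np.array([1.0, 2.0, 10.0, 11.0, 20.0, 21.0])
        groups = np.repeat(["a", "b", "c"], 2)
        res = {tuple(r["pair"]): r for r in dunn_posthoc(values, groups)}
        se = np.sqrt(3.5)  # * sqrt(1/2 + 1/2)
        assert res[("a", "b")]["z"] == pytest.approx(-2.0 / se, abs=1e-12)
        assert res[("a", "c")]["z"] == pytest.approx(-4.0 / se, abs=1e-12)
        # only the extreme pair reaches two-sided p < 0.05 at n = 2 per group
        assert res[("a", "c")]["p"] == pytest.approx(0.032509, abs=1e-5)
        assert res[("a", "b")]["p"] == pytest.approx(0.285049, abs=1e-5)

    def test_symmetric_under_label_swap(self, rng):
        # relabelling a<->b reverses the reported pair; the z for the same
        # ordered pair flips sign and the p-value is unchanged
        values = rng.normal(size=12)
        groups = np.repeat(["a", "b"], 6)
        swapped = np.where(groups == "a", "b", "a")
        r1 = dunn_posthoc(values, groups)[0]
        r2 = dunn_posthoc(values, swapped)[0]
        assert r1["pair"] == ("a", "b") and r2["pair"] == ("b", "a")
        assert r1["z"] == pytest.approx(r2["z"], abs=1e-12)  # same ranks either way
        assert r1["p"] == pytest.approx(r2["p"], abs=1e-12)


class TestBhFdr:
    def test_step_up_hand_example(self):
        # p_(4) = 0.03 <= 4/5 * 0.05 = 0.04, so ranks 1..4 are rejected
        p = [0.001, 0.01, 0.02, 0.03, 0.9]
        adjusted, rejected = bh_fdr(p, 0.05)
        np.testing.assert_array_equal(rejected, [True, True, True, True, False])
        assert np.all(adjusted >= np.asarray(p))

    def test_all_ones_nothing_rejected(self):
        adjusted, rejected = bh_fdr(np.ones(6), 0.05)
        assert not rejected.any() and np.all(adjusted == 1.0)

    def test_matches_brute_force_step_up(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 20))
            p = rng.random(m)
            adjusted, rejected = bh_fdr(p, 0.05)
            np.testing.assert_array_equal(rejected, bh_stepup_reject(p, 0.05))
            np.testing.assert_array_equal(rejected, adjusted <= 0.05)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12), st.floats(0.001, 0.999))
    def test_adding_larger_p_never_removes_rejection(self, ps, extra_frac):
        p = np.asarray(ps)
        _, rejected = bh_fdr(p, 0.05)
        bigger = min(1.0, max(ps) + (1 - max(ps)) * extra_frac)
        _, rejected2 = bh_fdr(np.append(p, bigger), 0.05)
        assert np.all(rejected2[:-1] | ~rejected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2], 0.05)


class TestSpearman:
    def test_monotone_function_gives_one(self):
        x = np.array([0.1, 1.0, 2.0, 5.0, 9.0])
        rho, p, n = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0) and n == 5

    def test_reversed_order_gives_minus_one(self):
        x = np.arange(6.0)
        rho, _, _ = spearman(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_rank_difference_example(self):
        # d = (0, 1, 1, -1, 1): sum d^2 = 8 -> rho = 1 - 6*8/(5*24) = 0.6
        rho, p, n = spearman([1, 2, 3, 4, 5], [3, 1, 2, 5, 4])
        assert rho == pytest.approx(0.6, abs=1e-12)

    def test_pairwise_deletion_reports_n(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, np.nan]
        y = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        rho, p, n = spearman(x, y)
        assert n == 4 and rho == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            spearman([1, 2, 3], [1, 2, 3])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            spearman([1, 2, 3, 4], [5, 5, 5, 5])


def _meta(groups, scores=None):
    n = len(groups)
    base = {
        "subject_id": [f"s{i}" for i in range(n)],
        "group": groups,
        "cdr_sb": (np.arange(n) % 7) / 2.0, "mmse": np.arange(n) % 30,
        "lmii": np.arange(n) % 15, "ravlt_delay": np.arange(n) % 12,
    }
    if scores:
        base.update(scores)
    return pd.DataFrame(base)


class TestGroupAnalysis:
    def test_planted_shift_is_family_minimum(self, rng):
        groups = np.repeat(["CN", "MCI", "AD"], [10, 8, 12])
        mixing = rng.normal(size=(30, 4))
        shift = {"CN": 3.0, "MCI": 1.5, "AD": 0.0}
        mixing[:, 1] += np.array([shift[g] for g in groups])
        table = run_group_analysis(mixing, _meta(list(groups)))
        omni = table[table["comparison"] == "omnibus"].set_index("component")
        assert omni["p_value"].idxmin() == 1
        assert omni.loc[1, "rejected"]

    def test_exactly_k_omnibus_rows(self, rng):
        groups = list(np.repeat(["CN", "MCI", "AD"], 4))
        table = run_group_analysis(rng.normal(size=(12, 5)), _meta(groups))
        assert (table["comparison"] == "omnibus").sum() == 5
        # Dunn rows: 3 pairs per component, unadjusted
        assert (table["comparison"] != "omnibus").sum() == 15
        assert table.loc[table["comparison"] != "omnibus", "p_adjusted"].isna().all()

    def test_missing_group_rejected(self, rng):
        groups = list(np.repeat(["CN", "MCI"], 6))
        with pytest.raises(ValueError, match="absent"):
            run_group_analysis(rng.normal(size=(12, 3)), _meta(groups))

    def test_permuted_labels_reject_at_most_nominal_rate(self, rng):
        groups = np.repeat(["CN", "MCI", "AD"], [10, 8, 12])
        mixing = rng.normal(size=(30, 4))
        rejections = 0
        n_perms = 200
        for _ in range(n_perms):
            permuted = list(rng.permutation(groups))
            table = run_group_analysis(mixing, _meta(permuted))
            rejections += table.loc[table["comparison"] == "omnibus", "rejected"].sum()
        assert rejections / (n_perms * 4) <= 0.05


class TestCognitionAnalysis:
    def test_planted_link_recovered_in_symptomatic_cohort(self, demo_cohort):
        _, meta, truth = demo_cohort
        table = run_cognition_analysis(truth.loadings_true, meta, cohort="symptomatic_only")
        cell = table.set_index(["component", "score"]).loc[(0, "mmse")]
        assert abs(cell["statistic"]) >= 0.7
        assert cell["rejected"]

    def test_full_cohort_n_bookkeeping(self, demo_cohort):
        _, meta, truth = demo_cohort
        sym = run_cognition_analysis(truth.loadings_true, meta, cohort="symptomatic_only")
        full = run_cognition_analysis(truth.loadings_true, meta, cohort="full")
        n_cn = (meta["group"] == "CN").sum()
        for score in ("mmse", "cdr_sb"):
            n_s = sym.set_index(["component", "score"]).loc[(0, score), "n"]
            n_f = full.set_index(["component", "score"]).loc[(0, score), "n"]
            assert n_f == n_s + n_cn  # no missing scores in the synthetic cohort

    def test_row_cardinality(self, rng):
        groups = list(np.repeat(["CN", "MCI", "AD"], 4))
        meta = _meta(groups, scores={"mmse": rng.normal(25, 2, 12).round()})
        table = run_cognition_analysis(rng.normal(size=(12, 3)), meta, cohort="full")
        assert len(table) == 3 * 4  # components x scores

    def test_unknown_cohort_rejected(self, rng):
        with pytest.raises(ValueError, match="cohort"):
            run_cognition_analysis(rng.normal(size=(12, 2)), _meta(list(np.repeat(["CN", "MCI", "AD"], 4))), cohort="nope")


def test_validate_metadata_reorders_to_matrix_order():
    meta = _meta(["CN", "MCI", "AD"])
    out = validate_metadata(meta, subject_ids=["s2", "s0", "s1"])
    assert list(out["subject_id"]) == ["s2", "s0", "s1"]
    with pytest.raises(ValueError, match="missing"):
        validate_metadata(meta, subject_ids=["s0", "s9"])
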