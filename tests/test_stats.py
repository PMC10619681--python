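"""Rank tests, FDR control, ROC metrics: checked against independent oracles."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hpglyco.stats import (
    bh_adjust,
    evaluate_markers,
    operating_point,
    roc_auc,
    roc_curve,
    stratified_evaluate,
    tier_counts,
    wilcoxon_rank_sum,
)


# ---------------------------------------------------------------- oracles
def permutation_wilcoxon_p(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration (tie-free data):
    2 x min(P(U <= u_obs), P(U >= u_obs)), clipped at 1."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for a in x for b in y if a > b)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        us.append(sum(1 for a in xs for b in ys if a > b))
    us = np.array(us)
    p_low = (us <= u_obs).mean()
    p_high = (us >= u_obs).mean()
    return min(1.0, 2 * min(p_low, p_high))


def pair_counting_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    case, ctrl = scores[labels], scores[~labels]
    wins = sum(1.0 for a in case for b in ctrl if a > b)
    ties = sum(1.0 for a in case for b in ctrl if a == b)
    return (wins + 0.5 * ties) / (len(case) * len(ctrl))


def step_up_bh(p):
    """Hand implementation of the BH step-up formula."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


# ---------------------------------------------------------------- wilcoxon
class TestWilcoxon:
    def test_separated_small_sample_exact_p(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1, abs=1e-12)  # 2 / C(6,3)
        assert res.direction == -1

    def test_identical_samples(self):
        res = wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0 and res.direction == 0

    def test_argument_swap_symmetry(self, rng):
        x, y = rng.normal(0, 1, 7), rng.normal(1, 1, 9)
        a, b = wilcoxon_rank_sum(x, y), wilcoxon_rank_sum(y, x)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)
        assert a.direction == -b.direction

    @pytest.mark.parametrize("n1, n2", [(2, 3), (3, 3), (4, 5), (5, 6), (6, 6)])
    def test_exact_path_matches_full_enumeration(self, n1, n2, rng):
        for _ in range(5):
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
            x, y = pooled[:n1], pooled[n1:]
            assert wilcoxon_rank_sum(x, y).p_value == pytest.approx(
                permutation_wilcoxon_p(x, y), abs=1e-12
            )

    def test_normal_approximation_close_to_exact_at_n8(self):
        """Exhaustive over all U values at n1 = n2 = 8, tie-free: the
        continuity-corrected normal approximation tracks the exact p to
        ~0.011 (worst case 0.0109, at the distribution center)."""
        from scipy.stats import mannwhitneyu

        def ranks_for_u(u):
            # 8 distinct ranks in 1..16 summing to 36 + u, so U1 = u
            ranks = list(range(1, 9))
            need, top = u, 16
            for i in range(7, -1, -1):
                inc = min(need, top - ranks[i])
                ranks[i] += inc
                need -= inc
                top = ranks[i] - 1
            return ranks

        worst = 0.0
        for u in range(0, 65):
            x = np.array(ranks_for_u(u), float)
            y = np.array(sorted(set(range(1, 17)) - set(ranks_for_u(u))), float)
            exact = wilcoxon_rank_sum(x, y).p_value  # exact path: min(n) = 8
            approx = mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").pvalue
            worst = max(worst, abs(exact - approx))
        assert worst < 0.011

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1.0], [2.0, 3.0])


# ---------------------------------------------------------------- BH
class TestBH:
    def test_single_p(self):
        q, flags = bh_adjust([0.03])
        assert q[0] == pytest.approx(0.03) and flags[0]

    def test_hand_example(self):
        q, _ = bh_adjust([0.01, 0.02, 0.9])
        assert np.allclose(q, [0.03, 0.03, 0.9])

    def test_empty(self):
        q, flags = bh_adjust([])
        assert len(q) == 0 and len(flags) == 0

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_step_up_formula(self, ps):
        q, flags = bh_adjust(ps, fdr=0.2)
        assert np.allclose(q, step_up_bh(ps))
        assert np.all(flags == (q <= 0.2))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=30))
    def test_q_monotone_in_p_rank(self, ps):
        q, _ = bh_adjust(ps)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)


# ---------------------------------------------------------------- ROC
class TestAUC:
    def test_perfect_and_tied(self):
        assert roc_auc([1, 2, 10, 20], [False, False, True, True]) == 1.0
        assert roc_auc([5, 5, 5, 5], [False, False, True, True]) == 0.5

    def test_hand_example(self):
        # cases (3, 5), controls (1, 4): wins 3>1, 5>1, 5>4 of 4 pairs
        assert roc_auc([3, 5, 1, 4], [True, True, False, False]) == 0.75

    def test_label_swap_complement(self, rng):
        scores = rng.normal(0, 1, 30)
        labels = rng.random(30) < 0.4
        if labels.any() and not labels.all():
            assert roc_auc(scores, labels) == pytest.approx(
                1 - roc_auc(scores, ~labels), abs=1e-12
            )

    @pytest.mark.parametrize("n", [5, 12, 50])
    def test_matches_pair_counting_and_sklearn(self, n, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(5):
            scores = np.round(rng.normal(0, 1, n), 1)  # induce ties
            labels = np.zeros(n, bool)
            labels[: n // 2] = True
            labels = rng.permutation(labels)
            auc = roc_auc(scores, labels)
            assert auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)

    def test_one_class_empty_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True])


class TestROCCurveAndOperatingPoints:
    def test_endpoints_present_and_monotone(self, rng):
        scores = rng.normal(0, 1, 40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        curve = roc_curve(scores, labels)
        assert curve.sensitivity[0] == 0 and curve.specificity[0] == 1
        assert curve.sensitivity[-1] == 1 and curve.specificity[-1] == 0
        # sensitivity non-increasing as specificity increases (threshold order)
        assert np.all(np.diff(curve.sensitivity) >= 0)
        assert np.all(np.diff(curve.specificity) <= 0)

    def test_perfect_marker(self):
        curve = roc_curve([1, 2, 10, 20], [False, False, True, True])
        assert operating_point(curve, "specificity") == 1.0
        assert operating_point(curve, "sensitivity") == 1.0

    def test_hand_example_sensitivity_at_90_specificity(self):
        curve = roc_curve([3, 5, 1, 4], [True, True, False, False])
        # spec >= 0.9 forces the threshold above the control at 4
        assert operating_point(curve, "specificity") == 0.5

    def test_useless_marker_yields_one_minus_level(self, rng):
        scores = rng.normal(0, 1, 2000)
        labels = np.repeat([True, False], 1000)
        curve = roc_curve(scores, labels)
        assert operating_point(curve, "specificity", 0.90) == pytest.approx(
            0.10, abs=0.04
        )


# ---------------------------------------------------------------- marker evaluation
def _frame_and_meta(rng, n_markers=6, n_per_group=12):
    samples = [f"s{i}" for i in range(3 * n_per_group)]
    meta = pd.DataFrame(
        {"group": ["control"] * n_per_group + ["early"] * n_per_group
         + ["late"] * n_per_group},
        index=pd.Index(samples, name="sample"),
    )
    data = rng.normal(10, 1, (n_markers, len(samples)))
    matrix = pd.DataFrame(data, index=[f"N184|HexNAc({4 + i})Hex(5)" for i in range(n_markers)],
                          columns=samples)
    return matrix, meta


class TestEvaluateMarkers:
    def test_designed_marker_tops_ranking(self, rng):
        matrix, meta = _frame_and_meta(rng)
        matrix.iloc[0, meta["group"].to_numpy() == "early"] += 3.0  # strong marker
        res = evaluate_markers(matrix, meta, ("control", "early"))
        assert res[0].marker == matrix.index[0]
        assert res[0].significant and res[0].auc_oriented > 0.9

    def test_down_regulated_marker_auc_below_half_fixed(self, rng):
        matrix, meta = _frame_and_meta(rng)
        matrix.iloc[1, meta["group"].to_numpy() == "early"] -= 3.0
        res = evaluate_markers(matrix, meta, ("control", "early"))
        hit = next(r for r in res if r.marker == matrix.index[1])
        assert hit.auc_fixed < 0.5 and hit.orientation == -1
        assert hit.auc_oriented == pytest.approx(1 - hit.auc_fixed)
        assert hit.sens_at_90spec > 0.8  # oriented operating point is informative

    def test_permuted_labels_respect_fdr(self, rng):
        """Null data: the average flagged fraction stays near the BH bound."""
        fracs = []
        for _ in range(60):
            matrix, meta = _frame_and_meta(rng, n_markers=15)
            res = evaluate_markers(matrix, meta, ("control", "early"))
            fracs.append(np.mean([r.significant for r in res]))
        margin = 3 * np.std(fracs) / np.sqrt(len(fracs))
        assert np.mean(fracs) <= 0.20 + margin

    def test_degenerate_contrast_rejected(self, rng):
        matrix, meta = _frame_and_meta(rng)
        with pytest.raises(ValueError):
            evaluate_markers(matrix, meta, ("early", "early"))

    def test_hcc_pool_uses_both_stages(self, rng):
        matrix, meta = _frame_and_meta(rng, n_per_group=10)
        res = evaluate_markers(matrix, meta, ("control", "hcc"))
        assert res[0].n_case == 20 and res[0].n_control == 10

    def test_tier_counts_banded_vs_nested(self):
        from hpglyco.stats import MarkerResult

        def mk(auc):
            return MarkerResult("m", "c", 5, 5, 0.5, 0.5, False, auc, max(auc, 1 - auc),
                                1, 0, 0)

        res = [mk(a) for a in (0.95, 0.85, 0.78, 0.72, 0.60)]
        tiers = tier_counts(res)
        assert tiers["banded"] == {">0.90": 1, "0.80-0.90": 1, "0.75-0.80": 1,
                                   "0.70-0.75": 1}
        assert tiers["nested"] == {">0.90": 1, ">0.80": 2, ">0.75": 3, ">0.70": 4}


class TestStratified:
    def test_small_stratum_skipped(self, rng):
        matrix, meta = _frame_and_meta(rng)
        meta["phenotype"] = "2-1"
        meta.iloc[:9, meta.columns.get_loc("phenotype")] = "1-1"
        out = stratified_evaluate(matrix, meta, ("control", "early"), "phenotype")
        assert "1-1" in out.skipped and "2-1" in out.per_stratum

    def test_whole_cohort_stratum_matches_unstratified(self, rng):
        matrix, meta = _frame_and_meta(rng)
        meta["phenotype"] = "2-2"
        out = stratified_evaluate(matrix, meta, ("control", "early"), "phenotype")
        direct = evaluate_markers(matrix, meta, ("control", "early"))
        strat = out.per_stratum["2-2"]
        assert [m.marker for m in strat] == [m.marker for m in direct]
        assert [m.auc_fixed for m in strat] == [m.auc_fixed for m in direct]
        assert np.allclose(out.comparison["delta"], 0.0)

    def test_phenotype_neutral_effect_consistent_across_strata(self, rng):
        matrix, meta = _frame_and_meta(rng, n_markers=4, n_per_group=40)
        matrix.iloc[0, meta["group"].to_numpy() == "early"] += 1.5
        meta["phenotype"] = np.where(rng.random(len(meta)) < 0.5, "2-1", "2-2")
        out = stratified_evaluate(matrix, meta, ("control", "early"), "phenotype")
        aucs = [out.per_stratum[s][0].auc_oriented for s in ("2-1", "2-2")]
        assert abs(aucs[0] - aucs[1]) < 0.15  # sampling error only
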