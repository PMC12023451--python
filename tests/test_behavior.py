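import numpy as np
import pandas as pd
import pytest

from olfephys import synth
from olfephys.behavior import (
    auc_se,
    block_performance,
    classify_trial,
    compare_auc,
    roc_curve,
    select_window,
    trial_score,
)


def pairwise_auc_oracle(pos_scores, neg_scores):
    """Normalized Mann–Whitney U with half credit for ties (brute force)."""
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p in pos_scores for n in neg_scores
    )
    return wins / (len(pos_scores) * len(neg_scores))


class TestClassification:
    @pytest.mark.parametrize(
        "label,licks,expected",
        [
            ("CS+", "1;1;1;1", "hit"),
            ("CS+", "1;0;1;0", "miss"),  # all-intervals criterion
            ("CS+", "0;0;0;0", "miss"),
            ("CS-", "0;0;0;0", "correct_rejection"),
            ("CS-", "1;1;1;1", "false_alarm"),
        ],
    )
    def test_outcomes(self, label, licks, expected):
        assert classify_trial(label, licks) == expected

    def test_any_lick_criterion_option(self):
        assert classify_trial("CS+", "1;0;0;0", require_all=False) == "hit"

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            classify_trial("CS?", "1;1;1;1")


class TestBlockPerformance:
    def test_perfect_session_reaches_criterion(self):
        sess = synth.gen_session(synth.SessionSpec(p_lick_csplus=1.0, p_lick_csminus=0.0, seed=0))
        blocks, reached = block_performance(sess)
        assert all(b.percent_correct == 100.0 for b in blocks)
        assert reached

    def test_chance_session_does_not(self):
        sess = synth.gen_session(
            synth.SessionSpec(p_lick_csplus=0.5, p_lick_csminus=0.5,
                              lick_semantics="trial", seed=1)
        )
        blocks, reached = block_performance(sess)
        assert not reached
        assert 25 <= np.mean([b.percent_correct for b in blocks]) <= 75

    def test_two_good_blocks_reach_criterion(self, session_factory):
        # blocks 0 and 2: 18/20 correct (90 %); block 1 at chance
        rows = []
        for blk, good in [(0, True), (1, False), (2, True)]:
            for i in range(10):
                hit = good or i < 5
                rows.append(("CS+", 4 if hit else 0))
            for i in range(10):
                cr = (good and i < 8) or (not good and i < 5)
                rows.append(("CS-", 0 if cr else 4))
        sess = session_factory(rows)
        blocks, reached = block_performance(sess)
        assert blocks[0].percent_correct == 90.0
        assert reached
        # the stricter three-consecutive-blocks variant is not satisfied here
        _, reached3 = block_performance(sess, criterion_mode="consec3")
        assert not reached3

    def test_counts_sum_to_valid_trials(self, session_factory):
        sess = session_factory([("CS+", 4), ("CS+", 0), ("CS-", 4), ("CS-", 0)] * 5)
        blocks, _ = block_performance(sess)
        assert all(b.n_valid == 20 for b in blocks)

    def test_invalid_trials_excluded(self, session_factory):
        sess = session_factory([("CS+", 4)] * 10 + [("CS-", 0)] * 10)
        sess.loc[0, "valid_flag"] = False
        blocks, _ = block_performance(sess)
        assert blocks[0].n_valid == 19

    def test_percent_correct_invariant_under_reordering(self, session_factory):
        rng = np.random.default_rng(0)
        sess = session_factory([("CS+", int(rng.integers(0, 5))) for _ in range(10)]
                               + [("CS-", int(rng.integers(0, 5))) for _ in range(10)])
        shuffled = sess.sample(frac=1, random_state=1).reset_index(drop=True)
        p1 = block_performance(sess)[0][0].percent_correct
        p2 = block_performance(shuffled)[0][0].percent_correct
        assert p1 == p2

    def test_empty_session_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            block_performance(pd.DataFrame(columns=["valid_flag"]))


class TestROC:
    def test_perfect_discrimination_gives_auc_one(self, session_factory):
        sess = session_factory([("CS+", 4)] * 30 + [("CS-", 0)] * 30)
        roc = roc_curve(sess)
        assert roc.auc == 1.0
        assert roc.se_auc == 0.0
        assert tuple(roc.points[0]) == (0.0, 0.0) and tuple(roc.points[-1]) == (1.0, 1.0)

    def test_binary_responder_single_point_trapezoid(self, session_factory):
        # TPR 0.8, FPR 0.2 with all-or-none licks → AUC (0.8 + 1 − 0.2)/2 = 0.8
        sess = session_factory(
            [("CS+", 4)] * 8 + [("CS+", 0)] * 2 + [("CS-", 4)] * 2 + [("CS-", 0)] * 8
        )
        assert roc_curve(sess).auc == pytest.approx(0.8)

    def test_auc_equals_mann_whitney_oracle(self, session_factory):
        rng = np.random.default_rng(3)
        for trial in range(5):
            rows = [("CS+", int(rng.integers(0, 5))) for _ in range(8)] + [
                ("CS-", int(rng.integers(0, 5))) for _ in range(8)
            ]
            sess = session_factory(rows)
            pos = [trial_score(r) for _, (lab, r2) in enumerate(rows) if lab == "CS+"
                   for r in [";".join(["1"] * r2 + ["0"] * (4 - r2))]]
            neg = [trial_score(";".join(["1"] * c + ["0"] * (4 - c)))
                   for lab, c in rows if lab == "CS-"]
            assert roc_curve(sess).auc == pytest.approx(pairwise_auc_oracle(pos, neg), abs=1e-12)

    def test_stimulus_independent_licking_averages_to_half(self):
        aucs = []
        for i in range(300):
            sess = synth.gen_session(
                synth.SessionSpec(n_blocks=3, p_lick_csplus=0.5, p_lick_csminus=0.5, seed=i)
            )
            aucs.append(roc_curve(select_window(sess, "first60")).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_single_class_window_rejected(self, session_factory):
        sess = session_factory([("CS+", 4)] * 10)
        with pytest.raises(ValueError, match="both CS"):
            roc_curve(sess)

    def test_windows_select_valid_trials_in_order(self):
        sess = synth.gen_session(synth.SessionSpec(seed=2))
        first = select_window(sess, "first60")
        last = select_window(sess, "last60")
        assert len(first) == len(last) == 60
        assert first.trial_index.iloc[0] == 0
        assert last.trial_index.iloc[-1] == 199


class TestAUCStandardError:
    def test_formula_limits(self):
        assert auc_se(1.0, 30, 30) == 0.0
        assert auc_se(0.5, 1, 1) == pytest.approx(0.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            auc_se(1.2, 10, 10)
        with pytest.raises(ValueError):
            auc_se(0.5, 0, 10)

    def test_against_bootstrap_oracle(self):
        """Hanley–McNeil SE within 15 % of a brute-force bootstrap SE of the AUC."""
        rng = np.random.default_rng(0)
        pos = rng.binomial(4, 0.55, 30)
        neg = rng.binomial(4, 0.45, 30)
        a_hat = pairwise_auc_oracle(pos, neg)
        boots = []
        for _ in range(400):
            bp = rng.choice(pos, 30)
            bn = rng.choice(neg, 30)
            boots.append(pairwise_auc_oracle(bp, bn))
        se_boot = float(np.std(boots))
        assert auc_se(a_hat, 30, 30) == pytest.approx(se_boot, rel=0.15)


class TestCompareAUC:
    def test_equal_aucs_give_z_zero_p_one(self, session_factory):
        sess = session_factory([("CS+", 4)] * 15 + [("CS+", 0)] * 15
                               + [("CS-", 4)] * 15 + [("CS-", 0)] * 15)
        roc = roc_curve(sess)
        z, p = compare_auc(roc, roc)
        assert z == 0.0 and p == 1.0

    def test_large_difference_is_significant(self, session_factory):
        a = session_factory([("CS+", 4)] * 29 + [("CS+", 0)] * 1
                            + [("CS-", 0)] * 29 + [("CS-", 4)] * 1)  # AUC ≈ 0.97
        b = session_factory([("CS+", 4)] * 21 + [("CS+", 0)] * 9
                            + [("CS-", 0)] * 21 + [("CS-", 4)] * 9)  # AUC ≈ 0.72
        z, p = compare_auc(roc_curve(a), roc_curve(b))
        assert p < 0.01

    def test_antisymmetric_in_argument_order(self, session_factory):
        a = session_factory([("CS+", 4)] * 25 + [("CS+", 0)] * 5
                            + [("CS-", 0)] * 25 + [("CS-", 4)] * 5)
        b = session_factory([("CS+", 4)] * 18 + [("CS+", 0)] * 12
                            + [("CS-", 0)] * 18 + [("CS-", 4)] * 12)
        z1, p1 = compare_auc(roc_curve(a), roc_curve(b))
        z2, p2 = compare_auc(roc_curve(b), roc_curve(a))
        assert z1 == -z2 and p1 == p2

    def test_type_one_error_under_equal_auc(self, session_factory):
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            rocs = []
            for _ in range(2):
                rows = [("CS+", int(s)) for s in rng.binomial(4, 0.6, 30)] + [
                    ("CS-", int(s)) for s in rng.binomial(4, 0.4, 30)
                ]
                rocs.append(roc_curve(session_factory(rows)))
            _, p = compare_auc(*rocs)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_sim <= 0.08
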