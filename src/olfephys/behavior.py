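"""Go/no-go session scoring, block performance, and ROC/AUC group comparison.

Sessions are trial tables (see ``traces.SESSION_COLUMNS``): each trial has a
block index, a CS label (CS+ rewarded / CS− unrewarded), per-0.5 s-interval
lick flags, and a validity flag.  A trial counts as a lick response when every
required interval contains at least one lick; hits and correct rejections are
correct responses.  The learning criterion is ≥85 % correct in two blocks of a
session (a three-consecutive-blocks variant is available).

The ROC uses the number of lick-positive intervals (0..4) as the graded
decision variable — the minimal graded score consistent with the lick-interval
protocol; sweeping its threshold yields the ROC points and the trapezoidal
AUC, which equals the normalized Mann–Whitney U of the same scores.  AUC
standard errors use the Hanley–McNeil closed form; group comparisons use the
independent-samples z test (different animals, zero correlation term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BlockSummary",
    "ROCResult",
    "parse_licks",
    "classify_trial",
    "trial_score",
    "block_performance",
    "select_window",
    "roc_curve",
    "auc_se",
    "compare_auc",
]

HIT, MISS, FALSE_ALARM, CORRECT_REJECTION = "hit", "miss", "false_alarm", "correct_rejection"
CRITERION_PCT = 85.0


@dataclass(frozen=True)
class BlockSummary:
    block: int
    percent_correct: float
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    @property
    def n_valid(self) -> int:
        return self.hits + self.misses + self.false_alarms + self.correct_rejections


@dataclass(frozen=True)
class ROCResult:
    points: np.ndarray  # (FPR, TPR) pairs from (0,0) to (1,1)
    auc: float
    se_auc: float
    n_pos: int
    n_neg: int
    window: str = "custom"


def parse_licks(interval_licks) -> np.ndarray:
    """Semicolon-joined 0/1 flags (or an iterable of ints) → int array."""
    if isinstance(interval_licks, str):
        return np.array([int(x) for x in interval_licks.split(";")], dtype=int)
    return np.asarray(interval_licks, dtype=int)


def trial_score(interval_licks) -> int:
    """Graded ROC decision variable: number of lick-positive intervals."""
    return int(parse_licks(interval_licks).sum())


def classify_trial(cs_label: str, interval_licks, require_all: bool = True) -> str:
    """Hit / miss / false alarm / correct rejection for one valid trial.

    The lick-response criterion is a lick in **every** interval (the task's
    reward rule); ``require_all=False`` relaxes it to any lick.
    """
    licks = parse_licks(interval_licks)
    responded = bool(licks.all()) if require_all else bool(licks.any())
    if cs_label == "CS+":
        return HIT if responded else MISS
    if cs_label == "CS-":
        return FALSE_ALARM if responded else CORRECT_REJECTION
    raise ValueError(f"unknown CS label {cs_label!r}")


def _valid(session: pd.DataFrame) -> pd.DataFrame:
    if len(session) == 0:
        raise ValueError("empty session")
    return session[session["valid_flag"].astype(bool)]


def block_performance(
    session: pd.DataFrame,
    criterion_pct: float = CRITERION_PCT,
    criterion_blocks: int = 2,
    criterion_mode: str = "any2",
) -> tuple[list[BlockSummary], bool]:
    """Per-block outcome counts and whether the learning criterion was reached.

    ``criterion_mode='any2'``: ≥ ``criterion_pct`` in ≥ ``criterion_blocks``
    blocks anywhere in the session; ``'consec3'``: in three consecutive blocks.
    """
    valid = _valid(session)
    if len(valid) == 0:
        raise ValueError("session has no valid trials")
    summaries = []
    for block, grp in valid.groupby("block", sort=True):
        outcomes = [classify_trial(r.cs_label, r.interval_licks) for r in grp.itertuples()]
        h = outcomes.count(HIT)
        m = outcomes.count(MISS)
        fa = outcomes.count(FALSE_ALARM)
        cr = outcomes.count(CORRECT_REJECTION)
        pct = 100.0 * (h + cr) / len(outcomes)
        summaries.append(BlockSummary(int(block), pct, h, m, fa, cr))
    pcts = np.array([s.percent_correct for s in summaries])
    if criterion_mode == "any2":
        reached = bool(np.sum(pcts >= criterion_pct) >= criterion_blocks)
    elif criterion_mode == "consec3":
        hit3 = np.convolve((pcts >= criterion_pct).astype(int), np.ones(3, dtype=int), "valid")
        reached = bool(len(pcts) >= 3 and hit3.max() >= 3)
    else:
        raise ValueError(f"unknown criterion_mode {criterion_mode!r}")
    return summaries, reached


def select_window(session: pd.DataFrame, window: str = "first60") -> pd.DataFrame:
    """First/last 60 valid trials in presentation order (or 'all')."""
    valid = _valid(session).sort_values("trial_index")
    if window == "all":
        return valid
    if window == "first60":
        return valid.iloc[:60]
    if window == "last60":
        return valid.iloc[-60:]
    raise ValueError(f"unknown window {window!r}")


def roc_curve(trials: pd.DataFrame, window: str = "custom") -> ROCResult:
    """ROC from the interval-count decision variable; AUC by the trapezoidal rule.

    True positive rate is the fraction of CS+ trials at or above a lick-count
    threshold, false positive rate the same for CS−; sweeping the threshold
    from strict to lax traces the curve from (0,0) to (1,1).  All-or-none
    responders yield the single-point trapezoid AUC = (TPR + 1 − FPR)/2.
    """
    valid = _valid(trials)
    scores = np.array([trial_score(r) for r in valid["interval_licks"]])
    is_pos = (valid["cs_label"] == "CS+").to_numpy()
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC window must contain both CS+ and CS− trials")
    pts = [(0.0, 0.0)]
    for thr in np.sort(np.unique(scores))[::-1]:
        tpr = float(np.mean(scores[is_pos] >= thr))
        fpr = float(np.mean(scores[~is_pos] >= thr))
        pts.append((fpr, tpr))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    points = np.array(pts)
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return ROCResult(points, auc, auc_se(auc, n_pos, n_neg), n_pos, n_neg, window)


def auc_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley–McNeil standard error of a trapezoidal AUC.

    se = sqrt[(A(1−A) + (n+−1)(Q1−A²) + (n−−1)(Q2−A²)) / (n+·n−)], with
    Q1 = A/(2−A) and Q2 = 2A²/(1+A).
    """
    if not 0 <= auc <= 1:
        raise ValueError(f"AUC must lie in [0,1], got {auc}")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one trial of each class")
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (
        n_pos * n_neg
    )
    return float(np.sqrt(max(var, 0.0)))


def compare_auc(roc_a: ROCResult, roc_b: ROCResult) -> tuple[float, float]:
    """Independent-groups Hanley–McNeil comparison: z and two-sided normal p."""
    denom = np.hypot(roc_a.se_auc, roc_b.se_auc)
    if denom == 0:
        if roc_a.auc == roc_b.auc:
            return 0.0, 1.0
        raise ValueError("both standard errors are zero with unequal AUCs")
    z = (roc_a.auc - roc_b.auc) / denom
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)
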