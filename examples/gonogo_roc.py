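"""Score a simulated go/no-go session: blocks, learning criterion, ROC/AUC.

A 10-block session with a block-wise learning curve (CS+ lick probability
rising, CS− falling).  Block performance is % correct (hits + correct
rejections); the ROC uses the number of lick-positive 0.5 s intervals as the
graded decision variable, computed over the first and last 60 valid trials.
"""

import numpy as np

from olfephys import behavior, synth

spec = synth.SessionSpec(
    p_lick_csplus=np.linspace(0.55, 0.97, 10),
    p_lick_csminus=np.linspace(0.45, 0.05, 10),
    lick_semantics="trial",
    seed=7,
)
session = synth.gen_session(spec)
blocks, reached = behavior.block_performance(session)
print("block % correct:", [round(b.percent_correct) for b in blocks])
print(f"85 %-in-two-blocks criterion reached: {reached}")

roc_first = behavior.roc_curve(behavior.select_window(session, "first60"), "first60")
roc_last = behavior.roc_curve(behavior.select_window(session, "last60"), "last60")
print(f"AUC first 60 trials: {roc_first.auc:.3f} ± {roc_first.se_auc:.3f}")
print(f"AUC last 60 trials:  {roc_last.auc:.3f} ± {roc_last.se_auc:.3f}")

z, p = behavior.compare_auc(roc_last, roc_first)
print(f"last vs first (Hanley–McNeil, independent groups): z = {z:.2f}, p = {p:.4f}")
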