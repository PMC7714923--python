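"""Evaluate the historical rank-frequency models for a 24-segment inventory.

Prints the probability of the top ranks under Zipf's law, Sigurd's geometric
series, Good's stick-breaking expectation, its negative-log approximation and
the Yule-Simon product form, and verifies the classic reductions: Yule-Simon
collapses to Zipf at lam=1 and to the geometric series at alpha=0.
"""

import numpy as np

from phonotail import RankModel, stick_break_expectation

n = 24
models = {
    "zipf (alpha=1)": RankModel("zipf", n, alpha=1.0),
    "sigurd (lam=0.8)": RankModel("sigurd_geometric", n, lam=0.8),
    "good stick-break": RankModel("good_stickbreak", n),
    "negative log": RankModel("neglog", n),
    "yule-simon (1, 0.8)": RankModel("yule_simon", n, alpha=1.0, lam=0.8),
}
ks = np.arange(1, 6)
print(f"p(rank k) for k = 1..5, inventory of {n} types:")
for name, m in models.items():
    probs = " ".join(f"{p:.4f}" for p in m.rank_pmf(ks))
    print(f"{name:>20}: {probs}")

ys = RankModel("yule_simon", n, alpha=1.0, lam=1.0)
zipf = RankModel("zipf", n, alpha=1.0)
print("\nmax |yule_simon(lam=1) - zipf|      =",
      f"{np.max(np.abs(ys.probabilities() - zipf.probabilities())):.2e}")
ys0 = RankModel("yule_simon", n, alpha=0.0, lam=0.8)
geo = RankModel("sigurd_geometric", n, lam=0.8)
print("max |yule_simon(alpha=0) - sigurd|  =",
      f"{np.max(np.abs(ys0.probabilities() - geo.probabilities())):.2e}")
print("stick-break vector sums to", stick_break_expectation(n).sum())
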