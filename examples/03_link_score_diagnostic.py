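"""Why the differential link score alone is a poor test statistic.

Two inducing links whose genes both change by a mean of 2 between
conditions have the same mean score of 4 — but in one case the per-pair
scores are constant (variance 0) and in the other they range from 2 to 6.
A variance-based test would call the constant case infinitely more
significant, even though the varying case shows exactly the positive
co-variation an inducing link predicts.  The coherent procedure therefore
tests link coherence plus per-gene significance instead of the score.
"""

from cone import SignedLink, differential_link_score

link = SignedLink("j", "k", "non_inhibiting")

# case (a): both genes rise by exactly 2 in every paired sample
case_a = differential_link_score(
    {"j": [0.0, 0.0, 0.0], "k": [0.0, 0.0, 0.0]},
    {"j": [2.0, 2.0, 2.0], "k": [2.0, 2.0, 2.0]},
    link,
)

# case (b): correlated changes (1,1), (2,2), (3,3) — mean change still 2
case_b = differential_link_score(
    {"j": [0.0, 0.0, 0.0], "k": [0.0, 0.0, 0.0]},
    {"j": [1.0, 2.0, 3.0], "k": [1.0, 2.0, 3.0]},
    link,
)

for name, res in (("constant", case_a), ("correlated", case_b)):
    print(f"{name:>11}: per-pair scores={[float(s) for s in res.per_sample_scores]}, "
          f"mean={res.mean_score:.1f}, variance={res.score_variance:.2f}")
# Same mean score (4.0) — only the variance differs, and there is no reason
# to prefer the constant case over the correlated one.
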