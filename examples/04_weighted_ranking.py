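"""Expression-weighted pathway ranking.

When the query miRNAs come with expression changes (e.g. log fold-changes
from a differential-expression experiment), pathways can be ranked so that
strongly dysregulated miRNAs dominate. Each miRNA is scored against every
pathway on its own (its individual consensus targets -> hypergeometric P),
and the pathway score is the expression-weighted sum of -log10 P:

    w_i      = |e_i| / sum_j |e_j|
    score(p) = sum_i w_i * (-log10 P_{i,p})

Magnitudes drive the weights; the sign (up/down) does not, so repression
and induction contribute equally. With a single query miRNA the ranking
reverts exactly to that miRNA's -log10 P ordering.
"""

import mirvote as mv

fx = mv.generate_fixture(mv.planted_spec(seed=0))
store = fx.store()

names = fx.truth["pairs"]["planted_query"]
# Pretend the first two miRNAs changed 8-fold, the rest barely moved.
expression = {m: (3.0 if i < 2 else 0.2) for i, m in enumerate(names)}
query = mv.QuerySet.from_list(names, expression)

ranking = mv.weighted_pathway_ranking(query, store, fx.pathways)

weights = mv.expression_weights(expression)
print("weights:", {m: round(w, 3) for m, w in weights.items()})
print(f"\n{'pathway':<8} {'weighted score':>14}")
for pid, score in ranking[:8]:
    mark = "  <-- planted" if pid == fx.truth["pathways"]["planted_pathway_id"] else ""
    print(f"{pid:<8} {score:>14.3f}{mark}")
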