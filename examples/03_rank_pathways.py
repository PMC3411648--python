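"""Rank pathways for a miRNA set: raw, empirical and BH-adjusted P-values.

Pathway enrichment of the consensus targets uses the cumulative
hypergeometric (upper-tail) test: given `n` target genes inside a universe
of `N` genes, of which `K` belong to the pathway, the raw P-value is
P(overlap >= k). Because pathway sizes and database structure make raw
P-values hard to compare across runs, a resampled null baseline converts
them to empirical P-values: B random miRNA sets of the same size are pushed
through the identical target-calling + enrichment pipeline, and

    empirical P = (r + 1) / (B + 1),  r = #{null raw P <= observed raw P}.
"""

import mirvote as mv
from mirvote.enrichment import add_bh_column

fx = mv.generate_fixture(mv.planted_spec(seed=0))
store = fx.store()
pathways = fx.pathways
universe = mv.default_universe(store, pathways)

query = mv.QuerySet.from_list(fx.truth["pairs"]["planted_query"])
targets = [c.gene_symbol for c in mv.select_targets(query, store)]

rows = mv.enrich(targets, pathways, universe)

# Build (or load from disk, via NullBaseline.save/load) a null baseline
# matched to the query size, then attach empirical P-values.
baseline = mv.build_null_baseline(store, pathways, sizes=[len(query.mirnas)],
                                  reps=200, seed=1)
mv.attach_empirical(rows, baseline, len(query.mirnas))
add_bh_column(rows)  # Benjamini-Hochberg q-values over the raw P column

planted = fx.truth["pathways"]["planted_pathway_id"]
print(f"planted pathway: {planted}\n")
print(f"{'pathway':<8} {'overlap':>7} {'-log10 P':>9} {'empirical P':>12} {'BH q':>8}")
for r in rows[:8]:
    mark = "  <-- planted" if r.pathway_id == planted else ""
    print(f"{r.pathway_id:<8} {r.overlap:>7} {r.neg_log_p:>9.2f} "
          f"{r.empirical_p:>12.4f} {r.bh_q:>8.4f}{mark}")
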