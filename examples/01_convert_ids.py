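"""Convert miRNA identifiers across annotation versions.

miRNA names drift between annotation releases: hairpins get renamed, star
strands get re-labelled, and some entries are retired outright. Any analysis
that joins a user's miRNA list against a prediction database must first map
every identifier onto the database's annotation version and flag the ones
that cannot be trusted.

This example builds a synthetic registry (so it runs fully offline) and
walks through the three interesting cases: a renamed miRNA, a retired entry,
and a lookup by sequence when the name is unknown.
"""

import mirvote as mv
from mirvote.simulate import FixtureSpec

fx = mv.generate_fixture(FixtureSpec(seed=0))
registry = fx.registry()

# 1. A name from an old annotation release resolves to its current name.
result = mv.convert_id("hsa-miR-189", registry)
print(f"hsa-miR-189  ->  {result.latest_name}   (status: {result.status})")

# 2. A retired accession is flagged, not silently dropped or passed through.
retired_acc = fx.truth["registry"]["retired_accessions"][0]
result = mv.convert_id(retired_acc, registry)
print(f"{retired_acc}  ->  status: {result.status}, usable: {result.usable}")

# 3. Batch conversion returns one record per input and logs a summary.
batch = mv.convert_batch(["hsa-miR-189", retired_acc, "not-a-mirna"], registry)
for r in batch:
    print(f"  {r.query:>16}  status={r.status:<15} latest={r.latest_name}")

# 4. When only the sequence is known, match it against the registry.
#    DNA alphabet is accepted (T is transliterated to U); matching is
#    ungapped, so a candidate must contain the query within `max_mismatches`.
entry = registry.entries[fx.truth["registry"]["active_accessions"][0]]
hits = mv.match_sequence(entry.sequence.replace("U", "T"), registry, max_mismatches=1)
best, mismatches = hits[0]
print(f"sequence lookup: {len(hits)} hit(s); best = "
      f"{best.accession} with {mismatches} mismatches")
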