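"""Generate a synthetic prediction database with a planted ground truth.

The simulator emits everything the analysis consumes — a versioned alias
registry, mature sequences, per-algorithm prediction tables, a validated-
pair table and a GMT pathway file — plus a `fixture.truth.json` sidecar
recording what was planted. The analysis code never reads the sidecar; it
exists so tests and benchmarks can check recovery against a known answer.

Key generator knobs (see FixtureSpec):
- hit_profile: distribution of algorithm-agreement counts per pair
  (default: 75% of pairs predicted by one algorithm, 16% by two, ...),
  allocated exactly via largest-remainder rounding, not sampled.
- planted: a PlantedSignal makes `n_query_mirnas` miRNAs share high-hit
  predictions for a reserved gene block, and builds one pathway from it.
"""

from pathlib import Path

import mirvote as mv
from mirvote.simulate import FixtureSpec, PlantedSignal

spec = FixtureSpec(
    n_mirnas=80,
    n_genes=500,
    n_pairs=8_000,
    n_pathways=20,
    planted=PlantedSignal(n_query_mirnas=4, pathway_size=15, strength=0.8),
    seed=11,
)
fx = mv.generate_fixture(spec)

out = Path("example_db")
paths = fx.write(out)
print("wrote:")
for key, p in sorted(paths.items()):
    print(f"  {key:<22} {p}  ({p.stat().st_size} bytes)")

print("\nplanted query miRNAs:", fx.truth["pairs"]["planted_query"])
print("planted pathway:     ", fx.truth["pathways"]["planted_pathway_id"])

# The written directory round-trips through the normal loaders:
store = mv.load_predictions(
    {t: paths[f"predictions:{t}"] for t in fx.algorithms},
    validated_files={"validated": paths["validated"]},
)
print(f"\nreloaded store: {store.n_prediction_rows} prediction rows, "
      f"{len(store.mirna_universe())} miRNAs, fingerprint {store.fingerprint()}")
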