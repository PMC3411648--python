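# Methods

This document records the statistical model, the defaults and their
rationale, the numerical conventions, and what the synthetic fixture
generator does and does not emulate.

## 1. Identifier conversion

miRNA annotation releases rename, re-strand and retire entries. The registry
is a versioned alias table: each record maps an accession to a name over a
half-open interval of annotation versions, with the version order declared in
a `#versions:` header line. Conversion resolves a query name or accession to
the entry's current name and reports one of five statuses:

- `already_current` — the query is the latest name;
- `converted` — an older name resolved to the current one;
- `retired` — the accession has no open record; excluded from analysis and
  logged as a warning, never silently dropped or passed through;
- `unknown` — no record matches;
- `ambiguous` — a historical name now belongs to several accessions. If one
  of the candidates carries the name *currently*, that holder wins;
  otherwise the result lists the candidates and is unusable.

`usable` is true only for `already_current` and `converted`.

**Sequence matching.** When only a sequence is known, `match_sequence` scans
all registry sequences with ungapped comparison: equal lengths use the
Hamming distance; unequal lengths slide the shorter sequence over the longer
and take the minimum mismatch count over fully contained windows, without
charging the length difference. Mature miRNAs are ≤ 30 nt, so the exhaustive
scan is exact and fast; no heuristic alignment (seeding, gapping) is needed
or wanted. DNA input is transliterated (T→U) and the transliteration is
logged.

## 2. Consensus target calling

**Voting filter.** A (miRNA, gene) pair's *hit count* is the number of
distinct prediction algorithms reporting it. Pairs with hit count ≥
`min_hits` are retained. Experimentally validated pairs bypass the threshold
when `include_validated` is on.

- `min_hits = 3` (default): with typical per-algorithm false-positive rates,
  agreement of three independent methods removes the bulk of
  single-algorithm noise while keeping sensitivity; it is the conventional
  consensus threshold for this class of tool.
- `include_validated = True` (default): experimental evidence outranks
  prediction agreement.

**O/E ratio.** For query set *Q*, let *Q′* be the query miRNAs that have at
least one retained pair (miRNAs contributing nothing are removed from the
denominator, so unpredictable queries do not dilute the signal). For gene
*g*:

- observed(g) = |{m ∈ Q′ : (m, g) retained}| / |Q′|
- expected(g) = |{m ∈ DB : (m, g) retained}| / |DB|, computed with the same
  `min_hits`/`include_validated` as the observed side (symmetry is what makes
  the whole-database query give O/E ≡ 1 — a property the test suite checks
  exactly);
- genes with observed = expected = 0 are excluded rather than scored 0/0.

`min_oe = 2` (default): a gene must be targeted at twice its background rate.
Results are sorted by descending O/E, then gene symbol.

## 3. Pathway enrichment

**Universe.** Default mode `pathways_and_store`: genes appearing in any
pathway **and** in the prediction store. Called targets outside the universe
are dropped (and counted in a log message). Modes `pathways` and `store` are
available when the user wants a broader denominator.

**Raw P.** With universe size *N*, pathway size-in-universe *K*, target count
*n* and overlap *k*, the raw P-value is the cumulative upper tail of the
hypergeometric distribution, `P(X ≥ k)`, computed as
`scipy.stats.hypergeom.sf(k − 1, N, K, n)`. The test suite verifies this
against exhaustive rational-arithmetic enumeration for every parameter
combination with N ≤ 12 (tolerance 1e−12) and the worked case
`P(X ≥ 3 | K=4, n=5, N=10) = 66/252`.

**Reporting.** `-log10 P`, with P floored at 1e−300 before the logarithm to
avoid −inf. Rows are sorted by descending `-log10 P`, ties broken by pathway
id. A Benjamini–Hochberg q-value column is available as an optional extra
(`add_bh_column`, via statsmodels); it adjusts the raw P-values and is not
part of the core ranking.

**Empirical P.** Raw hypergeometric P-values are not comparable across
pathway sizes and database structures, so a resampled null is used: for each
query size *s*, draw *B* sets of *s* miRNAs uniformly without replacement
from the store, push each through the *identical* pipeline
(voting → O/E → enrichment), and store the per-pathway sorted raw P-values.
Then

    empirical P = (r + 1) / (B + 1),  r = #{null raw P ≤ observed raw P}

The +1 convention keeps P in (0, 1] and is the standard unbiased estimator
for resampling tests. Null draws that yield no consensus targets contribute
raw P = 1 for every pathway. Baselines serialize to JSON with metadata
(seed, filter parameters, store fingerprint); loading against a different
store fails loudly. If the query size is absent from the baseline, the
nearest available size is used and logged.

**Calibration caveat.** Empirical P-values are uniform under the null only
where the null raw-P distribution is close to continuous. Small pathways
have an atom at raw P = 1 (null draws with zero overlap), which caps
attainable uniformity. The calibration test therefore checks the *largest*
pathway (by universe-intersected size) — a rule fixed a priori, not chosen
per run — with a two-sided Kolmogorov–Smirnov test at p > 0.01 for query
sizes 3 and 5 with B = 200.

## 4. Expression-weighted ranking

Weights `w_i = |e_i| / Σ_j |e_j|` use magnitudes only: strong repression and
strong induction are equally informative about pathway involvement. Each
query miRNA is scored alone through the same `select_targets` path (so the
voting/O/E semantics are identical), giving per-miRNA raw P-values `P_ip`;
the pathway score is `Σ_i w_i · (−log10 P_ip)`. All-zero expression vectors
are rejected as degenerate. Single-miRNA queries revert exactly to the
`-log10 P` ordering — an acceptance-tested identity.

## 5. Synthetic fixture generator

The generator exists so the full stack can be exercised offline with a known
answer. Defaults (`FixtureSpec`):

- 200 miRNAs, 2,000 genes, 7 algorithms, 100,000 prediction pairs. The pair
  density is anchored to published single-miRNA scales (a well-annotated
  miRNA having predictions for roughly a quarter of genes, of which ~20%
  survive consensus filtering); sparser defaults produce unrealistically
  frequent zero-overlap queries and break empirical-P calibration.
- Hit-count profile {1: 0.75, 2: 0.16, 3: 0.05, 4: 0.03, 5: 0.01} — three
  quarters of predicted pairs are single-algorithm noise, matching the
  motivating observation for consensus voting. Counts are allocated
  *exactly* by largest-remainder rounding, so the generated hit-1 fraction
  deviates from 0.75 only through pair-collision resolution (< 2% at ≥
  10,000 pairs, acceptance-tested).
- 100 pathways of 10–60 genes; 60 validated pairs (half overlapping existing
  predictions, half novel zero-hit pairs to exercise the bypass).
- Registry: annotation versions v6–v17; 30% of miRNAs carry a historical
  alias; 5% are retired. A fixed regression alias (`hsa-miR-189` →
  `hsa-miR-24-1*`) is always present, modelling a real, documented renaming
  of that miRNA between annotation releases.
- Planted signal (`planted_spec`): 5 query miRNAs share high-hit (≥ 4
  algorithms) predictions for a reserved block of genes; one pathway of 30
  genes draws `strength = 0.8` of its members from that block. Background
  pairs never touch the reserved block, so the truth sidecar is exact.

**What it does not emulate:** real binding-site sequence features, 3′UTR
lengths, algorithm-specific biases or correlations between algorithms
(algorithm assignments are exchangeable given the hit count), expression
correlation structure, and pathway overlap/hierarchy (pathways other than
the planted one are sampled independently). Conclusions about *relative
algorithm quality* cannot be drawn from fixtures; conclusions about the
pipeline's statistical behaviour can.

Everything is driven by `numpy.random.default_rng(seed)` with spawned child
streams per stage; identical seeds give byte-identical files, baselines and
result CSVs (acceptance-tested).

## 6. Numerical conventions

- P-value floor 1e−300 before `log10`; base-10 logarithms throughout.
- Hypergeometric tail via `scipy.stats.hypergeom.sf(k−1, N, K, n)` with
  explicit domain validation (raises on k < 0, K > N, n > N, k > min(K, n)).
- Deterministic orderings everywhere: targets by (−O/E, gene symbol),
  enrichment by (−log10 P, pathway id), baseline pathway axis in input
  order, JSON with fixed key order.
- The vectorized enrichment context used for baselines computes
  `expected = db_counts / n_db` with the same floating-point expression as
  the public API, so both routes agree bit-for-bit at threshold boundaries;
  its pathway-membership matrix is integer, not boolean, because a boolean
  matrix product would OR-reduce instead of counting overlaps.

## 7. Limitations

- Empirical P resolution is 1/(B+1); B = 200 suffices for calibration
  checks, real analyses should use B ≥ 1,000.
- The O/E ratio has no variance model; it is a filter, not a test. Genes
  with tiny expected proportions can pass on a single observation — the
  enrichment stage, not the O/E stage, carries the inference.
- Sequence matching is ungapped by design; indel-containing variants of a
  mature sequence will not be found.
- BH q-values are computed over raw P-values, whose null is not exactly
  uniform for small pathways; treat them as a screening aid.
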