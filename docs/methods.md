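# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-ensemble generator does and
does not emulate, and the numerical and design choices that were genuinely
open.

## Agreement-rate stratification

For one clinical case, let the ensemble contain `n` queried models of
which `m` returned a usable response (status `ok`). Candidates are first
clustered into diagnosis concepts (below); a cluster supported by `k`
distinct models has agreement rate `k / m` under the default
`responding_models` denominator, or `k / n` under
`all_queried_models`. Clusters are classified

- PRIMARY if rate ≥ 0.30,
- ALTERNATIVE if 0.10 ≤ rate < 0.30,
- MINORITY if rate < 0.10,

with both boundaries inclusive on their lower edge. The three strata
partition the cluster set; within a stratum clusters are ordered by rate
descending, then mean confidence descending, then canonical label
ascending (a total, deterministic order).

The denominator choice matters when models time out or overflow: counting
a silent failure as disagreement biases every rate downward. A model that
expressed no opinion is therefore excluded from the default denominator;
the literal all-queried behavior remains available as a config switch for
comparison.

Model-level consensus categories use the per-case *majority cluster*: the
top PRIMARY cluster, or the highest-rate cluster when PRIMARY is empty. A
model is aligned on a case iff any of its candidates belongs to that
cluster (models return ranked lists, not single answers; a stricter
rank-1-only mode is provided). The alignment rate over the cases a model
answered maps to high (≥ 0.60), moderate ([0.30, 0.60)), or low (< 0.30).
The 0.60 boundary belongs to "high" because only the high category's edge
is stated inclusively; "moderate" is the half-open interval below it. A
model that answered zero cases gets an undefined rate and category "low",
with a warning rather than an error.

## Label clustering

Agreement is counted over concepts, not strings. Labels are canonicalized
(accent fold, lowercase, apostrophes dropped, punctuation to whitespace,
whitespace collapsed; a trailing parenthetical such as "(Glycogen Storage
Disease V)" is split off as a secondary alias). Two candidates merge iff
their canonical labels are equal, a curated alias table links them, or
they share an identical full ICD-10 code; merging is transitive
(union-find over the link graph). The cluster's display label is the most
frequent verbatim member label, ties broken lexicographically.

Two deliberately conservative defaults:

- **Full-code equality, not 3-character category match.** Distinct
  diseases regularly share a category (E83.110 hereditary hemochromatosis
  vs E83.01 Wilson's disease); category-level merging exists as an opt-in
  switch.
- **No fuzzy string matching by default.** A silent fuzzy merge is
  precisely the mechanism by which a rare minority diagnosis would
  disappear into a near-named mainstream one — the failure mode the whole
  system exists to prevent. An optional difflib-ratio threshold is
  available for users who want it.

## Hedging-marker counting

Uncertainty and confidence markers are counted against a declared lexicon
(shipped default, fully overridable via YAML). Matching is
case-insensitive, word-boundary anchored, non-overlapping, longest match
first — "cannot rule out" consumes its span so a shorter term inside it is
not double-counted. Counts are total occurrences. Because marker counts
are meaningless without the lexicon that produced them, the lexicon is an
explicit input everywhere, never an ambient global. Both per-case totals
and per-model aggregations are exposed and labeled, since either
convention is defensible.

## Bias attribution

- **Mention rates.** For a target diagnosis (matched canonically and via
  the alias table) or a free-text term (matched in raw response text and
  rationales — suited to temporal and demographic-salience analyses),
  mentions are totaled per provenance group and divided by the number of
  registered models in the group. The normalization base is stated in the
  output (`normalization` field) because "per model" is ambiguous;
  per-registered-model keeps group sizes summing to the ensemble.
  The effect is max minus min group rate, with both groups named.
- **Cost-tier alignment.** Mean majority-alignment rate per tier on the
  percent scale, effect = free − paid, signed. The uncertainty of the
  difference is quantified by a percentile bootstrap over models (default
  1000 resamples); resamples that lose an entire tier carry no information
  about the difference and are dropped.
- **Breadth-consensus association.** Spearman rank correlation between
  per-case consensus and diagnostic breadth. Breadth is a count with a
  heavy right tail, so a rank statistic is the robust choice; a constant
  series has no defined rank correlation and is reported as null (three
  defined cases minimum).

## Report synthesis and failover

Reports are assembled by deterministic templating, not by a generative
model: a reproducible artifact cannot depend on an external text
generator, and everything the report asserts (labels, rates, supporters,
provenance) is already structured. The synthesizer-chain abstraction still
models failover for pluggable backends: ids are tried in order, the first
probe to succeed is used, every failure is logged with its cause, and
exhaustion raises an error carrying the complete attempt log.

The summary uncertainty band maps the consensus rate to high (≥ 80%),
moderate (60–79%), or low (< 60%) consensus — brackets chosen to span the
range heterogeneous ensembles actually produce (roughly 50–95% top-cluster
agreement in simulation), and configurable. Summary mode is a strict
subset of full mode; full mode renders every cluster, so nothing is
averaged away.

## Synthetic-ensemble generator

The generator emulates the statistical structure of a heterogeneous
diagnostic ensemble, with every distribution a construction of this
package (no quantitative generative model exists to copy):

- **Profiles.** Region drawn from a distribution defaulting to
  US 0.65 / Europe 0.10 / China 0.16 / Other 0.09 (the composition of
  current commercial ensembles is US-dominated); cost tier Bernoulli with
  default free fraction 0.5; release date uniform over 2022–2024.
- **Proposals.** Each model proposes each pool diagnosis independently
  with its probability — the simplest mechanism consistent with
  agreement-rate arithmetic; correlated models are out of scope for v1.
  A case may name a regional target whose probability gains δ for models
  of the matching region (validated so p + δ ≤ 1).
- **Hallucination.** With per-case probability `h` (default 0.05) a model
  adds one out-of-pool diagnosis from a fixed list, preserved downstream
  as a flagged speculative hypothesis.
- **Temporal anchoring.** With probability `anachronism_rate` (default
  0.05) a model proposes a historical condition (HIV/AIDS, tuberculosis,
  …) regardless of case relevance — the raw material for temporal mention
  analysis.
- **Confidence.** The first-mentioned candidate draws uniform on
  [0.6, 0.95], declining by a factor 0.85 per rank. These values exercise
  ordering and tie-breaking; they carry no clinical meaning.
- **Hedging.** Raw text carries uncertainty phrases with count
  Poisson(6·α) and confidence phrases Poisson(2·(1−α)), where α ∈ [0, 1]
  is the case's ambiguity.
- **Ambiguity sweeps.** `sweep_case_spec` builds pools whose lead
  probability falls (0.9 → 0.4) and whose 23-label geometric tail
  (decay 0.82) rises (base 0.02 → 0.5) as α goes 0 → 1, so consensus falls
  and breadth rises along the sweep. The tail must be long for this to
  work: with a short flat pool, thirty models saturate every alternative
  and breadth stops varying.

Seeds are mandatory — a `SimulationConfig` without one fails validation —
and all draws flow through a single `numpy` generator in a fixed
iteration order, so output is byte-reproducible. The ground truth
(realized profiles and every per-(model, case, diagnosis) probability
actually used) is retained for recovery tests.

What the generator does **not** emulate: correlated errors between models
trained on overlapping corpora, case-text-dependent reasoning, prompt
sensitivity, or any specific commercial model's behavior. Passing
recovery and calibration tests therefore demonstrates that the pipeline's
statistics are correct and well-calibrated on a known generative process,
not that real LLM ensembles behave like the simulator.

## Verification studies and their operating characteristics

Study conditions (fixed, also used by `scripts/acceptance.py`):

- **Boundary sweeps.** 100-model rate sweep for stratum edges; 0.001-step
  grid for model categories. Exact agreement expected.
- **Exhaustive oracle.** All support multisets with ≤ 10 models and ≤ 6
  diagnoses (19,437 ensembles) against direct inequality evaluation.
- **Regional-boost recovery.** δ = 0.4 on base p = 0.3, 30 models, 12
  cases, 200 seeded replicates; recovered when the boosted region's
  mentions/model exceeds the pooled baseline rate. The dominant failure
  mode is a draw with zero boosted-region models (probability ≈ 1% per
  run at a 16% region share), so the expected pass rate is ≈ 99% against
  a ≥ 95% requirement.
- **Cost-tier null calibration.** No injected cost effect, 100 replicates,
  1000-resample percentile bootstrap; the interval should cover 0 at
  ≈ 95%. The accepted band 85–100% allows binomial noise at 100 runs
  (SE ≈ 2.2%) plus the small-sample undercoverage percentile bootstraps
  exhibit with ~30 models per run.
- **Sweep direction.** α ∈ {0.1, 0.4, 0.7, 1.0} × 3 cases, 200
  replicates; Spearman(consensus, breadth) negative in ≥ 95%.
- **Failover and determinism.** All 2³ availability patterns; two
  identical seeded pipeline runs compared by artifact SHA-256.

## Known limitations

- Offline by design: no ontology services (SNOMED/UMLS), no live model
  APIs; the client contract plus mock and synthetic clients are the
  tested surface.
- The alias table is a small curated starter; real deployments need a
  larger synonym resource.
- Marker counting is lexicon matching, not clinical NLP; negation and
  scope are not modeled.
- Treatment-stance classification (aggressive vs conservative) is not
  implemented — no operational definition exists to implement.
- The orchestrator's time-budget enforcement is bookkeeping (post-hoc
  timeout status), not preemption.
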