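# Methods

This note documents the models, conventions and design choices behind
`clinsearch`, in the order data flows through the system.

## Terminology graphs and semantic expansion

A terminology is a set of concepts with per-language preferred terms and
synonyms and a parent/child hierarchy that must be a DAG (cycles are a hard
load error; terminologies are knowledge-organization systems, not arbitrary
graphs). Cross-terminology mappings are directed edges of kind `exact`,
`broader_to_narrower` or `narrower_to_broader`; every mapping is expected to
have its inverse present (`exact` is its own inverse kind). A missing
inverse is a *repairable* finding — `validate_graph` reports it and
`close_mappings` adds the inverses — rather than a load error, because
mapping asymmetry is common in practice and fixable.

**Expansion semantics.** `expand_concepts(seeds, spec)` is a breadth-first
search over states *(concept, mapping-hops-used)*. Hierarchy edges
(children for `descendants`, parents for `ancestors`) consume the depth
budget (`depth=None` = unbounded); mapping edges of the kinds selected in
`mapping_kinds` consume the single allowed mapping hop (unless
`transitive_mappings=True`) but no depth, and hierarchy expansion continues
in the target terminology with the remaining budget. The result always
contains the seeds and is monotone in depth. Whether mappings should be
crossed transitively during retrieval is genuinely open; the default is a
single hop, exposed as a flag, because transitive closure over heterogeneous
mapping sets is the classic source of semantic drift.

The retrieval default (`DEFAULT_RETRIEVAL_EXPANSION`) is unbounded descent
with exact mappings crossed once — the configuration a clinician refining a
code-based search would expect — and is overridable per query constraint.

## EAV store

Entities are `(type, id)` keys with schema-checked attributes of kind text,
number, date, code or concept-reference (single id or id set). Conventions
chosen for composability, where the underlying data model is silent:

- numeric and date intervals are half-open `[lo, hi)`; dates are ISO-8601 at
  day granularity (invalid dates are rejected at insert);
- an absent attribute never matches any predicate (three-valued logic
  collapsed to false) — sparsely recorded data simply fail to be retrieved;
- concept-valued attributes store terminology-qualified ids; semantic
  expansion happens in the search layer only, never at write time, so stored
  data are independent of expansion defaults.

Secondary indexes are hash maps value → key-set plus a bisect-maintained
sorted list of distinct values per (type, attribute) for range predicates;
text attributes get a token index. The store's core contract is *index ≡
full scan* for every supported predicate; `verify_indexes` re-derives every
posting from a scan, and the test suite asserts the equivalence on
randomized stores. Insertions and links are set-semantic and commute, so any
permutation of a batch yields the same store state.

## Annotation

The matcher is bag-of-words: a lexicon entry is the normalized token
multiset of a term; a match is a minimal token window, bounded to one
sentence, containing the multiset with at most `window` (default 3)
non-matching tokens between consecutive matched tokens, all term tokens
required. Score-1 (complete) matches only are emitted; partial-coverage
scoring exists in the data model but is off by default because emission
thresholds for partial matches cannot be validated without a reference
corpus. Normalization lowercases, strips diacritics (NFKD) and tokenizes on
word characters, keeping decimal numbers ("7,2") and "%" as single tokens;
offsets always index the raw text.

- **Overlaps:** when two matches nest and one entry's token set is a strict
  subset of the other's, only the longer match is kept (standard
  longest-match practice); genuine partial overlaps are both kept, so
  "insuffisance cardiaque NYHA classe III" yields both the heart-failure and
  the NYHA-class annotation.
- **Negation:** a small configurable French trigger list ("pas de",
  "absence de", "sans", "aucun(e)", "ni"), pre-position only, within 5
  tokens and the same sentence. This is a deliberately simple scope model;
  post-position negation and double negation are out of scope.
- **Values:** the nearest same-sentence number token within 5 tokens of the
  mention (ties broken leftward), excluding the mention's own tokens (so the
  "2" of "diabète de type 2" is never a value); the following token is
  attached as the unit when it is in the unit lexicon. The decimal comma is
  accepted.
- **Frequency filtering:** `rank_concept_frequencies` produces the review
  table for the operational workflow in which a human inspects the most
  frequent concepts and stoplists irrelevant ones; the tool never drops
  concepts automatically, because that judgment is clinical.

## Query language and engine

The grammar fixes a concrete syntax for an entity-oriented Boolean query:
named constraints (`C1: type[attr=value].attribute predicate;`), an output
entity type (`OUT patient;`), and a Boolean expression over constraint ids.
The bracketed entity filter is an extension that lets one constraint bind
two attributes of the *same* entity (test type and value of a lab test);
post-projection AND cannot express that, and lab criteria need it.

Engine semantics, where a choice had to be made:

- **Combination after projection.** Each constraint is evaluated natively,
  counted (the per-constraint partial counts a user sees), projected to the
  output type along the schema's shortest relationship path, and only then
  combined. This matches the behaviour in which heterogeneous constraints
  (diagnosis + narrative) combine into patient results.
- **NOT is complement in the stored universe of the output type**, never of
  a constraint's native type: exclusion criteria exclude patients, not
  diagnoses. Whether the original class of systems applies NOT before or
  after projection is not documented; this choice is stated, not inferred.
- **Projection paths** are shortest paths in the schema graph, with
  role-reversal steps; two distinct equal-length paths are an error
  requiring explicit configuration, because a silent arbitrary choice would
  corrupt query semantics. Patient-level constraints emitted at visit level
  fan out to all of the patient's stays.
- **Ordering** is lexicographic by key — a Boolean engine has no relevance
  ranking. Chronological co-occurrence operators are intentionally absent;
  plain date-interval predicates are supported.

`brute_force_evaluate` re-implements the whole contract by exhaustive
entity scans and raw relationship-row traversal; `evaluate ≡
brute_force_evaluate` on randomized query batteries is the engine's core
acceptance property.

## Synthetic data

The generator emulates the shape of warehouse data a prescreening study
needs — demographics, multi-visit stays in medical units, ICD-10-like coded
diagnoses drawn per-patient by prevalence, lab tests (neutrophils, HbA1c,
creatinine) from normal profiles, and short template French narratives with
affirmed, negated and valued mentions — at a default scale of 2,000 patients
/ ~6,000 stays / ~10,000 narratives (seconds on one CPU; all sizes are
parameters). One pseudo-random stream per artifact class derives from the
master seed so adding narrative templates does not perturb the population.

Ground truth is recorded at generation time from the generator's own
records (assigned ages, drawn lab values, planted mentions), never by
running the search engine; `verify_ledger` re-derives every cohort from
plain scans as an independent self-check. Narrative text is template-only by
default (optional distractor sentences use off-lexicon words only), which is
what makes the precision = recall = 1.0 assertions honest: they demonstrate
the pipeline's internal consistency — matcher, negation scope, value rules
and engine agree end to end with the planted facts — **not** performance on
real clinical prose, which is noisier in vocabulary, negation scope and
report structure than any template grammar.

Default condition prevalences (type 2 diabetes 12 %, heart failure 8 %,
hypertension 25 %, ...) and lab profiles are round, adult-hospital-plausible
values; cohort sizes follow from them rather than being tuned. The age
cohort supports exact-size forcing (a single-attribute criterion); the other
cohorts are prevalence-driven with membership recorded exactly. A small
spurious-NYHA rate (3 % of patients without a coded heart failure) keeps the
combined diagnosis-AND-narrative cohort a strict subset of both partial
results, as in real data where text and codes disagree.

## Criteria-support statistics

The confidence intervals on support-level percentages are Wald
(normal-approximation) intervals `p̂ ± z·sqrt(p̂(1−p̂)/n)`, truncated to
[0, 100] and rounded to one decimal. The method was fixed by verifying that
it reproduces every reference interval cell exactly; a p̂ of 0 or 1 yields a
zero-width interval, reported as-is.

Support scores default to full = 100, accurate = 80, broad = 60,
inaccurate = 40, none = 0 (the reference scale is 0–100 without fixed values;
these are configurable, and all fixture-based statistics except the score
means are score-map-independent). Per-trial means optionally weight *full*
criteria twice (`full_double`). The Wilcoxon signed-rank test drops zero
differences, mid-ranks ties, and computes the exact two-sided p for n ≤ 20
by enumerating all 2ⁿ sign assignments, `2·min(P(T≤t), P(T≥t))` capped at 1;
larger n falls back to the tie-corrected normal approximation (which tracks
the exact p within ~0.01 for n ≥ 15).

**Fixture reconstruction.** The packaged 95-criterion record set is
constrained by the reference support-level × criterion-type counts, the
support-level × source-combination matrix, the five trials'
inclusion/exclusion splits (6v16, 9v13, 5v4, 7v13, 9v13) and the reported
property that each trial's full-double-weighted inclusion mean exceeded its exclusion
mean. Within those constraints the assignment of types and trials inside a
level is not individually constrained; a fixed deterministic assignment satisfying all of
them ships in `data/criteria_records.csv`. Obstacle codes are assigned per
level heuristically and no shipped statistic depends on them. The reference
*average* CI widths could not be reproduced from the individual interval cells
under any plausible convention and are deliberately not computed.

## Known limitations

- The annotator is a dictionary matcher: no word-sense disambiguation, no
  embedding-based matching, no handling of document structure.
- The store is in-process and non-transactional; persistence is plain JSONL
  dumps. Distributed execution, caching and latency behaviour of a
  production warehouse are out of scope.
- Clinical levels implement patient / visit / health; a multi-hospital
  source level is not modelled.
- Narrative realism is limited to the template grammar; recall/precision
  results on synthetic text do not transfer to real narratives.
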