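# clinsearch

A desk-scale **semantic clinical data warehouse and search engine** for
cohort selection and clinical-trial prescreening research, with a built-in
evaluation framework for eligibility-criteria support.

Hospitals accumulate heterogeneous data — patient demographics, stays,
ICD-coded diagnoses, lab results, free-text clinical narratives — and the
practical question for trial recruitment is: *which eligibility criteria can
a search system over such a warehouse answer automatically?* `clinsearch`
implements the full stack needed to study that question on synthetic data
with known ground truth:

1. **Terminology portal** (`clinsearch.terminology`) — concept graphs with
   multilingual terms and synonyms, parent/child hierarchies (validated
   DAGs), and `exact` / `broader_to_narrower` / `narrower_to_broader`
   cross-terminology mappings. Concept sets expand by controlled-depth
   hierarchy descent/ascent and mapping hops.
2. **EAV entity store** (`clinsearch.eav`) — a generic
   entity-attribute-value graph held in key-value maps with secondary value
   and text indexes. Every predicate answered through an index is provably
   identical to a full scan (`verify_indexes`, `full_scan`).
3. **Semantic annotator** (`clinsearch.annotator`) — dictionary-driven
   bag-of-words concept matching over French clinical text with negation
   detection ("pas de …"), numeric value + unit extraction ("HbA1c à 7,2 %")
   and frequency-based stoplist workflows.
4. **Boolean entity-oriented search engine** (`clinsearch.query`,
   `clinsearch.engine`) — a formal query grammar with named constraints,
   AND/OR/NOT composition, semantic expansion of concept constraints, and
   projection of every constraint to an output clinical level (patient /
   visit / health) *before* Boolean combination, so that exclusion criteria
   exclude patients rather than diagnoses. A brute-force evaluator provides
   an independent oracle.
5. **Synthetic hospital generator** (`clinsearch.synthdata`) — deterministic
   populations (default 2,000 patients, ~6,000 stays, ~10,000 narratives)
   with planted, ledgered cohorts for five reference criteria: an age range,
   an HbA1c disjunction (≤6.5 % or ≥8 %), a neutrophil threshold
   (<1700/mm³), a negation-aware diabetes narrative search, and a combined
   heart-failure-diagnosis AND NYHA-III/IV-narrative criterion.
6. **Criteria-support statistics** (`clinsearch.evaluation`) — the six-level
   support grading (full/accurate/broad/inaccurate/none/not-applicable) with
   Wald confidence intervals, source-combination tables, automation and
   prescreening rates, per-trial mean support scores and an **exact**
   two-sided Wilcoxon signed-rank test by complete sign-assignment
   enumeration. A reconstructed 95-criterion, five-trial record set ships as
   a fixture.

## Worked example

```python
from clinsearch.engine import evaluate
from clinsearch.pipeline import annotate_dataset
from clinsearch.synthdata import GeneratorParams, build_dataset

ds = build_dataset(GeneratorParams(seed=0, n_patients=2000))
annotate_dataset(ds)                      # annotate narratives, index concepts
res = evaluate(ds.queries["hf_nyha"], ds.store, ds.network)
print(res.partial_counts, len(res.output_keys))
```

prints

```
{'C1': 306, 'C2': 113} 73
```

i.e. the heart-failure diagnosis constraint matches 306 diagnosis entities,
the NYHA III/IV narrative constraint 113 narratives, and their combination
at the patient level prescreens 73 patients — exactly the generator's
planted ground-truth cohort (`ds.ledger.cohorts["hf_nyha"]`). The narrowing
from either partial result to the combined patient set is the behaviour that
makes a Boolean entity-oriented engine useful as a prescreening tool.

Each capability has a narrative script under `examples/`; run them with
`python examples/04_cohort_search.py` etc. A thin CLI mirrors the four-step
search workflow (`clinsearch generate`, `constraint add`, `compose`,
`output set`, `run`, `report`); see `clinsearch --help`.

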