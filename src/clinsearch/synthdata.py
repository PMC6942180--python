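"""Deterministic synthetic hospital data with planted, ledgered ground truth.

Emulates — at desk scale — the kind of population a hospital data warehouse
holds: patients with demographics, multi-visit stays in medical units,
ICD-10-like coded diagnoses, numeric lab results with units, and short
French-like clinical narratives containing concept mentions, negation
phrases and quantitative expressions.  Every generated fact that a shipped
criterion query is supposed to retrieve is recorded in a ground-truth
ledger at generation time, so retrieval quality can be asserted exactly.

Design points
-------------
* One pseudo-random stream per artifact class (patients, stays, labs,
  diagnoses, narratives), all derived from the master seed, so adding
  narrative templates does not perturb the generated population.
* Narrative text is template-only: every sentence is produced by a grammar
  whose intended annotations are known, which makes recall-1.0 assertions
  honest.  Optional distractor sentences use only off-lexicon words.
* Ledger cohort membership is derived from the generator's own records
  (assigned ages, lab values, planted mentions) — never by running the
  search engine under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from . import eav
from .annotator import Document, write_documents
from .eav import Key, Store, default_clinical_schema
from .errors import GenerationError
from .terminology import (
    Concept,
    ConceptMapping,
    SemanticNetwork,
    Terminology,
    save_mappings,
    save_terminology,
)
from .textnorm import norm_text, tokenize

REFERENCE_DATE = date(2018, 1, 1)

DIABETES_FAMILY = ("MEDVOC:DIABETES", "MEDVOC:T1D", "MEDVOC:T2D")
NYHA_SEVERE = ("MEDVOC:NYHA3", "MEDVOC:NYHA4")


@dataclass
class GeneratorParams:
    seed: int = 0
    n_patients: int = 2000
    stays_mean_extra: float = 2.0          # stays per patient = 1 + Poisson(this) -> ~3
    extra_narrative_prob: float = 0.7      # second document per stay -> ~1.7 docs/stay
    #: condition prevalence by ICD-like family code
    prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "ICD10X:E11": 0.12,
            "ICD10X:E10": 0.02,
            "ICD10X:I50": 0.08,
            "ICD10X:I10": 0.25,
            "ICD10X:I48": 0.07,
            "ICD10X:J44": 0.05,
            "ICD10X:J45": 0.06,
        }
    )
    #: lab test -> (mean, sd, unit, decimals)
    lab_profiles: dict[str, tuple[float, float, str, int]] = field(
        default_factory=lambda: {
            "neutrophils": (4200.0, 1400.0, "/mm3", 0),
            "hba1c": (6.3, 1.2, "%", 1),
            "creatinine": (85.0, 25.0, "umol/l", 0),
        }
    )
    lab_prob: float = 0.6                  # probability a stay carries each lab test
    negated_diabetes_prob: float = 0.12    # non-diabetic patients with "pas de diabète"
    nyha_mention_prob: float = 0.65        # heart-failure patients with a NYHA sentence
    spurious_nyha_prob: float = 0.03       # NYHA sentence without a coded heart failure
    age_cohort_size: int | None = None     # force the 18-75 cohort to an exact size
    include_distractors: bool = False

    def __post_init__(self):
        for cid, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise GenerationError(f"prevalence for {cid} outside [0,1]: {p}")
        if self.age_cohort_size is not None and self.age_cohort_size > self.n_patients:
            raise GenerationError("age cohort target size exceeds n_patients")


@dataclass
class GroundTruthLedger:
    cohorts: dict[str, set[Key]] = field(default_factory=dict)
    #: narrative id -> list of (concept, negated, (value, unit) or None)
    mentions: dict[str, list[tuple[str, bool, tuple[float, str | None] | None]]] = field(
        default_factory=dict
    )


@dataclass
class SynthDataset:
    params: GeneratorParams
    network: SemanticNetwork
    store: Store
    documents: list[Document]
    ledger: GroundTruthLedger
    queries: dict[str, str]


# ---------------------------------------------------------------------------
# toy terminology


def _c(cid, fr=None, en=None, parents=(), syn_fr=()):
    pref = {}
    if fr:
        pref["fr"] = fr
    if en:
        pref["en"] = en
    return Concept(
        id=cid,
        preferred_term=pref,
        synonyms={"fr": list(syn_fr)} if syn_fr else {},
        parents=set(parents),
    )


def generate_terminology(params: GeneratorParams | None = None):
    """An ICD-10-like code hierarchy plus a synonym-rich clinical vocabulary
    with exact cross-mappings between the two (French and English labels).

    The content is fixed, hence trivially deterministic per seed."""
    icd = Terminology(id="ICD10X", languages={"fr", "en"})
    for c in [
        _c("ICD10X:ROOT", "racine", "root"),
        _c("ICD10X:E", "maladies endocriniennes", "endocrine diseases", ["ICD10X:ROOT"]),
        _c("ICD10X:E10-E14", "diabète sucré", "diabetes mellitus", ["ICD10X:E"]),
        _c("ICD10X:E10", "diabète de type 1", "type 1 diabetes mellitus", ["ICD10X:E10-E14"]),
        _c("ICD10X:E10.1", "diabète de type 1 avec acidocétose", "type 1 diabetes with ketoacidosis", ["ICD10X:E10"]),
        _c("ICD10X:E10.9", "diabète de type 1 sans complication", "type 1 diabetes without complications", ["ICD10X:E10"]),
        _c("ICD10X:E11", "diabète de type 2", "type 2 diabetes mellitus", ["ICD10X:E10-E14"]),
        _c("ICD10X:E11.0", "diabète de type 2 avec coma", "type 2 diabetes with coma", ["ICD10X:E11"]),
        _c("ICD10X:E11.9", "diabète de type 2 sans complication", "type 2 diabetes without complications", ["ICD10X:E11"]),
        _c("ICD10X:E13", "autres diabètes sucrés précisés", "other specified diabetes", ["ICD10X:E10-E14"]),
        _c("ICD10X:E14", "diabète sucré sans précision", "unspecified diabetes", ["ICD10X:E10-E14"]),
        _c("ICD10X:I", "maladies de l'appareil circulatoire", "circulatory diseases", ["ICD10X:ROOT"]),
        _c("ICD10X:I10", "hypertension essentielle", "essential hypertension", ["ICD10X:I"]),
        _c("ICD10X:I48", "fibrillation et flutter auriculaires", "atrial fibrillation and flutter", ["ICD10X:I"]),
        _c("ICD10X:I50", "insuffisance cardiaque", "heart failure", ["ICD10X:I"]),
        _c("ICD10X:I50.0", "insuffisance cardiaque congestive", "congestive heart failure", ["ICD10X:I50"]),
        _c("ICD10X:I50.1", "insuffisance ventriculaire gauche", "left ventricular failure", ["ICD10X:I50"]),
        _c("ICD10X:I50.9", "insuffisance cardiaque sans précision", "heart failure, unspecified", ["ICD10X:I50"]),
        _c("ICD10X:J", "maladies de l'appareil respiratoire", "respiratory diseases", ["ICD10X:ROOT"]),
        _c("ICD10X:J44", "autres maladies pulmonaires obstructives chroniques", "other COPD", ["ICD10X:J"]),
        _c("ICD10X:J45", "asthme", "asthma", ["ICD10X:J"]),
    ]:
        icd.concepts[c.id] = c

    voc = Terminology(id="MEDVOC", languages={"fr", "en"})
    for c in [
        _c("MEDVOC:DIABETES", "diabète sucré", "diabetes mellitus", syn_fr=["diabète"]),
        _c("MEDVOC:T1D", "diabète de type 1", "type 1 diabetes", ["MEDVOC:DIABETES"],
           syn_fr=["DT1", "diabète insulino-dépendant"]),
        _c("MEDVOC:T2D", "diabète de type 2", "type 2 diabetes", ["MEDVOC:DIABETES"],
           syn_fr=["DT2", "diabète non insulino-dépendant"]),
        _c("MEDVOC:HEART_FAILURE", "insuffisance cardiaque", "heart failure",
           syn_fr=["décompensation cardiaque"]),
        _c("MEDVOC:NYHA1", "NYHA classe I", "NYHA class I", ["MEDVOC:HEART_FAILURE"]),
        _c("MEDVOC:NYHA2", "NYHA classe II", "NYHA class II", ["MEDVOC:HEART_FAILURE"]),
        _c("MEDVOC:NYHA3", "NYHA classe III", "NYHA class III", ["MEDVOC:HEART_FAILURE"]),
        _c("MEDVOC:NYHA4", "NYHA classe IV", "NYHA class IV", ["MEDVOC:HEART_FAILURE"]),
        _c("MEDVOC:HBA1C", "hémoglobine glyquée", "glycated hemoglobin", syn_fr=["HbA1c"]),
        _c("MEDVOC:NEUTRO", "polynucléaires neutrophiles", "neutrophils", syn_fr=["neutrophiles"]),
        _c("MEDVOC:CREAT", "créatinine", "creatinine"),
        _c("MEDVOC:PREGNANCY", "grossesse", "pregnancy", syn_fr=["enceinte"]),
        _c("MEDVOC:HTA", "hypertension artérielle", "arterial hypertension", syn_fr=["HTA"]),
        _c("MEDVOC:AFIB", "fibrillation auriculaire", "atrial fibrillation", syn_fr=["ACFA"]),
        _c("MEDVOC:COPD", "bronchopneumopathie chronique obstructive", "COPD", syn_fr=["BPCO"]),
        _c("MEDVOC:ASTHMA", "asthme", "asthma"),
    ]:
        voc.concepts[c.id] = c

    exact_pairs = [
        ("MEDVOC:DIABETES", "ICD10X:E10-E14"),
        ("MEDVOC:T1D", "ICD10X:E10"),
        ("MEDVOC:T2D", "ICD10X:E11"),
        ("MEDVOC:HEART_FAILURE", "ICD10X:I50"),
        ("MEDVOC:HTA", "ICD10X:I10"),
        ("MEDVOC:AFIB", "ICD10X:I48"),
        ("MEDVOC:COPD", "ICD10X:J44"),
        ("MEDVOC:ASTHMA", "ICD10X:J45"),
    ]
    mappings: list[ConceptMapping] = []
    for a, b in exact_pairs:
        mappings.append(ConceptMapping(a, b, "exact"))
        mappings.append(ConceptMapping(b, a, "exact"))
    mappings.append(ConceptMapping("MEDVOC:DIABETES", "ICD10X:E11", "broader_to_narrower"))
    mappings.append(ConceptMapping("ICD10X:E11", "MEDVOC:DIABETES", "narrower_to_broader"))

    # derive the child links
    for t in (icd, voc):
        for c in t.concepts.values():
            for p in c.parents:
                t.concepts[p].children.add(c.id)
    return [icd, voc], mappings


MEDICAL_UNITS = [
    ("u-card", "Cardiologie"),
    ("u-endo", "Endocrinologie"),
    ("u-urg", "Urgences"),
    ("u-medint", "Medecine interne"),
    ("u-pneumo", "Pneumologie"),
]

#: condition family code -> concrete codes drawn for diagnosis entities
_FAMILY_CODES = {
    "ICD10X:E11": ["ICD10X:E11", "ICD10X:E11.0", "ICD10X:E11.9"],
    "ICD10X:E10": ["ICD10X:E10", "ICD10X:E10.1", "ICD10X:E10.9"],
    "ICD10X:I50": ["ICD10X:I50", "ICD10X:I50.0", "ICD10X:I50.1", "ICD10X:I50.9"],
}

_CONDITION_MENTION = {
    "ICD10X:E11": "MEDVOC:T2D",
    "ICD10X:E10": "MEDVOC:T1D",
    "ICD10X:I10": "MEDVOC:HTA",
    "ICD10X:I48": "MEDVOC:AFIB",
    "ICD10X:J44": "MEDVOC:COPD",
    "ICD10X:J45": "MEDVOC:ASTHMA",
}

_LAB_CONCEPT = {
    "neutrophils": "MEDVOC:NEUTRO",
    "hba1c": "MEDVOC:HBA1C",
    "creatinine": "MEDVOC:CREAT",
}

_DISTRACTORS = [
    "Le patient est rentre a domicile.",
    "Examen clinique realise ce jour.",
    "Suivi prevu en consultation.",
]


@dataclass
class _PatientPlan:
    key: Key
    age: int
    conditions: set[str]          # family codes
    stay_keys: list[Key] = field(default_factory=list)


def _rng(params: GeneratorParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stream])


def generate_population(params: GeneratorParams, network: SemanticNetwork):
    """Patients, stays, units, diagnoses, labs and procedures, plus the
    structured-criteria cohort ledger.

    Returns ``(store, plans, ledger)`` where ``plans`` carries per-patient
    condition assignments for the narrative generator.
    """
    store = Store(default_clinical_schema())
    ledger = GroundTruthLedger()
    for uid, name in MEDICAL_UNITS:
        store.insert_entity(key=("medical_unit", uid), attributes={"code": uid, "name": name})

    rng_p = _rng(params, 0)
    rng_s = _rng(params, 1)
    rng_lab = _rng(params, 2)
    rng_dx = _rng(params, 3)

    n = params.n_patients
    if params.age_cohort_size is None:
        ages = rng_p.integers(0, 95, size=n)
    else:
        k = params.age_cohort_size
        in_range = rng_p.choice(n, size=k, replace=False)
        ages = np.empty(n, dtype=int)
        mask = np.zeros(n, dtype=bool)
        mask[in_range] = True
        ages[mask] = rng_p.integers(18, 76, size=k)
        outside = np.concatenate([np.arange(0, 18), np.arange(76, 95)])
        ages[~mask] = rng_p.choice(outside, size=n - k)
    genders = rng_p.choice(["F", "M"], size=n)

    plans: list[_PatientPlan] = []
    cond_items = sorted(params.prevalence.items())
    for i in range(n):
        pid = f"p{i:05d}"
        key = ("patient", pid)
        age = int(ages[i])
        birth = REFERENCE_DATE - timedelta(days=int(age * 365.25 + int(rng_p.integers(0, 365))))
        store.insert_entity(
            key=key,
            attributes={"gender": str(genders[i]), "birth_date": birth, "age": age},
        )
        conditions = {c for c, p in cond_items if rng_dx.random() < p}
        plans.append(_PatientPlan(key=key, age=age, conditions=conditions))

    age_cohort = {p.key for p in plans if 18 <= p.age < 76}
    if params.age_cohort_size is not None and len(age_cohort) != params.age_cohort_size:
        raise GenerationError("planted age cohort does not match its target size")
    ledger.cohorts["age_18_75"] = age_cohort

    hba1c_cohort: set[Key] = set()
    neutro_cohort: set[Key] = set()
    dx_cohorts: dict[str, set[Key]] = {fam: set() for fam in _FAMILY_CODES}

    for plan in plans:
        n_stays = 1 + int(rng_s.poisson(params.stays_mean_extra))
        for s in range(n_stays):
            sid = f"s-{plan.key[1]}-{s}"
            start = REFERENCE_DATE - timedelta(days=int(rng_s.integers(1, 2100)))
            end = start + timedelta(days=int(rng_s.integers(1, 21)))
            skey = ("stay", sid)
            store.insert_entity(
                key=skey, attributes={"start_date": start, "end_date": end}
            )
            store.link_entities(plan.key, "has_stay", skey)
            unit = MEDICAL_UNITS[int(rng_s.integers(0, len(MEDICAL_UNITS)))][0]
            store.link_entities(skey, "in_unit", ("medical_unit", unit))
            plan.stay_keys.append(skey)

            # diagnoses: carriers always coded on their first stay
            for fam in sorted(plan.conditions):
                if s == 0 or rng_dx.random() < 0.5:
                    codes = _FAMILY_CODES.get(fam, [fam])
                    code = codes[int(rng_dx.integers(0, len(codes)))]
                    dkey = ("diagnosis", f"dg-{sid}-{fam.split(':')[1]}")
                    store.insert_entity(key=dkey, attributes={"code": code})
                    store.link_entities(skey, "has_diagnosis", dkey)
                    if fam in dx_cohorts:
                        dx_cohorts[fam].add(plan.key)

            # labs
            for t, (mean, sd, unit_name, decimals) in sorted(params.lab_profiles.items()):
                if rng_lab.random() < params.lab_prob:
                    v = float(np.round(max(0.1, rng_lab.normal(mean, sd)), decimals))
                    tkey = ("biological_test", f"t-{sid}-{t}")
                    store.insert_entity(
                        key=tkey,
                        attributes={
                            "test_type": t,
                            "value": v,
                            "unit": unit_name,
                            "date": start + timedelta(days=1),
                        },
                    )
                    store.link_entities(skey, "has_test", tkey)
                    if t == "hba1c" and (v <= 6.5 or v >= 8.0):
                        hba1c_cohort.add(plan.key)
                    if t == "neutrophils" and v < 1700.0:
                        neutro_cohort.add(plan.key)

    ledger.cohorts["hba1c_extreme"] = hba1c_cohort
    ledger.cohorts["neutropenia"] = neutro_cohort
    ledger.cohorts["heart_failure_dx"] = dx_cohorts["ICD10X:I50"]
    return store, plans, ledger


def generate_narratives(
    store: Store,
    plans: list[_PatientPlan],
    params: GeneratorParams,
    network: SemanticNetwork,
    ledger: GroundTruthLedger,
) -> list[Document]:
    """Template-generated French-like narratives with an exhaustive mention
    ledger, linked to each patient's stays.

    Completes the narrative-based cohorts in the ledger:
    ``diabetes_narrative`` (affirmed diabetes-family mention) and
    ``hf_nyha`` (coded heart failure AND affirmed NYHA III/IV mention)."""
    rng = _rng(params, 4)
    docs: list[Document] = []
    diabetes_cohort: set[Key] = set()
    nyha_cohort: set[Key] = set()

    def term_of(concept_id: str) -> str:
        c = network.resolve(concept_id)
        terms = c.terms("fr")
        if not terms:
            raise GenerationError(f"no French term for template slot {concept_id}")
        return terms[int(rng.integers(0, len(terms)))]

    def affirmed(concept_id: str):
        return f"Le patient presente : {term_of(concept_id)}.", (concept_id, False, None)

    def negated(concept_id: str):
        return f"Pas de {term_of(concept_id)}.", (concept_id, True, None)

    def valued(test: str):
        concept_id = _LAB_CONCEPT[test]
        mean, sd, unit, decimals = params.lab_profiles[test]
        text_v = f"{max(0.1, rng.normal(mean, sd)):.{decimals}f}"
        v = float(text_v)  # the ledgered value is exactly what the text prints
        if decimals and rng.random() < 0.5:
            text_v = text_v.replace(".", ",")
        # the annotator attaches the unit as the token following the number
        unit_token = tokenize(unit)[0].text
        term = term_of(concept_id)
        return f"{term} a {text_v} {unit}.", (concept_id, False, (v, unit_token))

    def nyha_sentence(klass: int):
        # emits both the heart-failure mention and the NYHA class mention
        nyha = f"MEDVOC:NYHA{klass}"
        roman = {1: "I", 2: "II", 3: "III", 4: "IV"}[klass]
        text = f"Insuffisance cardiaque NYHA classe {roman}."
        return text, [("MEDVOC:HEART_FAILURE", False, None), (nyha, False, None)]

    benign = ["MEDVOC:HTA", "MEDVOC:AFIB", "MEDVOC:COPD", "MEDVOC:ASTHMA"]

    for plan in plans:
        pkey = plan.key
        has_hf = "ICD10X:I50" in plan.conditions
        diab_fams = [f for f in ("ICD10X:E10", "ICD10X:E11") if f in plan.conditions]
        # sentences that must land somewhere in this patient's record
        pending: list[tuple[str, list]] = []
        if diab_fams:
            fam = diab_fams[int(rng.integers(0, len(diab_fams)))]
            s, m = affirmed(_CONDITION_MENTION[fam])
            pending.append((s, [m]))
            diabetes_cohort.add(pkey)
        elif rng.random() < params.negated_diabetes_prob:
            s, m = negated("MEDVOC:T2D" if rng.random() < 0.7 else "MEDVOC:DIABETES")
            pending.append((s, [m]))
        if has_hf and rng.random() < params.nyha_mention_prob:
            klass = int(rng.choice([2, 3, 4], p=[0.35, 0.4, 0.25]))
            s, ms = nyha_sentence(klass)
            pending.append((s, ms))
            if klass >= 3:
                nyha_cohort.add(pkey)
        elif not has_hf and rng.random() < params.spurious_nyha_prob:
            klass = int(rng.choice([2, 3, 4]))
            s, ms = nyha_sentence(klass)
            pending.append((s, ms))
            if klass >= 3:
                # no coded heart failure: contributes to the narrative
                # partial result only, never to the combined cohort
                nyha_cohort.add(pkey)

        for skey in plan.stay_keys:
            n_docs = 1 + (1 if rng.random() < params.extra_narrative_prob else 0)
            for j in range(n_docs):
                did = f"d-{skey[1]}-{j}"
                sentences: list[str] = []
                mentions: list[tuple] = []
                if pending:
                    s, ms = pending.pop(0)
                    sentences.append(s)
                    mentions.extend(ms)
                r = rng.random()
                if r < 0.3:
                    test = sorted(params.lab_profiles)[int(rng.integers(0, len(params.lab_profiles)))]
                    s, m = valued(test)
                    sentences.append(s)
                    mentions.append(m)
                elif r < 0.6:
                    s, m = affirmed(benign[int(rng.integers(0, len(benign)))])
                    sentences.append(s)
                    mentions.append(m)
                elif not sentences or params.include_distractors:
                    sentences.append(_DISTRACTORS[int(rng.integers(0, len(_DISTRACTORS)))])
                text = " ".join(sentences)
                doc = Document(id=did, text=text, language="fr")
                docs.append(doc)
                ledger.mentions[did] = mentions
                store.insert_entity(
                    key=("clinical_narrative", did),
                    attributes={"text": text, "language": "fr"},
                )
                store.link_entities(skey, "has_narrative", ("clinical_narrative", did))
        # any pending sentence not yet placed goes into one extra document
        for k, (s, ms) in enumerate(pending):
            skey = plan.stay_keys[0]
            did = f"d-{skey[1]}-x{k}"
            docs.append(Document(id=did, text=s, language="fr"))
            ledger.mentions[did] = list(ms)
            store.insert_entity(
                key=("clinical_narrative", did), attributes={"text": s, "language": "fr"}
            )
            store.link_entities(skey, "has_narrative", ("clinical_narrative", did))

    ledger.cohorts["diabetes_narrative"] = diabetes_cohort
    ledger.cohorts["hf_nyha"] = ledger.cohorts["heart_failure_dx"] & nyha_cohort
    ledger.cohorts["nyha_severe_narrative"] = nyha_cohort
    return docs


def emit_criterion_queries(params: GeneratorParams | None = None) -> dict[str, str]:
    """One engine query per planted criterion; each query's ground truth is
    the ledger cohort of the same name."""
    return {
        "age_18_75": "C1: patient.age in [18,76); OUT patient; C1",
        "hba1c_extreme": (
            "C1: biological_test[test_type=hba1c].value <= 6.5; "
            "C2: biological_test[test_type=hba1c].value >= 8; "
            "OUT patient; (C1 OR C2)"
        ),
        "neutropenia": (
            "C1: biological_test[test_type=neutrophils].value < 1700; OUT patient; C1"
        ),
        "diabetes_narrative": (
            "C1: clinical_narrative.concepts concept(MEDVOC:DIABETES, depth=unbounded, "
            "direction=descendants, mappings=none, negation=exclude); OUT patient; C1"
        ),
        "hf_nyha": (
            "C1: diagnosis.code concept(ICD10X:I50, depth=unbounded, direction=descendants, "
            "mappings=none); "
            "C2: clinical_narrative.concepts concept(MEDVOC:NYHA3, MEDVOC:NYHA4, depth=0, "
            "mappings=none, negation=exclude); "
            "OUT patient; (C1 AND C2)"
        ),
    }


def build_dataset(params: GeneratorParams | None = None) -> SynthDataset:
    """End-to-end generation: terminology, population, narratives, queries.

    The returned narratives are un-annotated; running the annotator and
    indexing its output into the store is the pipeline under test."""
    params = params or GeneratorParams()
    terms, mappings = generate_terminology(params)
    network = SemanticNetwork(terms, mappings)
    store, plans, ledger = generate_population(params, network)
    docs = generate_narratives(store, plans, params, network, ledger)
    return SynthDataset(
        params=params,
        network=network,
        store=store,
        documents=docs,
        ledger=ledger,
        queries=emit_criterion_queries(params),
    )


def write_dataset(dataset: SynthDataset, directory: str | Path) -> None:
    """Write the dataset in the dialects the other modules consume."""
    d = Path(directory)
    (d / "terminologies").mkdir(parents=True, exist_ok=True)
    for t in dataset.network.terminologies.values():
        save_terminology(t, d / "terminologies" / f"{t.id}.json")
    save_mappings(dataset.network.mappings, d / "mappings.csv")
    eav.write_dumps(dataset.store, d / "entities")
    write_documents(dataset.documents, d / "documents.jsonl")


# ---------------------------------------------------------------------------
# independent self-consistency checker


def verify_ledger(dataset: SynthDataset) -> list[str]:
    """Check every ledger fact against the dumps with plain scans (no
    indexes, no search engine).  Empty list iff self-consistent."""
    problems: list[str] = []
    store = dataset.store
    ents = list(store.entities())
    led = dataset.ledger

    ages = {
        e.key: e.attributes["age"] for e in ents if e.type == "patient"
    }
    expect_age = {k for k, a in ages.items() if 18 <= a < 76}
    if expect_age != led.cohorts["age_18_75"]:
        problems.append("age_18_75 cohort disagrees with a scan of patient ages")

    # map every leaf entity to its patient by scanning relationship rows
    rel = store.relationships()
    stay_of: dict[Key, Key] = {}
    patient_of_stay: dict[Key, Key] = {}
    for src, role, tgt in rel:
        if role == "has_stay":
            patient_of_stay[tgt] = src
        elif role in ("has_test", "has_diagnosis", "has_narrative"):
            stay_of[tgt] = src

    def patient_of(key: Key) -> Key:
        return patient_of_stay[stay_of[key]]

    expect_hba1c, expect_neutro, expect_hf = set(), set(), set()
    for e in ents:
        if e.type == "biological_test":
            v = e.attributes["value"]
            if e.attributes["test_type"] == "hba1c" and (v <= 6.5 or v >= 8.0):
                expect_hba1c.add(patient_of(e.key))
            if e.attributes["test_type"] == "neutrophils" and v < 1700.0:
                expect_neutro.add(patient_of(e.key))
        elif e.type == "diagnosis":
            code = next(iter(e.attributes["code"]))
            if code == "ICD10X:I50" or code.startswith("ICD10X:I50."):
                expect_hf.add(patient_of(e.key))
    if expect_hba1c != led.cohorts["hba1c_extreme"]:
        problems.append("hba1c_extreme cohort disagrees with a scan of lab values")
    if expect_neutro != led.cohorts["neutropenia"]:
        problems.append("neutropenia cohort disagrees with a scan of lab values")
    if expect_hf != led.cohorts["heart_failure_dx"]:
        problems.append("heart_failure_dx cohort disagrees with a scan of diagnosis codes")

    # narrative cohorts from the mention ledger
    docs_by_id = {d.id: d for d in dataset.documents}
    diab, nyha = set(), set()
    for did, mentions in led.mentions.items():
        if did not in docs_by_id:
            problems.append(f"mention ledger references unknown document {did}")
            continue
        text_norm = norm_text(docs_by_id[did].text)
        pat = patient_of(("clinical_narrative", did))
        for concept, neg, _value in mentions:
            terms = dataset.network.resolve(concept).terms("fr")
            if not any(norm_text(t) in text_norm for t in terms):
                problems.append(f"ledgered mention of {concept} not present in {did}")
            if not neg and concept in DIABETES_FAMILY:
                diab.add(pat)
            if not neg and concept in NYHA_SEVERE:
                nyha.add(pat)
    if diab != led.cohorts["diabetes_narrative"]:
        problems.append("diabetes_narrative cohort disagrees with the mention ledger")
    if nyha != led.cohorts["nyha_severe_narrative"]:
        problems.append("nyha_severe_narrative cohort disagrees with the mention ledger")
    if (expect_hf & nyha) != led.cohorts["hf_nyha"]:
        problems.append("hf_nyha cohort is not the intersection of its parts")
    return problems
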