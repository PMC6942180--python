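import numpy as np
import pytest

from clinsearch.pipeline import annotate_dataset
from clinsearch.synthdata import GeneratorParams, build_dataset
from clinsearch.terminology import Concept, ConceptMapping, SemanticNetwork, Terminology


def make_toy_terminology() -> Terminology:
    """A small French/English vocabulary with a 3-level hierarchy."""
    t = Terminology(id="TOY", languages={"fr", "en"})

    def add(cid, fr, parents=(), syn_fr=()):
        t.concepts[cid] = Concept(
            id=cid,
            preferred_term={"fr": fr},
            synonyms={"fr": list(syn_fr)} if syn_fr else {},
            parents=set(parents),
        )

    add("TOY:ROOT", "racine")
    add("TOY:DIAB", "diabète", ["TOY:ROOT"], syn_fr=["diabète sucré"])
    add("TOY:DIAB1", "diabète de type 1", ["TOY:DIAB"])
    add("TOY:DIAB2", "diabète de type 2", ["TOY:DIAB"], syn_fr=["DT2"])
    add("TOY:HF", "insuffisance cardiaque", ["TOY:ROOT"])
    add("TOY:NYHA3", "NYHA classe III", ["TOY:HF"])
    for c in t.concepts.values():
        for p in c.parents:
            t.concepts[p].children.add(c.id)
    return t


@pytest.fixture
def toy_terminology():
    return make_toy_terminology()


@pytest.fixture
def toy_network(toy_terminology):
    other = Terminology(id="OTH", languages={"fr"})
    other.concepts["OTH:D2"] = Concept(id="OTH:D2", preferred_term={"fr": "DNID"})
    other.concepts["OTH:D2X"] = Concept(
        id="OTH:D2X", preferred_term={"fr": "DNID complique"}, parents={"OTH:D2"}
    )
    other.concepts["OTH:D2"].children.add("OTH:D2X")
    mappings = [
        ConceptMapping("TOY:DIAB2", "OTH:D2", "exact"),
        ConceptMapping("OTH:D2", "TOY:DIAB2", "exact"),
    ]
    return SemanticNetwork([toy_terminology, other], mappings)


@pytest.fixture(scope="session")
def small_dataset():
    """Annotated 150-patient dataset shared by engine and pipeline tests."""
    ds = build_dataset(GeneratorParams(seed=7, n_patients=150))
    annotate_dataset(ds)
    return ds


# ---------------------------------------------------------------------------
# random query generation for the oracle-equivalence batteries


def random_query(rng: np.random.Generator) -> str:
    """A random well-formed query over the synthetic schema."""
    constraints = []
    n_constraints = int(rng.integers(1, 4))
    for i in range(1, n_constraints + 1):
        constraints.append(f"C{i}: {_random_constraint(rng)};")
    expr = _random_expr(rng, [f"C{i}" for i in range(1, n_constraints + 1)], depth=2)
    out_type = ["patient", "stay"][int(rng.integers(0, 2))]
    return " ".join(constraints) + f" OUT {out_type}; " + expr


def _random_constraint(rng) -> str:
    kind = int(rng.integers(0, 6))
    if kind == 0:
        a = int(rng.integers(0, 80))
        b = a + int(rng.integers(1, 40))
        return f"patient.age in [{a},{b})"
    if kind == 1:
        g = ["F", "M"][int(rng.integers(0, 2))]
        return f'patient.gender = "{g}"'
    if kind == 2:
        test = ["hba1c", "neutrophils", "creatinine"][int(rng.integers(0, 3))]
        thresholds = {"hba1c": (4, 12), "neutrophils": (1000, 8000), "creatinine": (40, 160)}
        lo, hi = thresholds[test]
        t = float(rng.uniform(lo, hi))
        op = ["<=", ">=", "<", ">"][int(rng.integers(0, 4))]
        return f"biological_test[test_type={test}].value {op} {t:.1f}"
    if kind == 3:
        seeds = ["ICD10X:I50", "ICD10X:E10-E14", "ICD10X:E11", "ICD10X:I", "ICD10X:J45"]
        seed = seeds[int(rng.integers(0, len(seeds)))]
        depth = ["0", "1", "2", "unbounded"][int(rng.integers(0, 4))]
        mappings = ["none", "exact"][int(rng.integers(0, 2))]
        return f"diagnosis.code concept({seed}, depth={depth}, mappings={mappings})"
    if kind == 4:
        seeds = ["MEDVOC:DIABETES", "MEDVOC:T2D", "MEDVOC:HEART_FAILURE", "MEDVOC:NYHA3", "MEDVOC:HTA"]
        k = int(rng.integers(1, 3))
        chosen = ", ".join(sorted({seeds[int(rng.integers(0, len(seeds)))] for _ in range(k)}))
        neg = ["exclude", "include"][int(rng.integers(0, 2))]
        depth = ["0", "unbounded"][int(rng.integers(0, 2))]
        return (
            f"clinical_narrative.concepts concept({chosen}, depth={depth}, "
            f"mappings=none, negation={neg})"
        )
    start_year = 2012 + int(rng.integers(0, 5))
    return f"stay.start_date in [{start_year}-01-01,{start_year + 1}-06-30)"


def _random_expr(rng, cids, depth) -> str:
    if depth == 0 or (len(cids) == 1 and rng.random() < 0.5):
        return cids[int(rng.integers(0, len(cids)))]
    r = rng.random()
    if r < 0.2:
        return f"NOT {_random_expr(rng, cids, depth - 1)}"
    op = "AND" if r < 0.6 else "OR"
    left = _random_expr(rng, cids, depth - 1)
    right = _random_expr(rng, cids, depth - 1)
    return f"({left} {op} {right})"
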