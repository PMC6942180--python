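"""EAV store: schema checks, indexing vs full-scan equivalence, traversal."""

import random
from datetime import date

import pytest

from clinsearch.eav import (
    DateInterval,
    Entity,
    Equals,
    NumericCmp,
    NumericInterval,
    Store,
    TokenContains,
    default_clinical_schema,
    define_schema,
    read_dumps,
    write_dumps,
)
from clinsearch.errors import ConflictError, EntityValidationError, QueryError, SchemaError


@pytest.fixture
def store():
    return Store(default_clinical_schema())


def insert_patient(store, pid, age=40, gender="F", birth="1970-06-01"):
    return store.insert_entity(
        key=("patient", pid), attributes={"age": age, "gender": gender, "birth_date": birth}
    )


class TestSchema:
    def test_single_type_schema(self):
        s = define_schema({"thing": {"name": "text"}})
        assert list(s.entity_types) == ["thing"]

    def test_default_schema_covers_all_levels(self):
        s = default_clinical_schema()
        assert len(s.entity_types) == 8
        assert set(s.levels.values()) == {"patient", "visit", "health"}
        assert set(s.levels) == set(s.entity_types)

    def test_dangling_relationship_endpoint(self):
        with pytest.raises(SchemaError):
            define_schema({"a": {}}, relationships=[("a", "r", "ghost")])

    def test_empty_schema_rejected(self):
        with pytest.raises(SchemaError):
            define_schema({})


class TestInsertGet:
    def test_round_trip(self, store):
        key = insert_patient(store, "p1", age=30)
        ent = store.get_entity(key)
        assert ent.attributes["age"] == 30.0
        assert ent.attributes["gender"] == "F"
        assert ent.attributes["birth_date"] == date(1970, 6, 1)

    def test_absent_is_none_not_error(self, store):
        assert store.get_entity(("patient", "ghost")) is None

    def test_malformed_key(self, store):
        with pytest.raises(KeyError):
            store.get_entity("patient-p1")

    def test_duplicate_key_conflict(self, store):
        insert_patient(store, "p1")
        with pytest.raises(ConflictError):
            insert_patient(store, "p1")

    def test_invalid_date_rejected(self, store):
        with pytest.raises(EntityValidationError, match="birth_date"):
            insert_patient(store, "p1", birth="2016-02-30")

    def test_type_mismatch_names_attribute(self, store):
        with pytest.raises(EntityValidationError, match="age"):
            insert_patient(store, "p1", age="forty")

    def test_many_random_inserts_all_retrievable(self, store):
        rng = random.Random(0)
        keys = []
        for i in range(1000):
            keys.append(insert_patient(store, f"p{i}", age=rng.randint(0, 99)))
        assert all(store.get_entity(k) is not None for k in keys)
        assert len(store.keys_of_type("patient")) == 1000


class TestIndexes:
    def test_numeric_interval_matches_scan(self, store):
        store.insert_entity(
            key=("biological_test", "t1"),
            attributes={"test_type": "hba1c", "value": 7.2, "unit": "%"},
        )
        store.insert_entity(
            key=("biological_test", "t2"),
            attributes={"test_type": "hba1c", "value": 9.0, "unit": "%"},
        )
        pred = NumericInterval(7.0, 8.0)
        got = store.lookup_by_attribute("biological_test", "value", pred)
        assert got == {("biological_test", "t1")}
        assert got == store.full_scan("biological_test", "value", pred)

    def test_empty_store_empty_answer(self, store):
        assert store.lookup_by_attribute("patient", "age", NumericInterval(18, 76)) == set()

    def test_incompatible_predicate_is_query_error(self, store):
        with pytest.raises(QueryError):
            store.lookup_by_attribute("patient", "age", TokenContains("x"))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_predicates_index_equals_scan(self, seed):
        rng = random.Random(seed)
        store = Store(default_clinical_schema())
        for i in range(400):
            store.insert_entity(
                key=("patient", f"p{i}"),
                attributes={
                    "age": rng.randint(0, 99),
                    "gender": rng.choice("FM"),
                    "birth_date": date(rng.randint(1920, 2017), rng.randint(1, 12), 28),
                },
            )
        preds = []
        for _ in range(40):
            a = rng.randint(0, 99)
            preds.append(NumericInterval(a, a + rng.randint(1, 30)))
            preds.append(NumericCmp(rng.choice(["<", "<=", ">", ">="]), rng.randint(0, 99)))
            preds.append(Equals(float(rng.randint(0, 99))))
        for pred in preds:
            assert store.lookup_by_attribute("patient", "age", pred) == store.full_scan(
                "patient", "age", pred
            )
        dpred = DateInterval("1950-01-01", "1990-01-01")
        assert store.lookup_by_attribute("patient", "birth_date", dpred) == store.full_scan(
            "patient", "birth_date", dpred
        )

    def test_absent_attribute_never_matches(self, store):
        store.insert_entity(key=("patient", "p1"), attributes={"gender": "F"})
        assert store.lookup_by_attribute("patient", "age", NumericInterval(None, None)) == set()


class TestLinksAndTraversal:
    def test_link_then_traverse(self, store):
        p = insert_patient(store, "p1")
        s = store.insert_entity(key=("stay", "s1"), attributes={"start_date": "2015-01-01"})
        store.link_entities(p, "has_stay", s)
        assert store.traverse({p}, ["has_stay"]) == {s}
        assert store.traverse({s}, ["~has_stay"]) == {p}

    def test_duplicate_link_idempotent(self, store):
        p = insert_patient(store, "p1")
        s = store.insert_entity(key=("stay", "s1"), attributes={})
        store.link_entities(p, "has_stay", s)
        store.link_entities(p, "has_stay", s)
        assert store.neighbors(p, "has_stay") == {s}
        assert len(store.relationships()) == 1

    def test_wrong_target_type(self, store):
        p = insert_patient(store, "p1")
        p2 = insert_patient(store, "p2")
        with pytest.raises(SchemaError):
            store.link_entities(p, "has_stay", p2)

    def test_undeclared_role(self, store):
        p = insert_patient(store, "p1")
        s = store.insert_entity(key=("stay", "s1"), attributes={})
        with pytest.raises(SchemaError):
            store.link_entities(p, "friend_of", s)

    def test_empty_path_is_identity(self, store):
        p = insert_patient(store, "p1")
        assert store.traverse({p}, []) == {p}

    def test_two_step_path_equals_composition(self, store):
        rng = random.Random(4)
        patients = [insert_patient(store, f"p{i}") for i in range(20)]
        stays, dxs = [], []
        for i in range(40):
            s = store.insert_entity(key=("stay", f"s{i}"), attributes={})
            store.link_entities(rng.choice(patients), "has_stay", s)
            stays.append(s)
        for i in range(60):
            d = store.insert_entity(key=("diagnosis", f"d{i}"), attributes={"code": "X:1"})
            store.link_entities(rng.choice(stays), "has_diagnosis", d)
            dxs.append(d)
        start = set(rng.sample(patients, 8))
        assert store.traverse(start, ["has_stay", "has_diagnosis"]) == store.traverse(
            store.traverse(start, ["has_stay"]), ["has_diagnosis"]
        )


class TestConsistency:
    def test_fresh_store_verifies(self, store):
        assert store.verify_indexes() == []

    def test_verifies_after_random_operations(self, small_dataset):
        assert small_dataset.store.verify_indexes() == []

    def test_corrupted_posting_reported(self, store):
        insert_patient(store, "p1", age=30)
        store._value_index[("patient", "age")][30.0].add(("patient", "ghost"))
        assert any("value index" in p for p in store.verify_indexes())

    def test_insert_order_independence(self):
        entities = [("patient", f"p{i}", {"age": i % 50, "gender": "FM"[i % 2]}) for i in range(50)]
        stores = []
        for seed in (0, 1):
            rng = random.Random(seed)
            batch = entities[:]
            rng.shuffle(batch)
            st = Store(default_clinical_schema())
            for t, i, attrs in batch:
                st.insert_entity(key=(t, i), attributes=attrs)
            stores.append(st)
        a, b = stores
        for pred in (NumericInterval(10, 30), Equals("F"), NumericCmp(">=", 25)):
            attr = "gender" if isinstance(pred, Equals) else "age"
            assert a.lookup_by_attribute("patient", attr, pred) == b.lookup_by_attribute(
                "patient", attr, pred
            )

    def test_dump_reload_preserves_query_answers(self, tmp_path, small_dataset):
        write_dumps(small_dataset.store, tmp_path / "dumps")
        reloaded = read_dumps(small_dataset.store.schema, tmp_path / "dumps")
        battery = [
            ("patient", "age", NumericInterval(18, 76)),
            ("patient", "gender", Equals("F")),
            ("biological_test", "value", NumericCmp("<", 1700)),
            ("stay", "start_date", DateInterval("2014-01-01", "2016-01-01")),
        ]
        for etype, attr, pred in battery:
            assert reloaded.lookup_by_attribute(etype, attr, pred) == small_dataset.store.lookup_by_attribute(etype, attr, pred)
        assert reloaded.relationships() == small_dataset.store.relationships()
        assert reloaded.verify_indexes() == []
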