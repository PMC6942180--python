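"""Entity-attribute-value clinical data store.

A generic in-process entity graph mirroring the conceptual model of a
semantic health data warehouse: typed entities (patients, stays, diagnoses,
biological tests, clinical narratives...) carry schema-checked attributes and
named relationships, all held in key-value maps with secondary indexes so
that any attribute predicate can be answered either through an index or by a
full scan — and the two are required to agree.

Keys are ``(entity_type, local_id)`` pairs; no surrogate integers are ever
exposed.  Numeric and date intervals are half-open ``[lo, hi)``; dates are
ISO-8601 at day granularity.  An absent attribute never matches any
predicate.
"""

from __future__ import annotations

import bisect
import csv
import json
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Iterator

from .errors import (
    ConflictError,
    ConfigurationError,
    EntityValidationError,
    IntegrityError,
    QueryError,
    SchemaError,
)
from .textnorm import norm_tokens

Key = tuple[str, str]  # (entity type, local id)


class ValueKind(Enum):
    TEXT = "text"
    NUMBER = "number"
    DATE = "date"
    CODE = "code"
    CONCEPT_REF = "concept_ref"  # one or a set of terminology-qualified concept ids


@dataclass(frozen=True)
class AttributeDef:
    name: str
    kind: ValueKind
    unit: str | None = None  # for NUMBER attributes


@dataclass(frozen=True)
class RelationshipDef:
    source: str
    role: str
    target: str
    cardinality: str = "many"  # "one" | "many"


@dataclass
class Schema:
    entity_types: dict[str, dict[str, AttributeDef]]
    relationships: list[RelationshipDef]
    levels: dict[str, str] = field(default_factory=dict)  # entity type -> clinical level

    def __post_init__(self):
        for r in self.relationships:
            for endpoint in (r.source, r.target):
                if endpoint not in self.entity_types:
                    raise SchemaError(f"relationship {r.role}: undeclared entity type {endpoint!r}")
        for etype, lvl in self.levels.items():
            if etype not in self.entity_types:
                raise SchemaError(f"level map names undeclared entity type {etype!r}")

    def attribute(self, etype: str, name: str) -> AttributeDef:
        try:
            attrs = self.entity_types[etype]
        except KeyError:
            raise SchemaError(f"undeclared entity type {etype!r}") from None
        try:
            return attrs[name]
        except KeyError:
            raise SchemaError(f"entity type {etype!r} has no attribute {name!r}") from None

    def relationship(self, source: str, role: str) -> RelationshipDef:
        for r in self.relationships:
            if r.source == source and r.role == role:
                return r
        raise SchemaError(f"no relationship {role!r} declared from {source!r}")


CLINICAL_LEVELS = {
    "patient": "patient",
    "stay": "visit",
    "medical_unit": "visit",
    "diagnosis": "health",
    "procedure": "health",
    "biological_test": "health",
    "clinical_narrative": "health",
    "drug": "health",
}


def default_clinical_schema() -> Schema:
    """The shipped warehouse schema: 8 entity types across the patient /
    visit / health clinical levels, linked through the stay."""
    A = AttributeDef
    K = ValueKind
    types = {
        "patient": {
            "gender": A("gender", K.CODE),
            "birth_date": A("birth_date", K.DATE),
            "age": A("age", K.NUMBER, unit="years"),
        },
        "stay": {
            "start_date": A("start_date", K.DATE),
            "end_date": A("end_date", K.DATE),
        },
        "medical_unit": {
            "code": A("code", K.CODE),
            "name": A("name", K.TEXT),
        },
        "diagnosis": {
            "code": A("code", K.CONCEPT_REF),
        },
        "procedure": {
            "code": A("code", K.CONCEPT_REF),
            "date": A("date", K.DATE),
        },
        "biological_test": {
            "test_type": A("test_type", K.CODE),
            "value": A("value", K.NUMBER),
            "unit": A("unit", K.CODE),
            "date": A("date", K.DATE),
        },
        "clinical_narrative": {
            "text": A("text", K.TEXT),
            "language": A("language", K.CODE),
            # filled by the annotation pipeline: all mentioned concepts, and
            # the subset whose mentions are not negated
            "concepts": A("concepts", K.CONCEPT_REF),
            "concepts_affirmed": A("concepts_affirmed", K.CONCEPT_REF),
        },
        "drug": {
            "code": A("code", K.CONCEPT_REF),
            "name": A("name", K.TEXT),
        },
    }
    rels = [
        RelationshipDef("patient", "has_stay", "stay"),
        RelationshipDef("stay", "has_diagnosis", "diagnosis"),
        RelationshipDef("stay", "has_procedure", "procedure"),
        RelationshipDef("stay", "has_test", "biological_test"),
        RelationshipDef("stay", "has_narrative", "clinical_narrative"),
        RelationshipDef("stay", "has_drug", "drug"),
        RelationshipDef("stay", "in_unit", "medical_unit"),
    ]
    return Schema(entity_types=types, relationships=rels, levels=dict(CLINICAL_LEVELS))


def define_schema(
    entity_types: dict[str, dict[str, Any]],
    relationships: Iterable[tuple[str, str, str]] = (),
    levels: dict[str, str] | None = None,
) -> Schema:
    """Build a Schema from a plain description.

    ``entity_types`` maps type name -> {attribute name -> kind name or
    :class:`AttributeDef`}; ``relationships`` is (source, role, target)
    triples.
    """
    if not entity_types:
        raise SchemaError("a schema needs at least one entity type")
    types: dict[str, dict[str, AttributeDef]] = {}
    for etype, attrs in entity_types.items():
        defs: dict[str, AttributeDef] = {}
        for name, kind in attrs.items():
            if isinstance(kind, AttributeDef):
                defs[name] = kind
            else:
                defs[name] = AttributeDef(name, ValueKind(kind))
        types[etype] = defs
    rels = [RelationshipDef(s, role, t) for s, role, t in relationships]
    return Schema(entity_types=types, relationships=rels, levels=levels or {})


# ---------------------------------------------------------------------------
# entities and values


@dataclass
class Entity:
    key: Key
    attributes: dict[str, Any] = field(default_factory=dict)

    @property
    def type(self) -> str:
        return self.key[0]

    @property
    def id(self) -> str:
        return self.key[1]


def _coerce_value(adef: AttributeDef, value: Any) -> Any:
    k = adef.kind
    if k is ValueKind.NUMBER:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise EntityValidationError(f"attribute {adef.name!r}: expected number, got {value!r}")
        return float(value)
    if k is ValueKind.DATE:
        if isinstance(value, date):
            return value
        try:
            return date.fromisoformat(str(value))
        except ValueError:
            raise EntityValidationError(f"attribute {adef.name!r}: invalid ISO date {value!r}") from None
    if k is ValueKind.TEXT:
        if not isinstance(value, str):
            raise EntityValidationError(f"attribute {adef.name!r}: expected text, got {value!r}")
        return value
    if k is ValueKind.CODE:
        if not isinstance(value, str):
            raise EntityValidationError(f"attribute {adef.name!r}: expected code string, got {value!r}")
        return value
    if k is ValueKind.CONCEPT_REF:
        if isinstance(value, str):
            return frozenset({value})
        if isinstance(value, (set, frozenset, list, tuple)):
            if not all(isinstance(v, str) for v in value):
                raise EntityValidationError(f"attribute {adef.name!r}: concept ids must be strings")
            return frozenset(value)
        raise EntityValidationError(f"attribute {adef.name!r}: expected concept id(s), got {value!r}")
    raise AssertionError(k)


# ---------------------------------------------------------------------------
# predicates


@dataclass(frozen=True)
class Equals:
    value: Any


@dataclass(frozen=True)
class NumericInterval:
    """Half-open interval [lo, hi); None endpoint = unbounded."""

    lo: float | None
    hi: float | None


@dataclass(frozen=True)
class NumericCmp:
    op: str  # "<" "<=" ">" ">="
    value: float


@dataclass(frozen=True)
class DateInterval:
    """Half-open [lo, hi) at day granularity; ISO strings or dates."""

    lo: str | date | None
    hi: str | date | None


@dataclass(frozen=True)
class TokenContains:
    token: str


@dataclass(frozen=True)
class ConceptIn:
    concepts: frozenset[str]


Predicate = Equals | NumericInterval | NumericCmp | DateInterval | TokenContains | ConceptIn

_KIND_COMPAT = {
    ValueKind.NUMBER: (Equals, NumericInterval, NumericCmp),
    ValueKind.DATE: (DateInterval, Equals),
    ValueKind.CODE: (Equals,),
    ValueKind.TEXT: (TokenContains, Equals),
    ValueKind.CONCEPT_REF: (ConceptIn, Equals),
}


def _as_date(v) -> date:
    return v if isinstance(v, date) else date.fromisoformat(str(v))


def predicate_holds(adef: AttributeDef, pred: Predicate, value: Any) -> bool:
    """Evaluate a predicate against one stored attribute value.

    ``value`` is the stored (already coerced) value; callers must treat an
    absent attribute as non-matching.
    """
    if not isinstance(pred, _KIND_COMPAT[adef.kind]):
        raise QueryError(
            f"predicate {type(pred).__name__} incompatible with {adef.kind.value} attribute {adef.name!r}"
        )
    if isinstance(pred, Equals):
        if adef.kind is ValueKind.CONCEPT_REF:
            return pred.value in value
        if adef.kind is ValueKind.DATE:
            return value == _as_date(pred.value)
        if adef.kind is ValueKind.NUMBER:
            return value == float(pred.value)
        return value == pred.value
    if isinstance(pred, NumericInterval):
        return (pred.lo is None or value >= pred.lo) and (pred.hi is None or value < pred.hi)
    if isinstance(pred, NumericCmp):
        return {
            "<": value < pred.value,
            "<=": value <= pred.value,
            ">": value > pred.value,
            ">=": value >= pred.value,
        }[pred.op]
    if isinstance(pred, DateInterval):
        lo = None if pred.lo is None else _as_date(pred.lo)
        hi = None if pred.hi is None else _as_date(pred.hi)
        return (lo is None or value >= lo) and (hi is None or value < hi)
    if isinstance(pred, TokenContains):
        toks = norm_tokens(pred.token)
        return bool(toks) and toks[0] in norm_tokens(value)
    if isinstance(pred, ConceptIn):
        return bool(value & pred.concepts)
    raise AssertionError(pred)


# ---------------------------------------------------------------------------
# store


class Store:
    """Key-value entity store with secondary value and text indexes."""

    def __init__(self, schema: Schema):
        self.schema = schema
        self._entities: dict[Key, Entity] = {}
        self._by_type: dict[str, set[Key]] = {t: set() for t in schema.entity_types}
        # (type, attr) -> value -> key set; plus a sorted distinct-value list
        self._value_index: dict[tuple[str, str], dict[Any, set[Key]]] = {}
        self._sorted_values: dict[tuple[str, str], list] = {}
        # (type, attr) -> normalized token -> key set
        self._text_index: dict[tuple[str, str], dict[str, set[Key]]] = {}
        # forward and reverse adjacency
        self._rel: dict[tuple[Key, str], set[Key]] = {}
        self._rel_rev: dict[tuple[Key, str], set[Key]] = {}
        self._rel_rows: set[tuple[Key, str, Key]] = set()

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self._entities)

    def keys_of_type(self, etype: str) -> set[Key]:
        if etype not in self.schema.entity_types:
            raise SchemaError(f"undeclared entity type {etype!r}")
        return set(self._by_type[etype])

    def entities(self) -> Iterator[Entity]:
        return iter(self._entities.values())

    def relationships(self) -> set[tuple[Key, str, Key]]:
        return set(self._rel_rows)

    def get_entity(self, key: Key) -> Entity | None:
        """The entity at ``key``, or None (absence is not an error)."""
        if not (isinstance(key, tuple) and len(key) == 2 and all(isinstance(p, str) for p in key)):
            raise KeyError(f"malformed entity key {key!r}")
        return self._entities.get(key)

    # -- mutation ----------------------------------------------------------

    def insert_entity(self, entity: Entity | None = None, *, key: Key | None = None, attributes: dict | None = None) -> Key:
        if entity is None:
            entity = Entity(key=key, attributes=dict(attributes or {}))
        etype = entity.type
        if etype not in self.schema.entity_types:
            raise SchemaError(f"undeclared entity type {etype!r}")
        if entity.key in self._entities:
            raise ConflictError(f"duplicate key {entity.key}")
        coerced = {}
        for name, value in entity.attributes.items():
            adef = self.schema.attribute(etype, name)
            coerced[name] = _coerce_value(adef, value)
        stored = Entity(key=entity.key, attributes=coerced)
        self._entities[stored.key] = stored
        self._by_type[etype].add(stored.key)
        for name, value in coerced.items():
            self._index_add(etype, name, value, stored.key)
        return stored.key

    def set_attribute(self, key: Key, name: str, value: Any) -> None:
        """Set or replace one attribute, keeping indexes consistent."""
        ent = self._entities.get(key)
        if ent is None:
            raise IntegrityError(f"no entity at {key}")
        adef = self.schema.attribute(ent.type, name)
        if name in ent.attributes:
            self._index_remove(ent.type, name, ent.attributes[name], key)
        coerced = _coerce_value(adef, value)
        ent.attributes[name] = coerced
        self._index_add(ent.type, name, coerced, key)

    def link_entities(self, source: Key, role: str, target: Key) -> None:
        rdef = self.schema.relationship(source[0], role)
        if target[0] != rdef.target:
            raise SchemaError(f"relationship {role!r} targets {rdef.target!r}, got {target[0]!r}")
        if source not in self._entities or target not in self._entities:
            missing = source if source not in self._entities else target
            raise IntegrityError(f"relationship endpoint {missing} does not exist")
        self._rel.setdefault((source, role), set()).add(target)
        self._rel_rev.setdefault((target, role), set()).add(source)
        self._rel_rows.add((source, role, target))

    # -- indexing ----------------------------------------------------------

    def _index_values(self, adef: AttributeDef, value: Any) -> list:
        if adef.kind is ValueKind.CONCEPT_REF:
            return sorted(value)
        return [value]

    def _index_add(self, etype: str, name: str, value: Any, key: Key) -> None:
        adef = self.schema.attribute(etype, name)
        if adef.kind is ValueKind.TEXT:
            idx = self._text_index.setdefault((etype, name), {})
            for tok in set(norm_tokens(value)):
                idx.setdefault(tok, set()).add(key)
            return
        idx = self._value_index.setdefault((etype, name), {})
        order = self._sorted_values.setdefault((etype, name), [])
        for v in self._index_values(adef, value):
            postings = idx.get(v)
            if postings is None:
                idx[v] = {key}
                bisect.insort(order, v)
            else:
                postings.add(key)

    def _index_remove(self, etype: str, name: str, value: Any, key: Key) -> None:
        adef = self.schema.attribute(etype, name)
        if adef.kind is ValueKind.TEXT:
            idx = self._text_index.get((etype, name), {})
            for tok in set(norm_tokens(value)):
                idx.get(tok, set()).discard(key)
            return
        idx = self._value_index.get((etype, name), {})
        order = self._sorted_values.get((etype, name), [])
        for v in self._index_values(adef, value):
            postings = idx.get(v)
            if postings is not None:
                postings.discard(key)
                if not postings:
                    del idx[v]
                    i = bisect.bisect_left(order, v)
                    if i < len(order) and order[i] == v:
                        order.pop(i)

    # -- lookup ------------------------------------------------------------

    def lookup_by_attribute(self, etype: str, attribute: str, pred: Predicate) -> set[Key]:
        """Index-backed evaluation of a predicate; equals the full scan."""
        adef = self.schema.attribute(etype, attribute)
        if not isinstance(pred, _KIND_COMPAT[adef.kind]):
            raise QueryError(
                f"predicate {type(pred).__name__} incompatible with {adef.kind.value} attribute {attribute!r}"
            )
        if adef.kind is ValueKind.TEXT:
            if isinstance(pred, TokenContains):
                toks = norm_tokens(pred.token)
                if not toks:
                    return set()
                idx = self._text_index.get((etype, attribute), {})
                return set(idx.get(toks[0], set()))
            return self.full_scan(etype, attribute, pred)  # Equals on full text: rare, scan
        idx = self._value_index.get((etype, attribute), {})
        if isinstance(pred, Equals):
            v = pred.value
            if adef.kind is ValueKind.DATE:
                v = _as_date(v)
            elif adef.kind is ValueKind.NUMBER:
                v = float(v)
            return set(idx.get(v, set()))
        if isinstance(pred, ConceptIn):
            out: set[Key] = set()
            for cid in pred.concepts:
                out |= idx.get(cid, set())
            return out
        # range predicates over the sorted distinct values
        order = self._sorted_values.get((etype, attribute), [])
        if isinstance(pred, NumericCmp):
            v = pred.value
            if pred.op == "<":
                i, j = 0, bisect.bisect_left(order, v)
            elif pred.op == "<=":
                i, j = 0, bisect.bisect_right(order, v)
            elif pred.op == ">=":
                i, j = bisect.bisect_left(order, v), len(order)
            else:  # ">"
                i, j = bisect.bisect_right(order, v), len(order)
        elif isinstance(pred, NumericInterval):
            i = 0 if pred.lo is None else bisect.bisect_left(order, pred.lo)
            j = len(order) if pred.hi is None else bisect.bisect_left(order, pred.hi)
        elif isinstance(pred, DateInterval):
            lo = None if pred.lo is None else _as_date(pred.lo)
            hi = None if pred.hi is None else _as_date(pred.hi)
            i = 0 if lo is None else bisect.bisect_left(order, lo)
            j = len(order) if hi is None else bisect.bisect_left(order, hi)
        else:  # pragma: no cover - exhausted above
            raise AssertionError(pred)
        out = set()
        for v in order[i:j]:
            out |= idx[v]
        return out

    def full_scan(self, etype: str, attribute: str, pred: Predicate) -> set[Key]:
        """Index-free oracle: filter every entity of the type."""
        adef = self.schema.attribute(etype, attribute)
        out = set()
        for key in self._by_type[etype]:
            ent = self._entities[key]
            if attribute in ent.attributes and predicate_holds(adef, pred, ent.attributes[attribute]):
                out.add(key)
        return out

    # -- traversal ---------------------------------------------------------

    def neighbors(self, key: Key, step: str) -> set[Key]:
        """One relationship step; ``"~role"`` traverses the role in reverse."""
        if step.startswith("~"):
            return set(self._rel_rev.get((key, step[1:]), set()))
        return set(self._rel.get((key, step), set()))

    def traverse(self, keys: Iterable[Key], path: Iterable[str]) -> set[Key]:
        """Follow a role path; empty path is the identity.  Steps are
        validated against the schema from the current frontier's type."""
        frontier = set(keys)
        for step in path:
            role = step[1:] if step.startswith("~") else step
            declared = {(r.source, r.target) for r in self.schema.relationships if r.role == role}
            if not declared:
                raise SchemaError(f"unknown relationship role {role!r} in path")
            if frontier:
                ftypes = {k[0] for k in frontier}
                ok_types = {t for s, t in declared} if step.startswith("~") else {s for s, t in declared}
                if not ftypes <= ok_types:
                    raise SchemaError(f"path step {step!r} invalid from type(s) {sorted(ftypes)}")
            nxt: set[Key] = set()
            for k in frontier:
                nxt |= self.neighbors(k, step)
            frontier = nxt
        return frontier

    # -- verification ------------------------------------------------------

    def verify_indexes(self) -> list[str]:
        """Empty list iff every index posting matches a full scan."""
        problems: list[str] = []
        for (etype, name), idx in self._value_index.items():
            adef = self.schema.attribute(etype, name)
            expected: dict[Any, set[Key]] = {}
            for key in self._by_type[etype]:
                ent = self._entities[key]
                if name in ent.attributes:
                    for v in self._index_values(adef, ent.attributes[name]):
                        expected.setdefault(v, set()).add(key)
            if {v: s for v, s in idx.items() if s} != expected:
                problems.append(f"value index ({etype}, {name}) disagrees with full scan")
            order = self._sorted_values.get((etype, name), [])
            if sorted(expected) != [v for v in order if v in expected] or set(order) - set(expected):
                problems.append(f"sorted value list ({etype}, {name}) inconsistent")
        for (etype, name), idx in self._text_index.items():
            expected = {}
            for key in self._by_type[etype]:
                ent = self._entities[key]
                if name in ent.attributes:
                    for tok in set(norm_tokens(ent.attributes[name])):
                        expected.setdefault(tok, set()).add(key)
            if {t: s for t, s in idx.items() if s} != expected:
                problems.append(f"text index ({etype}, {name}) disagrees with full scan")
        for (src, role, tgt) in self._rel_rows:
            if src not in self._entities or tgt not in self._entities:
                problems.append(f"relationship ({src}, {role}, {tgt}) has a dead endpoint")
        return problems


# ---------------------------------------------------------------------------
# serialization: one JSONL dump per entity type + a relationships CSV


def _value_to_json(adef: AttributeDef, value: Any) -> Any:
    if adef.kind is ValueKind.DATE:
        return value.isoformat()
    if adef.kind is ValueKind.CONCEPT_REF:
        return sorted(value)
    return value


def write_dumps(store: Store, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for etype in sorted(store.schema.entity_types):
        with (d / f"{etype}.jsonl").open("w", encoding="utf-8") as fh:
            for key in sorted(store._by_type[etype]):
                ent = store._entities[key]
                rec = {
                    "id": ent.id,
                    "attributes": {
                        n: _value_to_json(store.schema.attribute(etype, n), v)
                        for n, v in sorted(ent.attributes.items())
                    },
                }
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    with (d / "relationships.csv").open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source_type", "source_id", "role", "target_type", "target_id"])
        for src, role, tgt in sorted(store._rel_rows):
            w.writerow([src[0], src[1], role, tgt[0], tgt[1]])


def read_dumps(schema: Schema, directory: str | Path) -> Store:
    d = Path(directory)
    store = Store(schema)
    for etype in sorted(schema.entity_types):
        path = d / f"{etype}.jsonl"
        if not path.exists():
            continue
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                store.insert_entity(key=(etype, rec["id"]), attributes=rec["attributes"])
    rel_path = d / "relationships.csv"
    if rel_path.exists():
        with rel_path.open(encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                store.link_entities(
                    (row["source_type"], row["source_id"]),
                    row["role"],
                    (row["target_type"], row["target_id"]),
                )
    return store


# Module-level functional wrappers (the operation surface used in docs/tests).

def insert_entity(store: Store, entity: Entity) -> Key:
    return store.insert_entity(entity)


def get_entity(store: Store, key: Key) -> Entity | None:
    return store.get_entity(key)


def link_entities(store: Store, source: Key, role: str, target: Key) -> None:
    store.link_entities(source, role, target)


def lookup_by_attribute(store: Store, etype: str, attribute: str, pred: Predicate) -> set[Key]:
    return store.lookup_by_attribute(etype, attribute, pred)


def traverse(store: Store, keys: Iterable[Key], path: Iterable[str]) -> set[Key]:
    return store.traverse(keys, path)


def verify_indexes(store: Store) -> list[str]:
    return store.verify_indexes()
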