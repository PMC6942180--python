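"""Boolean entity-oriented search over the EAV store.

Each constraint is evaluated in its native entity type (with semantic
expansion of concept seeds and optional exclusion of negated narrative
mentions), counted, then projected to the query's output entity type along
the shortest relationship path in the schema; the Boolean expression is
combined AFTER projection, with NOT taken as the complement within the
stored universe of the output type — exclusion criteria exclude patients,
not diagnoses.

``brute_force_evaluate`` re-implements the same contract by exhaustive
scanning with no indexes and no precomputed projection paths; the two must
agree on every query, which is the module's core correctness property.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from typing import Iterable

from .eav import ConceptIn, Entity, Equals, Key, Store, ValueKind, predicate_holds
from .errors import ConfigurationError, QueryError
from .query import (
    And,
    ConceptPredicate,
    Constraint,
    Expr,
    Not,
    Or,
    Query,
    Ref,
    parse_query,
    render,
)
from .terminology import SemanticNetwork


@dataclass
class ResultSet:
    output_keys: list[Key]           # ordered, duplicate-free
    partial_counts: dict[str, int]   # constraint id -> native-type result count
    query_echo: str

    def __len__(self) -> int:
        return len(self.output_keys)


# ---------------------------------------------------------------------------
# projection paths


def projection_path(schema, from_type: str, to_type: str) -> list[str]:
    """Shortest role path between two entity types in the schema graph.

    Steps are role names, prefixed with ``~`` when the role is traversed in
    reverse.  Two distinct equal-length shortest paths raise
    :class:`QueryError` (a silent arbitrary choice would corrupt semantics).
    """
    if from_type == to_type:
        return []
    adj: dict[str, list[tuple[str, str]]] = {}
    for r in schema.relationships:
        adj.setdefault(r.source, []).append((r.role, r.target))
        adj.setdefault(r.target, []).append(("~" + r.role, r.source))
    # BFS counting the number of shortest paths
    dist = {from_type: 0}
    npaths = {from_type: 1}
    pred: dict[str, tuple[str, str]] = {}
    frontier = [from_type]
    while frontier:
        nxt = []
        for node in frontier:
            for step, other in adj.get(node, ()):
                if other not in dist:
                    dist[other] = dist[node] + 1
                    npaths[other] = npaths[node]
                    pred[other] = (node, step)
                    nxt.append(other)
                elif dist[other] == dist[node] + 1:
                    npaths[other] += npaths[node]
        frontier = nxt
    if to_type not in dist:
        raise QueryError(f"no projection path from {from_type!r} to {to_type!r}")
    if npaths[to_type] > 1:
        raise QueryError(
            f"ambiguous projection: {npaths[to_type]} equal-length paths from "
            f"{from_type!r} to {to_type!r}; configure an explicit path"
        )
    path: list[str] = []
    node = to_type
    while node != from_type:
        prev, step = pred[node]
        path.append(step)
        node = prev
    path.reverse()
    return path


def project(keys: Iterable[Key], from_type: str, output_type: str, store: Store) -> set[Key]:
    """Image of a native key set at the output type (identity if same type)."""
    path = projection_path(store.schema, from_type, output_type)
    return store.traverse(set(keys), path)


# ---------------------------------------------------------------------------
# constraint evaluation


def _expanded_concepts(pred: ConceptPredicate, network: SemanticNetwork) -> frozenset[str]:
    return frozenset(network.expand_concepts(pred.seeds, pred.expansion))


def _narrative_attribute(constraint: Constraint) -> str:
    """Concept searches over narratives honor the negation flag by switching
    between the affirmed-only and the all-mentions concept attribute."""
    pred = constraint.predicate
    if (
        isinstance(pred, ConceptPredicate)
        and pred.negation_excluded
        and constraint.attribute == "concepts"
    ):
        return "concepts_affirmed"
    return constraint.attribute


def evaluate_constraint(
    constraint: Constraint, store: Store, network: SemanticNetwork | None = None
) -> set[Key]:
    """Native key set of one constraint (index-backed)."""
    attribute = _narrative_attribute(constraint)
    pred = constraint.predicate
    if isinstance(pred, ConceptPredicate):
        if network is None:
            raise QueryError("concept predicates need a semantic network")
        store_pred = ConceptIn(_expanded_concepts(pred, network))
    else:
        store_pred = pred
    keys = store.lookup_by_attribute(constraint.entity_type, attribute, store_pred)
    if constraint.filter is not None:
        fattr, fval = constraint.filter
        adef = store.schema.attribute(constraint.entity_type, fattr)
        fv = float(fval) if adef.kind is ValueKind.NUMBER else fval
        keys &= store.lookup_by_attribute(constraint.entity_type, fattr, Equals(fv))
    return keys


# ---------------------------------------------------------------------------
# full evaluation


def _combine(expr: Expr, sets: dict[str, set[Key]], universe: set[Key]) -> set[Key]:
    if isinstance(expr, Ref):
        return sets[expr.id]
    if isinstance(expr, Not):
        return universe - _combine(expr.child, sets, universe)
    if isinstance(expr, And):
        out = universe
        for c in expr.children:
            out = out & _combine(c, sets, universe)
        return out
    if isinstance(expr, Or):
        out: set[Key] = set()
        for c in expr.children:
            out = out | _combine(c, sets, universe)
        return out
    raise QueryError(f"unknown expression node {expr!r}")


def evaluate(
    query: Query | str, store: Store, network: SemanticNetwork | None = None
) -> ResultSet:
    """Evaluate a query: per-constraint native sets and counts, projection to
    the output type, Boolean combination, deterministic key ordering."""
    if isinstance(query, str):
        query = parse_query(query)
    out_type = query.output.output_type
    if out_type not in store.schema.entity_types:
        raise QueryError(f"unknown output entity type {out_type!r}")
    projected: dict[str, set[Key]] = {}
    counts: dict[str, int] = {}
    for c in query.constraints:
        native = evaluate_constraint(c, store, network)
        counts[c.id] = len(native)
        projected[c.id] = project(native, c.entity_type, out_type, store)
    universe = store.keys_of_type(out_type)
    result = _combine(query.expr, projected, universe)
    return ResultSet(output_keys=sorted(result), partial_counts=counts, query_echo=render(query))


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_evaluate(
    query: Query | str, store: Store, network: SemanticNetwork | None = None
) -> ResultSet:
    """Same contract as :func:`evaluate` via exhaustive scans: predicate
    filtering entity by entity, projection by repeated scans of the
    relationship rows, no indexes."""
    if isinstance(query, str):
        query = parse_query(query)
    out_type = query.output.output_type
    if out_type not in store.schema.entity_types:
        raise QueryError(f"unknown output entity type {out_type!r}")
    rel_rows = store.relationships()
    projected: dict[str, set[Key]] = {}
    counts: dict[str, int] = {}
    for c in query.constraints:
        native = _scan_constraint(c, store, network)
        counts[c.id] = len(native)
        projected[c.id] = _scan_project(native, c.entity_type, out_type, store, rel_rows)
    universe = {e.key for e in store.entities() if e.type == out_type}
    result = _combine(query.expr, projected, universe)
    return ResultSet(output_keys=sorted(result), partial_counts=counts, query_echo=render(query))


def _scan_constraint(
    constraint: Constraint, store: Store, network: SemanticNetwork | None
) -> set[Key]:
    attribute = _narrative_attribute(constraint)
    pred = constraint.predicate
    if isinstance(pred, ConceptPredicate):
        if network is None:
            raise QueryError("concept predicates need a semantic network")
        pred = ConceptIn(_expanded_concepts(pred, network))
    adef = store.schema.attribute(constraint.entity_type, attribute)
    out = set()
    for ent in store.entities():
        if ent.type != constraint.entity_type or attribute not in ent.attributes:
            continue
        if constraint.filter is not None:
            fattr, fval = constraint.filter
            fdef = store.schema.attribute(ent.type, fattr)
            want = float(fval) if fdef.kind is ValueKind.NUMBER else fval
            if fattr not in ent.attributes or not predicate_holds(fdef, Equals(want), ent.attributes[fattr]):
                continue
        if predicate_holds(adef, pred, ent.attributes[attribute]):
            out.add(ent.key)
    return out


def _scan_project(
    keys: set[Key], from_type: str, out_type: str, store: Store, rel_rows: set
) -> set[Key]:
    """BFS over relationship rows from each key until the output type is
    reached, using the same shortest-path-with-ambiguity-check contract but
    recomputed from the raw rows."""
    path = projection_path(store.schema, from_type, out_type)  # contract check only
    frontier = set(keys)
    for step in path:
        reverse = step.startswith("~")
        role = step[1:] if reverse else step
        nxt: set[Key] = set()
        for src, r, tgt in rel_rows:
            if r != role:
                continue
            if reverse and tgt in frontier:
                nxt.add(src)
            elif not reverse and src in frontier:
                nxt.add(tgt)
        frontier = nxt
    return frontier


# ---------------------------------------------------------------------------
# result rendering


def render_results(result: ResultSet, fmt: str, store: Store) -> str:
    """Serialize a result set: one row per output entity with its attributes,
    partial counts as a summary header."""
    if fmt not in ("csv", "jsonl"):
        raise ConfigurationError(f"unknown output format {fmt!r} (use csv or jsonl)")
    entities = [store.get_entity(k) for k in result.output_keys]
    if fmt == "jsonl":
        lines = [
            json.dumps(
                {
                    "type": "summary",
                    "n_results": len(result.output_keys),
                    "partial_counts": result.partial_counts,
                    "query": result.query_echo,
                },
                ensure_ascii=False,
            )
        ]
        for ent in entities:
            lines.append(json.dumps(_row_dict(ent, store), ensure_ascii=False, sort_keys=True))
        return "\n".join(lines) + "\n"
    # csv
    attr_names = sorted({n for ent in entities for n in ent.attributes}) if entities else []
    buf = io.StringIO()
    w = csv.writer(buf)
    for cid in sorted(result.partial_counts):
        w.writerow(["#partial", cid, result.partial_counts[cid]])
    w.writerow(["entity_type", "id"] + attr_names)
    for ent in entities:
        row = _row_dict(ent, store)
        w.writerow([ent.type, ent.id] + [_csv_cell(row["attributes"].get(n)) for n in attr_names])
    return buf.getvalue()


def _row_dict(ent: Entity, store: Store) -> dict:
    attrs = {}
    for n, v in ent.attributes.items():
        adef = store.schema.attribute(ent.type, n)
        if adef.kind is ValueKind.DATE:
            attrs[n] = v.isoformat()
        elif adef.kind is ValueKind.CONCEPT_REF:
            attrs[n] = sorted(v)
        else:
            attrs[n] = v
    return {"entity_type": ent.type, "id": ent.id, "attributes": attrs}


def _csv_cell(v):
    if v is None:
        return ""
    if isinstance(v, list):
        return "|".join(v)
    return v
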