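"""Boolean entity-oriented query language.

A query defines named constraints over entity attributes, an output entity
type, and a Boolean expression combining the constraints::

    C1: patient.age in [18,76);
    C2: biological_test[test_type=hba1c].value <= 6.5;
    C3: clinical_narrative.concepts concept(MEDVOC:T2D, depth=unbounded, negation=exclude);
    OUT patient;
    (C1 AND (C2 OR NOT C3))

Predicates
----------
* ``in [a,b)``            — half-open numeric or date interval (ISO dates)
* ``<= x``, ``>= x``, ``< x``, ``> x``  — numeric comparison
* ``= "literal"`` / ``= ident`` / ``= number``   — equality
* ``contains "word"``     — token containment in a text attribute
* ``concept(ids..., depth=N|unbounded, direction=descendants|ancestors|none,
  mappings=exact+broader_to_narrower|none, negation=exclude|include)``
  — concept membership after semantic expansion of the seeds

An optional entity filter ``type[attr=value].attr`` restricts the constraint
to entities whose ``attr`` equals ``value`` before the predicate applies, so
one constraint can bind both a lab test's type and its value.

The parser is a hand-written tokenizer + recursive descent; ``render`` emits
a canonical string that reparses to an identical AST.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Union

from .eav import (
    DateInterval,
    Equals,
    NumericCmp,
    NumericInterval,
    Predicate,
    TokenContains,
)
from .errors import ParseError, QueryError
from .terminology import MAPPING_KINDS, ExpansionSpec

_DATE_RE = re.compile(r"\d{4}-\d{2}-\d{2}$")


@dataclass(frozen=True)
class ConceptPredicate:
    """Concept membership with semantic expansion (the search layer expands
    the seeds; the store only sees the final concept id set)."""

    seeds: tuple[str, ...]
    expansion: ExpansionSpec = ExpansionSpec()
    negation_excluded: bool = False


@dataclass(frozen=True)
class Constraint:
    id: str
    entity_type: str
    attribute: str
    predicate: Union[Predicate, ConceptPredicate]
    filter: tuple[str, str] | None = None  # (attribute, value) equality pre-filter


@dataclass(frozen=True)
class Ref:
    id: str


@dataclass(frozen=True)
class Not:
    child: "Expr"


@dataclass(frozen=True)
class And:
    children: tuple["Expr", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["Expr", ...]


Expr = Union[Ref, Not, And, Or]


@dataclass(frozen=True)
class OutputSpec:
    output_type: str


@dataclass(frozen=True)
class Query:
    constraints: tuple[Constraint, ...]
    output: OutputSpec
    expr: Expr

    def constraint(self, cid: str) -> Constraint:
        for c in self.constraints:
            if c.id == cid:
                return c
        raise QueryError(f"undefined constraint id {cid!r}")


# ---------------------------------------------------------------------------
# tokenizer

_TOKEN_SPEC = [
    ("DATE", r"\d{4}-\d{2}-\d{2}"),
    ("NUMBER", r"-?\d+(?:\.\d+)?"),
    ("STRING", r'"[^"]*"'),
    ("OP", r"<=|>=|<|>|=|\(|\)|\[|\]|\{|\}|:|;|\.|,|\+|~"),
    ("IDENT", r"[A-Za-z_][\w:\-]*"),
    ("WS", r"\s+"),
]
_MASTER_RE = re.compile("|".join(f"(?P<{n}>{p})" for n, p in _TOKEN_SPEC))


@dataclass
class _Tok:
    kind: str
    text: str
    pos: int


class _Lexer:
    def __init__(self, text: str):
        self.text = text
        self.toks: list[_Tok] = []
        pos = 0
        while pos < len(text):
            m = _MASTER_RE.match(text, pos)
            if m is None:
                self._err(f"unexpected character {text[pos]!r}", pos)
            if m.lastgroup != "WS":
                self.toks.append(_Tok(m.lastgroup, m.group(0), pos))
            pos = m.end()
        self.i = 0

    def _err(self, msg: str, pos: int):
        line = self.text.count("\n", 0, pos) + 1
        col = pos - (self.text.rfind("\n", 0, pos) + 1) + 1
        raise ParseError(msg, pos, line, col)

    def peek(self) -> _Tok | None:
        return self.toks[self.i] if self.i < len(self.toks) else None

    def next(self) -> _Tok:
        t = self.peek()
        if t is None:
            self._err("unexpected end of query", len(self.text))
        self.i += 1
        return t

    def expect(self, text: str) -> _Tok:
        t = self.peek()
        if t is None:
            self._err(f"expected {text!r} but query ended", len(self.text))
        if t.text != text:
            self._err(f"expected {text!r}, found {t.text!r}", t.pos)
        return self.next()

    def accept(self, text: str) -> bool:
        t = self.peek()
        if t is not None and t.text == text:
            self.i += 1
            return True
        return False


# ---------------------------------------------------------------------------
# parser


def parse_query(text: str) -> Query:
    """Parse a query string; raises :class:`ParseError` with position info."""
    lx = _Lexer(text)
    constraints: list[Constraint] = []
    while True:
        t = lx.peek()
        if t is None:
            lx._err("expected 'OUT <type>;' before the Boolean expression", len(text))
        if t.text.upper() == "OUT":
            break
        constraints.append(_parse_constraint(lx))
    lx.next()  # OUT
    out_tok = lx.next()
    if out_tok.kind != "IDENT":
        lx._err(f"expected an entity type after OUT, found {out_tok.text!r}", out_tok.pos)
    lx.expect(";")
    expr = _parse_or(lx)
    trailing = lx.peek()
    if trailing is not None:
        lx._err(f"unexpected trailing input {trailing.text!r}", trailing.pos)
    if not constraints:
        raise QueryError("a query needs at least one constraint")
    seen = set()
    for c in constraints:
        if c.id in seen:
            raise QueryError(f"constraint id {c.id!r} defined twice")
        seen.add(c.id)
    for ref in _refs(expr):
        if ref not in seen:
            raise QueryError(f"expression references undefined constraint {ref!r}")
    return Query(constraints=tuple(constraints), output=OutputSpec(out_tok.text), expr=expr)


def _refs(e: Expr) -> set[str]:
    if isinstance(e, Ref):
        return {e.id}
    if isinstance(e, Not):
        return _refs(e.child)
    out: set[str] = set()
    for c in e.children:
        out |= _refs(c)
    return out


def _parse_constraint(lx: _Lexer) -> Constraint:
    cid = lx.next()
    if cid.kind != "IDENT":
        lx._err(f"expected a constraint id, found {cid.text!r}", cid.pos)
    # ':' is a valid identifier character (concept ids), so "C1:" or even
    # "C1:patient" may arrive as one token — split the constraint id off
    cid_text, colon, rest = cid.text.partition(":")
    if not colon:
        lx.expect(":")
    if colon and rest:
        etype = _Tok("IDENT", rest, cid.pos + len(cid_text) + 1)
    else:
        etype = lx.next()
    if etype.kind != "IDENT":
        lx._err(f"expected an entity type, found {etype.text!r}", etype.pos)
    cid = _Tok("IDENT", cid_text, cid.pos)
    filt = None
    if lx.accept("["):
        fattr = lx.next()
        lx.expect("=")
        fval = lx.next()
        lx.expect("]")
        filt = (fattr.text, fval.text.strip('"'))
    lx.expect(".")
    attr = lx.next()
    if attr.kind != "IDENT":
        lx._err(f"expected an attribute name, found {attr.text!r}", attr.pos)
    pred = _parse_predicate(lx)
    lx.expect(";")
    return Constraint(id=cid.text, entity_type=etype.text, attribute=attr.text, predicate=pred, filter=filt)


def _parse_predicate(lx: _Lexer):
    t = lx.peek()
    if t is None:
        lx._err("expected a predicate", len(lx.text))
    word = t.text.lower()
    if word == "in":
        lx.next()
        lx.expect("[")
        lo = lx.next()
        lx.expect(",")
        hi = lx.next()
        lx.expect(")")
        if lo.kind == "DATE" or hi.kind == "DATE":
            return DateInterval(lo.text, hi.text)
        return NumericInterval(float(lo.text), float(hi.text))
    if t.text in ("<=", ">=", "<", ">"):
        lx.next()
        v = lx.next()
        if v.kind != "NUMBER":
            lx._err(f"expected a number after {t.text!r}, found {v.text!r}", v.pos)
        return NumericCmp(t.text, float(v.text))
    if t.text == "=":
        lx.next()
        v = lx.next()
        if v.kind == "NUMBER":
            return Equals(float(v.text))
        return Equals(v.text.strip('"'))
    if word == "contains":
        lx.next()
        v = lx.next()
        return TokenContains(v.text.strip('"'))
    if word == "concept":
        lx.next()
        return _parse_concept_predicate(lx)
    lx._err(f"unknown predicate starting at {t.text!r}", t.pos)


def _parse_concept_predicate(lx: _Lexer) -> ConceptPredicate:
    lx.expect("(")
    seeds: list[str] = []
    opts: dict[str, str] = {}
    while True:
        t = lx.next()
        if t.kind not in ("IDENT", "NUMBER"):
            lx._err(f"expected a concept id or option, found {t.text!r}", t.pos)
        nxt = lx.peek()
        if nxt is not None and nxt.text == "=":
            lx.next()
            name = t.text.lower()
            value = _parse_option_value(lx)
            opts[name] = value
        else:
            # concept ids may contain dots (ICD10X:E11.0): re-join them
            seed = t.text
            while lx.accept("."):
                seed += "." + lx.next().text
            seeds.append(seed)
        if lx.accept(","):
            continue
        lx.expect(")")
        break
    if not seeds:
        raise QueryError("concept predicate needs at least one seed concept id")
    expansion = _expansion_from_options(opts)
    negation_excluded = opts.get("negation", "include") == "exclude"
    return ConceptPredicate(seeds=tuple(seeds), expansion=expansion, negation_excluded=negation_excluded)


def _parse_option_value(lx: _Lexer) -> str:
    parts = [lx.next().text]
    while lx.accept("+"):
        parts.append(lx.next().text)
    return "+".join(parts)


def _expansion_from_options(opts: dict[str, str]) -> ExpansionSpec:
    depth_s = opts.get("depth", "unbounded")
    depth = None if depth_s.lower() == "unbounded" else int(float(depth_s))
    direction = opts.get("direction", "descendants").lower()
    mapping_s = opts.get("mappings", "exact").lower()
    if mapping_s == "none":
        kinds: frozenset[str] = frozenset()
    else:
        kinds = frozenset(mapping_s.split("+"))
        bad = kinds - set(MAPPING_KINDS)
        if bad:
            raise QueryError(f"unknown mapping kinds {sorted(bad)}")
    if opts.get("negation", "include") not in ("include", "exclude"):
        raise QueryError(f"negation option must be include or exclude, got {opts['negation']!r}")
    return ExpansionSpec(direction=direction, depth=depth, mapping_kinds=kinds)


def _parse_or(lx: _Lexer) -> Expr:
    left = _parse_and(lx)
    children = [left]
    while True:
        t = lx.peek()
        if t is not None and t.text.upper() == "OR":
            lx.next()
            children.append(_parse_and(lx))
        else:
            break
    return children[0] if len(children) == 1 else Or(tuple(children))


def _parse_and(lx: _Lexer) -> Expr:
    children = [_parse_not(lx)]
    while True:
        t = lx.peek()
        if t is not None and t.text.upper() == "AND":
            lx.next()
            children.append(_parse_not(lx))
        else:
            break
    return children[0] if len(children) == 1 else And(tuple(children))


def _parse_not(lx: _Lexer) -> Expr:
    t = lx.peek()
    if t is None:
        lx._err("expected an expression", len(lx.text))
    if t.text.upper() == "NOT":
        lx.next()
        return Not(_parse_not(lx))
    if t.text == "(":
        lx.next()
        inner = _parse_or(lx)
        lx.expect(")")
        return inner
    if t.kind == "IDENT":
        lx.next()
        return Ref(t.text)
    lx._err(f"expected a constraint id, NOT or '(', found {t.text!r}", t.pos)


# ---------------------------------------------------------------------------
# rendering (canonical form: render(parse(q)) reparses to the same AST)


def render(query: Query) -> str:
    parts = [_render_constraint(c) for c in query.constraints]
    parts.append(f"OUT {query.output.output_type};")
    parts.append(render_expr(query.expr))
    return " ".join(parts)


def _render_constraint(c: Constraint) -> str:
    filt = "" if c.filter is None else f"[{c.filter[0]}={c.filter[1]}]"
    return f"{c.id}: {c.entity_type}{filt}.{c.attribute} {_render_predicate(c.predicate)};"


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def _render_predicate(p) -> str:
    if isinstance(p, NumericInterval):
        return f"in [{_fmt_num(p.lo)},{_fmt_num(p.hi)})"
    if isinstance(p, DateInterval):
        lo = p.lo if isinstance(p.lo, str) else p.lo.isoformat()
        hi = p.hi if isinstance(p.hi, str) else p.hi.isoformat()
        return f"in [{lo},{hi})"
    if isinstance(p, NumericCmp):
        return f"{p.op} {_fmt_num(p.value)}"
    if isinstance(p, Equals):
        if isinstance(p.value, float):
            return f"= {_fmt_num(p.value)}"
        return f'= "{p.value}"'
    if isinstance(p, TokenContains):
        return f'contains "{p.token}"'
    if isinstance(p, ConceptPredicate):
        bits = list(p.seeds)
        e = p.expansion
        bits.append(f"depth={'unbounded' if e.depth is None else e.depth}")
        bits.append(f"direction={e.direction}")
        bits.append(f"mappings={'+'.join(sorted(e.mapping_kinds)) if e.mapping_kinds else 'none'}")
        bits.append(f"negation={'exclude' if p.negation_excluded else 'include'}")
        return f"concept({', '.join(bits)})"
    raise QueryError(f"cannot render predicate {p!r}")


def render_expr(e: Expr) -> str:
    if isinstance(e, Ref):
        return e.id
    if isinstance(e, Not):
        return f"NOT {render_expr(e.child)}"
    op = " AND " if isinstance(e, And) else " OR "
    return "(" + op.join(render_expr(c) for c in e.children) + ")"
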