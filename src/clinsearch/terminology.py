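"""Miniature cross-terminology portal.

Loads controlled vocabularies (terminologies/ontologies) with multilingual
preferred terms and synonyms, parent-child hierarchies, and cross-terminology
mappings, and supports the semantic operations a cohort-search engine needs:
controlled-depth hierarchy expansion, mapping traversal and prefix
autocompletion.

Concept ids are terminology-qualified strings such as ``"ICD10X:E11"`` so a
set of concepts from several terminologies can be handled uniformly without a
central registry.

File dialects
-------------
* ``json``: one UTF-8 JSON document per terminology::

      {"id": "ICD10X", "languages": ["en", "fr"],
       "concepts": [
         {"id": "ICD10X:E11",
          "preferred_term": {"en": "Type 2 diabetes", "fr": "Diabète de type 2"},
          "synonyms": {"fr": ["DT2"]},
          "parents": ["ICD10X:E10-E14"]}, ...]}

  Child links are derived from parent links on load (and must be their exact
  inverse if present in the file).

* ``csv``: flat code lists ``id,parent,label_en,label_fr`` for quick imports.

Mappings travel separately as CSV rows ``source,target,kind`` with kind one
of ``exact``, ``broader_to_narrower``, ``narrower_to_broader``.
"""

from __future__ import annotations

import csv
import json
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping as TMapping

from .errors import ConceptLookupError, ConfigurationError, FormatError, IntegrityError
from .textnorm import norm_text

MAPPING_KINDS = ("exact", "broader_to_narrower", "narrower_to_broader")
_INVERSE_KIND = {
    "exact": "exact",
    "broader_to_narrower": "narrower_to_broader",
    "narrower_to_broader": "broader_to_narrower",
}


@dataclass
class Concept:
    id: str
    preferred_term: dict[str, str] = field(default_factory=dict)
    synonyms: dict[str, list[str]] = field(default_factory=dict)
    parents: set[str] = field(default_factory=set)
    children: set[str] = field(default_factory=set)

    def terms(self, language: str) -> list[str]:
        """All labels of this concept in one language (preferred term first)."""
        out = []
        if language in self.preferred_term:
            out.append(self.preferred_term[language])
        out.extend(self.synonyms.get(language, ()))
        return out


@dataclass
class Terminology:
    id: str
    languages: set[str] = field(default_factory=set)
    concepts: dict[str, Concept] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.concepts)

    def edge_count(self) -> int:
        return sum(len(c.parents) for c in self.concepts.values())


@dataclass(frozen=True)
class ConceptMapping:
    """Directed cross-terminology mapping edge."""

    source: str
    target: str
    kind: str

    def inverse(self) -> "ConceptMapping":
        return ConceptMapping(self.target, self.source, _INVERSE_KIND[self.kind])


@dataclass(frozen=True)
class ExpansionSpec:
    """How to enlarge a seed concept set.

    ``depth`` bounds the number of hierarchy steps (None = unbounded); mapping
    hops do not consume depth.  With ``transitive_mappings`` False (the
    default) a path may cross at most one mapping edge; hierarchy expansion
    continues in the target terminology with the remaining depth budget.
    """

    direction: str = "descendants"  # descendants | ancestors | none
    depth: int | None = None
    mapping_kinds: frozenset[str] = frozenset({"exact"})
    cross_terminology: bool = True
    transitive_mappings: bool = False

    def __post_init__(self):
        if self.direction not in ("descendants", "ancestors", "none"):
            raise ConfigurationError(f"unknown expansion direction {self.direction!r}")
        bad = set(self.mapping_kinds) - set(MAPPING_KINDS)
        if bad:
            raise ConfigurationError(f"unknown mapping kinds {sorted(bad)}")
        if self.depth is not None and self.depth < 0:
            raise ConfigurationError("depth must be non-negative or None")


IDENTITY_EXPANSION = ExpansionSpec(direction="none", depth=0, mapping_kinds=frozenset())

#: Default used by the search layer: descend the full hierarchy and cross
#: exact mappings once.  Overridable per query constraint.
DEFAULT_RETRIEVAL_EXPANSION = ExpansionSpec()


@dataclass
class ValidationReport:
    cycles: list[list[str]] = field(default_factory=list)
    dangling_parents: list[tuple[str, str]] = field(default_factory=list)  # (concept, missing parent)
    asymmetric_links: list[tuple[str, str]] = field(default_factory=list)  # parent/child not inverse
    unknown_mapping_endpoints: list[ConceptMapping] = field(default_factory=list)
    missing_mapping_inverses: list[ConceptMapping] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.cycles
            or self.dangling_parents
            or self.asymmetric_links
            or self.unknown_mapping_endpoints
            or self.missing_mapping_inverses
        )


# ---------------------------------------------------------------------------
# loading / saving


def _concept_from_record(rec: dict, where: str) -> Concept:
    try:
        cid = rec["id"]
    except KeyError:
        raise FormatError(f"{where}: concept record without 'id'") from None
    if not isinstance(cid, str) or ":" not in cid:
        raise FormatError(f"{where}: concept id {cid!r} is not terminology-qualified")
    return Concept(
        id=cid,
        preferred_term=dict(rec.get("preferred_term", {})),
        synonyms={k: list(v) for k, v in rec.get("synonyms", {}).items()},
        parents=set(rec.get("parents", ())),
        children=set(rec.get("children", ())),
    )


def load_terminology(source: str | Path, dialect: str = "json") -> Terminology:
    """Load and validate one terminology file.

    Raises :class:`FormatError` on parse problems (naming the offending
    record), :class:`IntegrityError` on dangling parent references or
    hierarchy cycles.
    """
    path = Path(source)
    if dialect == "json":
        try:
            doc = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as e:
            raise FormatError(f"{path}: invalid JSON at line {e.lineno}: {e.msg}") from e
        if not isinstance(doc, dict) or "id" not in doc:
            raise FormatError(f"{path}: terminology document must be an object with an 'id'")
        term = Terminology(id=doc["id"], languages=set(doc.get("languages", ())))
        for i, rec in enumerate(doc.get("concepts", ())):
            c = _concept_from_record(rec, f"{path} concept #{i}")
            if c.id in term.concepts:
                raise IntegrityError(f"{path}: duplicate concept id {c.id}")
            term.concepts[c.id] = c
    elif dialect == "csv":
        term_id = path.stem
        term = Terminology(id=term_id, languages={"en", "fr"})
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "id" not in reader.fieldnames:
                raise FormatError(f"{path}: CSV code list needs an 'id' column")
            for lineno, row in enumerate(reader, start=2):
                cid = row["id"].strip()
                if not cid:
                    raise FormatError(f"{path} line {lineno}: empty id")
                if ":" not in cid:
                    cid = f"{term_id}:{cid}"
                c = Concept(id=cid)
                parent = (row.get("parent") or "").strip()
                if parent:
                    if ":" not in parent:
                        parent = f"{term_id}:{parent}"
                    c.parents.add(parent)
                for lang in ("en", "fr"):
                    label = (row.get(f"label_{lang}") or "").strip()
                    if label:
                        c.preferred_term[lang] = label
                if cid in term.concepts:
                    raise IntegrityError(f"{path} line {lineno}: duplicate concept id {cid}")
                term.concepts[cid] = c
    else:
        raise ConfigurationError(f"unknown terminology dialect {dialect!r}")

    _close_children(term)
    report = _check_hierarchy(term)
    if report.dangling_parents:
        offenders = ", ".join(f"{c}->{p}" for c, p in report.dangling_parents[:10])
        raise IntegrityError(f"{path}: dangling parent references: {offenders}")
    if report.cycles:
        raise IntegrityError(f"{path}: hierarchy cycle(s): {report.cycles[:3]}")
    return term


def _close_children(term: Terminology) -> None:
    """Make parent/child sets mutually inverse (children derived from parents)."""
    for c in term.concepts.values():
        for p in c.parents:
            if p in term.concepts:
                term.concepts[p].children.add(c.id)
        for ch in c.children:
            if ch in term.concepts:
                term.concepts[ch].parents.add(c.id)


def _check_hierarchy(term: Terminology) -> ValidationReport:
    report = ValidationReport()
    for c in term.concepts.values():
        for p in c.parents:
            if p not in term.concepts:
                report.dangling_parents.append((c.id, p))
            elif c.id not in term.concepts[p].children:
                report.asymmetric_links.append((p, c.id))
        for ch in c.children:
            if ch in term.concepts and c.id not in term.concepts[ch].parents:
                report.asymmetric_links.append((c.id, ch))
    # cycle detection on the parent->child relation (iterative DFS, 3 colors)
    color: dict[str, int] = {}
    for start in term.concepts:
        if color.get(start):
            continue
        stack: list[tuple[str, Iterable[str]]] = [(start, iter(sorted(term.concepts[start].children)))]
        color[start] = 1
        path = [start]
        while stack:
            node, it = stack[-1]
            advanced = False
            for ch in it:
                if ch not in term.concepts:
                    continue
                if color.get(ch) == 1:
                    i = path.index(ch)
                    report.cycles.append(path[i:] + [ch])
                elif not color.get(ch):
                    color[ch] = 1
                    path.append(ch)
                    stack.append((ch, iter(sorted(term.concepts[ch].children))))
                    advanced = True
                    break
            if not advanced:
                color[node] = 2
                path.pop()
                stack.pop()
    return report


def save_terminology(term: Terminology, path: str | Path) -> None:
    doc = {
        "id": term.id,
        "languages": sorted(term.languages),
        "concepts": [
            {
                "id": c.id,
                "preferred_term": c.preferred_term,
                "synonyms": c.synonyms,
                "parents": sorted(c.parents),
            }
            for c in sorted(term.concepts.values(), key=lambda c: c.id)
        ],
    }
    Path(path).write_text(json.dumps(doc, ensure_ascii=False, indent=1), encoding="utf-8")


def load_mappings(path: str | Path) -> list[ConceptMapping]:
    out = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"source", "target", "kind"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path}: mappings CSV needs columns source,target,kind")
        for lineno, row in enumerate(reader, start=2):
            kind = row["kind"].strip()
            if kind not in MAPPING_KINDS:
                raise FormatError(f"{path} line {lineno}: unknown mapping kind {kind!r}")
            out.append(ConceptMapping(row["source"].strip(), row["target"].strip(), kind))
    return out


def save_mappings(mappings: Iterable[ConceptMapping], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source", "target", "kind"])
        for m in sorted(mappings, key=lambda m: (m.source, m.target, m.kind)):
            w.writerow([m.source, m.target, m.kind])


def close_mappings(mappings: Iterable[ConceptMapping]) -> list[ConceptMapping]:
    """Return the mapping set closed under inversion (repair for asymmetry warnings)."""
    s = set(mappings)
    s.update(m.inverse() for m in list(s))
    return sorted(s, key=lambda m: (m.source, m.target, m.kind))


# ---------------------------------------------------------------------------
# semantic network


class SemanticNetwork:
    """A collection of terminologies plus cross-terminology mappings.

    The single entry point the annotator and search engine use to resolve,
    expand and autocomplete concepts.
    """

    def __init__(
        self,
        terminologies: Iterable[Terminology] = (),
        mappings: Iterable[ConceptMapping] = (),
    ):
        self.terminologies: dict[str, Terminology] = {}
        for t in terminologies:
            if t.id in self.terminologies:
                raise IntegrityError(f"duplicate terminology id {t.id}")
            self.terminologies[t.id] = t
        self.mappings: list[ConceptMapping] = list(mappings)
        self._mapping_index: dict[str, list[ConceptMapping]] = {}
        for m in self.mappings:
            self._mapping_index.setdefault(m.source, []).append(m)

    # -- lookup ------------------------------------------------------------

    def resolve(self, concept_id: str) -> Concept:
        tid = concept_id.split(":", 1)[0]
        term = self.terminologies.get(tid)
        if term is None or concept_id not in term.concepts:
            raise ConceptLookupError(concept_id)
        return term.concepts[concept_id]

    def __contains__(self, concept_id: str) -> bool:
        tid = concept_id.split(":", 1)[0]
        t = self.terminologies.get(tid)
        return t is not None and concept_id in t.concepts

    @property
    def languages(self) -> set[str]:
        out: set[str] = set()
        for t in self.terminologies.values():
            out |= t.languages
        return out

    # -- expansion ---------------------------------------------------------

    def _hierarchy_neighbors(self, cid: str, direction: str) -> set[str]:
        c = self.resolve(cid)
        if direction == "descendants":
            return set(c.children)
        if direction == "ancestors":
            return set(c.parents)
        return set()

    def _mapping_neighbors(self, cid: str, spec: ExpansionSpec) -> set[str]:
        out = set()
        for m in self._mapping_index.get(cid, ()):
            if m.kind not in spec.mapping_kinds:
                continue
            if not spec.cross_terminology and m.source.split(":", 1)[0] != m.target.split(":", 1)[0]:
                continue
            if m.target in self:
                out.add(m.target)
        return out

    def expand_concepts(self, seeds: Iterable[str], spec: ExpansionSpec = DEFAULT_RETRIEVAL_EXPANSION) -> set[str]:
        """Seeds plus every concept reachable under ``spec``.

        Breadth-first search over states ``(concept, mapping hops used)``;
        hierarchy edges consume depth budget, mapping edges consume the single
        mapping hop (unless ``transitive_mappings``).  Deterministic, always a
        superset of the seeds.
        """
        seeds = list(seeds)
        for s in seeds:
            self.resolve(s)  # raises ConceptLookupError on unknown seeds
        max_hops = None if spec.transitive_mappings else 1
        # state -> remaining depth budget (None = unbounded); keep best budget seen
        best: dict[tuple[str, int], int | None] = {}
        q: deque[tuple[str, int, int | None]] = deque()
        for s in seeds:
            best[(s, 0)] = spec.depth
            q.append((s, 0, spec.depth))
        while q:
            cid, hops, budget = q.popleft()
            if budget is None or budget > 0:
                nb = budget if budget is None else budget - 1
                for nxt in sorted(self._hierarchy_neighbors(cid, spec.direction)):
                    self._push(best, q, nxt, hops, nb)
            if max_hops is None or hops < max_hops:
                for nxt in sorted(self._mapping_neighbors(cid, spec)):
                    self._push(best, q, nxt, hops + 1 if max_hops is not None else hops, budget)
        return {cid for cid, _ in best}

    @staticmethod
    def _push(best, q, cid, hops, budget) -> None:
        key = (cid, hops)
        prev = best.get(key, -1)
        better = prev == -1 or (budget is None and prev is not None) or (
            budget is not None and prev is not None and prev != -1 and budget > prev
        )
        if better:
            best[key] = budget
            q.append((cid, hops, budget))

    # -- autocomplete ------------------------------------------------------

    def autocomplete(self, prefix: str, language: str, limit: int = 10) -> list[tuple[str, str]]:
        """Ranked ``(term, concept_id)`` pairs whose normalized term starts
        with the normalized prefix.

        Exact term matches rank first, then shorter terms, then lexicographic.
        """
        if language not in self.languages:
            raise ConfigurationError(f"no loaded terminology covers language {language!r}")
        p = norm_text(prefix).strip()
        if not p:
            raise ConfigurationError("empty prefix after normalization")
        hits: list[tuple[tuple, str, str]] = []
        for term in self.terminologies.values():
            for c in term.concepts.values():
                for label in c.terms(language):
                    n = norm_text(label)
                    if n.startswith(p):
                        rank = (0 if n == p else 1, len(label), n, c.id)
                        hits.append((rank, label, c.id))
        hits.sort(key=lambda h: h[0])
        return [(label, cid) for _, label, cid in hits[:limit]]


def expand_concepts(
    seeds: Iterable[str],
    spec: ExpansionSpec,
    terminologies: SemanticNetwork | Iterable[Terminology],
    mappings: Iterable[ConceptMapping] = (),
) -> set[str]:
    """Functional wrapper over :meth:`SemanticNetwork.expand_concepts`."""
    net = terminologies if isinstance(terminologies, SemanticNetwork) else SemanticNetwork(terminologies, mappings)
    return net.expand_concepts(seeds, spec)


def autocomplete(
    prefix: str,
    language: str,
    terminologies: SemanticNetwork | Iterable[Terminology],
    limit: int = 10,
) -> list[tuple[str, str]]:
    net = terminologies if isinstance(terminologies, SemanticNetwork) else SemanticNetwork(terminologies)
    return net.autocomplete(prefix, language, limit)


def validate_graph(
    terminologies: Iterable[Terminology] | SemanticNetwork,
    mappings: Iterable[ConceptMapping] | None = None,
) -> ValidationReport:
    """Full-graph validation report; empty report iff all invariants hold."""
    if isinstance(terminologies, SemanticNetwork):
        terms = list(terminologies.terminologies.values())
        maps = list(terminologies.mappings) if mappings is None else list(mappings)
    else:
        terms = list(terminologies)
        maps = list(mappings or ())
    report = ValidationReport()
    known: set[str] = set()
    for t in terms:
        sub = _check_hierarchy(t)
        report.cycles += sub.cycles
        report.dangling_parents += sub.dangling_parents
        report.asymmetric_links += sub.asymmetric_links
        known |= set(t.concepts)
    mapset = set(maps)
    for m in maps:
        if m.source not in known or m.target not in known:
            report.unknown_mapping_endpoints.append(m)
        elif m.inverse() not in mapset:
            report.missing_mapping_inverses.append(m)
    return report
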