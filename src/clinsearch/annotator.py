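"""Dictionary-based semantic annotation of clinical narratives.

Maps words and expressions of (mostly French) free text to terminology
concepts with a bag-of-words matcher, then post-processes the matches for
negation ("pas de diabète") and attached numeric values ("HbA1c à 7,2 %").

The matcher is order-free within a sentence-bounded window: a lexicon entry
matches wherever all of its normalized term tokens occur with at most
``window`` non-matching tokens between consecutive matched tokens.  When two
matches nest and one term's token set is a subset of the other's, only the
longer match is kept (longest-match suppression); genuine partial overlaps
are both kept.

Frequency ranking and stoplist filtering support the operational workflow in
which the most frequent concepts are reviewed by a human and irrelevant ones
(boilerplate like the hospital's own name) are stoplisted; the annotator
never drops concepts on its own.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigurationError
from .terminology import Terminology
from .textnorm import Token, norm_tokens, parse_number, tokenize

DEFAULT_NEGATION_TRIGGERS = ("pas de", "absence de", "sans", "aucun", "aucune", "ni")
# single normalized tokens: the unit is recognized as the one token that
# follows the number ("7.2 %", "1450 /mm3" -> token "mm3", "85 umol/l" -> "umol")
DEFAULT_UNITS = ("%", "mm3", "g", "kg", "mmol", "umol", "mg", "ui", "ans")


@dataclass(frozen=True)
class Document:
    id: str
    text: str
    language: str = "fr"


@dataclass(frozen=True)
class Annotation:
    """One concept occurrence in one narrative.

    ``start``/``end`` are 0-based half-open character offsets into the raw
    text; ``score`` is match completeness (1.0 = every term token matched —
    the only kind emitted by default).
    """

    document: str
    concept: str
    start: int
    end: int
    matched_tokens: tuple[str, ...]
    negated: bool = False
    value: tuple[float, str | None] | None = None
    score: float = 1.0


@dataclass(frozen=True)
class AnnotatorConfig:
    window: int = 3                      # max token gap inside a match
    sentence_bounded: bool = True
    negation_triggers: tuple[str, ...] = DEFAULT_NEGATION_TRIGGERS
    negation_window: int = 5             # tokens between trigger end and mention start
    value_window: int = 5                # tokens between mention and its numeric value
    units: tuple[str, ...] = DEFAULT_UNITS
    max_term_length: int = 8             # lexicon entries longer than this are skipped
    stoplist: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.window < 0:
            raise ConfigurationError("window must be >= 0")
        if self.negation_window > 0 and not self.negation_triggers:
            raise ConfigurationError("negation enabled but no triggers configured")


@dataclass
class Lexicon:
    """Normalized term-token multisets mapped to the concepts they label."""

    # sorted token tuple (multiset encoding) -> list of (concept id, original term)
    entries: dict[tuple[str, ...], list[tuple[str, str]]] = field(default_factory=dict)
    skipped_long_terms: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def entry_count(self) -> int:
        """Number of (term, concept) pairs held."""
        return sum(len(v) for v in self.entries.values())


def build_lexicon(
    terminologies: Iterable[Terminology],
    languages: Sequence[str] = ("fr",),
    config: AnnotatorConfig = AnnotatorConfig(),
) -> Lexicon:
    """One entry per preferred term or synonym in the requested languages.

    Terms longer than ``config.max_term_length`` tokens are skipped and
    counted.  A term labelling two concepts maps to both (ambiguity is
    preserved).
    """
    lex = Lexicon()
    n_terms = 0
    any_terms = 0
    for term in terminologies:
        for concept in term.concepts.values():
            any_terms += len(concept.preferred_term) + sum(len(v) for v in concept.synonyms.values())
            for lang in languages:
                for label in concept.terms(lang):
                    toks = norm_tokens(label)
                    if not toks:
                        continue
                    n_terms += 1
                    if len(toks) > config.max_term_length:
                        lex.skipped_long_terms += 1
                        continue
                    key = tuple(sorted(toks))
                    bucket = lex.entries.setdefault(key, [])
                    if (concept.id, label) not in bucket:
                        bucket.append((concept.id, label))
    if n_terms == 0 and any_terms > 0:
        langs = ", ".join(languages)
        raise ConfigurationError(f"no terms found in requested language(s): {langs}")
    return lex


# ---------------------------------------------------------------------------
# matching


def _find_matches(
    sent_tokens: list[Token], entry: tuple[str, ...], window: int
) -> list[tuple[int, ...]]:
    """All minimal matched-position tuples of a token multiset in a sentence.

    A match consumes each entry token exactly once, scanning left to right
    from each candidate start, allowing at most ``window`` non-matching
    tokens between consecutive matched tokens.
    """
    need_template = Counter(entry)
    matches: list[tuple[int, ...]] = []
    for start in range(len(sent_tokens)):
        if need_template.get(sent_tokens[start].norm, 0) == 0:
            continue
        need = need_template.copy()
        positions = []
        gap = 0
        i = start
        while i < len(sent_tokens):
            tok = sent_tokens[i].norm
            if need.get(tok, 0) > 0:
                need[tok] -= 1
                positions.append(i)
                gap = 0
                if sum(need.values()) == 0:
                    break
            else:
                gap += 1
                if gap > window:
                    break
            i += 1
        if sum(need.values()) == 0:
            matches.append(tuple(positions))
    # minimality: drop a match whose position span strictly contains another's
    minimal = []
    for m in matches:
        if not any(
            o != m and o[0] >= m[0] and o[-1] <= m[-1] and (o[0] > m[0] or o[-1] < m[-1])
            for o in matches
        ):
            minimal.append(m)
    return sorted(set(minimal))


def annotate(
    document: Document,
    lexicon: Lexicon,
    config: AnnotatorConfig = AnnotatorConfig(),
) -> list[Annotation]:
    """Bag-of-words concept matching over one document.

    Returns annotations ordered by (span start, concept id), with negation
    flags and numeric values already attached.
    """
    tokens = tokenize(document.text)
    raw = _match_concepts(document, tokens, lexicon, config)
    raw = detect_negation(raw, tokens, config)
    raw = extract_values(raw, tokens, config)
    return sorted(raw, key=lambda a: (a.start, a.concept, a.end))


def _match_concepts(
    document: Document, tokens: list[Token], lexicon: Lexicon, config: AnnotatorConfig
) -> list[Annotation]:
    # group token indexes by sentence (or one big group if unbounded)
    groups: dict[int, list[int]] = {}
    for i, t in enumerate(tokens):
        groups.setdefault(t.sentence if config.sentence_bounded else 0, []).append(i)

    found: list[tuple[Annotation, frozenset[str]]] = []  # annotation + entry token set
    for idxs in groups.values():
        sent = [tokens[i] for i in idxs]
        present = Counter(t.norm for t in sent)
        for entry, concepts in lexicon.entries.items():
            need = Counter(entry)
            if any(present[tok] < n for tok, n in need.items()):
                continue
            for positions in _find_matches(sent, entry, config.window):
                abs_positions = tuple(idxs[p] for p in positions)
                start = tokens[abs_positions[0]].start
                end = tokens[abs_positions[-1]].end
                matched = tuple(tokens[p].norm for p in abs_positions)
                for concept_id, _label in concepts:
                    found.append(
                        (
                            Annotation(
                                document=document.id,
                                concept=concept_id,
                                start=start,
                                end=end,
                                matched_tokens=matched,
                                score=1.0,
                            ),
                            frozenset(entry),
                        )
                    )

    # longest-match suppression: nested span + token-subset entry -> keep longer
    keep = []
    for a, a_set in found:
        suppressed = False
        for b, b_set in found:
            if a is b:
                continue
            if a_set < b_set and b.start <= a.start and a.end <= b.end:
                suppressed = True
                break
        if not suppressed:
            keep.append(a)
    # dedupe identical (concept, span)
    out = {(a.concept, a.start, a.end): a for a in keep}
    return list(out.values())


def detect_negation(
    annotations: Iterable[Annotation], tokens: list[Token], config: AnnotatorConfig
) -> list[Annotation]:
    """Flag annotations preceded, within the same sentence and within
    ``negation_window`` tokens, by a negation trigger phrase."""
    triggers = [norm_tokens(t) for t in config.negation_triggers if norm_tokens(t)]
    norms = [t.norm for t in tokens]
    out = []
    for a in annotations:
        first = _token_index_at(tokens, a.start)
        negated = False
        if first is not None and triggers:
            sent = tokens[first].sentence
            for trig in triggers:
                L = len(trig)
                # trigger must end at e-1 with first - e <= negation_window
                lo = max(0, first - config.negation_window - L)
                for s in range(lo, first):
                    e = s + L
                    if e > first:
                        break
                    if norms[s:e] == list(trig) and tokens[s].sentence == sent and first - e <= config.negation_window:
                        negated = True
                        break
                if negated:
                    break
        out.append(replace(a, negated=negated))
    return out


def extract_values(
    annotations: Iterable[Annotation], tokens: list[Token], config: AnnotatorConfig
) -> list[Annotation]:
    """Attach the nearest same-sentence number token (within
    ``value_window`` tokens of the mention, ties broken leftward) plus its
    trailing unit token when that token is in the unit lexicon."""
    units = {u.lower() for u in config.units}
    out = []
    for a in annotations:
        first = _token_index_at(tokens, a.start)
        last = _token_index_at(tokens, a.end - 1, last=True)
        if first is None or last is None:
            out.append(a)
            continue
        sent = tokens[first].sentence
        span_idx = set(range(first, last + 1))
        best: tuple[int, int] | None = None  # (distance, index)
        for i, t in enumerate(tokens):
            if not t.is_number or t.sentence != sent or i in span_idx:
                continue
            dist = first - i if i < first else i - last
            if dist > config.value_window:
                continue
            if best is None or dist < best[0] or (dist == best[0] and i < best[1]):
                best = (dist, i)
        if best is None:
            out.append(a)
            continue
        i = best[1]
        unit = None
        if i + 1 < len(tokens) and tokens[i + 1].norm in units and tokens[i + 1].sentence == sent:
            unit = tokens[i + 1].text
        out.append(replace(a, value=(parse_number(tokens[i].text), unit)))
    return out


def _token_index_at(tokens: list[Token], offset: int, last: bool = False) -> int | None:
    for i, t in enumerate(tokens):
        if t.start <= offset < t.end:
            return i
    # fall back: nearest token starting after (or before, for span ends)
    if last:
        prev = None
        for i, t in enumerate(tokens):
            if t.end <= offset + 1:
                prev = i
        return prev
    for i, t in enumerate(tokens):
        if t.start >= offset:
            return i
    return None


# ---------------------------------------------------------------------------
# corpus-level operations


def rank_concept_frequencies(annotations: Iterable[Annotation]) -> list[tuple[str, int]]:
    """Exact concept counts, ordered by (count desc, concept id asc).

    This is the review file for the manual top-k concept filtering workflow.
    """
    counts = Counter(a.concept for a in annotations)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def apply_stoplist(
    annotations: Iterable[Annotation], stoplist: Iterable[str]
) -> tuple[list[Annotation], int]:
    """Remove annotations whose concept is stoplisted; returns (kept, n_removed)."""
    stop = set(stoplist)
    kept, removed = [], 0
    for a in annotations:
        if a.concept in stop:
            removed += 1
        else:
            kept.append(a)
    return kept, removed


# ---------------------------------------------------------------------------
# JSONL input/output


def read_documents(path: str | Path) -> list[Document]:
    docs = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                rec = json.loads(line)
                docs.append(Document(id=rec["id"], text=rec["text"], language=rec.get("language", "fr")))
    return docs


def write_documents(docs: Iterable[Document], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(json.dumps({"id": d.id, "text": d.text, "language": d.language}, ensure_ascii=False) + "\n")


def write_annotations(annotations: Iterable[Annotation], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for a in annotations:
            rec = {
                "document": a.document,
                "concept": a.concept,
                "start": a.start,
                "end": a.end,
                "matched_tokens": list(a.matched_tokens),
                "negated": a.negated,
                "value": None if a.value is None else [a.value[0], a.value[1]],
                "score": a.score,
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_annotations(path: str | Path) -> list[Annotation]:
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            value = rec.get("value")
            out.append(
                Annotation(
                    document=rec["document"],
                    concept=rec["concept"],
                    start=rec["start"],
                    end=rec["end"],
                    matched_tokens=tuple(rec["matched_tokens"]),
                    negated=rec["negated"],
                    value=None if value is None else (float(value[0]), value[1]),
                    score=rec.get("score", 1.0),
                )
            )
    return out


def index_annotations(store, annotations: Iterable[Annotation]) -> int:
    """Write per-narrative concept sets into the store.

    Sets the ``concepts`` (all mentioned) and ``concepts_affirmed``
    (non-negated mentions) attributes of each clinical_narrative entity so
    the search engine can run concept constraints with or without negated
    mentions.  Returns the number of narratives updated.
    """
    by_doc: dict[str, list[Annotation]] = {}
    for a in annotations:
        by_doc.setdefault(a.document, []).append(a)
    n = 0
    for doc_id, anns in by_doc.items():
        key = ("clinical_narrative", doc_id)
        if store.get_entity(key) is None:
            continue
        store.set_attribute(key, "concepts", frozenset(a.concept for a in anns))
        affirmed = frozenset(a.concept for a in anns if not a.negated)
        store.set_attribute(key, "concepts_affirmed", affirmed)
        n += 1
    return n
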