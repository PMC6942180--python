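"""Annotate a French clinical narrative: concepts, negation, numeric values.

The bag-of-words matcher maps expressions to terminology concepts; negation
triggers ("pas de") flag negated mentions and nearby numbers become attached
values with units.
"""

from clinsearch.annotator import Document, annotate, build_lexicon
from clinsearch.synthdata import generate_terminology

terms, _ = generate_terminology()
medvoc = [t for t in terms if t.id == "MEDVOC"]
lexicon = build_lexicon(medvoc, languages=("fr",))

doc = Document(
    id="cr-1",
    text="Insuffisance cardiaque NYHA classe III. Pas de diabète de type 2. HbA1c à 6,1 %.",
    language="fr",
)
for a in annotate(doc, lexicon):
    span = doc.text[a.start : a.end]
    print(f"{a.concept:22s} {span!r:42s} negated={a.negated} value={a.value}")
# Expected: an affirmed heart-failure mention plus its NYHA class, a NEGATED
# type-2-diabetes mention (excluded by negation-aware searches), and a
# glycated-hemoglobin mention carrying the value (6.1, '%') parsed from the
# decimal-comma French notation.
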