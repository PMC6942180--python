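"""End-to-end glue: annotate a dataset's narratives and index the results.

The annotation lexicon is built from the clinical vocabulary terminologies
only (narratives are written in clinical language; coded terminologies like
the ICD-like hierarchy describe structured diagnoses, which the engine
reaches through concept expansion and mappings instead)."""

from __future__ import annotations

from .annotator import Annotation, AnnotatorConfig, annotate, build_lexicon, index_annotations
from .synthdata import SynthDataset

#: terminologies whose terms feed the narrative-annotation lexicon
ANNOTATION_TERMINOLOGIES = ("MEDVOC",)


def annotate_dataset(
    dataset: SynthDataset,
    config: AnnotatorConfig = AnnotatorConfig(),
    languages=("fr",),
) -> list[Annotation]:
    """Annotate every narrative and write the per-narrative concept sets
    into the store; returns the full annotation list."""
    terms = [
        t
        for tid, t in dataset.network.terminologies.items()
        if tid in ANNOTATION_TERMINOLOGIES
    ]
    lexicon = build_lexicon(terms, languages, config)
    annotations: list[Annotation] = []
    for doc in dataset.documents:
        annotations.extend(annotate(doc, lexicon, config))
    index_annotations(dataset.store, annotations)
    return annotations
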