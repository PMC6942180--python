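"""Load the toy terminologies and expand a concept set semantically.

Hierarchy descent plus exact cross-terminology mappings turn one seed
concept into the full family of codes a cohort query should match.
"""

from clinsearch.synthdata import generate_terminology
from clinsearch.terminology import ExpansionSpec, SemanticNetwork

terms, mappings = generate_terminology()
net = SemanticNetwork(terms, mappings)

seeds = {"MEDVOC:DIABETES"}
spec = ExpansionSpec(direction="descendants", depth=None, mapping_kinds=frozenset({"exact"}))
expanded = net.expand_concepts(seeds, spec)

print(f"seed concepts: {sorted(seeds)}")
print(f"expanded to {len(expanded)} concepts:")
for cid in sorted(expanded):
    print("  ", cid)
# The expansion contains the clinical vocabulary's diabetes subtypes AND the
# ICD-like codes reached through the exact mappings (E10-E14 block and its
# descendants) — exactly the set a diagnosis-code search should accept.

print("\nautocomplete 'diab' (fr):")
for term, cid in net.autocomplete("diab", "fr", limit=5):
    print(f"   {term!r} -> {cid}")
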