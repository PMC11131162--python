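"""Bridging pedigree relations to and from SNOMED CT person concepts.

Annotation travels relation -> concept for every shipped mapping; the
reverse direction exists only for precisely corresponding pairs, so a
membership in (say) sct_Niece_person — which includes nieces by marriage —
never entails a blood relation.
"""

from kinqc import FactBase, ParentLink, Person, SexQuality, infer_all
from kinqc.model import FEMALE, MALE
from kinqc.sct import (ConceptAssertion, annotate, check_concept_consistency,
                       default_mappings, entail_from_concepts)

fb = FactBase()
for pid, sex in (("amy", FEMALE), ("bob", MALE), ("carl", MALE)):
    fb.add_person(Person(pid))
    fb.add_sex_quality(SexQuality(pid, sex))
fb.add_parent_link(ParentLink("amy", "bob"))
fb.add_parent_link(ParentLink("amy", "carl"))

assertions = annotate(fb, infer_all(fb))
print("concept memberships derived from the pedigree:")
for a in assertions:
    print(f"  {a.particular}: {a.concept}")

claims = entail_from_concepts(assertions)
print(f"\n{len(claims)} existential claims entailed back from the concepts")
print("(only bidirectional mappings entail; niece/grandparent stay one-way)")

# an externally asserted membership with no pedigree witness is flagged
bad = [ConceptAssertion("carl", "sct_Natural-parent_person")]
for v in check_concept_consistency(fb, bad):
    print("\nbridge violation:", v.note)
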