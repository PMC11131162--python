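"""Deriving kinship relations and family-history categories.

Builds the parent-with-own-daughter pedigree by hand, materialises every
derivable relation, and classifies one relative into the nine
family-history categories.  The multi-category result (parent AND maternal
grandparent) is exactly the kind of signal that co-occurs with an unusual
ancestry situation.
"""

from kinqc import FactBase, ParentLink, Person, SexQuality, classify, infer_all
from kinqc.model import FEMALE, MALE, TimePoint

fb = FactBase()
for pid, sex, birth in (("noah", MALE, 1900), ("mara", FEMALE, 1902),
                        ("evelyn", FEMALE, 1925), ("katherine", FEMALE, 1945)):
    fb.add_person(Person(pid, TimePoint(birth)))
    fb.add_sex_quality(SexQuality(pid, sex))
for parent, child in (("noah", "evelyn"), ("mara", "evelyn"),
                      ("noah", "katherine"), ("evelyn", "katherine")):
    fb.add_parent_link(ParentLink(parent, child))

relations = infer_all(fb)
print(f"{len(relations)} derivable relation instances, e.g.:")
for r in relations:
    if r.relation in ("natural-ancestor-of", "natural-maternal-grandparent-of"):
        print(f"  {r.relation}({', '.join(r.args)})   supported by {list(r.support)}")

categories = classify(fb, subject="katherine", relative="noah")
print("\nfamily-history categories of noah relative to katherine:",
      sorted(f"{int(c)}={c.label}" for c in categories))
print("two categories at once — a useful hint that this pedigree deserves a look.")
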