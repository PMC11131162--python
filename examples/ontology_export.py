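"""Exporting the ontology as CLIF modules and reasoning over its rules.

Builds the six-module bundle, prints the per-module axiom counts, and uses
the Kowalski-rule engine to show that a pedigree in which someone would be
their own ancestor violates the irreflexivity constraint.
"""

from kinqc.clif import build_bundle, count_axioms
from kinqc.engine import check_satisfiable
from kinqc.rules import irreflexive_ancestor_constraint, kinship_rules

bundle = build_bundle()
print("ontology bundle", bundle.content_hash())
for module, entry in count_axioms(bundle).items():
    print(f"  {module + '.clif':24s} {entry['total']:3d} axioms  {entry['by_subindex']}")

rules = kinship_rules() + [irreflexive_ancestor_constraint()]
cyclic = {("has-natural-child", "a", "b"), ("has-natural-child", "b", "a")}
sat, witness = check_satisfiable(rules, cyclic)
print(f"\nmutual parent-child facts satisfiable? {sat} (witness: {witness})")
sat, _ = check_satisfiable(rules, {("has-natural-child", "a", "b")})
print(f"after dropping one of the two links:    {sat}")
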