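# kinqc

Pedigree kinship inference and family-history data quality control, with
SNOMED CT bridging and a CLIF ontology export.

## The problem

Population screening programmes — the motivating case is cholangiocarcinoma
screening in northeastern Thailand, whose enrollment form asks whether any
relative was diagnosed and offers nine relative categories — accumulate
registries of family-history claims that are entered by hand and riddled
with the usual entry mistakes.  Most such mistakes surface as kinship
patterns that are *possible but atypical*: a person recorded as co-parenting
with their own descendant, close blood relatives recorded as spouses or as
co-parents, or two contemporaneous marriages of one person.  `kinqc` turns a
realist kinship ontology into an executable engine that derives all blood
and spousal relations from ground pedigree facts, raises exactly those
atypicality alerts, reconciles questionnaire claims against the pedigree,
and exports its axioms in a machine-readable form.

It is aimed at registry curators and biomedical-ontology developers who want
pedigree QC that is *explained by axioms* rather than ad-hoc scripts.

## The model

Ground facts are gamete-origin parenthood `has-natural-child(x, y)`, sex
qualities inhering in persons (`male-sex`, `female-sex` — a bearer may carry
both), and marriage bonds: relational qualities inhering in exactly two
persons and carrying a temporal extent.  From these the package derives,
atemporally:

    natural-ancestor-of(x, y)  ≡  parent(x, y) ∨ ∃z parent(x, z) ∧ ancestor(z, y)
    natural-father-of(x, y)    ≡  parent(x, y) ∧ ∃q inheres-in(q, x) ∧ q : male-sex
    natural-sibling-of(x, y)   ≡  x ≠ y ∧ ∃p parent(p, x) ∧ parent(p, y)

and so on through grandparents (maternal/paternal via the *linking* parent's
sex), aunts/uncles with age-ordered variants, nieces/nephews and first
cousins.  Only spousehood is time-indexed, through the bond's interval.
Four alert axioms define the unusual situations; the set of blood relations
that count as "close" is a tunable policy defaulting to
{parent, sibling, grandparent, aunt, uncle, first-cousin}.

Every derivation is computed twice: procedurally, and as the least fixpoint
of a Kowalski-form Horn rule base evaluated by a small forward-chaining
engine.  Agreement of the two routes is asserted in the test suite and
recomputed by the acceptance script.

## Worked example

```sh
$ python examples/kinship_relations.py
23 derivable relation instances, e.g.:
  ...
  natural-maternal-grandparent-of(noah, katherine)   supported by
      [('has-natural-child', 'noah', 'evelyn'),
       ('has-natural-child', 'evelyn', 'katherine'),
       ('sex-quality', 'evelyn', 'female-sex')]

family-history categories of noah relative to katherine: ['2=maternal-grandparent', '5=parent']
```

`noah` fathered `katherine` with his own daughter `evelyn`, so he is at once
katherine's parent (category 5) and, through evelyn, her maternal
grandparent (category 2).  The QC detectors flag the same pedigree with one
`ancestry-loop` alert, triple `(noah, katherine, evelyn)`, and one
`close-relative-coparents` alert — the multi-category classification and the
alerts are two views of the same atypical structure.

The command-line surface wraps the same operations:

```sh
kinqc simulate --seed 11 --out-dir sim/            # synthetic pedigree + unions
kinqc qc sim/pedigree.tsv --unions sim/unions.tsv  # exit 1 iff alerts found
kinqc infer sim/pedigree.tsv --unions sim/unions.tsv
kinqc classify sim/pedigree.tsv --records records.tsv
kinqc bridge sim/pedigree.tsv --unions sim/unions.tsv
kinqc export-clif --out-dir ontology/              # the six .clif modules
```

Input is PED/FAM-style TSV (`person_id father_id mother_id sex birth death`,
`0` = missing parent, `.` = missing date, sex 1/2/0) plus a unions table
(`bond_id partner_a partner_b start end`).

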