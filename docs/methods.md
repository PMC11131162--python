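# Methods

## Ontological reading

The engine executes a realist kinship model.  Parenthood is *gamete-origin*
parenthood: `has-natural-child(x, y)` means a gamete of x is among those
from which y originates, so every relation prefixed `natural-` is a blood
relation — adoptive, step- and by-marriage readings are out of scope
(spousehood is the single non-blood relation modelled).  Sex is not an
attribute of a person but a quality inhering in one; the model deliberately
admits a bearer of both the male-sex and the female-sex quality, and under
the literal definitions such a parent is simultaneously a natural father and
a natural mother.  We implement that literal consequence rather than
special-casing it.

Blood relations are atemporal: once the parent facts hold, ancestry,
siblinghood, aunt-hood etc. hold timelessly.  Spousehood alone is temporal —
it is carried by a marriage bond, a relational quality inhering in exactly
two persons with a half-open interval `[start, end)`; an open end is a
current marriage.  Queries are `has_spouse_at(x, y, t)` and
`has_spouse_ever(x, y)`.

Decisions taken where the design was genuinely open:

* **Siblinghood** is "shares ≥ 1 natural parent" (half-siblings count); a
  `full_siblings_only` switch requires a shared male-sexed and a shared
  female-sexed parent.  The inclusive default matches the umbrella reading
  of the corresponding SNOMED CT concept and the blood-sense reading of the
  questionnaire's sibling category.
* **Maternal/paternal grandparenthood** is decided by the sex of the
  *linking* parent (the child's mother vs father), not by the grandparent's
  own sex.
* **Older/younger aunt/uncle** compare the aunt/uncle's birth with the
  *linking parent's* birth, existentially over linking parents; if either
  birth is unknown the ordered variants are simply not derivable (the base
  aunt/uncle relation still is).
* **First cousins** exclude pairs that are themselves siblings, so the
  sibling and first-cousin alert conditions stay disjoint.
* **Aunt/uncle are blood-only**: a parent's sibling's spouse is not an aunt.

## Integrity constraints vs alerts

Impossible structures are *integrity violations* (hard errors in the data):
self-parenthood, parental cycles (someone would be their own ancestor),
self-spousehood, two distinct same-sexed parents of one child (impossible
under gamete-origin parenthood for the human case), and bonds starting
outside a partner's known lifespan.  Unknown births/deaths are permissive —
checks are skipped, never failed, so incomplete registries are not flooded.

Atypical-but-possible structures are *alerts*, explicitly non-normative:

1. **ancestry-loop** — `(x, y, z)` with `has-natural-child(x, y)`,
   `ancestor(x, z)`, `ancestor(z, y)`;
2. **close-relative-coparents** — close blood relatives co-parenting a
   common person;
3. **close-relative-spouses** — close blood relatives joined by a bond;
4. **plural-spousal** — one person with two bonds to distinct partners whose
   intervals share a time point (remarriage to the same partner never
   triggers).

"Close" is a policy: default {parent, sibling, grandparent, aunt, uncle,
first-cousin}, evaluated in both argument orders because blood-closeness is
intuitively symmetric.  Narrowing the policy can only remove alerts
(monotonicity is property-tested); widening it far (distant cousins) buys
recall at a false-positive cost, so the default is conservative.  The
plural-spousal detector can be disabled outright for contexts in which
plural marriage is unremarkable.

## Dual derivation routes

Every relation and alert is derivable two ways:

* procedurally (`kinqc.inference`, `kinqc.unusual`), using networkx for
  reachability;
* declaratively, as the least fixpoint of a Horn rule base
  (`kinqc.rules` + `kinqc.engine`), with naive bottom-up evaluation over
  indexed ground facts and greedy join ordering.

Existential structure is pre-skolemized at fact extraction: the sex-quality
and bond facts *are* the Skolem witnesses, birth ordering and bond-interval
overlap are pre-computed into `birth-before`/`bonds-overlap` atoms, and the
one negative condition (the first-cousin definition's sibling exclusion) is
supplied as a closed-world complement relation (`not-natural-sibling-of`)
computed directly from the parent links.  This keeps the rule base
negation-free and the engine total; the cost is that those pre-computed
atoms are trusted inputs rather than derived ones.  Axioms with disjunctive
antecedents are split into one Horn rule per disjunct
(`to_kowalski`); a disjunctive consequent is outside the fragment and is
rejected.  Constraints are rules with an empty consequent; satisfiability
checking runs the fixpoint and then searches constraint bodies, returning a
violating binding as witness.

Fixpoint iteration terminates because there are no function symbols; the
tests assert completion within the |constants|^arity bound.

## SNOMED CT bridging

The bridge table is data (a TSV shipped in the package), not code, because
it is expected to grow.  Each row names a relation, the argument role that
gains the concept, the concept's fully specified name in the
`sct_Name_person` convention, and a direction.  Precisely corresponding
pairs (natural child, natural parent, natural sibling) are bidirectional;
nearly corresponding concepts (niece/nephew, maternal/paternal grandparent —
each of which includes by-marriage readings) map relation→concept only, and
the engine never produces a reverse entailment for them.  Relations with no
sufficiently close concept (natural ancestor, the age-ordered aunts/uncles)
are deliberately unmapped.  Numeric SCTIDs are an optional column left blank
by default: the source material gives FSN-style names only, and inventing
codes would be fabrication.  For symmetric relations the concept is asserted
for both ends (both orders are materialised, so a subject-role mapping
covers them).  Reverse entailments are existential claims
("some partner stands in the relation"); the consistency checker flags an
externally supplied membership under a bidirectional mapping whose claim has
no witness in the pedigree.

## Family-history categories

The nine questionnaire categories are: (1) paternal grandparent,
(2) maternal grandparent, (3) older aunt/uncle, (4) younger aunt/uncle,
(5) parent, (6) child, (7) sibling, (8) nephew/niece, (9) spouse.
Categories 1–8 are evaluated on blood relations only (the original-language
terms carry blood senses even where English glosses do not); category 9 uses
has-spouse-ever, the form supplying no date context.  Classification may
return several categories at once — in a consistent pedigree that
co-occurs with an unusual situation and is surfaced as a QC signal, not
suppressed.  Reconciliation statuses: confirmed, contradicted,
unverifiable (the pedigree derives no category for the pair), and
indeterminate-age (an aunt/uncle claim whose age order a missing birth
leaves open).

## CLIF export

The ontology is re-authored from the implemented relation inventory and
emitted as six modules (`ancestry`, `cca01-ground`, `ancestry-sct`,
`sct-ancestry`, `sct-declarations`, `unusual`), every axiom wrapped as
`(cl:comment "description [index|subindex]" sentence)` with indexes unique
across the bundle; the comment-based annotation convention is our choice.
The unusual module contains exactly one axiom per detector, rendered with
the symmetric closeness disjunction the detectors actually evaluate.  The
core module's axiom count is an emergent property of the inventory (23 at
the shipped default), not a target.  An optional `inspiration.clif` holds
untransformed source-style axioms and is explicitly not part of the bundle.

## Synthetic pedigrees

`generate_clean(seed, generations=4, founders=8, mean_children=2.5,
marriage_rate=0.8)` emulates a screening-registry pedigree: founder couples,
sibship sizes 1 + Poisson(mean−1) (mean 2.5 ≈ a completed-fertility cohort in
the screened region), integer-tick births spaced one 20-tick generation
apart and distinct within each sibship (so age-ordered relations are
determinate), 80 % of non-final-generation members marrying, and every
married-in spouse an unrelated outsider.  By construction the result has no
integrity violations and no unusual situations; the final generation stays
unmarried so that cousin-marriage injection sites exist.  One seed is split
into one child stream per stage (sex, fertility, marriage, birth jitter), so
adding a stage never perturbs earlier draws.

What the generator does **not** emulate: deaths (everyone is alive —
lifespan checks are exercised by hand-built fixtures only), missing data,
divorce/remarriage, consanguinity at realistic background rates,
multi-founder admixture, or calendar-date time scales.  Passing detector
tests on it therefore shows correctness of the logic on well-formed input,
not robustness to the messiness of real registries — that is what the
permissive-unknown policies and integrity checks are for.

Injection plants disjoint anomalies with a manifest of every expected
alert.  One injected situation can entail alerts of two kinds: a parent
co-parenting with their own child is both an ancestry loop and a
close-relative co-parenting, and the manifest records both.

## Numerical and procedural choices

* Deterministic ordering everywhere (sorted relation instances, alerts,
  axiom indexes) for reproducible diffs.
* Tabular dialect: missing parent `0`, missing date `.`, sex 1/2/0; a
  both-sexed bearer is representable only in the JSON serialization, and the
  TSV writer refuses it loudly.
* Time points are ISO dates or integer ticks; the scales never mix within
  one fact base (comparison raises).
* Problem sizes in the test and acceptance suites: 200 pedigrees of ~15–30
  persons for dual-route equivalence, 100 clean seeds for detector
  soundness, closures checked against a boolean matrix-squaring oracle up to
  50 persons — sizes at which the naive-but-indexed fixpoint evaluation is
  comfortably fast while still exercising every rule.

## Known limitations

* The rule engine is Horn-only; disjunctive conclusions and genuine
  negation are out of fragment (closed-world complements are precomputed).
* No affinal relations beyond spousehood, no cousin degrees beyond first,
  no twin relations, and no reasoning over SNOMED CT's own hierarchy.
* Single pedigree namespace per file (no multi-family IDs).
* The classifier's spouse category ignores dates; a divorced-then-reported
  spouse still confirms category 9.
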