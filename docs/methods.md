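# Methods

This note documents the models and procedures the package implements,
the assumptions behind them, the synthetic-data calibration, and the
design choices made where the design was genuinely open.

## The EQ model and complexity score

A phenotype is an Entity–Quality (EQ) statement: an anatomical entity
expression E, a quality term Q, and optionally a related entity RE when
Q is relational (e.g. *attached_to*). Entity expressions are trees of
ontology terms joined by relations (post-composition); the grammar is

```
EXPR := TERM { REL ["some"] "(" EXPR ")" }
TERM := CURIE | 'quoted label'
REL  := part_of | is_a
```

**EQ complexity** is the number of ontology classes plus relation
properties used in one statement: term nodes and relation edges of E,
plus one for Q, plus term nodes and relation edges of RE if present.
The implicit E–Q and Q–RE attachments are *not* counted — this is the
only counting rule consistent with the two reference scores the package
tests pin down (a bare entity+absent statement scores 2; a depth-three
post-composed entity with a relational quality and a single-term related
entity scores 7). The minimum possible score is 2. Whether a
"towards"-style property on the RE attachment should ever count is
undecidable from those two reference cases; we count neither attachment,
and both references come out right.

## Ontology reasoning

Ontologies are restricted to `is_a` and `part_of`. All reasoning is
directed reachability over a chosen subset of the two relations:
`superclosure` (ancestors), `subclosure` (descendants), and
`class_space(roots, mode)` — the set of non-obsolete, non-root terms
with a path to every root (`ALL_OF`) or at least one (`ANY_OF`). For
this two-relation fragment union-reachability subsumes the chain rules
(is_a∘part_of and part_of∘is_a), so the closures agree with what an EL
reasoner infers for subclassing plus existential parthood, at a fraction
of the machinery. Closures are non-reflexive, matching the "children of
a root" reading of class-space counts and keeping roots out of their own
spaces. Obsolete terms are retained on load but excluded from closures
and class spaces by default (toggleable). Other OBO relationship types
are dropped with a warning.

The OBO reader/writer covers the 1.2 flat-file subset needed here
(`id`, `name`, `is_a`, `relationship: part_of`, `is_obsolete`,
`subset`). It is written in-package because the contract wants parse
errors with line numbers, cycle errors that name a cycle, and a
deterministic writer; tests cross-check written files against an
independent OBO parser. Generalized (unnamed generic) terms are flagged
either by a `subset: generalized` tag or an external one-CURIE-per-line
id list.

## Quality classification

Qualities are assigned to Neomorphic, Morphology, Position, or Number by
is_a subsumption under configurable PATO anchors (present `PATO:0000467`,
absent `PATO:0000462`, morphology `PATO:0000051`, position
`PATO:0000140`, amount `PATO:0000070`), first match in that precedence
order, else Other. Neomorphic must precede Number because present and
absent are themselves subtypes of *amount*; without precedence they
would be double-classified. Relational qualities get no special rule —
*attached to* classifies wherever its is_a ancestry puts it (Morphology
in the bundled mini quality ontology, where it sits under *structure*).

## Phenomic metrics

* **Entity extraction** walks every term of every E and RE tree, keeps
  terms inside the configured class space, and drops generalized terms.
  Entities mentioned only under an *absent* quality still count as used:
  an explicit absence is phenomic content, unlike missing data.
* **Overlap** reports sizes, unique and shared counts and their
  percentages; the identities `unique_a = size_a − shared` and
  `union = size_a + size_b − shared` hold for all inputs and are
  property-tested.
* **Coverage** is `100·|used ∩ space|/|space|`.
* **Profiles** give mean/median/max complexity, entity-side and
  quality-side sizes, and quality-class percentages per publication.
* **Group comparisons** always treat per-publication statistics as the
  replicates (never pooled EQs — group ranges and t-tests only make
  sense over publications) and use a two-sided two-sample t-test, Welch
  by default with Student switchable for sensitivity checks.

Reporting rounds half-up (49 from 48.86, 18.8 from 18.75): whole
percents in overlap tables, one decimal for coverage and means. JSON
bundles always carry the unrounded values; every rounded figure derives
from them by that single rule.

## Supermatrix inference

Per statement: a quality subsumed by *absent* asserts ABSENT for the E
core term; one subsumed by *present* asserts PRESENT for the core; any
other quality implies PRESENT for **every** named, non-generalized term
in the E and RE trees that lies in the class space — describing the
orientation of a process entails the process (and the bone bearing it)
exists. Missing data yields nothing: an entity a source could not code
is never treated as absent, because conflating missing with absent is
precisely the error this analysis is meant to expose.

Propagation closes the assertion set under two rules: PRESENT propagates
up over both is_a and part_of (a part existing entails some whole; a
subclass instance is a superclass instance), ABSENT propagates down (no
whole ⇒ no parts; no class ⇒ no subclasses). These are the sound
directions for existential part_of plus subclassing; richer relation
semantics (e.g. develops_from) are out of scope, so this two-rule system
is this package's definition of ontology-aware inference. Propagated
assertions carry the shortest ontology path from their origin as
provenance.

Cells are PRESENT/ABSENT/POLYMORPHIC/UNKNOWN by support; every
POLYMORPHIC cell yields exactly one conflict per (taxon, entity),
tagged `direct` (both sides have non-propagated support), `mixed`, or
`inferred` (both sides propagation-only). NEXUS output codes 0/1/{01}/?
with lexicographically sorted taxa and characters so artifacts diff
cleanly; round-trips through an independent NEXUS reader are tested
cell-wise.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions of the curated
fin-to-limb corpora the package is designed around: 7 monograph-style
and 6 matrix-style publications; per-publication statement counts
negative-binomial with means 52.1 and 56.2 (dispersion 1.3, chosen so
the spread matches the published per-publication ranges of roughly
19–158); EQs per statement 1+Poisson with means 119.3/52.1 ≈ 2.29 and
215.8/56.2 ≈ 3.84; taxa per publication Poisson with means 8.7 and
32.2 over a pool of 60 taxa containing 4 focal taxa shared by
construction; quality-class mixtures Morphology/Neomorphic/Position/
Number = 54.3/12.4/30.5/2.8 % (monograph) and 36.8/37.2/16.0/10.0 %
(matrix); and EQ-complexity distributions that are truncated geometric
on {2..15} with the ratio solved numerically to hit means 3.4 and 2.9.
The geometric shape itself is an artifact choice — only the means,
minima, and maxima of the real complexity distributions are published —
and is documented as such.

Each generated EQ hits its drawn complexity target **exactly**: an even
target c is realised as a part_of chain of c/2 entity terms, an odd
target adds a single-term related entity. That parity construction lets
the scorer be validated against known values rather than the other way
round.

Generated corpora are **closure-consistent** by construction: per taxon
the generator tracks the reflexive upward closure of everything implied
present and the reflexive downward closure of everything asserted
absent, and samples new statement entities outside the forbidden sets.
A present/absent contradiction can therefore only exist if explicitly
injected. Injection picks leaf entities whose closures touch neither
set, plants a presence-implying statement in one corpus collection and
an explicit absence in the other, and records exactly those (taxon,
entity) pairs as ground truth — which the pipeline's conflict report
must then recover with no false positives and none missed.

Determinism: every artifact draws from its own stream derived from the
master seed by a labelled sub-seed (CRC32 of the stream name, masked
below 2^31), so identical configurations give byte-identical outputs and
partial regeneration does not disturb sibling artifacts.

What the generator does **not** emulate: real anatomical nomenclature,
realistic taxon sampling structure, correlated characters, curator
idiosyncrasies, or text of comparative statements (these are a boolean
flag drawn at the published per-statement rate for monographs). Passing
tests therefore demonstrate the pipeline's correctness and statistical
behaviour under the published summary structure, not fidelity to any
particular real corpus.

## Numerical and degenerate-input choices

* Rounding is half-up via decimal arithmetic (Python's builtin `round`
  is banker's rounding and would print 18.7 for 18.75).
* Percentages with empty denominators are reported as NA, never 0.
* `compare_groups` requires ≥2 values per group; the zero-variance
  equal-means case reports t=0, p=1 instead of NaN.
* Empty corpora give NaN quality profiles and are rejected by
  complexity profiling; empty class spaces are rejected by coverage.
* Label resolution is strict by default; lenient mode turns unresolvable
  labels into flagged placeholder terms so partially-resolved fixtures
  can flow through extraction (placeholders are never in any class
  space, so they cannot contaminate metrics).
* All emitted tables, matrices, and OBO files are deterministically
  ordered.

## Problem sizes used in testing

The test suite exercises the pipeline on compact instances chosen to
keep the properties sharp: random DAGs of up to 50 nodes against a
brute-force reachability oracle (100 graphs), 100 seeded conflict-free
studies pushed through the full pipeline, classifier recovery on 10,000
sampled EQs, and a 1,218-term two-root ontology whose class space has
exactly 1,216 members — the size of the real appendage class space the
coverage figures are quoted against. Default-calibration studies
(thousands of EQs) run in seconds.

## Known limitations

* Only is_a and part_of are modelled; ontologies whose semantics lean on
  other relations (develops_from, homologous_to) lose that structure on
  load (with a warning).
* The quality side of an EQ is a single term, so quality-size statistics
  are degenerate at 1; post-composed qualities found in some real
  corpora are not representable.
* Conflicts are reported, never reconciled or weighted by source
  reliability.
* Per-taxon filtering is exact identifier match; no taxonomy expansion.
* The OBO reader targets the documented subset, not full OBO 1.2; real
  ontology releases load in practice but only the subset's semantics are
  honoured or tested.
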