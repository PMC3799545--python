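# Methods

## Scope and overall shape

`crosspheno` is a deterministic data-transformation pipeline, not a fitted
model: given OBO-format building-block ontologies, cross-product (logical
definition) files and curated annotation tables, it produces a merged
cross-species phenotype ontology (`crossSpeciesPheno.obo`) and a human-gene
annotation table (`HSgenes_crossSpeciesPhenoAnnotation.txt`). Every stage
is a pure function of its inputs; rerunning any stage on unchanged inputs
reproduces its artifacts byte for byte (no wall-clock stamps, no
hash-order dependence — all serialization is explicitly sorted).

## The EQ fragment and its subsumption semantics

A phenotype class is defined as
`has_part some (Q ⊓ inheres_in some E [⊓ towards some T] [⊓ qualifier some abnormal] [⊓ extra differentiae])`.
The `has_part` wrapper is shared by all phenotype classes, so it cancels
in pairwise subsumption and is never materialized; the reasoner operates
on the (quality, bearer, towards, qualifier, extras) tuple directly.

`A ⊑ B` holds iff:

* `Q_A ⊑ Q_B` under the merged building-block closure (mandatory — both
  definitions must have a genus);
* if B names a bearer, A names one and `E_A ⊑ E_B`; an absent bearer on B
  is vacuously entailed (fewer conjuncts = more general class, the
  existential reading);
* the same rule for `towards` and `qualifier`;
* every extra differentia of B is entailed by some extra differentia of A
  under the same (normalized) relation.

A CURIE absent from the merged closure entails only itself; the condition
degrades to syntactic equality and the class is reported once. This keeps
a stale definition from silently poisoning a build while still letting
identical definitions merge.

**Entity modes.** Bearer entailment has two modes. The default, `is_a`,
uses pure subclass reachability. The liberal mode, `is_a+part_of`, adds
`part_of` edges to bearer reachability only (never to quality or
`towards` entailment). The published semantics of the original
OWL-reasoner-based construction with respect to `inheres_in ∘ part_of`
propagation is not recoverable, so both readings are supported and the
conservative one is the default; the liberal mode provably yields a
superset of subclass pairs (property-tested).

**Classification.** Pairwise O(n²) structural subsumption with the cheap
quality test first, unioned with (a) asserted `is_a` edges inside each
pre-composed phenotype ontology, trusted as given, and (b) asserted
equivalences (lexical HP↔MP alignments) in both directions; the union is
transitively closed and its strongly connected components are the
equivalence groups. The EQ fragment has no role chains, so pairwise
comparison is complete for it; on every randomized case up to 8 phenotype
classes the output is verified equal to an independent brute-force oracle
(direct condition enumeration + Floyd–Warshall + mutual-reachability
partition).

**Cycles.** Two-way reachability created by asserted equivalences is
contracted silently (bridging legitimately makes ZFA:eye and UBERON:eye
mutually reachable); any `is_a` cycle that survives contraction aborts the
build, since building-block hierarchies are supposed to be DAGs.

## Normalization choices

* Definitions lacking the *abnormal* qualifier (PATO:0000460) get it added
  so that qualifier comparison never separates otherwise-identical
  definitions. A definition carrying a *different* qualifier is kept as-is
  and reported, rather than overwritten — rewriting curated content felt
  wrong for a consistency pass. The operation is idempotent
  (property-tested).
* Relations are normalized along a config-driven `subPropertyOf`-style
  chain; `occurs_in`, `results_in_morphogenesis_of`,
  `results_in_development_of` and `inheres_in_part_of` default to
  `inheres_in`-like. The first `inheres_in`-like filler becomes the bearer;
  additional ones stay as extra differentiae (reported), so subsumption
  then requires them to match pairwise — the conservative reading for
  relational qualities over two entities.
* Namespace adornments on relation names (`OBO_REL:inheres_in`) are
  stripped when the local part is a word; numeric-local CURIEs
  (`RO:0000052`) are left intact.
* GO cross-product definitions (entity-level, non-phenotype prefixes) are
  classified first among themselves and their inferred subsumptions are
  folded into the building-block closure as extra `is_a` edges before
  phenotype classification. The full equivalence between a GO class and
  its defining expression is not exploited beyond this (limitation below).

## Bridging

* Uberon bridge: one equivalence axiom per (Uberon class, xref) whose
  prefix is in {ZFA, MA, FMA}; only xrefs asserted on the Uberon side are
  used, and classes in Uberon's `upper_level` subset (e.g. *tissue*) are
  excluded — bridging through them would equate wildly different
  structures.
* Lexical HP↔MP alignment: exact match on normalized labels (lowercase,
  punctuation stripped, whitespace collapsed). A normalized label matching
  more than one class on either side produces no axiom (ambiguity guard).
  Exact synonyms can be enabled by config, default off; no stemming or
  fuzzy matching — exact match is the reproducible floor, and any axiom
  count is version-bound anyway.

## ZP synthesis

Only `abnormal`-modifier lines mint classes; `normal` lines are dropped
and reported. One class per unique definition content; the label is
`abnormal(ly) {quality label} {entity label}`. Numbering is stable via a
persisted id-map keyed by a canonical definition string
(`quality|bearer|towards|qualifier|extras`); novel definitions receive the
smallest unused number at or above a configurable base, assigned in
(quality, entity) sort order. The tested pheno.txt layout is the 8-column
one (gene id, Entrez, symbol, entity, entity label, quality, quality
label, modifier); a configurable column map accommodates wider exports.

## Merging and export

Primary id priority is HP > MP > ZP, ties broken by lexicographically
smallest id. HP-first is the published policy; ranking MP above ZP when no
HP member exists is this build's declared choice (MP is the larger curated
vocabulary) and is deterministic. The subclass DAG is rewritten onto
primary ids, transitively reduced, and exported with only phenotype
classes; a single reserved root (`UPHENO:0000001`) collects parentless
clusters so downstream tools see a rooted, connected DAG. Invariants
enforced by tests: every phenotype id appears exactly once (primary or
alt_id); the closure of the exported `is_a` edges equals the reasoner's
subsumption exactly; shuffled inputs give byte-identical output.

## Annotation transfer

* Human: disease→phenotype rows join disease→gene maps. The OMIM map is
  keyed `OMIM:<mim>`; the simplified Orphanet table is two columns
  (disease id, gene symbol), symbols resolving to Entrez through the
  mim2gene table (a third Entrez column is also accepted). Records
  identical up to evidence merge with evidence unioned; diseases with
  phenotypes but no gene are counted and dropped.
* Mouse: genotype-level rows resolve to every involved marker (comma- or
  pipe-separated marker column); each marker's annotations transfer to all
  of its human orthologs.
* Zebrafish: the zp.annot table transfers over ZFIN orthology the same
  way. A model gene with several human orthologs fans out to all of them
  (counted).
* Phenotype ids are rewritten to cluster primary ids before output, so no
  record references a class outside the merged ontology.
* Output row: Entrez, human symbol, `label (ID)`, then the source — for
  model records `symbol (id/TAG)` with tags ZEBRAF and MOUSE, for human
  records the comma-joined evidence set (`OMIM`, `OMIM,Orphanet`).

## Synthetic fixtures

The generator emulates the *shape* of the real inputs — mirrored toy
anatomy trees bridged by Uberon xrefs, a toy quality hierarchy,
cross-product files, post-composed zebrafish lines, orthology and disease
tables — at desk scale (defaults: 6 anatomy classes per species, 4
qualities, depth 3, 3 phenotype classes per ontology, 3 genes per
species, full bridging). Random phenotype classes draw *distinct*
(quality, canonical-entity) pairs from a shared pool, so without the
hand-built cases no two generated classes are equivalent and class counts
are exactly predictable; labels carry an ontology tag so lexical alignment
never fires on them.

The hand-built cases wire the ids and labels of the published worked
examples (hypoglycemia/aldohexose; hypoplastic eye / posterior
microphthalmia / bilateral microphthalmos with genes in all three
species; the gall-bladder alt_id merge), with one synthetic quality
(`posteriorly hypoplastic` ⊑ *hypoplastic*) standing in for the unstated
axioms that make *posterior microphthalmia* a strict subclass — the
fixture encodes axioms sufficient for the published inferences, it does
not claim to reconstruct the original definition files. The seeded id-map
pins ZP:0003395 and ZP:0004170 to their published definitions; ZP
numbering is otherwise not reconstructable.

What the fixtures do **not** emulate: real-scale ontologies (tens of
thousands of classes), noisy or dangling cross-references, obsolete-term
churn, multi-entity relational qualities in ZFIN exports, the full
Orphanet XML schema, and version drift between ontology releases.
Passing tests therefore demonstrate correctness of the construction logic
and its invariants, not agreement with any dated release's class and
annotation counts — those depend on external database versions and are
out of scope by design.

## Numerical/engineering notes

* All randomness is a single `random.Random(seed)`; same seed, same bytes.
* The OBO writer sorts stanzas by id and tags in a canonical order;
  document equality is content-based (whitespace- and order-insensitive),
  making parse∘write∘parse = parse a stable fixed point (tested over
  hundreds of randomized documents, and cross-checked against an
  independent OBO parser on ids, names and `is_a` edges).
* Closure queries are memoized per equivalence-class representative;
  graph algorithms (reachability, SCC, transitive reduction) delegate to
  networkx, while the EQ subsumption logic itself is implemented here.
* Degenerate inputs: an empty pheno.txt yields a build with zero ZP
  classes; malformed TSV lines and rejected cross-product stanzas are
  counted in the machine-readable run report (`report.json`,
  `skipped.tsv`) rather than aborting; a missing input file fails fast,
  naming the config key.

## Known limitations

* No OWL-DL features beyond the EQ fragment: no role chains, negation,
  cardinality, or unsatisfiability detection.
* GO definition equivalences are used only to enrich the GO hierarchy,
  not to rewrite phenotype bearers into anatomical space.
* Lexical alignment is exact-match only; curated mapping ingestion is not
  implemented.
* Orthology maps are consumed, never inferred.
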