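# crosspheno

A builder for a single cross-species phenotype ontology covering human,
mouse and zebrafish, together with a table annotating human genes with
phenotype classes from all three species.

## The problem

Human genes with Mendelian phenotype annotations are outnumbered several
times over by human genes whose only phenotype evidence lives in a mouse or
zebrafish ortholog. That evidence is curated against species-specific
vocabularies — the Human Phenotype Ontology (HPO), the Mammalian Phenotype
Ontology (MPO), and ZFIN's on-the-fly ("post-composed") Entity–Quality
annotations — so it cannot be queried as one body of knowledge. This
package rebuilds the construction pipeline that fuses them: it reads the
ontologies' *logical definitions*, reasons them into a single subsumption
hierarchy, merges equivalent classes across species, and propagates
model-organism gene annotations to human genes over orthology. It is aimed
at computational phenomics work — semantic-similarity, gene-prioritization
and enrichment analyses that need one ontology and one annotation table.

## The model

Every phenotype class is logically defined in the Entity–Quality (EQ)
scheme as a class expression

```
C  ≡  has_part some (Q  ⊓  inheres_in some E  ⊓  towards some T  ⊓  qualifier some abnormal)
```

where Q is a PATO quality (e.g. *hypoplastic*), E a bearer entity (an
anatomical structure or GO process), and T an optional second entity such
as a ChEBI chemical. Because every phenotype class shares the `has_part`
wrapper, subsumption in this fragment reduces to componentwise entailment:
`A ⊑ B` iff `Q_A ⊑ Q_B`, each slot present on B is matched by the
corresponding slot on A under the building-block closure, and absent slots
on B are vacuously entailed. The package ships a structural reasoner that
decides exactly this fragment, checked test-by-test against brute-force
oracles.

The pipeline has four stages:

1. **Bridging.** Uberon cross-references mint equivalence axioms onto the
   species anatomy ontologies (ZFA, MA, FMA), skipping Uberon's
   `upper_level` generalities; exact-label lexical matching aligns HP and
   MP classes; `occurs_in`-style relations in GO cross-products are
   normalized to `inheres_in`.
2. **ZP synthesis.** Each unique abnormal (quality, entity) pair in the
   zebrafish post-composed annotation table becomes a pre-composed class in
   the ZP id space, labeled `abnormal(ly) <quality> <entity>`, with a
   persisted id-map keeping numbering stable across releases.
3. **Classification and merging.** All phenotype classes are classified
   over the merged building-block closure; clusters of mutually-subsuming
   classes collapse to a single class (HPO id primary when present, the
   rest stored as `alt_id`), the hierarchy is transitively reduced, and
   only phenotype classes are exported to `crossSpeciesPheno.obo`.
4. **Annotation transfer.** Human genes gain annotations from OMIM/Orphanet
   disease joins and from MPO/ZP annotations carried over MGI and ZFIN
   orthology, written to `HSgenes_crossSpeciesPhenoAnnotation.txt`.

## Worked example

No downloads are needed: the fixture generator emits a complete synthetic
input set, including the hand-built worked-example cases.

```python
import tempfile
from pathlib import Path
from crosspheno import FixtureSpec, generate_fixture, run_pipeline

work = Path(tempfile.mkdtemp())
config = generate_fixture(FixtureSpec(seed=1), work / "inputs")
result = run_pipeline(config, out_dir=work / "build")

print(f"phenotype classes exported: {len(result.clusters)}")
print(f"ZP classes minted:          {len(result.zp_classes)}")
print(f"annotation records:         {len(result.annotations)}")

gall = next(c for c in result.clusters if c.primary_id == "HP:0005609")
print(f"merged cluster:             {gall.primary_id} ({gall.label}) "
      f"alt_id {sorted(gall.alt_ids)}")

for record in result.annotations_for("HP:0007633"):
    print(record.human_gene_entrez, record.human_gene_symbol,
          record.pheno_class, record.source_species)
```

prints

```
phenotype classes exported: 21
ZP classes minted:          5
annotation records:         13
merged cluster:             HP:0005609 (Gallbladder dysfunction) alt_id ['ZP:0004170']
6949 TCOF1 HP:0007633 human
83439 TCF7L1 ZP:0003395 zebrafish
167681 PRSS56 MP:9000001 mouse
```

The merged-cluster line shows the cross-species collapse: the zebrafish
class *abnormal(ly) decreased functionality gall bladder* (ZP:0004170) is
inferred equivalent to the human *Gallbladder dysfunction* class and
survives only as an `alt_id`. The final query asks for every gene linked
to *Bilateral microphthalmos* (HP:0007633): the human gene comes from a
disease join, while the zebrafish and mouse genes arrive because their
phenotype classes — *abnormal(ly) hypoplastic eye* (ZP:0003395) and
*posterior microphthalmia* — are **inferred** subclasses of the queried
human term, and orthology carries their annotations to human gene ids.
The corresponding row of the annotation table reads

```
83439	TCF7L1	abnormal(ly) hypoplastic eye (ZP:0003395)	tcf7l1a (ZDB-GENE-980605-30/ZEBRAF)
```

The same run is available from the shell:

```sh
crosspheno fixture --out inputs --seed 1
crosspheno run --config inputs/config.yaml --out build
```

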