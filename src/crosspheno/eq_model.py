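"""Entity-Quality logical definitions and their class-expression semantics.

A phenotype class is logically defined as a PATO quality differentiated by
a bearer entity (``inheres_in``), optionally a ``towards`` entity (e.g. a
ChEBI chemical) and the ``abnormal`` qualifier (PATO:0000460).  Every
definition is implicitly wrapped in ``has_part some (...)``; since all
phenotype classes share the wrapper it cancels in pairwise subsumption and
is never materialized.

Definitions are parsed from cross-product OBO files ("xp files") whose
stanzas carry ``intersection_of`` tags: one bare genus (the quality) plus
(relation, filler) pairs.  Relations like ``occurs_in`` that are declared
subproperties of ``inheres_in`` are normalized so their filler acts as the
bearer for reasoning.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

from .obo_io import OboDocument, TermStanza
from .reports import BuildReport

PATO_ABNORMAL = "PATO:0000460"

REL_INHERES_IN = "inheres_in"
REL_TOWARDS = "towards"
REL_QUALIFIER = "qualifier"


@dataclass(frozen=True)
class RelationKind:
    """A differentia relation and the relation it normalizes to (if any)."""

    name: str
    normalizes_to: str | None = None


class RelationMap:
    """Resolves a relation name along its ``normalizes_to`` chain.

    The chain must be acyclic and terminate at ``inheres_in`` or at a
    self-fixed point; unknown relations resolve to themselves.
    """

    def __init__(self, kinds=()):
        self._next = {k.name: k.normalizes_to for k in kinds}
        for name in self._next:
            self.resolve(name)  # validates acyclicity eagerly

    def resolve(self, name: str) -> str:
        seen = []
        while True:
            nxt = self._next.get(name)
            if nxt is None or nxt == name:
                return name
            if name in seen:
                raise ValueError(f"cyclic relation normalization at {name!r}")
            seen.append(name)
            name = nxt


#: occurs_in (GO process definitions) and its kin are inheres_in-like, as the
#: extra-equivalences typedef file declared them.
DEFAULT_RELATION_MAP = RelationMap([
    RelationKind(REL_INHERES_IN),
    RelationKind(REL_TOWARDS),
    RelationKind(REL_QUALIFIER),
    RelationKind("occurs_in", REL_INHERES_IN),
    RelationKind("results_in_morphogenesis_of", REL_INHERES_IN),
    RelationKind("results_in_development_of", REL_INHERES_IN),
    RelationKind("inheres_in_part_of", REL_INHERES_IN),
])


@dataclass(frozen=True)
class EQDefinition:
    """The (quality, bearer, towards, qualifier, extras) tuple for one class."""

    defined_class: str
    quality: str
    bearer: str | None = None
    towards: str | None = None
    qualifier: str | None = None
    extra_entities: tuple[tuple[str, str], ...] = ()

    def content_key(self) -> str:
        """Canonical definition-content string (ignores the defined class).

        Used for deduplication and as the persistent key in ZP id-map files.
        """
        parts = [self.quality, self.bearer or "", self.towards or "",
                 self.qualifier or ""]
        parts.extend(f"{r}={c}" for r, c in sorted(self.extra_entities))
        return "|".join(parts)

    def referenced_classes(self) -> set[str]:
        out = {self.quality}
        for c in (self.bearer, self.towards, self.qualifier):
            if c is not None:
                out.add(c)
        out.update(c for _, c in self.extra_entities)
        return out


def _clean_relation(rel: str) -> str:
    """Strip namespace adornments from a relation name.

    Cross-product files inconsistently write ``OBO_REL:inheres_in`` or
    ``inheres_in``; when the local part of a prefixed name is a word (not a
    numeric opaque id like RO:0000052) the prefix is dropped.
    """
    if ":" in rel:
        prefix, local = rel.rsplit(":", 1)
        if local and not local.isdigit():
            return local
    return rel


def parse_xp_file(doc: OboDocument, report: BuildReport | None = None) -> list[EQDefinition]:
    """Extract one :class:`EQDefinition` per stanza carrying ``intersection_of``.

    Stanzas without logical definitions are skipped and counted; a stanza
    with zero or more than one genus entry, or fewer than two entries in
    total, is rejected with a report entry.  Duplicate definitions for the
    same class keep the first and report the rest.
    """
    report = report if report is not None else BuildReport()
    defs: list[EQDefinition] = []
    seen: set[str] = set()
    for st in doc.stanzas:
        if not st.intersection_of:
            report.count("xp.skipped_undefined")
            continue
        genus = st.genus_entries()
        if len(genus) != 1:
            report.skip("xp.rejected", st.id or "?",
                        f"{len(genus)} genus entries in intersection_of")
            continue
        if len(st.intersection_of) < 2:
            report.skip("xp.rejected", st.id or "?",
                        "intersection_of with fewer than 2 entries")
            continue
        if st.id in seen:
            report.skip("xp.rejected", st.id, "duplicate definition; first kept")
            continue
        bearer = towards = qualifier = None
        extras: list[tuple[str, str]] = []
        for rel, filler in st.differentia_entries():
            rel = _clean_relation(rel)
            if rel == REL_INHERES_IN and bearer is None:
                bearer = filler
            elif rel == REL_TOWARDS and towards is None:
                towards = filler
            elif rel == REL_QUALIFIER and qualifier is None:
                qualifier = filler
            else:
                extras.append((rel, filler))
        seen.add(st.id)
        defs.append(EQDefinition(
            defined_class=st.id,
            quality=genus[0],
            bearer=bearer,
            towards=towards,
            qualifier=qualifier,
            extra_entities=tuple(sorted(extras)),
        ))
    return defs


def definition_to_stanza(defn: EQDefinition, label: str | None = None) -> TermStanza:
    """Serialize a definition back to an ``intersection_of`` stanza."""
    entries: list[tuple[str, str]] = [("", defn.quality)]
    if defn.bearer is not None:
        entries.append((REL_INHERES_IN, defn.bearer))
    if defn.towards is not None:
        entries.append((REL_TOWARDS, defn.towards))
    if defn.qualifier is not None:
        entries.append((REL_QUALIFIER, defn.qualifier))
    entries.extend(defn.extra_entities)
    return TermStanza(id=defn.defined_class, name=label, intersection_of=entries)


def normalize_definitions(defs, relmap: RelationMap = DEFAULT_RELATION_MAP,
                          report: BuildReport | None = None) -> list[EQDefinition]:
    """Qualifier and relation normalization; idempotent.

    Definitions lacking the ``abnormal`` qualifier get PATO:0000460 added
    for consistency.  Extra differentiae whose relation chain ends at
    ``inheres_in`` have their filler promoted to the bearer slot when it is
    empty, otherwise they stay as extra ``inheres_in`` entries (reported,
    first bearer wins).
    """
    report = report if report is not None else BuildReport()
    out: list[EQDefinition] = []
    for d in defs:
        qualifier = d.qualifier
        if qualifier is None:
            qualifier = PATO_ABNORMAL
            report.count("normalize.qualifier_added")
        elif qualifier != PATO_ABNORMAL:
            report.skip_once("normalize.nonstandard_qualifier", d.defined_class,
                             f"qualifier {qualifier} kept (not {PATO_ABNORMAL})")
        bearer = d.bearer
        extras: list[tuple[str, str]] = []
        for rel, filler in d.extra_entities:
            resolved = relmap.resolve(rel)
            if resolved == REL_INHERES_IN:
                if bearer is None:
                    bearer = filler
                elif filler == bearer:
                    continue  # redundant restatement of the bearer
                else:
                    report.skip_once("normalize.conflicting_bearer", d.defined_class,
                                     f"extra bearer {filler}; first bearer {bearer} wins")
                    extras.append((REL_INHERES_IN, filler))
            else:
                extras.append((resolved, filler))
        out.append(replace(d, qualifier=qualifier, bearer=bearer,
                           extra_entities=tuple(sorted(extras))))
    return out
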