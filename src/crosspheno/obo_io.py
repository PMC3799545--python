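"""Reader and writer for the OBO flat-file dialect used throughout the build.

The dialect is the OBO 1.2-style tag set as shipped by ontology releases and
by cross-product ("logical definition") files: ``[Term]`` stanzas carrying
``id``, ``name``, ``alt_id``, ``subset``, ``xref``, ``is_a``,
``relationship``, ``synonym``, ``intersection_of`` and ``is_obsolete`` tags.
Unknown tags are preserved verbatim but carry no semantics here, and CURIEs
are treated as opaque ``PREFIX:LOCAL`` strings — no IRI expansion ever
happens.  Non-``[Term]`` stanzas (``[Typedef]`` etc.) are recorded verbatim
and written back untouched.

The writer is deterministic: stanzas are sorted by id and tags emitted in a
fixed canonical order, so equal documents serialize to byte-identical text.
Document equality is content-based (whitespace- and order-insensitive),
which is what makes the parse/write round trip a stable fixed point.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "OboParseError",
    "TermStanza",
    "OboDocument",
    "parse_obo",
    "write_obo",
    "read_obo_file",
    "write_obo_file",
]

DEFAULT_FORMAT_VERSION = "1.2"

_SYNONYM_RE = re.compile(r'^"(?P<text>.*)"\s*(?P<scope>[A-Z_]*)')


class OboParseError(ValueError):
    """Malformed OBO input: duplicate ids, bad tag lines, id-less stanzas."""


def _strip_comment(value: str) -> str:
    # a trailing comment starts at the first unescaped "!"
    out = []
    prev = ""
    for ch in value:
        if ch == "!" and prev != "\\":
            break
        out.append(ch)
        prev = ch
    return "".join(out).strip()


@dataclass
class TermStanza:
    """One ``[Term]`` stanza.

    ``intersection_of`` entries are ``(relation, CURIE)`` pairs where the
    genus (bare CURIE) entry uses an empty-string relation.
    """

    id: str | None = None
    name: str | None = None
    is_a: list[str] = field(default_factory=list)
    relationships: list[tuple[str, str]] = field(default_factory=list)
    alt_ids: list[str] = field(default_factory=list)
    xrefs: list[str] = field(default_factory=list)
    subsets: list[str] = field(default_factory=list)
    intersection_of: list[tuple[str, str]] = field(default_factory=list)
    synonyms: list[tuple[str, str]] = field(default_factory=list)
    is_obsolete: bool = False
    other_tags: list[tuple[str, str]] = field(default_factory=list)

    def genus_entries(self) -> list[str]:
        return [c for r, c in self.intersection_of if r == ""]

    def differentia_entries(self) -> list[tuple[str, str]]:
        return [(r, c) for r, c in self.intersection_of if r != ""]

    def canonical(self) -> tuple:
        return (
            self.id,
            self.name,
            tuple(sorted(self.is_a)),
            tuple(sorted(self.relationships)),
            tuple(sorted(self.alt_ids)),
            tuple(sorted(self.xrefs)),
            tuple(sorted(self.subsets)),
            tuple(sorted(self.intersection_of)),
            tuple(sorted(self.synonyms)),
            self.is_obsolete,
            tuple(sorted(self.other_tags)),
        )

    def __eq__(self, other):
        if not isinstance(other, TermStanza):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self):
        return hash(self.canonical())


@dataclass
class OboDocument:
    header: list[tuple[str, str]] = field(default_factory=list)
    stanzas: list[TermStanza] = field(default_factory=list)
    raw_stanzas: list[tuple[str, ...]] = field(default_factory=list)

    def term(self, curie: str) -> TermStanza:
        for st in self.stanzas:
            if st.id == curie:
                return st
        raise KeyError(curie)

    def term_ids(self) -> list[str]:
        return [st.id for st in self.stanzas]

    def canonical(self) -> tuple:
        hdr = list(self.header)
        if not any(k == "format-version" for k, _ in hdr):
            hdr.append(("format-version", DEFAULT_FORMAT_VERSION))
        return (
            tuple(sorted(hdr)),
            tuple(sorted((st.canonical() for st in self.stanzas))),
            tuple(sorted(self.raw_stanzas)),
        )

    def __eq__(self, other):
        if not isinstance(other, OboDocument):
            return NotImplemented
        return self.canonical() == other.canonical()

    def __hash__(self):
        return hash(self.canonical())


def _require_value(value: str, tag: str, lineno: int) -> str:
    if not value:
        raise OboParseError(f"line {lineno}: empty value for tag {tag!r}")
    return value


def parse_obo(text) -> OboDocument:
    """Parse OBO text (a string or a readable stream) into an :class:`OboDocument`.

    Trailing ``!``-comments are stripped; tag order within a stanza is not
    significant.  A duplicate term id is a hard error naming the id; a line
    that is neither blank, a stanza header nor a ``tag: value`` pair is an
    error naming the line number.  Obsolete terms have their ``is_a`` lines
    dropped (they carry no hierarchy semantics).
    """
    if hasattr(text, "read"):
        text = text.read()
    doc = OboDocument()
    seen_ids: set[str] = set()
    mode = "header"  # header | term | raw
    cur: TermStanza | None = None
    cur_raw: list[str] | None = None

    def finish(lineno: int) -> None:
        nonlocal cur, cur_raw
        if cur is not None:
            if cur.id is None:
                raise OboParseError(f"stanza ending near line {lineno} has no id")
            if cur.id in seen_ids:
                raise OboParseError(f"duplicate term id: {cur.id}")
            seen_ids.add(cur.id)
            if cur.is_obsolete:
                cur.is_a = []
            doc.stanzas.append(cur)
            cur = None
        if cur_raw is not None:
            doc.raw_stanzas.append(tuple(cur_raw))
            cur_raw = None

    lineno = 0
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if line.startswith("[") and line.endswith("]"):
            finish(lineno)
            if line == "[Term]":
                mode = "term"
                cur = TermStanza()
            else:
                mode = "raw"
                cur_raw = [line]
            continue
        if not line or line.startswith("!"):
            continue
        if mode == "raw":
            cur_raw.append(line)
            continue
        tag, sep, value = line.partition(":")
        if not sep or not tag.strip():
            raise OboParseError(f"line {lineno}: malformed tag line: {line!r}")
        tag = tag.strip()
        value = _strip_comment(value)
        if mode == "header":
            doc.header.append((tag, value))
            continue

        if tag == "id":
            cur.id = _require_value(value, tag, lineno).split()[0]
        elif tag == "name":
            cur.name = value
        elif tag in ("is_a", "alt_id", "xref", "subset"):
            token = _require_value(value, tag, lineno).split()[0]
            {"is_a": cur.is_a, "alt_id": cur.alt_ids,
             "xref": cur.xrefs, "subset": cur.subsets}[tag].append(token)
        elif tag == "relationship":
            parts = value.split()
            if len(parts) < 2:
                raise OboParseError(f"line {lineno}: malformed relationship: {line!r}")
            cur.relationships.append((parts[0], parts[1]))
        elif tag == "intersection_of":
            parts = value.split()
            if len(parts) == 1:
                cur.intersection_of.append(("", parts[0]))
            elif len(parts) == 2:
                cur.intersection_of.append((parts[0], parts[1]))
            else:
                raise OboParseError(f"line {lineno}: malformed intersection_of: {line!r}")
        elif tag == "synonym":
            m = _SYNONYM_RE.match(value)
            if not m:
                raise OboParseError(f"line {lineno}: malformed synonym: {line!r}")
            cur.synonyms.append((m.group("text"), m.group("scope") or "RELATED"))
        elif tag == "is_obsolete":
            cur.is_obsolete = value.lower() == "true"
        else:
            cur.other_tags.append((tag, value))
    finish(lineno + 1)
    return doc


def write_obo(doc: OboDocument) -> str:
    """Serialize a document deterministically.

    Stanzas are sorted by id; tags are written in canonical order
    (id, name, alt_id, subset, xref, is_a, relationship, intersection_of,
    synonym, is_obsolete, then preserved unknown tags).  Equal documents
    produce byte-identical output.
    """
    out: list[str] = []
    header = list(doc.header)
    if not any(k == "format-version" for k, _ in header):
        header.insert(0, ("format-version", DEFAULT_FORMAT_VERSION))
    fv = [kv for kv in header if kv[0] == "format-version"][:1]
    rest = sorted(kv for kv in header if kv[0] != "format-version")
    for k, v in fv + rest:
        out.append(f"{k}: {v}".rstrip())

    for st in sorted(doc.stanzas, key=lambda s: (s.id is None, s.id or "")):
        if st.id is None:
            raise ValueError("cannot write a stanza lacking an id")
        out.append("")
        out.append("[Term]")
        out.append(f"id: {st.id}")
        if st.name is not None:
            out.append(f"name: {st.name}")
        for a in sorted(st.alt_ids):
            out.append(f"alt_id: {a}")
        for s in sorted(st.subsets):
            out.append(f"subset: {s}")
        for x in sorted(st.xrefs):
            out.append(f"xref: {x}")
        for p in sorted(st.is_a):
            out.append(f"is_a: {p}")
        for r, c in sorted(st.relationships):
            out.append(f"relationship: {r} {c}")
        for c in sorted(st.genus_entries()):
            out.append(f"intersection_of: {c}")
        for r, c in sorted(st.differentia_entries()):
            out.append(f"intersection_of: {r} {c}")
        for text, scope in sorted(st.synonyms):
            out.append(f'synonym: "{text}" {scope} []')
        if st.is_obsolete:
            out.append("is_obsolete: true")
        for t, v in sorted(st.other_tags):
            out.append(f"{t}: {v}".rstrip())

    for raw in sorted(doc.raw_stanzas):
        out.append("")
        out.extend(raw)
    return "\n".join(out) + "\n"


def read_obo_file(path) -> OboDocument:
    return parse_obo(Path(path).read_text())


def write_obo_file(doc: OboDocument, path) -> None:
    Path(path).write_text(write_obo(doc))
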