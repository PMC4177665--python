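"""Data model and readers/writers for multi-resource synonym compendia.

A *compendium* is a key-value map from concepts (or headwords) to the terms
annotated for them, where every concept-term record carries a presence
bit-vector over the D contributing resources — its multi-list capture
history.  Two modes are supported:

``undirected_concepts``
    Biomedical style: each concept has exactly one preferred term; the
    remaining terms are its synonyms.

``directed_headwords``
    General-thesaurus style: the concept key is a headword and each record
    is a directed headword->synonym pair; a pair and its inverse are
    distinct records.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal

Mode = Literal["undirected_concepts", "directed_headwords"]

_NATIVE_HEADER = "#resources"
_MODE_HEADER = "#mode"


class CompendiumFormatError(ValueError):
    """Raised when a compendium file violates the format contract."""


def _norm(text: str) -> str:
    """NFC-normalize and strip outer whitespace; case is preserved."""
    out = unicodedata.normalize("NFC", text).strip()
    if any(unicodedata.category(ch).startswith("C") for ch in out):
        raise ValueError(f"control characters are not allowed in {out!r}")
    return out


@dataclass(frozen=True)
class ResourceSet:
    """Ordered, unique identifiers of the D resources being intersected."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) < 1:
            raise ValueError("at least one resource is required")
        if any(not n for n in self.names):
            raise ValueError("resource names must be non-empty")
        if len(set(self.names)) != len(self.names):
            raise ValueError("resource names must be unique")

    @property
    def d(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class TermRecord:
    """One concept-term record with its presence bit-vector."""

    term: str
    presence: tuple[int, ...]
    is_preferred: bool = False

    def __post_init__(self) -> None:
        self.term = _norm(self.term)
        self.presence = tuple(int(b) for b in self.presence)
        if not self.term:
            raise ValueError("term is empty after whitespace normalization")
        if any(b not in (0, 1) for b in self.presence):
            raise ValueError("presence vector must be binary")
        if not any(self.presence):
            raise ValueError(f"term {self.term!r} has an all-zero presence vector")


@dataclass
class ConceptEntry:
    concept_id: str
    terms: list[TermRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.concept_id = _norm(self.concept_id)
        if not self.concept_id:
            raise ValueError("concept_id must be non-empty")


@dataclass
class Compendium:
    resources: ResourceSet
    entries: dict[str, ConceptEntry] = field(default_factory=dict)
    mode: Mode = "undirected_concepts"

    @property
    def n_concepts(self) -> int:
        return len(self.entries)

    @property
    def n_terms(self) -> int:
        return sum(len(e.terms) for e in self.entries.values())

    def iter_records(self) -> Iterable[tuple[str, TermRecord]]:
        for cid in self.entries:
            for rec in self.entries[cid].terms:
                yield cid, rec

    def add_record(self, concept_id: str, record: TermRecord, *, merge: bool = False) -> None:
        """Insert one record, enforcing the no-duplicate-(concept, term) rule.

        With ``merge=True`` a duplicate pair is merged by OR-ing the presence
        vectors (and OR-ing the preferred flag) instead of raising.
        """
        concept_id = _norm(concept_id)
        if len(record.presence) != self.resources.d:
            raise CompendiumFormatError(
                f"presence vector length {len(record.presence)} != D={self.resources.d}"
            )
        entry = self.entries.setdefault(concept_id, ConceptEntry(concept_id))
        for existing in entry.terms:
            if existing.term == record.term:
                if not merge:
                    raise CompendiumFormatError(
                        f"duplicate (concept, term) pair ({concept_id!r}, {record.term!r})"
                    )
                existing.presence = tuple(
                    a | b for a, b in zip(existing.presence, record.presence)
                )
                existing.is_preferred = existing.is_preferred or record.is_preferred
                return
        entry.terms.append(record)

    def validate(self) -> None:
        d = self.resources.d
        for cid, entry in self.entries.items():
            if not entry.terms:
                raise ValueError(f"concept {cid!r} has no terms")
            terms = [t.term for t in entry.terms]
            if len(set(terms)) != len(terms):
                raise ValueError(f"duplicate terms under concept {cid!r}")
            for rec in entry.terms:
                if len(rec.presence) != d:
                    raise ValueError(
                        f"presence length mismatch for ({cid!r}, {rec.term!r})"
                    )
            if self.mode == "undirected_concepts":
                n_pref = sum(t.is_preferred for t in entry.terms)
                if n_pref != 1:
                    raise ValueError(
                        f"concept {cid!r} has {n_pref} preferred terms (expected exactly 1)"
                    )


# ---------------------------------------------------------------------------
# Readers / writers
#
# Native dialect (UTF-8 TSV, one row per concept-term record):
#   #resources<TAB>name_1<TAB>...<TAB>name_D
#   #mode<TAB>undirected_concepts            (optional; default shown)
#   concept<TAB>term<TAB>bitstring<TAB>preferred_flag
#
# "sfile" dialect (one line per headword, whitespace-tokenized):
#   name_1 name_2 ... name_D
#   headword syn_1 bits_1 syn_2 bits_2 ...
# ---------------------------------------------------------------------------


def read_compendium(
    path: str | Path,
    dialect: str = "auto",
    *,
    merge_duplicates: bool = False,
) -> Compendium:
    """Read a compendium file, sniffing the dialect when asked to.

    The detected dialect is recorded on the returned object as
    ``compendium.dialect`` so that auto-detection is never silent.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    # split on newlines only: terms may contain characters that
    # str.splitlines would treat as line breaks
    lines = [ln.rstrip("\r") for ln in text.split("\n") if ln.strip()]
    if not lines:
        raise CompendiumFormatError(f"{path}: empty file")
    if dialect == "auto":
        dialect = "native" if lines[0].startswith(_NATIVE_HEADER) else "sfile"
    if dialect == "native":
        comp = _read_native(lines, path, merge_duplicates)
    elif dialect == "sfile":
        comp = _read_sfile(lines, path, merge_duplicates)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    comp.validate()
    comp.dialect = dialect  # type: ignore[attr-defined]
    return comp


def _parse_bits(token: str, d: int, path: Path, lineno: int) -> tuple[int, ...]:
    if len(token) != d or set(token) - {"0", "1"}:
        raise CompendiumFormatError(
            f"{path}:{lineno}: bit-vector {token!r} is not a {d}-bit binary string"
        )
    return tuple(int(ch) for ch in token)


def _read_native(lines: list[str], path: Path, merge: bool) -> Compendium:
    header = lines[0].split("\t")
    if header[0] != _NATIVE_HEADER or len(header) < 2:
        raise CompendiumFormatError(f"{path}:1: malformed '#resources' header")
    resources = ResourceSet(tuple(header[1:]))
    mode: Mode = "undirected_concepts"
    body_start = 1
    if len(lines) > 1 and lines[1].startswith(_MODE_HEADER):
        mode_val = lines[1].split("\t")[1]
        if mode_val not in ("undirected_concepts", "directed_headwords"):
            raise CompendiumFormatError(f"{path}:2: unknown mode {mode_val!r}")
        mode = mode_val  # type: ignore[assignment]
        body_start = 2
    comp = Compendium(resources, mode=mode)
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        fields = line.split("\t")
        if len(fields) != 4:
            raise CompendiumFormatError(
                f"{path}:{lineno}: expected 4 tab-separated fields, got {len(fields)}"
            )
        concept, term, bits, pref = fields
        presence = _parse_bits(bits, resources.d, path, lineno)
        comp.add_record(
            concept,
            TermRecord(term, presence, is_preferred=pref == "1"),
            merge=merge,
        )
    return comp


def _read_sfile(lines: list[str], path: Path, merge: bool) -> Compendium:
    resources = ResourceSet(tuple(lines[0].split()))
    d = resources.d
    comp = Compendium(resources, mode="directed_headwords")
    for lineno, line in enumerate(lines[1:], start=2):
        tokens = line.split()
        if len(tokens) < 3 or len(tokens) % 2 == 0:
            raise CompendiumFormatError(
                f"{path}:{lineno}: expected 'headword (synonym bits)+', "
                f"got {len(tokens)} tokens"
            )
        headword = tokens[0]
        for syn, bits in zip(tokens[1::2], tokens[2::2]):
            presence = _parse_bits(bits, d, path, lineno)
            comp.add_record(headword, TermRecord(syn, presence), merge=merge)
    return comp


def write_compendium(compendium: Compendium, path: str | Path) -> None:
    """Serialize in the native TSV dialect; read(write(x)) == x."""
    compendium.validate()
    path = Path(path)
    out: list[str] = ["\t".join([_NATIVE_HEADER, *compendium.resources.names])]
    out.append(f"{_MODE_HEADER}\t{compendium.mode}")
    for cid, rec in compendium.iter_records():
        bits = "".join(str(b) for b in rec.presence)
        out.append(f"{cid}\t{rec.term}\t{bits}\t{1 if rec.is_preferred else 0}")
    path.write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass
class SummaryStats:
    n_concepts: int
    n_terms: int
    n_synonym_pairs: int
    mean_synonyms_per_concept: float
    per_resource_concepts: dict[str, int]
    per_resource_terms: dict[str, int]
    synonyms_per_concept_hist: dict[int, int]

    def to_json(self) -> str:
        payload = dict(self.__dict__)
        payload["synonyms_per_concept_hist"] = {
            str(k): v for k, v in sorted(self.synonyms_per_concept_hist.items())
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def summarize(compendium: Compendium) -> SummaryStats:
    """Basic coverage statistics.

    In ``undirected_concepts`` mode a concept with t terms carries t - 1
    synonyms (one term is preferred); in ``directed_headwords`` mode every
    record already is a headword->synonym pair.
    """
    compendium.validate()
    biomedical = compendium.mode == "undirected_concepts"
    names = compendium.resources.names
    per_res_concepts = dict.fromkeys(names, 0)
    per_res_terms = dict.fromkeys(names, 0)
    hist: dict[int, int] = {}
    n_pairs = 0
    for entry in compendium.entries.values():
        syn = len(entry.terms) - 1 if biomedical else len(entry.terms)
        n_pairs += syn
        hist[syn] = hist.get(syn, 0) + 1
        seen = [False] * compendium.resources.d
        for rec in entry.terms:
            for d, bit in enumerate(rec.presence):
                if bit:
                    per_res_terms[names[d]] += 1
                    seen[d] = True
        for d, flag in enumerate(seen):
            if flag:
                per_res_concepts[names[d]] += 1
    n_concepts = compendium.n_concepts
    mean = n_pairs / n_concepts if n_concepts else 0.0
    return SummaryStats(
        n_concepts=n_concepts,
        n_terms=compendium.n_terms,
        n_synonym_pairs=n_pairs,
        mean_synonyms_per_concept=mean,
        per_resource_concepts=per_res_concepts,
        per_resource_terms=per_res_terms,
        synonyms_per_concept_hist=hist,
    )


def directionalize(
    compendium: Compendium,
    bidirectional_resources: tuple[str, ...] = (),
) -> Compendium:
    """Recast a compendium as directed headword->synonym records.

    Each input record contributes itself; inverses are *not* fabricated —
    a pair documented only as (A, B) yields exactly one directed record,
    and its inverse counts as a distinct (possibly undocumented) entity.
    Resources listed in ``bidirectional_resources`` (e.g. a WordNet-style
    thesaurus that documents synonymy symmetrically) additionally have the
    inverse of each of their pairs materialized with only that resource's
    bit set.
    """
    res = compendium.resources
    bidir = [res.index(name) for name in bidirectional_resources]
    out = Compendium(res, mode="directed_headwords")
    for cid, rec in compendium.iter_records():
        out.add_record(
            cid, TermRecord(rec.term, rec.presence, is_preferred=rec.is_preferred),
            merge=True,
        )
    for cid, rec in compendium.iter_records():
        inv_bits = [0] * res.d
        for d in bidir:
            if rec.presence[d]:
                inv_bits[d] = 1
        if any(inv_bits):
            out.add_record(rec.term, TermRecord(cid, tuple(inv_bits)), merge=True)
    out.validate()
    return out


Normalizer = Callable[[str], str | None]
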