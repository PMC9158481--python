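"""GTDB-style taxonomy tables and rank-prefixed lineage strings.

A lineage is the ordered seven-rank chain domain → phylum → class →
order → family → genus → species, written with GTDB rank prefixes::

    d__Archaea;p__Halobacteriota;c__Methanomicrobia;o__Methanomicrobiales;
    f__Methanoregulaceae;g__Methanoregula;s__Methanoregula sp003170075

Taxonomy tables are the two-column tab-separated layout GTDB publishes
(accession TAB lineage), one table per domain.  Reading is
gzip-transparent.  Placeholder ranks (``s__`` with nothing after the
prefix) are rejected: the downstream icicle needs seven named layers.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from typing import IO, Iterable

from .errors import LineageFormatError, TaxonomyFormatError
from .matching import normalize_accession

__all__ = [
    "RANKS",
    "Lineage",
    "TaxonomyTable",
    "parse_lineage",
    "serialize_lineage",
    "load_taxonomy",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


@dataclass(frozen=True)
class Lineage:
    """Seven-rank taxonomic path for one accession.

    The field for the class rank is named ``clazz`` to avoid the
    reserved word; it is still serialized with the ``c__`` prefix.
    Species names carry their genus name as a prefix (binomial
    nomenclature), which is enforced at parse time.
    """

    domain: str
    phylum: str
    clazz: str
    order: str
    family: str
    genus: str
    species: str

    def names(self) -> tuple[str, ...]:
        """Rank names in depth order, domain (0) through species (6)."""
        return (
            self.domain,
            self.phylum,
            self.clazz,
            self.order,
            self.family,
            self.genus,
            self.species,
        )


def parse_lineage(text: str) -> Lineage:
    """Parse a rank-prefixed lineage string into a :class:`Lineage`.

    Raises :class:`LineageFormatError` naming the offending field when
    the field count, prefix order, or a name is wrong.
    """
    fields = [f.strip() for f in text.split(";")]
    if len(fields) != 7:
        raise LineageFormatError(
            f"expected 7 ';'-separated rank fields, got {len(fields)}: {text!r}"
        )
    names: list[str] = []
    for i, (field_text, prefix, rank) in enumerate(zip(fields, _PREFIXES, RANKS)):
        if not field_text.startswith(prefix):
            raise LineageFormatError(
                f"field {i + 1} ({rank}) must start with {prefix!r}: {field_text!r}"
            )
        name = field_text[len(prefix):].strip()
        if not name:
            raise LineageFormatError(
                f"field {i + 1} ({rank}) is empty after its prefix: {field_text!r}"
            )
        names.append(name)
    genus, species = names[5], names[6]
    if not (species == genus or species.startswith(genus + " ")):
        raise LineageFormatError(
            f"species name {species!r} does not begin with its genus {genus!r}"
        )
    return Lineage(*names)


def serialize_lineage(lineage: Lineage) -> str:
    """Inverse of :func:`parse_lineage`."""
    return ";".join(p + n for p, n in zip(_PREFIXES, lineage.names()))


class TaxonomyTable:
    """Mapping of normalized accession → :class:`Lineage` for one domain."""

    def __init__(self, domain_name: str, entries: dict[str, Lineage]):
        for accession, lineage in entries.items():
            if lineage.domain != domain_name:
                raise TaxonomyFormatError(
                    f"entry {accession!r} has domain {lineage.domain!r}, "
                    f"table is for {domain_name!r}"
                )
        self.domain_name = domain_name
        self.entries = dict(entries)

    @property
    def m(self) -> int:
        """Number of entries (the selected-domain array size)."""
        return len(self.entries)

    def get(self, normalized_accession: str) -> Lineage | None:
        return self.entries.get(normalized_accession)

    def __contains__(self, normalized_accession: str) -> bool:
        return normalized_accession in self.entries

    def __len__(self) -> int:
        return self.m


def _open_lines(source: str | IO[str] | IO[bytes] | Iterable[str]):
    """Yield text lines from a path, text/binary stream, or line iterable."""
    if isinstance(source, str):
        with open(source, "rb") as fh:
            magic = fh.read(2)
        opener = gzip.open if magic == b"\x1f\x8b" else open
        with opener(source, "rt", encoding="utf-8") as fh:  # type: ignore[call-overload]
            yield from fh
        return
    if isinstance(source, io.TextIOBase):
        yield from source
        return
    first = getattr(source, "read", None)
    if first is not None and "b" in getattr(source, "mode", ""):
        yield from io.TextIOWrapper(source, encoding="utf-8")  # type: ignore[arg-type]
        return
    yield from source  # an iterable of lines


def sniff_domain(path: str) -> str:
    """Read the domain name from the first data line of a taxonomy TSV."""
    for line in _open_lines(path):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise TaxonomyFormatError(
                "line 1: expected 'accession<TAB>lineage' while sniffing the domain"
            )
        return parse_lineage(parts[1]).domain
    raise TaxonomyFormatError(f"taxonomy file {path!r} contains no entries")


def load_taxonomy(source: str | IO[str] | Iterable[str], domain_name: str) -> TaxonomyTable:
    """Load a GTDB-style taxonomy TSV for one domain.

    Each line is ``accession<TAB>lineage``.  Accession keys are
    normalized (``GB_``/``RS_`` prefixes stripped, spaces → underscores)
    and must be unique; every lineage must belong to ``domain_name``.
    Errors carry 1-based line numbers.
    """
    entries: dict[str, Lineage] = {}
    originals: dict[str, str] = {}
    for lineno, line in enumerate(_open_lines(source), start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise TaxonomyFormatError(
                f"line {lineno}: expected 'accession<TAB>lineage', "
                f"got {len(parts)} tab-separated fields"
            )
        raw_accession, lineage_text = parts
        key = normalize_accession(raw_accession.strip())
        if not key:
            raise TaxonomyFormatError(f"line {lineno}: empty accession")
        if key in entries:
            raise TaxonomyFormatError(
                f"line {lineno}: duplicate accession {raw_accession.strip()!r} "
                f"(normalizes to {key!r}, first seen as {originals[key]!r})"
            )
        try:
            lineage = parse_lineage(lineage_text)
        except LineageFormatError as exc:
            raise TaxonomyFormatError(f"line {lineno}: {exc}") from exc
        if lineage.domain != domain_name:
            raise TaxonomyFormatError(
                f"line {lineno}: domain {lineage.domain!r} does not match "
                f"table domain {domain_name!r}"
            )
        entries[key] = lineage
        originals[key] = raw_accession.strip()
    return TaxonomyTable(domain_name, entries)
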