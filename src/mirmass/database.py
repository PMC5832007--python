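"""Parsing, validation and indexing of the miRNA database and modification table.

The database format is the mature-miRNA FASTA dialect used by miRBase: each
header is ``>name accession free-text description`` and each body is an RNA
sequence over A/C/G/U (miRBase writes U; T is accepted and mapped).  The
modification table is tab-separated in the MODOMICS spirit: short code, full
name, parent base, and a signed elemental delta formula.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .mass_model import (
    AtomicMassTable,
    ElementalComposition,
    FormulaError,
    MassOptions,
    TerminalChemistry,
    mass_of_composition,
    oligo_mass,
)

__all__ = [
    "MiRNARecord",
    "Modification",
    "MiRNADatabase",
    "SequenceError",
    "DatabaseError",
    "validate_sequence",
    "parse_mature_fasta",
    "parse_modifications",
    "default_modifications",
    "annotate_masses",
    "write_mature_fasta",
]

# Mature miRNAs are typically 16-28 nt; lengths outside are flagged, not rejected.
TYPICAL_LENGTH_RANGE = (16, 28)

_CANONICAL = frozenset("ACGU")


class SequenceError(ValueError):
    """Raised for a sequence containing a non-canonical character."""


class DatabaseError(ValueError):
    """Raised for malformed database input (headers, duplicates, bad rows)."""


def validate_sequence(raw: str) -> str:
    """Canonicalize a user-entered RNA sequence.

    Whitespace is ignored, case folded to upper, T mapped to U, and common
    terminal decorations stripped: a leading ``5'``/``5′`` marker and/or a
    leading ``p`` (fragments are often written ``pUUGCAUAGUC``), a trailing
    ``3'``/``3′`` marker and/or ``-OH``.  Any residual non-A/C/G/U character
    is rejected with its position.
    """
    s = "".join(raw.split())
    # terminal decorations, stripped before case folding ('p' vs base letters)
    for prefix in ("5′", "5'"):
        if s.startswith(prefix):
            s = s[len(prefix):]
    if s[:1] in ("p", "P"):
        s = s[1:]
    for suffix in ("3′", "3'"):
        if s.endswith(suffix):
            s = s[: -len(suffix)]
    if s.upper().endswith("-OH"):
        s = s[:-3]
    s = s.upper().replace("T", "U")
    for i, ch in enumerate(s):
        if ch not in _CANONICAL:
            raise SequenceError(
                f"illegal character {ch!r} at position {i + 1} in sequence"
            )
    return s


@dataclass(frozen=True)
class MiRNARecord:
    """One mature miRNA: name, accession, canonical sequence."""

    name: str
    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise SequenceError(f"record {self.name!r} has an empty sequence")
        bad = set(self.sequence) - _CANONICAL
        if bad:
            raise SequenceError(
                f"record {self.name!r} contains non-canonical characters {sorted(bad)}"
            )
        lo, hi = TYPICAL_LENGTH_RANGE
        if not lo <= len(self.sequence) <= hi:
            warnings.warn(
                f"record {self.name!r} is {len(self.sequence)} nt, outside the "
                f"typical mature-miRNA range {lo}-{hi}",
                stacklevel=2,
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Modification:
    """One nucleotide modification as an elemental delta against its parent base.

    ``delta`` may be all-zero: pseudouridine is an isomerization of uridine and
    is mass-silent.  The stored delta masses are always recomputed from the
    delta composition.
    """

    code: str
    name: str
    parent_base: str
    delta: ElementalComposition
    delta_monoisotopic: float = field(init=False)
    delta_average: float = field(init=False)

    def __post_init__(self):
        if self.parent_base not in ("A", "C", "G", "U", "any"):
            raise DatabaseError(
                f"modification {self.code!r}: parent base must be A/C/G/U/any"
            )
        object.__setattr__(
            self, "delta_monoisotopic", mass_of_composition(self.delta, "monoisotopic")
        )
        object.__setattr__(
            self, "delta_average", mass_of_composition(self.delta, "average")
        )

    def delta_mass(self, mass_kind: str) -> float:
        if mass_kind == "monoisotopic":
            return self.delta_monoisotopic
        if mass_kind == "average":
            return self.delta_average
        raise ValueError(f"unknown mass kind {mass_kind!r}")

    def is_mass_silent(self) -> bool:
        return len(self.delta) == 0


def _cache_key(options: MassOptions) -> tuple:
    return (
        options.mass_kind,
        options.ion_mode,
        options.termini.five_prime,
        options.termini.three_prime,
    )


class MiRNADatabase:
    """Ordered collection of miRNA records with name/accession/sequence indexes.

    Names and accessions are unique; distinct names may share a sequence
    (sequence lookups return every carrier).  Ion masses under a given option
    set are cached on first use and always equal on-the-fly recomputation.
    """

    def __init__(self, records: Iterable[MiRNARecord] = (),
                 table: AtomicMassTable | None = None):
        self._records: list[MiRNARecord] = []
        self._by_name: dict[str, int] = {}
        self._by_accession: dict[str, int] = {}
        self._by_sequence: dict[str, list[int]] = {}
        self._mass_cache: dict[tuple, list[float]] = {}
        self._table = table
        for rec in records:
            self.add(rec)

    def add(self, rec: MiRNARecord) -> None:
        key = rec.name.lower()
        if key in self._by_name:
            raise DatabaseError(f"duplicate miRNA name {rec.name!r}")
        akey = rec.accession.lower()
        if akey in self._by_accession:
            raise DatabaseError(f"duplicate accession {rec.accession!r}")
        idx = len(self._records)
        self._records.append(rec)
        self._by_name[key] = idx
        self._by_accession[akey] = idx
        self._by_sequence.setdefault(rec.sequence, []).append(idx)
        self._mass_cache.clear()

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[MiRNARecord]:
        return iter(self._records)

    def __getitem__(self, idx: int) -> MiRNARecord:
        return self._records[idx]

    @property
    def records(self) -> Sequence[MiRNARecord]:
        return tuple(self._records)

    def get_by_name(self, name: str) -> MiRNARecord | None:
        idx = self._by_name.get(name.strip().lower())
        return None if idx is None else self._records[idx]

    def get_by_accession(self, accession: str) -> MiRNARecord | None:
        idx = self._by_accession.get(accession.strip().lower())
        return None if idx is None else self._records[idx]

    def get_by_sequence(self, sequence: str) -> list[MiRNARecord]:
        seq = validate_sequence(sequence)
        return [self._records[i] for i in self._by_sequence.get(seq, [])]

    def masses(self, options: MassOptions) -> list[float]:
        """Ionized mass of every record under ``options`` (cached)."""
        key = _cache_key(options)
        cached = self._mass_cache.get(key)
        if cached is None:
            cached = [
                oligo_mass(r.sequence, options, self._table) for r in self._records
            ]
            self._mass_cache[key] = cached
        return cached

    def mass_of(self, rec: MiRNARecord, options: MassOptions) -> float:
        return oligo_mass(rec.sequence, options, self._table)

    # ------------------------------------------------------------------ dumps

    def to_fasta(self) -> str:
        return write_mature_fasta(self)

    def to_tsv(self, options: MassOptions | None = None) -> str:
        """TSV dump of records; adds a mass column when options are given."""
        header = ["name", "accession", "sequence", "length"]
        masses = None
        if options is not None:
            header.append(f"{options.ion_mode}_{options.mass_kind}_mass")
            masses = self.masses(options)
        lines = ["\t".join(header)]
        for i, rec in enumerate(self._records):
            row = [rec.name, rec.accession, rec.sequence, str(rec.length)]
            if masses is not None:
                row.append(f"{masses[i]:.4f}")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    def to_json(self, options: MassOptions | None = None) -> str:
        masses = self.masses(options) if options is not None else None
        out = []
        for i, rec in enumerate(self._records):
            item = {
                "name": rec.name,
                "accession": rec.accession,
                "sequence": rec.sequence,
                "length": rec.length,
            }
            if masses is not None:
                item["mass"] = round(masses[i], 4)
            out.append(item)
        return json.dumps(out, indent=1)


def parse_mature_fasta(
    stream, species_prefix: str | None = "hsa-"
) -> MiRNADatabase:
    """Parse a mature-miRNA FASTA stream into a database.

    Headers are whitespace-split: field 1 is the miRNA name, field 2 the
    accession, the rest free description.  Records whose name does not start
    with ``species_prefix`` are dropped (pass ``None`` to keep everything).
    Multi-line bodies are concatenated; header errors carry the line number.
    """
    if isinstance(stream, (str, bytes)):
        raise TypeError("pass a text stream or path-opened file, not a string")
    lines = stream.read().splitlines()
    header_lineno = [i + 1 for i, ln in enumerate(lines) if ln.startswith(">")]
    db = MiRNADatabase()
    handle = io.StringIO("\n".join(lines))
    for rec_idx, (title, seq) in enumerate(SimpleFastaParser(handle)):
        lineno = header_lineno[rec_idx]
        fields = title.split()
        if len(fields) < 2:
            raise DatabaseError(
                f"line {lineno}: header {title!r} lacks an accession token"
            )
        name, accession = fields[0], fields[1]
        description = " ".join(fields[2:])
        if species_prefix is not None and not name.startswith(species_prefix):
            continue
        try:
            canonical = validate_sequence(seq)
        except SequenceError as exc:
            raise DatabaseError(f"line {lineno}: record {name!r}: {exc}") from exc
        db.add(MiRNARecord(name, accession, canonical, description))
    return db


def write_mature_fasta(db: MiRNADatabase) -> str:
    """Serialize a database back to the mature-FASTA dialect (round-trippable)."""
    chunks = []
    for rec in db:
        desc = f" {rec.description}" if rec.description else ""
        chunks.append(f">{rec.name} {rec.accession}{desc}\n{rec.sequence}\n")
    return "".join(chunks)


def parse_modifications(stream) -> list[Modification]:
    """Parse a tab-separated modification table.

    Columns: short code, full name, parent base, signed delta formula
    (``+CH2``, ``-H-N+O``, ``+0`` for mass-silent).  ``#`` comments and blank
    lines are skipped; a bad row is rejected with its line number.
    """
    mods = []
    seen = set()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise DatabaseError(
                f"line {lineno}: expected 4 tab-separated fields, got {len(parts)}"
            )
        code, name, parent, formula = (p.strip() for p in parts)
        if code in seen:
            raise DatabaseError(f"line {lineno}: duplicate modification code {code!r}")
        try:
            delta = ElementalComposition.parse(formula)
        except FormulaError as exc:
            raise DatabaseError(f"line {lineno}: {exc}") from exc
        try:
            mod = Modification(code, name, parent, delta)
        except KeyError as exc:
            raise DatabaseError(f"line {lineno}: {exc}") from exc
        seen.add(code)
        mods.append(mod)
    return mods


def default_modifications() -> list[Modification]:
    """The packaged curated table of common RNA modifications."""
    text = resources.files("mirmass.data").joinpath("modifications.tsv").read_text()
    return parse_modifications(io.StringIO(text))


def annotate_masses(db: MiRNADatabase, options: MassOptions) -> MiRNADatabase:
    """Precompute (and cache) every record's ionized mass under ``options``.

    Idempotent; returns the same database for chaining.
    """
    db.masses(options)
    return db
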