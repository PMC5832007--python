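"""Mass search, identifier lookup, modified-mass calculation and fragment search.

These are the operations a mass-spectrometrist runs against the miRNA
database: match an observed m/z to unmodified miRNAs within a ± Da window,
match it allowing exactly one nucleotide modification, retrieve a record by
name/accession/sequence, forward-compute the expected mass of a modified
miRNA, and align a sequence fragment against every record with coverage
reporting.  Queries are compared in ionized-mass space (the user enters an
observed m/z); all matching uses a symmetric absolute tolerance in Daltons.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from fractions import Fraction
from math import floor
from typing import Iterable, Sequence

from .database import (
    MiRNADatabase,
    MiRNARecord,
    Modification,
    validate_sequence,
)
from .mass_model import MassOptions

__all__ = [
    "MassMatch",
    "LookupHit",
    "ModifiedMassResult",
    "FragmentHit",
    "BatchReport",
    "search_by_mass",
    "search_modified",
    "lookup",
    "modified_mass",
    "fragment_search",
    "coverage_percent",
    "read_peak_list",
    "batch_search",
]


@dataclass(frozen=True)
class MassMatch:
    """One search hit: record, its computed ion mass, signed error, modification.

    ``modification`` is None exactly when the hit came from the unmodified
    search; ``mass_error`` is computed minus query.
    """

    record: MiRNARecord
    computed_mass: float
    mass_error: float
    modification: Modification | None = None

    def sort_key(self) -> tuple:
        mod_code = self.modification.code if self.modification else ""
        return (abs(self.mass_error), self.record.name, mod_code)


@dataclass(frozen=True)
class LookupHit:
    """A record retrieved by identifier, with its mass under current options."""

    record: MiRNARecord
    mass: float


@dataclass(frozen=True)
class ModifiedMassResult:
    """Forward-computed expected mass of a singly modified miRNA."""

    record: MiRNARecord
    unmodified_mass: float
    modification: Modification
    modified_mass: float


@dataclass(frozen=True)
class FragmentHit:
    """One exact-substring alignment of a fragment against a miRNA."""

    record: MiRNARecord
    start_positions: tuple[int, ...]
    coverage: float  # percent, one truncated decimal


@dataclass(frozen=True)
class BatchReport:
    """Per-peak search results for a peak list, plus summary counts."""

    results: tuple[tuple[float, tuple[MassMatch, ...]], ...]
    errors: tuple[tuple[int, str], ...]  # (line number, offending text)

    @property
    def n_matched(self) -> int:
        return sum(1 for _, hits in self.results if hits)

    @property
    def n_unmatched(self) -> int:
        return sum(1 for _, hits in self.results if not hits)


def _sorted_mass_index(db: MiRNADatabase, options: MassOptions):
    masses = db.masses(options)
    order = sorted(range(len(masses)), key=lambda i: masses[i])
    return [masses[i] for i in order], order


def search_by_mass(
    db: MiRNADatabase, query_mass: float, options: MassOptions = MassOptions()
) -> list[MassMatch]:
    """All unmodified records whose ion mass lies in [query - tol, query + tol].

    Sorted by absolute mass error, ties broken by name.
    """
    if query_mass <= 0:
        raise ValueError("query mass must be positive")
    tol = options.tolerance_da
    sorted_masses, order = _sorted_mass_index(db, options)
    lo = bisect_left(sorted_masses, query_mass - tol)
    hi = bisect_right(sorted_masses, query_mass + tol)
    hits = [
        MassMatch(db[order[k]], sorted_masses[k], sorted_masses[k] - query_mass)
        for k in range(lo, hi)
    ]
    hits.sort(key=MassMatch.sort_key)
    return hits


def search_modified(
    db: MiRNADatabase,
    mods: Sequence[Modification],
    query_mass: float,
    options: MassOptions = MassOptions(),
    base_aware: bool = False,
) -> list[MassMatch]:
    """All (record, modification) pairs with |mass + delta - query| <= tol.

    Exactly one modification per miRNA is considered.  With ``base_aware``,
    pairs whose parent base does not occur in the sequence are excluded
    (parent ``any`` always qualifies); by default every modification is tried
    against every record.
    """
    if query_mass <= 0:
        raise ValueError("query mass must be positive")
    if not mods:
        raise ValueError("modification list is empty")
    tol = options.tolerance_da
    sorted_masses, order = _sorted_mass_index(db, options)
    hits: list[MassMatch] = []
    for mod in mods:
        delta = mod.delta_mass(options.mass_kind)
        target = query_mass - delta
        lo = bisect_left(sorted_masses, target - tol)
        hi = bisect_right(sorted_masses, target + tol)
        for k in range(lo, hi):
            rec = db[order[k]]
            if base_aware and mod.parent_base != "any" \
                    and mod.parent_base not in rec.sequence:
                continue
            computed = sorted_masses[k] + delta
            hits.append(MassMatch(rec, computed, computed - query_mass, mod))
    hits.sort(key=MassMatch.sort_key)
    return hits


def lookup(
    db: MiRNADatabase,
    field: str,
    value: str,
    options: MassOptions = MassOptions(),
) -> list[LookupHit]:
    """Exact retrieval by ``name``, ``accession`` or ``sequence``.

    Name/accession match case-insensitively; sequence values are canonicalized
    first.  No match is not an error: the result is simply empty.
    """
    if not value or not value.strip():
        raise ValueError("lookup value must be non-empty")
    if field == "name":
        rec = db.get_by_name(value)
        found = [rec] if rec else []
    elif field == "accession":
        rec = db.get_by_accession(value)
        found = [rec] if rec else []
    elif field == "sequence":
        found = db.get_by_sequence(value)
    else:
        raise ValueError(f"unknown lookup field {field!r}")
    return [LookupHit(r, db.mass_of(r, options)) for r in found]


def modified_mass(
    db: MiRNADatabase,
    name: str,
    modification_code: str,
    mods: Sequence[Modification],
    options: MassOptions = MassOptions(),
) -> ModifiedMassResult:
    """Expected ion mass of ``name`` carrying one copy of the modification."""
    rec = db.get_by_name(name)
    if rec is None:
        raise KeyError(f"miRNA {name!r} not found in the database")
    by_code = {m.code: m for m in mods}
    mod = by_code.get(modification_code)
    if mod is None:
        raise KeyError(f"unknown modification code {modification_code!r}")
    unmod = db.mass_of(rec, options)
    return ModifiedMassResult(rec, unmod, mod, unmod + mod.delta_mass(options.mass_kind))


def coverage_percent(fragment_length: int, mirna_length: int) -> float:
    """Fragment length as a percent of the miRNA length, truncated to 1 decimal.

    Truncation (not rounding) is the reporting convention: 8/22 -> 36.3.
    Computed in exact rational arithmetic to avoid float edge cases.
    """
    if not 1 <= fragment_length <= mirna_length:
        raise ValueError(
            f"need 1 <= fragment length <= miRNA length, "
            f"got {fragment_length}/{mirna_length}"
        )
    return floor(Fraction(1000 * fragment_length, mirna_length)) / 10


def fragment_search(db: MiRNADatabase, fragment: str) -> list[FragmentHit]:
    """Exact-substring alignment of a fragment against every record.

    Forward strand only, no mismatches.  Hits carry every 0-based start
    position and the sequence coverage percent; sorted by coverage descending,
    then name.
    """
    frag = validate_sequence(fragment)
    if not frag:
        raise ValueError("fragment is empty after normalization")
    hits = []
    for rec in db:
        positions = []
        start = rec.sequence.find(frag)
        while start != -1:
            positions.append(start)
            start = rec.sequence.find(frag, start + 1)
        if positions:
            hits.append(
                FragmentHit(rec, tuple(positions),
                            coverage_percent(len(frag), rec.length))
            )
    hits.sort(key=lambda h: (-h.coverage, h.record.name))
    return hits


def read_peak_list(stream) -> tuple[list[float], list[tuple[int, str]]]:
    """Parse a plain-text peak list: one m/z per line, ``#`` comments allowed.

    Returns (peaks, errors); a malformed line is reported with its number and
    the remaining lines are still processed.
    """
    peaks: list[float] = []
    errors: list[tuple[int, str]] = []
    for lineno, line in enumerate(stream, start=1):
        text = line.split("#", 1)[0].strip()
        if not text:
            continue
        try:
            value = float(text)
        except ValueError:
            errors.append((lineno, line.rstrip("\n")))
            continue
        if value <= 0:
            errors.append((lineno, line.rstrip("\n")))
            continue
        peaks.append(value)
    return peaks, errors


def batch_search(
    db: MiRNADatabase,
    mods: Sequence[Modification],
    peaks: Iterable[float],
    options: MassOptions = MassOptions(),
    modified: bool = False,
    base_aware: bool = False,
    errors: Sequence[tuple[int, str]] = (),
) -> BatchReport:
    """Map the single-mass search over a peak list.

    Equivalent to running :func:`search_by_mass` (or :func:`search_modified`
    with ``modified=True``) independently on every peak.
    """
    results = []
    for peak in peaks:
        if modified:
            hits = search_modified(db, mods, peak, options, base_aware)
        else:
            hits = search_by_mass(db, peak, options)
        results.append((peak, tuple(hits)))
    return BatchReport(tuple(results), tuple(errors))
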