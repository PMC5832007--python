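"""Elemental-composition and mass arithmetic for RNA oligonucleotides.

The mass model is deliberately small and exact: an oligonucleotide is the sum
of internal-chain residue formulas (nucleoside-5'-monophosphate minus water)
plus one water of condensation, adjusted for the chemistry at each terminus,
and optionally ionized by gaining or losing one hydrogen atom ([M+H]+ /
[M-H]-, the singly charged species dominating MALDI spectra).

Atomic masses and residue formulas are loaded from human-readable TSV files
shipped with the package (see ``mirmass/data/``); users may substitute their
own tables.  Only singly charged ions are modeled — multiply charged spectra
must be deconvoluted upstream.  The electron mass (~0.00055 Da) is neglected
in ionization, as in common oligonucleotide calculators.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

__all__ = [
    "AtomicMassTable",
    "ElementalComposition",
    "TerminalChemistry",
    "MassOptions",
    "MASS_KINDS",
    "ION_MODES",
    "residue_composition",
    "oligo_composition",
    "mass_of_composition",
    "oligo_mass",
    "ionize",
    "WATER",
    "HPO3",
]

MASS_KINDS = ("monoisotopic", "average")
ION_MODES = ("protonated", "deprotonated", "neutral")
TERMINAL_GROUPS = ("phosphate", "hydroxyl")

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
_FORMULA_TOKEN_RE = re.compile(r"([+-]?)((?:[A-Z][a-z]?\d*)+|0)")


class FormulaError(ValueError):
    """Raised for an elemental formula that cannot be parsed."""


class ElementalComposition(Mapping[str, int]):
    """Immutable element -> integer atom count mapping.

    An absolute composition has all counts >= 0; negative counts are allowed
    only when the composition represents a delta (e.g. the ``-H-N+O`` shift of
    adenosine-to-inosine editing).  Supports ``+``, ``-`` and integer ``*``.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean = {}
        for elem, n in (counts or {}).items():
            if n != int(n):
                raise FormulaError(f"non-integer count {n!r} for element {elem}")
            if n != 0:
                clean[str(elem)] = int(n)
        object.__setattr__(self, "_counts", clean)

    def __setattr__(self, name, value):  # immutability guard
        raise AttributeError("ElementalComposition is immutable")

    def __getitem__(self, elem: str) -> int:
        return self._counts.get(elem, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, elem) -> bool:
        return elem in self._counts

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = dict(self._counts)
        for elem, n in other.items():
            counts[elem] = counts.get(elem, 0) + n
        return ElementalComposition(counts)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = dict(self._counts)
        for elem, n in other.items():
            counts[elem] = counts.get(elem, 0) - n
        return ElementalComposition(counts)

    def __mul__(self, k: int) -> "ElementalComposition":
        return ElementalComposition({e: n * k for e, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other) -> bool:
        if isinstance(other, ElementalComposition):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        return f"ElementalComposition({self.formula()!r})"

    def is_absolute(self) -> bool:
        return all(n >= 0 for n in self._counts.values())

    def formula(self) -> str:
        """Hill-ish formula string; negative counts rendered as a signed tail."""
        pos = {e: n for e, n in self._counts.items() if n > 0}
        neg = {e: -n for e, n in self._counts.items() if n < 0}
        if not pos and not neg:
            return "0"

        def block(d: dict) -> str:
            return "".join(
                f"{e}{n if n != 1 else ''}" for e, n in sorted(d.items())
            )

        out = block(pos)
        if neg:
            out += "-" + "-".join(
                f"{e}{n if n != 1 else ''}" for e, n in sorted(neg.items())
            )
        return out

    @classmethod
    def parse(cls, formula: str) -> "ElementalComposition":
        """Parse ``C10H12N5O6P`` or a signed delta like ``+CH2``, ``-H-N+O``, ``+0``.

        Each sign applies to the single element group that follows it; an
        unsigned leading group is positive.  ``+0`` (or ``0``) is the empty,
        mass-silent composition.
        """
        s = formula.strip().replace(" ", "")
        if not s:
            raise FormulaError("empty formula")
        counts: dict[str, int] = {}
        pos = 0
        while pos < len(s):
            m = _FORMULA_TOKEN_RE.match(s, pos)
            if not m:
                raise FormulaError(f"cannot parse formula {formula!r} at {s[pos:]!r}")
            sign = -1 if m.group(1) == "-" else 1
            body = m.group(2)
            if body != "0":
                for em in _ELEMENT_RE.finditer(body):
                    if not em.group(1):
                        continue
                    n = int(em.group(2)) if em.group(2) else 1
                    counts[em.group(1)] = counts.get(em.group(1), 0) + sign * n
            pos = m.end()
        return cls(counts)


WATER = ElementalComposition.parse("H2O")
HPO3 = ElementalComposition.parse("HPO3")
_H_ATOM = ElementalComposition.parse("H")


@dataclass(frozen=True)
class AtomicMassTable:
    """Element -> (monoisotopic, average) masses in Da; immutable after load."""

    masses: Mapping[str, tuple[float, float]]

    def __post_init__(self):
        frozen = {}
        for elem, (mono, avg) in self.masses.items():
            if mono <= 0 or avg <= 0:
                raise ValueError(f"non-positive mass for element {elem}")
            if abs(mono - avg) >= 0.2:
                raise ValueError(
                    f"monoisotopic/average masses of {elem} differ by >= 0.2 Da"
                )
            frozen[elem] = (float(mono), float(avg))
        object.__setattr__(self, "masses", frozen)

    def mass(self, element: str, mass_kind: str) -> float:
        try:
            mono, avg = self.masses[element]
        except KeyError:
            raise KeyError(f"element {element!r} not in atomic mass table") from None
        if mass_kind == "monoisotopic":
            return mono
        if mass_kind == "average":
            return avg
        raise ValueError(f"unknown mass kind {mass_kind!r}")

    def __contains__(self, element: str) -> bool:
        return element in self.masses

    @classmethod
    def from_tsv(cls, stream) -> "AtomicMassTable":
        """Load from TSV lines ``element<TAB>monoisotopic<TAB>average``; '#' comments."""
        masses = {}
        for line in stream:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed atomic-mass row: {line!r}")
            masses[parts[0]] = (float(parts[1]), float(parts[2]))
        return cls(masses)

    @classmethod
    def default(cls) -> "AtomicMassTable":
        return _default_table()


_DEFAULT_TABLE: AtomicMassTable | None = None
_RESIDUES: dict[str, ElementalComposition] | None = None


def _default_table() -> AtomicMassTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        text = resources.files("mirmass.data").joinpath("atomic_masses.tsv").read_text()
        _DEFAULT_TABLE = AtomicMassTable.from_tsv(text.splitlines())
    return _DEFAULT_TABLE


def _residue_table() -> dict[str, ElementalComposition]:
    global _RESIDUES
    if _RESIDUES is None:
        text = resources.files("mirmass.data").joinpath("residues.tsv").read_text()
        table = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            base, formula = line.split("\t")
            table[base] = ElementalComposition.parse(formula)
        _RESIDUES = table
    return _RESIDUES


@dataclass(frozen=True)
class TerminalChemistry:
    """Chemical groups at the oligo ends; each shifts the mass by one HPO3."""

    five_prime: str = "phosphate"
    three_prime: str = "hydroxyl"

    def __post_init__(self):
        for name, value in (("five_prime", self.five_prime),
                            ("three_prime", self.three_prime)):
            if value not in TERMINAL_GROUPS:
                raise ValueError(
                    f"{name} must be one of {TERMINAL_GROUPS}, got {value!r}"
                )


@dataclass(frozen=True)
class MassOptions:
    """Search/calculation options.

    Defaults follow positive-mode MALDI practice: protonated ions, average
    mass, 5'-phosphate / 3'-hydroxyl termini, and a ±0.01 Da match window.
    """

    mass_kind: str = "average"
    ion_mode: str = "protonated"
    termini: TerminalChemistry = field(default_factory=TerminalChemistry)
    tolerance_da: float = 0.01

    def __post_init__(self):
        if self.mass_kind not in MASS_KINDS:
            raise ValueError(f"mass_kind must be one of {MASS_KINDS}")
        if self.ion_mode not in ION_MODES:
            raise ValueError(f"ion_mode must be one of {ION_MODES}")
        if self.tolerance_da < 0:
            raise ValueError("tolerance_da must be >= 0")


def residue_composition(base: str) -> ElementalComposition:
    """Internal-chain residue formula (NMP minus water) for one canonical base."""
    try:
        return _residue_table()[base]
    except KeyError:
        raise ValueError(
            f"unknown RNA base {base!r}; expected one of A, C, G, U"
        ) from None


def oligo_composition(
    sequence: str, termini: TerminalChemistry = TerminalChemistry()
) -> ElementalComposition:
    """Elemental composition of an RNA oligo under the given terminal chemistry.

    The residue sum plus one water yields the 5'-phosphate / 3'-hydroxyl
    molecule; a 5'-hydroxyl removes one HPO3 and a 3'-phosphate adds one.
    """
    if not sequence:
        raise ValueError("empty sequence")
    comp = WATER
    for base in sequence:
        comp = comp + residue_composition(base)
    if termini.five_prime == "hydroxyl":
        comp = comp - HPO3
    if termini.three_prime == "phosphate":
        comp = comp + HPO3
    return comp


def mass_of_composition(
    comp: ElementalComposition,
    mass_kind: str = "average",
    table: AtomicMassTable | None = None,
) -> float:
    """Linear mass of a composition: sum of count(e) * mass(e)."""
    table = table or _default_table()
    total = 0.0
    for elem, n in comp.items():
        if elem not in table:
            raise KeyError(f"element {elem!r} not in atomic mass table")
        total += n * table.mass(elem, mass_kind)
    return total


def ionize(
    neutral_mass: float,
    ion_mode: str = "protonated",
    mass_kind: str = "average",
    table: AtomicMassTable | None = None,
) -> float:
    """Singly charged ion mass: +H atom (protonated), -H atom (deprotonated)."""
    table = table or _default_table()
    if ion_mode == "neutral":
        return neutral_mass
    h = table.mass("H", mass_kind)
    if ion_mode == "protonated":
        return neutral_mass + h
    if ion_mode == "deprotonated":
        return neutral_mass - h
    raise ValueError(f"unknown ion mode {ion_mode!r}")


def oligo_mass(
    sequence: str,
    options: MassOptions = MassOptions(),
    table: AtomicMassTable | None = None,
) -> float:
    """Mass of an RNA oligo under the given options (ionized per ion_mode)."""
    neutral = mass_of_composition(
        oligo_composition(sequence, options.termini), options.mass_kind, table
    )
    return ionize(neutral, options.ion_mode, options.mass_kind, table)
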