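"""Deterministic synthetic miRNA databases and the packaged worked example.

Every operation in the package is testable offline: a seeded generator emits
mature-FASTA databases with known structure (planted records, optional
isobaric sequence pairs, planted modification events), and a small packaged
fixture database ships with the code.  Decoy sequences are uniform over
A/C/G/U — the fixtures provide *structure* for tests, not base-composition
realism.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from random import Random
from typing import Sequence

from .database import MiRNADatabase, parse_mature_fasta
from .mass_model import (
    WATER,
    MassOptions,
    TerminalChemistry,
    ionize,
    mass_of_composition,
    residue_composition,
)

__all__ = ["FixtureSpec", "generate_synthetic_db", "worked_example_db",
           "MIR153_NAME", "MIR153_ACCESSION", "MIR153_SEQUENCE"]

# The worked-example mature miRNA used throughout the documentation and tests.
MIR153_NAME = "hsa-miR-153"
MIR153_ACCESSION = "MIMAT0000439"
MIR153_SEQUENCE = "UUGCAUAGUCACAAAAGUGAUC"

_BASES = "ACGU"


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic database; same spec + seed -> identical bytes.

    ``planted_records`` are emitted verbatim before any random decoys.  With
    ``isobaric_pair`` two distinct permutations of one random sequence are
    planted (identical composition, hence identical mass).
    ``planted_modifications`` names (record name, modification code) pairs for
    forward/inverse round-trip tests; the records must be planted or generated
    members of the database.
    """

    count: int = 25
    length_range: tuple[int, int] = (16, 28)
    seed: int = 0
    planted_records: tuple[tuple[str, str, str], ...] = (
        (MIR153_NAME, MIR153_ACCESSION, MIR153_SEQUENCE),
    )
    isobaric_pair: bool = False
    planted_modifications: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError(f"impossible length range {self.length_range}")
        needed = len(self.planted_records) + (2 if self.isobaric_pair else 0)
        if self.count < needed:
            raise ValueError(
                f"count {self.count} below the {needed} planted records"
            )


def _residue_masses(mass_kind: str) -> dict[str, float]:
    return {b: mass_of_composition(residue_composition(b), mass_kind)
            for b in _BASES}


def _chain_mass(sequence: str, mass_kind: str, ion_mode: str) -> float:
    """Per-residue float summation — a second route to the oligo mass.

    Sums precomputed residue masses one float at a time plus water, instead of
    aggregating an elemental composition first; used for the manifest so the
    manifest and the mass model can check each other.
    """
    per = _residue_masses(mass_kind)
    total = sum(per[b] for b in sequence) + mass_of_composition(WATER, mass_kind)
    return ionize(total, ion_mode, mass_kind)


def generate_synthetic_db(spec: FixtureSpec) -> tuple[str, str]:
    """Generate (FASTA text, manifest TSV text) for a synthetic database.

    Decoys are uniform-random sequences in the configured length range with
    sequential synthetic names/accessions.  The manifest lists every record
    with neutral average and monoisotopic masses computed by per-residue
    summation (independent of the composition-aggregation route).
    """
    rng = Random(spec.seed)
    entries: list[tuple[str, str, str]] = list(spec.planted_records)

    if spec.isobaric_pair:
        lo, hi = spec.length_range
        base_seq = "".join(rng.choice(_BASES) for _ in range(rng.randint(max(lo, 2), hi)))
        perm = list(base_seq)
        while "".join(perm) == base_seq:
            rng.shuffle(perm)
        for tag, seq in (("a", base_seq), ("b", "".join(perm))):
            idx = len(entries) + 1
            entries.append(
                (f"hsa-syn-iso-{tag}", f"SYNT{9000000 + idx:07d}", seq)
            )

    i = 0
    while len(entries) < spec.count:
        i += 1
        lo, hi = spec.length_range
        seq = "".join(rng.choice(_BASES) for _ in range(rng.randint(lo, hi)))
        entries.append((f"hsa-syn-miR-{i:03d}", f"SYNT{i:07d}", seq))

    fasta = "".join(
        f">{name} {acc} synthetic fixture record\n{seq}\n"
        for name, acc, seq in entries
    )

    planted_mods = {name: code for name, code in spec.planted_modifications}
    rows = ["# synthetic database manifest (masses are neutral, per-residue summation)",
            "name\taccession\tsequence\tlength\tneutral_average\t"
            "neutral_monoisotopic\tplanted_modification"]
    for name, acc, seq in entries:
        rows.append(
            "\t".join([
                name, acc, seq, str(len(seq)),
                f"{_chain_mass(seq, 'average', 'neutral'):.6f}",
                f"{_chain_mass(seq, 'monoisotopic', 'neutral'):.6f}",
                planted_mods.get(name, "-"),
            ])
        )
    return fasta, "\n".join(rows) + "\n"


def synthetic_database(spec: FixtureSpec) -> MiRNADatabase:
    """Generate and parse a synthetic database in one step."""
    fasta, _ = generate_synthetic_db(spec)
    return parse_mature_fasta(io.StringIO(fasta), species_prefix="hsa-")


def worked_example_db() -> MiRNADatabase:
    """The packaged 25-record fixture database.

    Contains hsa-miR-153 plus 24 synthetic decoys, two of which share the
    9-mer prefix UUGCAUAGU (but not the 10-mer UUGCAUAGUC), so fragment-search
    discrimination between unique and ambiguous partial sequences is
    exercisable without downloading a full mature-miRNA release.
    """
    text = resources.files("mirmass.data").joinpath("worked_example.fa").read_text()
    return parse_mature_fasta(io.StringIO(text), species_prefix="hsa-")
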