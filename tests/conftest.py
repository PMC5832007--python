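import io
import random

import pytest

from mirmass import (
    MiRNADatabase,
    MiRNARecord,
    default_modifications,
    worked_example_db,
)

# Ribonucleoside molecular formulas, written down independently of the
# package's residue table: the bookkeeping oracle builds chain compositions
# as nucleoside + HPO3 - H2O per residue.
NUCLEOSIDES = {
    "A": {"C": 10, "H": 13, "N": 5, "O": 4},
    "G": {"C": 10, "H": 13, "N": 5, "O": 5},
    "C": {"C": 9, "H": 13, "N": 3, "O": 5},
    "U": {"C": 9, "H": 12, "N": 2, "O": 6},
}


def oracle_composition(sequence, five_prime="phosphate", three_prime="hydroxyl"):
    """Atom-count bookkeeping oracle for the 5'P/3'OH oligo and variants."""
    counts = {}

    def add(formula, k=1):
        for elem, n in formula.items():
            counts[elem] = counts.get(elem, 0) + k * n

    for base in sequence:
        add(NUCLEOSIDES[base])
        add({"H": 1, "P": 1, "O": 3})        # phosphodiester phosphate
        add({"H": 2, "O": 1}, k=-1)          # condensation water
    add({"H": 2, "O": 1})                    # terminal water back
    if five_prime == "hydroxyl":
        add({"H": 1, "P": 1, "O": 3}, k=-1)
    if three_prime == "phosphate":
        add({"H": 1, "P": 1, "O": 3})
    return {e: n for e, n in counts.items() if n}


def random_sequence(rng: random.Random, lo=16, hi=28) -> str:
    return "".join(rng.choice("ACGU") for _ in range(rng.randint(lo, hi)))


def make_random_db(rng: random.Random, n=50) -> MiRNADatabase:
    return MiRNADatabase(
        MiRNARecord(f"hsa-rnd-{i:03d}", f"RAND{i:07d}", random_sequence(rng))
        for i in range(n)
    )


@pytest.fixture(scope="session")
def fixture_db() -> MiRNADatabase:
    return worked_example_db()


@pytest.fixture(scope="session")
def mods():
    return default_modifications()


@pytest.fixture()
def tiny_fasta() -> io.StringIO:
    return io.StringIO(
        ">hsa-miR-153 MIMAT0000439 Homo sapiens miR-153\n"
        "UUGCAUAGUCACAAAAGUGAUC\n"
        ">hsa-let-7a-5p MIMAT0000062 Homo sapiens let-7a-5p\n"
        "UGAGGUAGUAGGUUGUAUAGUU\n"
        ">mmu-miR-1a-3p MIMAT0000123 Mus musculus miR-1a-3p\n"
        "UGGAAUGUAAAGAAGUAUGUAU\n"
    )
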