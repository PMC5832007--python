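"""Search tests: brute-force oracle equivalence, self-recovery across option
combinations, forward/inverse round trips, coverage arithmetic, batch mapping."""

import io
import random

import pytest

from mirmass.database import default_modifications
from mirmass.mass_model import MassOptions, TerminalChemistry, oligo_mass
from mirmass.search import (
    batch_search,
    coverage_percent,
    fragment_search,
    lookup,
    modified_mass,
    read_peak_list,
    search_by_mass,
    search_modified,
)
from conftest import make_random_db, random_sequence

ALL_OPTION_COMBOS = [
    MassOptions(mass_kind=kind, ion_mode=mode,
                termini=TerminalChemistry(fp, tp))
    for kind in ("average", "monoisotopic")
    for mode in ("protonated", "deprotonated", "neutral")
    for fp in ("phosphate", "hydroxyl")
    for tp in ("hydroxyl", "phosphate")
]


def brute_force_unmodified(db, query, options):
    return sorted(
        (rec.name for rec in db
         if abs(oligo_mass(rec.sequence, options) - query) <= options.tolerance_da)
    )


def brute_force_modified(db, mods, query, options, base_aware=False):
    pairs = []
    for rec in db:
        for mod in mods:
            if base_aware and mod.parent_base != "any" \
                    and mod.parent_base not in rec.sequence:
                continue
            total = oligo_mass(rec.sequence, options) + mod.delta_mass(options.mass_kind)
            if abs(total - query) <= options.tolerance_da:
                pairs.append((rec.name, mod.code))
    return sorted(pairs)


class TestSearchByMass:
    @pytest.mark.parametrize("options", ALL_OPTION_COMBOS,
                             ids=lambda o: f"{o.mass_kind}-{o.ion_mode}-"
                                           f"{o.termini.five_prime[0]}{o.termini.three_prime[0]}")
    def test_self_recovery_all_options(self, fixture_db, options):
        """Every record is re-found by its own mass at the default tolerance."""
        for rec in fixture_db:
            hits = search_by_mass(fixture_db, fixture_db.mass_of(rec, options), options)
            assert rec.name in {h.record.name for h in hits}

    def test_equals_brute_force_scan(self):
        rng = random.Random(42)
        db = make_random_db(rng, n=50)
        masses = db.masses(MassOptions())
        for _ in range(100):
            # queries near real masses so windows are non-trivially populated
            query = rng.choice(masses) + rng.uniform(-2, 2)
            tol = rng.choice([0.01, 0.5, 5.0])
            options = MassOptions(tolerance_da=tol)
            hits = search_by_mass(db, query, options)
            assert sorted(h.record.name for h in hits) == \
                brute_force_unmodified(db, query, options)
            for h in hits:
                assert abs(h.mass_error) <= tol
                assert h.modification is None

    def test_sorted_by_abs_error_then_name(self, fixture_db):
        opts = MassOptions(tolerance_da=500.0)
        hits = search_by_mass(fixture_db, 7000.0, opts)
        assert len(hits) > 2
        keys = [(abs(h.mass_error), h.record.name) for h in hits]
        assert keys == sorted(keys)

    def test_tolerance_monotonicity(self, fixture_db):
        query = 7091.27
        previous = set()
        for tol in (0.001, 0.01, 0.1, 1.0, 10.0, 100.0):
            names = {h.record.name for h in search_by_mass(
                fixture_db, query, MassOptions(tolerance_da=tol))}
            assert previous <= names
            previous = names

    def test_nonpositive_query_rejected(self, fixture_db):
        with pytest.raises(ValueError):
            search_by_mass(fixture_db, 0.0)


class TestSearchModified:
    def test_equals_exhaustive_pair_enumeration(self, mods):
        rng = random.Random(7)
        db = make_random_db(rng, n=50)
        ten_mods = mods[:10]
        masses = db.masses(MassOptions())
        for trial in range(100):
            query = rng.choice(masses) + rng.uniform(-20, 20)
            options = MassOptions(tolerance_da=rng.choice([0.01, 1.0, 10.0]))
            base_aware = trial % 2 == 0
            hits = search_modified(db, ten_mods, query, options, base_aware)
            got = sorted((h.record.name, h.modification.code) for h in hits)
            assert got == brute_force_modified(db, ten_mods, query, options, base_aware)

    def test_mass_silent_modification_matches_unmodified_mass(self, fixture_db, mods):
        rec = fixture_db.get_by_name("hsa-miR-153")
        query = fixture_db.mass_of(rec, MassOptions())
        hits = search_modified(fixture_db, mods, query)
        assert ("hsa-miR-153", "Y") in {(h.record.name, h.modification.code)
                                        for h in hits}

    def test_zero_delta_search_superset_of_unmodified(self, fixture_db, mods):
        """With the mass-silent entry present, every unmodified hit reappears."""
        query = fixture_db.mass_of(fixture_db.get_by_name("hsa-miR-153"),
                                   MassOptions())
        unmod = {h.record.name for h in search_by_mass(fixture_db, query)}
        modded = {h.record.name for h in search_modified(fixture_db, mods, query)}
        assert unmod <= modded

    def test_forward_then_inverse(self, fixture_db, mods):
        result = modified_mass(fixture_db, "hsa-miR-153", "m6A", mods)
        hits = search_modified(fixture_db, mods, result.modified_mass,
                               MassOptions(tolerance_da=0.01))
        assert ("hsa-miR-153", "m6A") in {(h.record.name, h.modification.code)
                                          for h in hits}

    def test_base_aware_excludes_absent_parent(self, mods):
        from mirmass.database import MiRNADatabase, MiRNARecord
        db = MiRNADatabase([MiRNARecord("hsa-noa", "MIMAT0000201",
                                        "GGGGCCCCUUUUGGGGC")])  # no adenosine
        m6a = [m for m in mods if m.code == "m6A"]
        query = oligo_mass("GGGGCCCCUUUUGGGGC") + m6a[0].delta_average
        assert search_modified(db, m6a, query, base_aware=False)
        assert not search_modified(db, m6a, query, base_aware=True)


class TestLookup:
    def test_by_name(self, fixture_db):
        (hit,) = lookup(fixture_db, "name", "hsa-miR-153")
        assert hit.record.length == 22
        assert hit.mass == pytest.approx(7091.21, abs=0.01)

    def test_by_accession_and_sequence(self, fixture_db):
        (by_acc,) = lookup(fixture_db, "accession", "MIMAT0000439")
        (by_seq,) = lookup(fixture_db, "sequence", "u ugcAUAGUCACAAAAGUGAUC")
        assert by_acc.record is by_seq.record

    def test_not_found_is_empty_not_error(self, fixture_db):
        assert lookup(fixture_db, "name", "hsa-miR-nonexistent") == []

    def test_empty_value_rejected(self, fixture_db):
        with pytest.raises(ValueError):
            lookup(fixture_db, "name", "   ")


class TestModifiedMassCalc:
    def test_pseudouridine_mass_silent(self, fixture_db, mods):
        res = modified_mass(fixture_db, "hsa-miR-153", "Y", mods)
        assert res.modified_mass == res.unmodified_mass

    def test_m6a_adds_ch2(self, fixture_db, mods):
        res = modified_mass(fixture_db, "hsa-miR-153", "m6A", mods)
        assert res.modified_mass - res.unmodified_mass == pytest.approx(
            14.027, abs=1e-3)

    def test_delta_identity_all_mods_both_kinds(self, fixture_db, mods):
        for kind in ("average", "monoisotopic"):
            opts = MassOptions(mass_kind=kind)
            for mod in mods:
                res = modified_mass(fixture_db, "hsa-miR-153", mod.code, mods, opts)
                assert res.modified_mass - res.unmodified_mass == pytest.approx(
                    mod.delta_mass(kind), abs=1e-9)

    def test_unknown_inputs_rejected(self, fixture_db, mods):
        with pytest.raises(KeyError):
            modified_mass(fixture_db, "hsa-miR-none", "m6A", mods)
        with pytest.raises(KeyError):
            modified_mass(fixture_db, "hsa-miR-153", "zz9", mods)


class TestFragmentSearch:
    def test_decorated_fragment_unique_hit(self, fixture_db):
        hits = fragment_search(fixture_db, "pUUGCAUAGUC")
        assert [(h.record.name, h.start_positions, h.coverage) for h in hits] == [
            ("hsa-miR-153", (0,), 45.4)]

    def test_full_sequence_is_full_coverage(self, fixture_db):
        hits = fragment_search(fixture_db, "UUGCAUAGUCACAAAAGUGAUC")
        assert hits[0].coverage == 100.0

    def test_overlong_fragment_empty(self, fixture_db):
        assert fragment_search(fixture_db, "A" * 32) == []

    def test_equals_naive_scan(self):
        rng = random.Random(3)
        db = make_random_db(rng, n=50)
        for _ in range(100):
            donor = rng.choice(db.records)
            k = rng.randint(1, donor.length)
            start = rng.randint(0, donor.length - k)
            frag = donor.sequence[start:start + k]
            hits = fragment_search(db, frag)
            naive = {
                rec.name: tuple(i for i in range(rec.length - len(frag) + 1)
                                if rec.sequence[i:i + len(frag)] == frag)
                for rec in db
            }
            naive = {n: p for n, p in naive.items() if p}
            assert {h.record.name: h.start_positions for h in hits} == naive
            # sorted by coverage descending, then name
            keys = [(-h.coverage, h.record.name) for h in hits]
            assert keys == sorted(keys)

    def test_coverage_monotone_in_fragment_length(self, fixture_db):
        """Shortening the queried prefix never increases coverage on miR-153."""
        seq = "UUGCAUAGUCACAAAAGUGAUC"
        coverages = []
        for k in range(len(seq), 0, -1):
            hits = fragment_search(fixture_db, seq[:k])
            (cov,) = [h.coverage for h in hits if h.record.name == "hsa-miR-153"]
            coverages.append(cov)
        assert coverages == sorted(coverages, reverse=True)

    def test_empty_fragment_rejected(self, fixture_db):
        with pytest.raises(ValueError):
            fragment_search(fixture_db, "  p ")


class TestCoveragePercent:
    @pytest.mark.parametrize("frag,full,expected", [
        (10, 22, 45.4), (9, 22, 40.9), (8, 22, 36.3), (7, 22, 31.8),
        (6, 22, 27.2), (5, 22, 22.7), (4, 22, 18.1), (3, 22, 13.6),
        (2, 22, 9.0), (1, 22, 4.5), (22, 22, 100.0),
    ])
    def test_truncated_percent(self, frag, full, expected):
        assert coverage_percent(frag, full) == expected

    def test_bounds_rejected(self):
        with pytest.raises(ValueError):
            coverage_percent(0, 22)
        with pytest.raises(ValueError):
            coverage_percent(23, 22)


class TestBatch:
    def test_peak_list_parsing_reports_bad_lines(self):
        stream = io.StringIO(
            "7091.27\n# comment\n\nnot-a-number\n6000.5 # inline\n-4\n")
        peaks, errors = read_peak_list(stream)
        assert peaks == [7091.27, 6000.5]
        assert [ln for ln, _ in errors] == [4, 6]

    def test_equivalent_to_independent_searches(self, mods):
        rng = random.Random(13)
        db = make_random_db(rng, n=30)
        masses = db.masses(MassOptions())
        peaks = [rng.choice(masses) + rng.uniform(-1, 1) for _ in range(20)]
        options = MassOptions(tolerance_da=1.0)
        for modified in (False, True):
            report = batch_search(db, mods, peaks, options, modified=modified)
            assert len(report.results) == 20
            for peak, hits in report.results:
                single = (search_modified(db, mods, peak, options) if modified
                          else search_by_mass(db, peak, options))
                assert list(hits) == single
            assert report.n_matched + report.n_unmatched == 20

    def test_empty_list_empty_report(self, fixture_db, mods):
        report = batch_search(fixture_db, mods, [])
        assert report.results == ()
        assert report.n_matched == report.n_unmatched == 0
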