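# Methods

## The problem

Intact-mass measurement by MALDI mass spectrometry yields predominantly
singly charged ions of mature microRNAs (short 16–28 nt single-stranded
RNAs).  Because the molecular mass of a miRNA is an intrinsic, sequence-determined
property, an observed m/z can identify the molecule directly — provided one
can (a) compute oligonucleotide masses exactly under the chemistry actually
present in the sample, and (b) search a database of known mature miRNAs
within the instrument's mass accuracy.  `mirmass` implements that pipeline as
a library and CLI: mass model, database layer, tolerance-window search
(with and without a single nucleotide modification), identifier lookup,
forward modified-mass prediction, and exact-substring fragment alignment
with coverage reporting.

## Mass model

An RNA oligonucleotide is modeled as a sum of internal-chain residues, each
the nucleoside-5′-monophosphate minus one water:

- A → C10H12N5O6P, G → C10H12N5O7P, C → C9H12N3O7P, U → C9H11N2O8P.

The chain sum plus one water of condensation gives the 5′-phosphate /
3′-hydroxyl molecule; a 5′-hydroxyl subtracts one HPO3 (79.98 Da average)
and a 3′-phosphate adds one.  Ionization adds (protonated, [M+H]+) or
subtracts (deprotonated, [M−H]−) one hydrogen-atom mass of the chosen mass
kind; the electron mass (~0.00055 Da) is neglected, as in common
oligonucleotide calculators, and only singly charged ions are modeled —
multiply charged (e.g. ESI) spectra must be deconvoluted upstream.

Masses come in two kinds: *monoisotopic* (principal-isotope masses) and
*average* (IUPAC standard atomic weights).  Both tables ship as a
human-readable TSV (`mirmass/data/atomic_masses.tsv`) so users can pin or
substitute their own values; the residue formulas live in a second TSV.
All composition arithmetic is exact integer bookkeeping
(`ElementalComposition`); masses are floats computed linearly from the
composition, carried at full precision internally and shown to two decimals
only in text-format CLI output (TSV/JSON reports keep full precision so
they parse back losslessly).

## Defaults and tunable parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `mass_kind` | average | — | intact-mass MALDI work on multi-kDa oligos usually reads the average peak |
| `ion_mode` | protonated | — | positive-mode MALDI is the common acquisition mode for miRNA |
| `termini` | 5′-phosphate / 3′-hydroxyl | — | the biological end chemistry of Dicer-processed mature miRNA |
| `tolerance_da` | 0.01 | Da | a symmetric ±Da window; widen to match the instrument's accuracy |

The tolerance is an absolute ± window in Daltons (not ppm): the matching
predicate is `|computed − query| ≤ tol`, evaluated in ionized-mass space
because the user enters an observed m/z.  Results are sorted by absolute
mass error, then name, then modification code — the ordering is a package
choice fixed for determinism.

## Modification-aware search

The modified search considers **exactly one** modification per miRNA: for
each (record, modification) pair it tests
`|mass(record) + Δ(mod) − query| ≤ tol`.  Modifications are rows of a TSV
table (code, full name, parent base, signed elemental delta such as `+CH2`
or `-H-N+O`); delta masses are always recomputed from the delta
composition.  Pseudouridine has an identically zero delta — it is a
mass-silent isomerization of uridine — so it matches wherever the
unmodified mass matches, which is the correct physical statement.  By
default every modification is paired with every record; the optional
`base_aware` mode excludes pairs whose parent base does not occur in the
sequence (chemical plausibility on demand).  Multi-modification
combinations are out of scope.

The shipped table (`mirmass/data/modifications.tsv`) is a small curated set
of common modifications (methylations, acetylation, thiolation,
dihydrouridine, pseudouridine, A→I editing, isopentenyl and
threonylcarbamoyl adducts).  It is deliberately not a full MODOMICS
snapshot — snapshots drift — and any user table in the same format can be
passed with `--mods`.

## Database layer

Input is the mature-miRNA FASTA dialect used by miRBase: header
`>name accession description`, body over A/C/G/U.  Parsing goes through
Biopython's FASTA reader with header line numbers tracked for error
reporting; records are filtered by species prefix (default `hsa-`).  Names
and accessions must be unique; distinct names may share a sequence (real
releases contain such duplicates) and sequence lookup returns every
carrier.  User-entered sequences are normalized: whitespace ignored, case
folded, T→U, and terminal decorations (`5′`, a leading `p`, `3′`, `-OH`)
stripped, so fragments written in the bench notation `pUUGCAUAGUC` are
accepted verbatim.  Lengths outside 16–28 nt produce a warning, not an
error.  Ion masses per option set are cached on the database and always
equal on-the-fly recomputation.

The package does **not** bundle a full mature-miRNA release (size,
licensing, and version drift); it bundles a 25-record fixture database and
reads any user-supplied `mature.fa`.

## Fragment search and coverage

Fragment alignment is exact substring matching on the forward strand — the
feature aligns sequencing-derived fragments of the miRNA itself, so
mismatches and reverse complements are intentionally excluded.  Hits report
every 0-based start position and the sequence coverage, defined as
`100 · fragment_length / miRNA_length` **truncated** (not rounded) to one
decimal: 8/22 reports 36.3, not 36.4.  Truncation is computed in exact
rational arithmetic (`Fraction`) to avoid float boundary artifacts.

## Synthetic fixtures

The generator (`mirmass.fixtures`) emits seeded, byte-reproducible FASTA
databases: planted records first (by default the 22-nt worked-example miRNA
hsa-miR-153), optionally an isobaric pair (two distinct permutations of one
sequence — identical base multiset, hence identical mass), then
uniform-random decoys in a configurable length range (default 16–28 nt).
A manifest TSV lists every record with neutral masses computed by
per-residue float summation, a second code route that cross-checks the
composition-aggregation route.  Decoys are uniform over bases; no attempt
is made to mimic real base composition, secondary structure, spectral
noise, or intensity — the fixtures provide planted *structure* for tests.
Passing tests therefore demonstrate arithmetic and search correctness, not
performance on real spectra with noise, adducts, or co-eluting species.

The packaged worked-example database (25 records) contains hsa-miR-153 and
24 synthetic decoys, two of which embed the 9-mer UUGCAUAGU but not the
10-mer UUGCAUAGUC, so the transition from a unique 10-mer identification to
an ambiguous 9-mer is exercisable offline.  Absolute hit counts for partial
sequences against a *full* release are release-dependent and are not
asserted anywhere; to check them, point the CLI at your own `mature.fa`:

```
mirmass fragment --seq pUUGCAUAGUC --db mature.fa
```

## Numerical choices and edge cases

- Composition counts are integers; a negative count is legal only in a
  delta (e.g. A→I editing, `-H-N+O`).
- Mass cache vs recomputation agrees to 1e-9 Da by construction (same code
  path); manifest vs mass model to 1e-5 (independent float summation
  order).
- Empty sequences, non-A/C/G/U characters (position-reported), malformed
  headers (line-reported), unknown elements in formulas, and non-positive
  query masses are rejected with specific messages; an *empty search
  result* is not an error (exit 0, "0 matches").
- Malformed peak-list lines are reported with their line number and the
  remaining peaks still processed.

## Known limitations

- No isotope-distribution simulation; no adducts beyond ±H (no Na+/K+);
  no charge states beyond 1.
- No MS/MS (CID) fragment-ion prediction or scoring — tandem-MS
  interpretation is left to dedicated tools.
- Isobaric miRNAs (permutation isomers) are indistinguishable by intact
  mass; the search intentionally returns all of them and leaves
  disambiguation to fragment search or orthogonal experiments.
- The atomic-weight vintage shifts average masses of multi-kDa oligos by a
  few hundredths of a Da relative to other calculators; the shipped table
  is pinned in a data file precisely so this is reproducible.
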