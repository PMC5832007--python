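# mirmass

Identify human microRNAs from mass-spectrometric masses.

Mature miRNAs are 16–28 nt single-stranded RNAs whose molecular mass is an
intrinsic, sequence-determined property: an intact-mass measurement (MALDI
produces predominantly singly charged ions) can identify a miRNA directly,
without tandem MS.  `mirmass` is the scriptable toolkit for that workflow,
aimed at mass spectrometrists and RNA bioinformaticians:

- **Mass model** — exact elemental-composition arithmetic for RNA oligos
  with configurable terminal chemistry (5′/3′ phosphate or hydroxyl),
  monoisotopic or average masses, and ±H ionization ([M+H]⁺ / [M−H]⁻).
- **Mass search** — match an observed m/z against a mature-miRNA database
  (miRBase `mature.fa` dialect) within a symmetric ± Da window, unmodified
  or allowing exactly **one** nucleotide modification per miRNA
  (`|mass(miRNA) + Δ(mod) − query| ≤ tol`), with a MODOMICS-style
  modification table (methylations `+CH2`, mass-silent pseudouridine `+0`,
  A→I editing `−H−N+O`, …).
- **Lookup & forward calculation** — retrieve a record by name / MIMAT
  accession / sequence; predict the expected mass of a chosen miRNA
  carrying a chosen modification.
- **Fragment search** — exact-substring alignment of a sequence fragment
  against every record, reporting positions and the sequence coverage
  `⌊1000·|fragment|/|miRNA|⌋/10` % (truncated to one decimal).
- **Fixtures** — a seeded synthetic-database generator and a packaged
  25-record example database, so everything runs offline.

## Worked example

The packaged database contains the 22-nt hsa-miR-153
(`5′ pUUGCAUAGUCACAAAAGUGAUC-OH 3′`).  Its singly protonated average mass
under the defaults (positive mode, average mass, 5′-phosphate,
3′-hydroxyl):

```console
$ mirmass lookup --name hsa-miR-153
1 match
hsa-miR-153  MIMAT0000439  UUGCAUAGUCACAAAAGUGAUC  7091.21 Da  (error +0.0000)
```

Searching an observed peak at 7091.27 Da with a ±0.1 Da window re-finds it
(the signed error is computed − query):

```console
$ mirmass search-mass --mass 7091.27 --tol 0.1
1 match
hsa-miR-153  MIMAT0000439  UUGCAUAGUCACAAAAGUGAUC  7091.21 Da  (error -0.0569)
```

A 10-mer fragment read off a spectrum identifies it uniquely, covering
45.4% of the sequence (bench decorations like the leading `p` are
stripped automatically); the 9-mer is already ambiguous against the
packaged decoys:

```console
$ mirmass fragment --seq pUUGCAUAGUC
1 match
hsa-miR-153  MIMAT0000439  UUGCAUAGUCACAAAAGUGAUC  pos 0  coverage 45.4%
```

Forward-predict a modified species, then recover it by mass:

```console
$ mirmass calc-modified --name hsa-miR-153 --modification m6A
hsa-miR-153  MIMAT0000439
unmodified mass: 7091.21 Da
modification:    m6A (N6-methyladenosine)
modified mass:   7105.24 Da

$ mirmass search-mass --mass 7105.24 --tol 0.01 --modified --base-aware
...includes hsa-miR-153 with every +CH2 methylation: intact mass alone
cannot tell m6A from m5C — that is a physical degeneracy, not a bug.
```

Point any command at a real release with `--db mature.fa` (records are
filtered to the `hsa-` prefix by default) and at your own modification
table with `--mods table.tsv`.  Batch mode maps the search over a
plain-text peak list: `mirmass batch --peaks peaks.txt --tol 0.1`.

## Library use

```python
from mirmass import MassOptions, oligo_mass, search_by_mass, worked_example_db

db = worked_example_db()
opts = MassOptions(tolerance_da=0.1)          # protonated, average, 5'P/3'OH
print(oligo_mass("UUGCAUAGUCACAAAAGUGAUC"))   # 7091.213104
for hit in search_by_mass(db, 7091.27, opts):
    print(hit.record.name, hit.computed_mass, hit.mass_error)
```

See `docs/methods.md` for the model, its assumptions, and known limits.
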