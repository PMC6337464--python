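# Methods

## Parsing model

PDB entries are fixed-width record files: the first six columns of each
line name the record type, and every field of a record sits at a fixed
1-based column range. The reader slices the five supported record types
(ATOM, HETATM, SHEET, HELIX, SEQRES) at the column positions of the wwPDB
format v3.3 dialect — the de-facto format of `*.ent` files — trims
flanking spaces, and converts fields to their semantic types. Key ATOM
columns: serial 7–11, atom name 13–16, altLoc 17, resName 18–20, chain 22,
resSeq 23–26, iCode 27, x/y/z 31–38/39–46/47–54, occupancy 55–60,
B-factor 61–66, element 77–78, charge 79–80.

Decisions taken where the format leaves room:

* **Encoding** — Latin-1. PDB files are ASCII in practice; Latin-1 maps
  every byte, so a stray byte can never abort a batch run on a decode
  error.
* **Strictness** — strict by default: a line shorter than its last
  mandatory column, or with a non-parsing mandatory numeric field, raises
  with the line number. Lenient mode skips such lines and counts them;
  the count travels with the rowset and the job report. ETL correctness
  first: silent data loss must be opt-in and visible.
* **Model context** — `MODEL n` sets the model number for subsequent
  coordinate rows; entries without MODEL records are model 1 (single-model
  X-ray entries omit the record). `ENDMDL` does not reset the context;
  the next `MODEL` does.
* **Protein ID** — the HEADER idCode (columns 63–66), uppercased since PDB
  identifiers are case-insensitive; the file stem (or sequential-record
  index) is the fallback when no HEADER is present.
* **altLoc** — all alternate locations are retained; the extractor is
  lossless and downstream analysis decides.
* **Null numerics** — blank optional numeric fields (occupancy, B-factor,
  registration residue numbers, helix length) are missing values in
  memory and empty fields in CSV.

Compression is detected by the two gzip magic bytes, never by extension.

## Sequential files

A sequential file is a byte-level concatenation of entries, each
terminated by its END record; it is bit-exact with `cat` of members that
already end with END. Records are cut at lines whose first token is
exactly `END` — `ENDMDL` is a distinct record type and never terminates a
record. Iteration is streaming: memory holds at most one record plus one
line.

* **Record cap** — 4 MiB (4 × 2²⁰ bytes) of *decompressed* text, because
  records are parsed decompressed. Oversize members are rejected at build
  time; an oversize record encountered mid-iteration raises with its
  index. `partition_inputs` splits a collection around the cap so callers
  can concatenate the small files and extract the large ones individually.
* **Missing END** — normalized by appending `END` at build time. At
  iteration time a trailing END-less block is an error in strict mode and
  a final record in lenient mode.
* **Blank lines** between concatenated entries are tolerated and ignored;
  the delimiter rule says nothing about them and rejecting them would
  punish hand-built files.
* **Compression granularity** — whole sequential files are gzipped;
  per-record compression is not supported. gzip members are written with
  a fixed mtime and no embedded filename so equal inputs give equal bytes.

## Extraction engine

The unit of work is one entry — an individual file or one sequential
record — mirroring the constraint that an entry is extracted atomically by
exactly one worker; there is no intra-entry parallelism. Workers form a
local process pool sized by the *parallelization factor* (default: the
number of available processors). Partial rowsets are aggregated by a
stable sort on (input position, record index, row order), so the output —
and the CSV written from it — is byte-identical for any worker count.
Stable input order is a design choice made for testability; no other
aggregation order is implied by the method itself.

CSV output is RFC-4180-style: header row, dot decimal separator, minimal
quoting, newline-terminated final line, empty fields for nulls.

## Cα–Cα distances and the fuzzy query

Within each (protein, model, chain) group, Cα atoms (`ATOM` records named
`CA`; the first alternate location per residue wins) are taken in file
order and one distance row is emitted per adjacent pair. Adjacency is the
sliding window over extracted rows, not residue-number arithmetic, so
insertion codes and numbering gaps cannot silently reorder pairs; a
`seqGap` column (resSeqTo − resSeqFrom) annotates each pair so users can
exclude pairs bridging missing residues — the package itself does not
decide that question. Pairs never span chain, model or protein
boundaries. HETATM `CA` (calcium) is excluded by construction: the
analysis consumes the ATOM section only.

The fuzzy set *around c Å* has Gaussian membership
μ(d) = exp(−(d−c)²/(2σ²)) with c = 3.81 Å, the trans-peptide Cα–Cα
spacing. Selection keeps pairs with μ(d) ≥ λ; `≥` (rather than `>`) is
chosen so λ = 1 keeps exactly the center and λ = 0 keeps everything. The
λ-cut is the closed interval |d − c| ≤ σ√(2 ln(1/λ)).

**Width σ = 0.04 Å (default).** The defining behaviour of the query is
that a 3.78 Å distance satisfies the condition at λ = 0.5 while 3.87 Å
does not. Since the half-height half-width of the Gaussian is
σ√(2 ln 2) ≈ 1.177σ, those two constraints bound σ to (0.0255, 0.0510) Å;
0.04 sits in the middle of that interval. σ is an exposed parameter, not
a constant.

## Synthetic fixtures

The generator emulates a corpus of single- or multi-model, multi-chain
protein entries at the level the extractor and the distance analysis
care about: valid fixed-width columns, HEADER/SEQRES/MODEL/TER/END
structure, N–CA–C backbone triplets per residue, consecutive Cα spacing
exactly 3.81 Å before noise, residues cycled through the twenty standard
amino acids, and an optional HETATM water to exercise that code path.

* **Geometry** — the Cα trace is a seeded axis-aligned random walk (a
  random ± unit axis per step, never immediately reversing, reflected at
  the bounds of the `%8.3f` coordinate field). Axis alignment keeps
  noise-free coordinates on the 3-decimal grid of the format, so the
  written file reproduces the ideal spacing exactly rather than to
  quantization error. N and C sit at fixed offsets from their Cα. This is
  chemically naive by design: the artifact tests parsing and distance
  geometry, not stereochemistry.
* **Noise model** — after placement each Cα is displaced by an independent
  N(0, s²I₃) vector (s = `noise_sd`). The difference of two adjacent
  displacements is N(0, 2s²I₃), so the pair distance d satisfies
  d²/(2s²) ~ χ²₃(noncentral, nc = spacing²/(2s²)). `expected_kept_fraction`
  converts that to the closed-form probability that a pair survives the
  λ-cut, which the parameter-recovery test compares with the empirical
  kept fraction. Coordinates are quantized to 0.001 Å by the format; the
  extra variance (~1.7 × 10⁻⁷ Ų per coordinate difference) is four
  orders of magnitude below the noise term at s = 0.02 and is neglected.
* **Determinism** — the RNG is seeded from (seed, entry index), so equal
  specs give byte-identical corpora, including gzipped ones.
* **Limits** — resSeq is a 4-column field, so chains are capped at 9999
  residues; large-n statistical tests use several chains instead
  (e.g. 4 × 2500 residues ≈ 10⁴ consecutive pairs). Chains start at the
  origin and may self-intersect; there are no side chains, no realistic
  secondary structure, and no ligands beyond the optional water.

What passing tests show — and don't. Fixtures exercise the format's
fixed-width mechanics, multi-model/multi-chain bookkeeping, storage
layouts and the noise-model statistics. They do not contain alternate
locations with occupancies, insertion codes, chain breaks from
unresolved residues, or non-protein polymers; the parser handles the
first three structurally (altLoc retention, iCode fields, `seqGap`
annotation) but real-corpus behaviour of those paths is only covered by
the hand-built cases in the unit tests.

## Numerical and statistical choices in tests

* The explicit Euclidean form and the vector-norm form of the distance
  are checked to 1 × 10⁻¹² relative tolerance on 10⁵ random pairs.
* "Noise-free distances equal the spacing" is asserted to 10⁻¹² Å —
  exactness up to double rounding, since coordinates like 11.43 − 7.62
  differ from 3.81 by a few ulps.
* The parameter-recovery test compares the kept fraction with the
  closed-form expectation within three standard errors. Adjacent pairs
  share one Cα displacement, so keep indicators are lag-1 dependent; the
  SE uses the lag-1 autocorrelation correction √(1 + 2ρ̂) (floored at the
  iid value), the standard first-order correction for a stationary
  dependent mean.
* Strict monotone decay of μ is asserted only within 0.3 Å of the center,
  where exp has not underflowed to 0.0, and for gaps above 10⁻⁶ Å, where
  the difference is resolvable in double precision.

## Known limitations

mmCIF and PDBML inputs are out of scope, as are all record types beyond
the five sections (no CONECT, REMARK, CRYST1), random access into
sequential files, and chemical validation. The worker pool is a local
process pool; distributed execution and cloud storage backends are
non-goals. Problem sizes in the test suite (corpora of 1–100 entries,
~10⁴ distance pairs) are chosen so the full suite runs in well under a
minute per module while still pinning the statistics; all generators
scale to larger corpora through the same interfaces.
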