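# Methods

## Read-1 structure and barcode calling

Read 1 is described declaratively as an ordered list of segments
(barcode slots, literal linkers, one UMI, ignored spacers). Linkers are
anchors: each is located by substitution-only approximate search within
`flank + 2` bases of its expected offset (at most `max_linker_mismatch`
mismatches, default 1), and downstream segment coordinates are taken
relative to the located linker, so one upstream indel shifts the whole
tail coherently. Barcode segments are extracted as *expanded windows* —
the nominal span widened by `flank` bases (default 2) on each side — and
indel tolerance is delegated entirely to the downstream matcher: reads
are never error-corrected in place, and base qualities are carried
through but unused.

A window is resolved against its slot's whitelist by semi-global edit
distance (barcode fully consumed, window flanks free; computed with
edlib's infix mode, with an exact-substring prefilter that cannot change
any call because a distance-0 hit is necessarily an exact occurrence).
The unique minimizer within `max_edit` (default 2 for 8-mers) is
assigned; a tie at the minimal distance is ambiguous and the read is
discarded — there is deliberately no tie-breaking, because a guessed
pixel is worse than a dropped read. `max_edit = 2` balances rescue of
FFPE-grade errors against collision risk for 8-mer whitelists; it is a
config knob, as is the flank. A known consequence of the layout
arithmetic: an insertion or deletion *inside the last barcode* shifts
the UMI window by one base, because nothing downstream re-anchors it.
Such reads keep their correct pixel but may carry a perturbed UMI; at
low per-read error rates this inflates UMI counts by at most the error
rate and is invisible in error-free data.

Demultiplexing happens before alignment: surviving reads are written to
a demux table (read id → pixel, UMI) and optionally re-named
(`name|PX:3x17|UMI:ACGTAC`) for an external aligner. Joining alignments
to the table by read id is equivalent to demultiplexing the aligned BAM,
since the join key is the same either way.

## Whole-RNA annotation

Sources are ingested in three dialects — GENCODE-style GTF, generic GTF
(including miRBase-style `miRNA_primary_transcript`/`miRNA` rows, which
become a hairpin transcript plus `-5p`/`-3p` mature-arm exon records),
and BED6 with an RNA-class column. All coordinates are 0-based half-open
internally; GTF converts at the I/O boundary. Records from different
sources that share class, strand and record kind and overlap
reciprocally by at least `merge_overlap` (default 0.9) are collapsed —
transitively — into one entry spanning the union interval, named by the
earliest-listed source. The 0.9 default is conservative: it merges
redundant copies of the same structure across databases without fusing
genuinely adjacent paralogs; it is exposed in config because database
pairs differ in coordinate discipline.

Introns are derived per transcript as the transcript interval minus the
exon union, one feature per gap, *named by the gene* so that the count
matrix has a single intron row per gene (matching the granularity at
which intron evidence is useful, e.g. for maturation-stage analyses).
Exons and derived introns of each transcript partition its span exactly;
this is asserted by tests.

## Assignment

Only exon and derived-intron records compete for reads; transcript
records are structural scaffolding. For a fragment with aligned blocks
(match/deletion runs, split at splice skips), each candidate feature —
any exon/intron record overlapping *any block* on the policy-compatible
strand — is scored with `(L_o − L_no)/L_a`. Collecting candidates per
block rather than per envelope keeps intron records that span a splice
gap out of the candidate set. Scores are exact rationals
(`fractions.Fraction`); tie detection by floating point would
occasionally split or fuse composite multi-mapping rows. On a tie the
read counts toward a composite feature named by the sorted,
plus-joined names of all tied features; when an exon and an intron tie,
the read is exon-layer (containment in an exon is the stronger
statement, and exon records are the shorter, more specific intervals).

Post-alignment filters: only primary alignments are scored (one
fragment, one vote — required for well-defined UMI counting); fragments
aligning fewer than 20 bases or soft-clipped beyond 50 % are dropped;
reads with no positive-scoring candidate are unassigned. All knobs are
in config.

## Quantification

Reads with identical (pixel, feature, layer, UMI) collapse to one
molecule; UMI collapse is exact-sequence. Directional 1-edit UMI
clustering was deliberately left out: it requires an error model the
data does not identify at toy scale, and exact matching is deterministic
and order-invariant (asserted by tests). Matrices keep every
whitelist-defined pixel as a column, even empty ones, so runs over the
same grid are column-alignable; composite multi-mapping rows are
retained for the downstream user to keep or drop. Output is Matrix
Market plus feature/pixel TSV sidecars per layer and one long-form TSV;
the files round-trip exactly.

## Validation

The principle: a genuine compact RNA shows markedly higher read depth
inside its annotation than in flanking background, whereas an annotation
sitting on randomly fragmented background RNA does not. The test
operationalises "read depth" as alignment-span midpoints, which makes
each read one Bernoulli trial and the null exact: with background = one
upstream + one downstream flank of `flank_mult × L_in` bases each
(default 1×), clipped at chromosome ends and masked wherever another
same-strand feature lies, the in-feature count under no enrichment is
Binomial(n, p0), `p0 = L_in/(L_in + L_bg)`. The p-value is the one-sided
exact binomial tail; q-values are Benjamini–Hochberg. A feature is
valid iff `q ≤ 0.05`, fold enrichment ≥ 2, and at least 5 in-feature
reads (all configurable). Features with no background length or no
reads at all are untestable and kept, flagged. This binomial
construction is this package's own concrete realisation of the
depth-step principle; the constants are surfaced in config precisely
because they are choices, not facts.

Validation runs on pseudo-bulk (all pixels pooled): per-pixel depths in
degraded tissue are far too sparse for per-pixel testing, and a
feature-level verdict then filters every pixel column identically. By
default only compact RNA classes are tested (miRNA, tRNA, sno/sn/scaRNA,
piRNA, Y RNA, miscRNA): mRNA genes are orders of magnitude longer than
fragments, so the depth-step logic does not apply to them.

## Synthetic data

The generator emulates the pipeline's inputs end to end with known
truth: random genome; spliced genes, miRNA hairpins with both mature
arms, and spurious features placed non-overlapping with ≥ 400 bp gaps
(so validation flanks are clean by construction); whitelists drawn with
pairwise Hamming distance ≥ 4; reads planted per (feature, pixel) pair
with distinct UMIs; a ground-truth SAM written by exact placement.
Defaults are the standard study conditions: 2 × 100 kb chromosomes, 20
genes × 3 exons (200 nt exons, 300 nt introns), 10 miRNAs (22 nt arms),
4 spurious features, a 16 × 16 grid, 5 UMIs per planted pair, 60 nt
fragments, error processes off. Each feature is planted in 24 randomly
chosen pixels — roughly 9 % pixel occupancy, a realistic sparse-tissue
density. Spliced reads are split 60/40 across adjacent exons: an even
split would score zero against both exons (the overlap-score formula is
antisymmetric around half-overlap) and be dropped by design, so an even
split plants reads the pipeline is defined to discard. Spurious features
receive only uniformly scattered background reads (40 each by default),
whose expected assignment is computed analytically in the generator
(assigned iff more than half the read lies inside the feature, as the
sole candidate).

What the generator does **not** model: sequence-composition realism,
position-dependent error profiles, chimeric reads, UMI errors, and real
FFPE fragment-length distributions. Passing tests therefore demonstrate
the pipeline's logic — parsing, calling, scoring, counting, testing —
under controlled error processes, not its behaviour on any particular
tissue.

One master seed spawns named child streams (genome, annotation, grid,
reads, errors) via `numpy.random.SeedSequence`, so a fixed seed yields
byte-identical files across runs and across worker counts.

## Numerical and degenerate-input choices

- Overlap-score ties: exact rationals, no epsilon.
- Linker location ties: nearest expected offset, then leftmost.
- Fold enrichment conventions: ∞ when the background is empty but the
  feature is not; 0 when the feature is empty; untestable when both are
  or when no background length exists.
- Windows shorter than `barcode_length − max_edit` are unmatched, not
  errors; empty annotation sources load as empty lists with a warning;
  an empty assignment stream produces a valid 0-row matrix with all
  whitelist pixels as columns.
- Demux work is chunked (and optionally fanned out over processes);
  per-read work is pure, so outputs are byte-identical for any worker
  count. Assignment streams the SAM in file order single-pass.

## Problem sizes

The test suite and the acceptance script use the default study
conditions above (~8 000 reads per simulated dataset), 10 000-instance
brute-force cross-checks for barcode calling and assignment, and 500
simulated features per validation error-rate estimate. These sizes give
exact or tight-binomial checks while keeping any run to seconds.

## Known limitations

- The UMI-shift effect for indels in the last barcode slot (above).
- Composite multi-mapping rows are curated by their full composite name
  only; a composite row is not dropped when one of its components fails
  validation.
- `merge_similar` keeps the highest-priority name but does not reconcile
  child/parent links of merged transcripts across sources; at the
  default threshold this only affects redundant same-structure entries.
- The depth-enrichment test assumes approximately uniform background
  fragmentation around the feature; strong local coverage structure
  (e.g. an unannotated overlapping transcript) can defeat it — the
  same-strand masking mitigates but does not eliminate this.
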