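# Methods

This note records how genomodel's components work, the parameters that
matter, what the synthetic data does and does not emulate, and the
design choices made where the design was genuinely open.

## Metadata model and query language

All persistent entities (individuals, samples, instrument data,
processing profiles, models, builds, steps, reference sequences,
annotations) live in a single-file SQLite database as JSON payloads
keyed by `(kind, id)`. IDs are human-readable type-prefixed counters
(`S1`, `I3`, `M1`, `B2`), so provenance reads naturally. A plain-text
snapshot (one JSON-lines file per kind) can be exported and re-imported
to reconstruct the system from metadata alone.

Listing commands accept a filter expression: comparisons
`path op literal` with `=`, `!=`, `<`, `>`, `like` (`%` wildcards) and
`in [v1,v2]`, joined by `and` (binds tighter) and `or`; parentheses are
allowed, literals may be bare words, single-quoted strings or numbers.
Dotted paths hop across entity references
(`instrument_data.sample.individual.common_name`). Evaluation is total:
a path that does not resolve on a row simply fails to match — also
under `!=`, which keeps the semantics monotone in the presence of
heterogeneous rows. Comparisons are numeric when both sides parse as
numbers, string otherwise. Single-quoted literals cannot contain a
quote character; there is no escape syntax.

Integrity rules enforced at write time: references must resolve
(insertion is atomic), `(flow_cell_id, lane, index_sequence)` is unique
across instrument data, a processing profile becomes immutable once any
build has used it, and a succeeded build is frozen entirely (its
resolved inputs, parameters snapshot and output files; tampering with
output files is detected by manifest re-hashing). The index barcode is
treated as an opaque identity field; demultiplexing is assumed to have
happened upstream.

Subject consistency: instrument data attached to a model must come from
the model's subject — directly when the subject is a sample, or via any
of the individual's samples when the subject is an individual.

## Strategy language

Detection strategies are declarative expressions stored as ordinary
profile parameters (`snv_detection_strategy`,
`indel_detection_strategy`, `sv_detection_strategy`,
`cnv_detection_strategy`):

    strategy   := term ('union' term)*
    term       := factor ('intersect' factor)*
    factor     := atom ('filtered by' filterlist)?
    atom       := NAME VERSION PARAMS? | '(' strategy ')'
    filterlist := filter (',' filter)*
    PARAMS     := '[' ... ']'

`filtered by` binds tighter than `intersect`, which binds tighter than
`union` — detectors are filtered first, then callsets are intersected,
then unioned. Expansion into a plan graph is driven by the tool
registry: a detector marked *chunkable* scatters into one step per
chromosome followed by a single gather; filters chain on the callset;
combinators become merge steps. Per-chromosome chunking is a property
of the tool, not of the strategy text, because it is the detector's
execution model that determines whether work divides cleanly.

Canonical strategy digests are invariant under whitespace, redundant
parentheses, parameter order, and child order of `union`/`intersect`
(both are commutative); associativity is *not* normalized — `(a∪b)∪c`
and `a∪(b∪c)` are different trees and hash differently, which is
acceptable because digests only need to recognize equal trees, and the
result cache already collapses equal work at execution time. Identical
sub-expressions within one strategy are likewise left to the cache
rather than deduplicated structurally.

Callset combination uses a matching policy: allele-aware identity
`(chrom, pos, ref, alt)` for SNVs/indels (the conservative choice —
two different alt alleles at one site are different events), and
reciprocal overlap ≥ 0.5 with equal type label for SV/CNV intervals
(the standard interval-concordance convention). Union merges metadata
left-priority (left record's counts win; flags are unioned).

## Build engine and shortcutting

A build freezes its model's inputs (model-valued inputs resolve to the
input model's most recently *succeeded* build — a still-running or
failed newer build is never used), composes the pipeline's plan graph
and executes it in a deterministic topological order (any topological
order gives byte-identical outputs; a randomized order is available and
tested). Execution is sequential: at desk scale the contract worth
testing is order-independence, not a scheduler. Cluster job ids are
synthetic local ids.

Every step's result is stored content-keyed:

    result_id = SHA-256(tool name, tool version, implementation
                        fingerprint, sorted params, ordered input digests)

where raw files digest by content and step inputs by the producing
step's result id. When a step's key matches an existing record the step
*shortcuts*: its outputs are verified by re-hashing (a corrupted cache
entry is treated as a miss and recomputed — self-healing) and reused
without running the tool. The package version is recorded per build but
deliberately excluded from the key, so results survive engine upgrades
that do not change tool implementations; `strict_version_key=True` adds
it for the conservative behavior. The implementation fingerprint (a
digest of the tool's source) is what protects against stale reuse when
a sandbox override shadows a shipped tool.

Failure policy: a failing step fails the build, but independent
branches keep executing first (maximizing reusable results); dependent
steps are left in status `new`. Step statuses move only forward
(`new→scheduled→running→{succeeded,failed}`, or `new→shortcut`).

Provenance is a derived-from graph: build → manifest results → input
digests → upstream results → … → instrument data / reference /
annotation leaves. A digest index maps every registered raw file and
every recorded output to its source node, so files consumed across
build boundaries (e.g. a somatic build reading a tumor alignment file)
resolve to the result that produced them.

## Computational stages

These are intentionally small reference implementations; the
orchestration around them is the product.

* **Aligner** (`naive-align`): seed-and-extend with non-overlapping
  k-mer seeds (pigeonhole rescue of mismatched seeds), Hamming scoring,
  unique-best placement with leftmost tie-break (ties get mapping
  quality 0, unique hits 60), and a single-gap rescue (≤ 10 bp) that
  anchors the first and last seed and picks the mismatch-minimizing
  split point. Forward strand only — the read simulator emits
  forward-strand reads. Defaults: `seed_length=16`, `max_mismatches=4`.
* **SNV caller** (`naive-snv`): per-position pileup over reads with
  mapping quality ≥ 1; emit the most frequent non-reference base
  (lexicographic tie-break) when depth ≥ `min_depth=8` and allele
  fraction ≥ `min_vaf=0.2`.
* **Indel caller** (`naive-indel`): indels read directly from alignment
  CIGARs, left-normalized against the reference, same depth/fraction
  thresholds at the anchor base.
* **Somatic subtraction**: drop tumor calls present in the normal
  callset or with normal-pileup allele fraction > `max_normal_vaf=0.05`;
  positions with no normal coverage count as fraction 0 and are logged.
* **LOH**: normal-het is defined as called VAF in [0.2, 0.8]; a het
  site with tumor VAF ≥ `hom_vaf_threshold=0.9` is flagged `LOH`.
  LOH toward the *reference* allele leaves no alt record in the tumor
  callset to flag; such sites are logged, not flagged. Per-site flags
  are summarized into segments (gap ≤ 10 kb) in the step log.
* **CNV** (`naive-cnv`): per-window (default 1000 bp) read-start
  counts, tumor scaled to the normal library size,
  `log2((t·s + 0.5)/(n + 0.5))`. Whole-library scaling means a large
  amplified fraction shifts *all* windows down slightly; the
  amplified-minus-neutral contrast recovers the planted log2 exactly,
  and is what the acceptance script reports.
* **SV** (`naive-sv`): a deletion-candidate screen (windows covered in
  normal, empty in tumor). The in-silico assembly validation filter is
  a pass-through stub that exists to be recorded in provenance.
* **Annotation**: gene intervals from BED (0-based half-open on disk,
  1-based inclusive internally; a position equal to the BED end does
  not overlap). Region classes rank coding > UTR > intron >
  intergenic-proximal; tiers are a local convention mapping that order
  to 1–4.

All thresholds above are this package's defaults, recorded in the
shipped processing profiles and overridable per profile.

## I/O dialects

Outputs are hashed into manifests, so writers are byte-deterministic:
a minimal VCF 4.1 subset (fixed header block; INFO ordered DP, AC, VAF
to 4 decimals, then flags, then sorted annotations; LF endings; no
FORMAT/genotype columns; unknown INFO keys round-trip verbatim), BED4
for intervals, FASTA (read case-folded to upper, duplicate names
rejected), and a TSV dump for toy alignments in place of BAM. Binary
formats (BAM/CRAM/Tabix) are out of scope at this scale.

## Synthetic data

The generator emulates exactly what the pipelines consume: a uniform
random reference (optional GC bias) with a repeating gene tiling
(UTR/coding/intron blocks plus proximal flanks), diploid samples built
as two haplotype sequences (germline hets on one haplotype, homs on
both, somatic hets on one tumor haplotype, LOH sites alt on both tumor
haplotypes), uniform single-end reads drawn equally from the two
haplotypes with i.i.d. substitution errors, and instrument-data units
split across flow cells/lanes/barcodes. Heterozygous VAF ≈ 0.5 emerges
from haplotype sampling rather than by construction.

Defaults are the study conditions exercised end to end: 2 chromosomes ×
15 kb, 100 germline SNVs (30% hom), 50 somatic SNVs, 10 LOH events,
tumor 40× / normal 30×, 100 bp reads, 0.5% substitution error, one 2×
amplified segment over the middle third of chr1. Variants keep 150 bp
off chromosome ends (uniform coverage) and ≥ 10 bp spacing.

Not emulated: paired ends and insert sizes, quality scores and
error-profile structure (indel errors, homopolymer bias), reverse
strand reads, repeats beyond what a uniform random sequence contains,
contamination/purity gradients, subclonal fractions. Passing tests
therefore demonstrate the orchestration and calling logic under clean
conditions, not caller performance on real data.

## Numerical and degenerate-input choices

Deterministic tie-breaks everywhere: leftmost alignment placement,
lexicographic alt-allele ties, lexicographic topological order, sorted
manifest and VCF output. Empty callsets, empty windows (pseudo-count
0.5), zero-coverage positions (fraction treated as 0 with a log line)
and missing dotted paths (no match, never an error) are all defined.
Seeds: one seeded generator per fixture operation, with sub-operations
offset (+1, +2, +3) from the bundle seed recorded in `bundle.json`.

## Known limitations

* The toy aligner is exact-scan based and scales to tens of kilobases,
  not real genomes; mapping quality is binary (0/60).
* Somatic scoring is threshold-based; there is no statistical model of
  sequencing error or purity.
* The result cache trusts content digests; concurrent builds in one
  root are not locked against each other (execution is sequential by
  design).
* Bundles record absolute paths; a moved bundle must be re-imported.
* The web interface, cluster schedulers and full-text search of the
  large-scale ancestors of this design are intentionally out of scope.
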