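# genomodel

A desk-scale genome-analysis management engine for tumor/normal
sequencing studies. It provides what a sequencing-core LIMS-plus-
pipeline platform provides — but small enough to run on a laptop
against synthetic data:

* a **provenance-tracking metadata model**: individual → sample →
  instrument data (flow cell / lane / index barcode) → model → build →
  result, queried with a dotted-path expression syntax
  (`individual.common_name = patient1`);
* a **declarative strategy language** for variant detection —
  processing-profile fields such as
  `snv_detection_strategy = "naive-snv 1.0 filtered by depth-filter 1.0 [min_depth=8]"`
  expand into executable sub-workflows with per-chromosome
  scatter/gather and a union/intersect callset algebra;
* **content-keyed result reuse ("shortcutting")**: every step's output
  is recorded under a SHA-256 key of (tool, version, implementation
  fingerprint, parameters, input digests); a later build that computes
  the same key reuses the result and runs nothing;
* **immutable builds** with full lineage: every output file traces back
  to the instrument data, reference and annotation that produced it;
* built-in **toy alignment and variant-calling stages** (seed-and-extend
  aligner, pileup SNV/indel callers, tumor/normal somatic subtraction,
  LOH flagging, window read-depth CNV ratios, gene-effect annotation),
  so complete somatic pipelines run end to end with no external tools;
* a **synthetic fixture generator** producing diploid tumor/normal
  genomes with planted germline, somatic and LOH variants, simulated
  reads and a ready-to-import metadata bundle.

It is aimed at people building or teaching analysis-pipeline
infrastructure: the orchestration semantics (reproducibility,
caching, provenance) are the product; the bundled callers are
deliberately simple reference implementations.

## The core model

A **model** binds one *subject* (an individual or a sample), one
immutable **processing profile** (every tool name, version and
parameter, including the four detection-strategy expressions) and a set
of *inputs*. Executing a model creates a **build** — an immutable
snapshot with its own data directory and a manifest of output digests.
Models can take other models as inputs; a build resolves those to the
input model's last complete build, so a somatic-variation build records
exactly which tumor and normal alignment builds it consumed.

Somatic calling follows the standard tumor/normal scheme: per-sample
pileup calls (emit a variant at depth ≥ 8 with allele fraction
VAF = alt/depth ≥ 0.2), subtraction of the matched normal (retain tumor
calls absent from the normal callset with normal allele fraction
≤ 0.05, flagged `SOMATIC`), LOH flagging (normal-het sites,
0.2 ≤ VAF ≤ 0.8, that are effectively homozygous in the tumor,
VAF ≥ 0.9), window read-depth log2 ratios for CNV, and gene/region/tier
annotation.

## Worked example

```sh
export GENOME_SYS_ROOT=./gms_home
genome fixture demo --seed 1          # generate + import the synthetic bundle
genome sample list "individual.common_name = patient1"
```
```
id common_name individual.common_name
S1 tumor       patient1
S2 normal      patient1
S3 relapse     patient1
```
```sh
genome instrument-data list "sample.id = S1"
```
```
id flow_cell_id lane index_sequence sample.id
I1 ABC123       1    <NULL>         S1
I2 ABC123       2    AGCT           S1
I3 ABC123       2    TCAG           S1
```
```sh
genome model define reference-alignment --subject id=S1 \
    --processing-profile id=P2 --name "TST1 tumor"
# defined genome model M1
genome model input add instrument_data id=M1 "flow_cell_id='ABC123' and lane in [1,2]"
# assigned instrument data I1, I2 and I3 to model M1
genome model input add reference id=M1 R1
genome model build start id=M1
# new build B1 started for model M1 with data directory at
#   ./gms_home/fs/model_data/M1/buildB1/
genome model build view id=B1
```

The build view lists every workflow step with its status; nested
steps (per-chromosome scatter under a detector) are indented, and steps
whose result already exists for the same inputs and parameters show
status `shortcut` instead of running. Repeating the same somatic build
shortcuts 100% of its 21 steps and executes zero tools; defining a
second somatic model whose profile differs only in
`sv_detection_strategy` re-executes exactly the two SV-branch steps.

On the default fixture (2×15 kb reference, 100 germline + 50 somatic
planted SNVs, 10 LOH events, tumor 40× / normal 30×, 0.5% base error)
the somatic pipeline recovers **50/50 planted somatic SNVs at 100%
precision**, flags **10/10 planted LOH sites with no false flags**, and
the 2× amplified segment shows an amplified-minus-neutral read-depth
contrast of **≈1.0 log2**. The `genome tools` tree lists the registered
implementations; a user sandbox (`<root>/sandbox/*.py`) shadows shipped
tools by name+version, and the overriding implementation's fingerprint
enters the result keys so cached results from different code are never
silently reused.

## Layout

| module | role |
|---|---|
| `genomodel.entities`, `genomodel.store`, `genomodel.filters` | persistent metadata model, expression queries, snapshot export/import |
| `genomodel.strategy`, `genomodel.plan`, `genomodel.variants` | strategy DSL, plan graphs, callset algebra |
| `genomodel.engine` | builds, result cache, shortcutting, provenance |
| `genomodel.align`, `genomodel.ops`, `genomodel.tools` | toy computational stages and the tool registry |
| `genomodel.formats` | VCF/BED/FASTA/alignment-TSV dialects |
| `genomodel.pipelines` | reference-alignment and somatic-variation pipeline types |
| `genomodel.fixture` | synthetic data and the importable demo bundle |
| `genomodel.cli` | the `genome` / `gmt` command tree |

See `docs/methods.md` for the model's assumptions, parameter defaults
and known limitations.
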