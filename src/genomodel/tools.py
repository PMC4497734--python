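"""Tool registry: the library of runnable components.

Every pipeline step names a registered tool (name + version).  A tool
declares the workflow input roles it consumes, whether it can scatter
by chromosome, and the callset format it emits.  Each registered
implementation carries a *fingerprint* (a digest of its source code)
that enters the result-cache key, so a locally overridden tool never
silently reuses results produced by different code.

Resolution walks an ordered search path — a user sandbox layer before
the shipped layer — so an analyst's local tool of the same name and
version shadows the production one.  Sandbox tools are plain Python
files in ``<root>/sandbox/`` that call ``register(...)``.
"""
from __future__ import annotations

import hashlib
import inspect
from dataclasses import dataclass, field
from pathlib import Path

from . import ops
from . import formats
from .ops import GeneAnnotation
from .variants import VariantSet, combine_variant_sets


class ToolError(ValueError):
    pass


def _fingerprint(func) -> str:
    try:
        src = inspect.getsource(func)
    except (OSError, TypeError):
        src = repr(func)
    return hashlib.sha256(src.encode()).hexdigest()[:16]


@dataclass
class ToolImpl:
    name: str
    version: str
    func: object                         # callable(StepContext) -> None
    input_roles: tuple[str, ...] = ()
    chunkable: bool = False
    callset_format: str = "vcf"          # vcf | bed
    fingerprint: str = ""

    def __post_init__(self):
        if not self.fingerprint:
            self.fingerprint = _fingerprint(self.func)

    @property
    def callset_file(self) -> str:
        return f"calls.{self.callset_format}"


class ToolRegistry:
    """Layered name/version lookup: first layer wins."""

    def __init__(self):
        self._layers: list[dict[tuple[str, str], ToolImpl]] = [{}, {}]
        # layer 0 = user sandbox, layer 1 = shipped

    def register(self, tool: ToolImpl, layer: int = 1) -> ToolImpl:
        self._layers[layer][(tool.name, tool.version)] = tool
        return tool

    def resolve(self, name: str, version: str | None = None) -> ToolImpl:
        for layer in self._layers:
            if version is None:
                hits = sorted(k for k in layer if k[0] == name)
                if hits:
                    return layer[hits[-1]]
            elif (name, version) in layer:
                return layer[(name, version)]
        raise ToolError(f"unknown tool {name!r}" + (f" version {version!r}" if version else ""))

    def names(self) -> list[tuple[str, str]]:
        seen = {}
        for layer in reversed(self._layers):
            seen.update(layer)
        return sorted(seen)

    def clear_sandbox(self) -> None:
        self._layers[0].clear()

    def load_sandbox(self, directory: str | Path) -> int:
        """Execute ``*.py`` files in a sandbox directory; each may call
        ``register(name, version, func, ...)`` to shadow shipped tools."""
        directory = Path(directory)
        self.clear_sandbox()
        n = 0
        if not directory.is_dir():
            return 0
        for f in sorted(directory.glob("*.py")):
            ns = {"register": lambda *a, **kw: self._sandbox_register(*a, **kw),
                  "ops": ops, "formats": formats}
            exec(compile(f.read_text(), str(f), "exec"), ns)
            n += 1
        return n

    def _sandbox_register(self, name, version, func, input_roles=(), chunkable=False,
                          callset_format="vcf"):
        src_fp = hashlib.sha256(inspect.getsource(func).encode()
                                if _has_source(func) else repr(func).encode()).hexdigest()[:16]
        self.register(ToolImpl(name, version, func, tuple(input_roles), chunkable,
                               callset_format, fingerprint=src_fp), layer=0)


def _has_source(func) -> bool:
    try:
        inspect.getsource(func)
        return True
    except (OSError, TypeError):
        return False


# ---------------------------------------------------------------------------
# shipped tool implementations
#
# Every tool receives a StepContext (see engine module) exposing:
#   ctx.input(role) -> Path, ctx.out(filename) -> Path,
#   ctx.params: dict[str, str], ctx.log(msg)
# ---------------------------------------------------------------------------

def _f(ctx, key, default):
    return float(ctx.params.get(key, default))


def _i(ctx, key, default):
    return int(ctx.params.get(key, default))


def _load_reference(ctx):
    return formats.read_fasta(ctx.input("reference"))


def _maybe_filter_chrom(items, ctx, attr="chrom"):
    chrom = ctx.params.get("chromosome")
    if chrom:
        return [a for a in items if getattr(a, attr) == chrom]
    return items


def tool_naive_align(ctx):
    from .align import align_reads
    reads = formats.read_reads_tsv(ctx.input("reads"))
    reference = _load_reference(ctx)
    alns = align_reads(reads, reference,
                       seed_length=_i(ctx, "seed_length", 16),
                       max_mismatches=_i(ctx, "max_mismatches", 4))
    ctx.log(f"naive-align: {len(alns)}/{len(reads)} reads placed")
    formats.write_alignments(alns, ctx.out("alignments.tsv"))


def tool_merge_alignments(ctx):
    merged = []
    for role in sorted(ctx.inputs):
        if role.startswith("aln_"):
            merged.extend(formats.read_alignments(ctx.input(role)))
    merged.sort(key=lambda a: (a.chrom, a.start, a.read_id))
    ctx.log(f"merge-alignments: {len(merged)} alignments")
    formats.write_alignments(merged, ctx.out("alignments.tsv"))


def tool_naive_snv(ctx):
    alns = _maybe_filter_chrom(formats.read_alignments(ctx.input("alignments")), ctx)
    calls = ops.call_snvs_pileup(alns, _load_reference(ctx),
                                 min_depth=_i(ctx, "min_depth", ops.DEFAULT_MIN_DEPTH),
                                 min_vaf=_f(ctx, "min_vaf", ops.DEFAULT_MIN_VAF),
                                 min_mapq=_i(ctx, "min_mapq", ops.DEFAULT_MIN_MAPQ))
    ctx.log(f"naive-snv: {len(calls)} SNVs")
    formats.write_vcf(calls, ctx.out("calls.vcf"))


def tool_naive_indel(ctx):
    alns = _maybe_filter_chrom(formats.read_alignments(ctx.input("alignments")), ctx)
    calls = ops.call_indels_pileup(alns, _load_reference(ctx),
                                   min_depth=_i(ctx, "min_depth", ops.DEFAULT_MIN_DEPTH),
                                   min_vaf=_f(ctx, "min_vaf", ops.DEFAULT_MIN_VAF),
                                   min_mapq=_i(ctx, "min_mapq", ops.DEFAULT_MIN_MAPQ))
    ctx.log(f"naive-indel: {len(calls)} indels")
    formats.write_vcf(calls, ctx.out("calls.vcf"))


def tool_naive_cnv(ctx):
    tumor = formats.read_alignments(ctx.input("tumor_alignments"))
    normal = formats.read_alignments(ctx.input("normal_alignments"))
    reference = _load_reference(ctx)
    window = _i(ctx, "window_size", 1000)
    rows = ops.cnv_depth_ratio(tumor, normal, window_size=window,
                               chrom_lengths={c: len(s) for c, s in reference.items()})
    ctx.log(f"naive-cnv: {len(rows)} windows")
    with open(ctx.out("calls.bed"), "w", encoding="ascii", newline="\n") as fh:
        for chrom, start, ratio in rows:
            fh.write(f"{chrom}\t{start - 1}\t{start - 1 + window}\tlog2={ratio:.4f}\n")


def tool_naive_sv(ctx):
    tumor = formats.read_alignments(ctx.input("tumor_alignments"))
    normal = formats.read_alignments(ctx.input("normal_alignments"))
    calls = ops.sv_deletion_candidates(tumor, normal,
                                       window_size=_i(ctx, "window_size", 200),
                                       min_normal_reads=_i(ctx, "min_normal_reads", 4))
    ctx.log(f"naive-sv: {len(calls)} candidate deletions")
    formats.write_bed(calls, ctx.out("calls.bed"))


def tool_depth_filter(ctx):
    calls = formats.read_vcf(ctx.input("calls"))
    min_depth = _i(ctx, "min_depth", ops.DEFAULT_MIN_DEPTH)
    kept = VariantSet([v for v in calls if v.depth >= min_depth])
    ctx.log(f"depth-filter: kept {len(kept)}/{len(calls)}")
    formats.write_vcf(kept, ctx.out("calls.vcf"))


def tool_vaf_filter(ctx):
    calls = formats.read_vcf(ctx.input("calls"))
    min_vaf = _f(ctx, "min_vaf", ops.DEFAULT_MIN_VAF)
    kept = VariantSet([v for v in calls if v.vaf >= min_vaf])
    ctx.log(f"vaf-filter: kept {len(kept)}/{len(calls)}")
    formats.write_vcf(kept, ctx.out("calls.vcf"))


def tool_sv_assembly_validate(ctx):
    """Stub for in-silico assembly validation of SV candidates: records
    its name/version in provenance and passes every candidate through."""
    fmt = formats.variant_format_for(ctx.input("calls"))
    calls = formats.read_variants(ctx.input("calls"), fmt)
    ctx.log(f"sv-assembly-validate: pass-through of {len(calls)} candidates")
    formats.write_variants(calls, ctx.out(f"calls.{fmt}"), fmt)


def tool_combine_variants(ctx):
    fmt = ctx.params.get("format", "vcf")
    left = formats.read_variants(ctx.input("left"), fmt)
    right = formats.read_variants(ctx.input("right"), fmt)
    out = combine_variant_sets(ctx.params.get("op", "union"), left, right,
                               matching=ctx.params.get("matching",
                                                       "interval" if fmt == "bed" else "allele"))
    ctx.log(f"combine-variants: {ctx.params.get('op')} -> {len(out)}")
    formats.write_variants(out, ctx.out(f"calls.{fmt}"), fmt)


def tool_gather_variants(ctx):
    fmt = ctx.params.get("format", "vcf")
    merged = []
    for role in sorted(ctx.inputs):
        if role.startswith("part_"):
            merged.extend(formats.read_variants(ctx.input(role), fmt).variants)
    out = VariantSet(merged)
    ctx.log(f"gather-variants: {len(out)} records")
    formats.write_variants(out, ctx.out(f"calls.{fmt}"), fmt)


def tool_somatic_subtract(ctx):
    tumor = formats.read_vcf(ctx.input("tumor_calls"))
    normal = formats.read_vcf(ctx.input("normal_calls"))
    normal_aln = formats.read_alignments(ctx.input("normal_alignments"))
    pileup = ops.build_pileup(normal_aln, _load_reference(ctx))
    out = ops.somatic_subtract(tumor, normal, pileup,
                               max_normal_vaf=_f(ctx, "max_normal_vaf",
                                                 ops.DEFAULT_MAX_NORMAL_VAF),
                               log=ctx.log)
    ctx.log(f"somatic-subtract: {len(out)}/{len(tumor)} tumor calls retained as somatic")
    formats.write_vcf(out, ctx.out("calls.vcf"))


def tool_loh_flag(ctx):
    tumor = formats.read_vcf(ctx.input("tumor_calls"))
    normal = formats.read_vcf(ctx.input("normal_calls"))
    flagged = ops.loh_annotate(normal, tumor,
                               hom_vaf_threshold=_f(ctx, "hom_vaf_threshold",
                                                    ops.DEFAULT_HOM_VAF),
                               log=ctx.log)
    loh_only = VariantSet([v for v in flagged if "LOH" in v.flags])
    for chrom, start, end, n in ops.loh_segments(loh_only):
        ctx.log(f"LOH segment {chrom}:{start}-{end} ({n} sites)")
    ctx.log(f"loh-flag: {len(loh_only)} LOH sites")
    formats.write_vcf(loh_only, ctx.out("calls.vcf"))


def tool_annotate_effects(ctx):
    calls = formats.read_vcf(ctx.input("calls"))
    annotation = GeneAnnotation.from_bed_rows(formats.read_bed(ctx.input("annotation")))
    out = ops.annotate_effects(calls, annotation)
    tier1 = sum(1 for v in out if v.info_dict().get("TIER") == "1")
    ctx.log(f"annotate-effects: {len(out)} variants annotated, {tier1} tier 1")
    formats.write_vcf(out, ctx.out("calls.vcf"))


def default_registry() -> ToolRegistry:
    reg = ToolRegistry()
    for tool in (
        ToolImpl("naive-align", "1.0", tool_naive_align, ("reads", "reference")),
        ToolImpl("merge-alignments", "1.0", tool_merge_alignments, ()),
        ToolImpl("naive-snv", "1.0", tool_naive_snv, ("alignments", "reference"),
                 chunkable=True),
        ToolImpl("naive-indel", "1.0", tool_naive_indel, ("alignments", "reference"),
                 chunkable=True),
        ToolImpl("naive-cnv", "1.0", tool_naive_cnv,
                 ("tumor_alignments", "normal_alignments", "reference"),
                 callset_format="bed"),
        ToolImpl("naive-sv", "1.0", tool_naive_sv,
                 ("tumor_alignments", "normal_alignments"), callset_format="bed"),
        ToolImpl("depth-filter", "1.0", tool_depth_filter, ()),
        ToolImpl("vaf-filter", "1.0", tool_vaf_filter, ()),
        ToolImpl("sv-assembly-validate", "1.0", tool_sv_assembly_validate, ()),
        ToolImpl("combine-variants", "1.0", tool_combine_variants, ()),
        ToolImpl("gather-variants", "1.0", tool_gather_variants, ()),
        ToolImpl("somatic-subtract", "1.0", tool_somatic_subtract,
                 ("normal_alignments", "reference")),
        ToolImpl("loh-flag", "1.0", tool_loh_flag, ()),
        ToolImpl("annotate-effects", "1.0", tool_annotate_effects, ("annotation",)),
    ):
        reg.register(tool)
    return reg
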