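"""Reference implementations of the computational pipeline stages.

These are the pure functions behind the registered tools: pileup SNV
and indel calling, tumor/normal somatic subtraction, LOH flagging,
window read-depth CNV ratios and gene-effect annotation.  They operate
on toy alignments and the internal 1-based inclusive convention; each
is deterministic given its inputs.
"""
from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .align import Alignment
from .variants import Variant, VariantSet

BASES = "ACGT"

# defaults recorded in the shipped processing profiles; local conventions
DEFAULT_MIN_DEPTH = 8
DEFAULT_MIN_VAF = 0.2
DEFAULT_MIN_MAPQ = 1
DEFAULT_MAX_NORMAL_VAF = 0.05
DEFAULT_HOM_VAF = 0.9
#: normal-sample VAF band treated as heterozygous for LOH analysis
HET_BAND = (0.2, 0.8)


@dataclass
class Pileup:
    """Per-position base counts plus indel events keyed by allele."""

    base_counts: dict[tuple[str, int], Counter] = field(default_factory=dict)
    # (chrom, pos, ref, alt) -> supporting read count; pos is the anchor base
    indel_counts: dict[tuple, int] = field(default_factory=dict)

    def depth(self, chrom: str, pos: int) -> int:
        return sum(self.base_counts.get((chrom, pos), Counter()).values())

    def allele_fraction(self, chrom: str, pos: int, base: str) -> float | None:
        """Fraction of reads supporting ``base``; None when no coverage."""
        c = self.base_counts.get((chrom, pos))
        if not c:
            return None
        total = sum(c.values())
        return c.get(base, 0) / total if total else None


def build_pileup(alignments: list[Alignment], reference: dict[str, str],
                 min_mapq: int = DEFAULT_MIN_MAPQ) -> Pileup:
    pu = Pileup()
    for a in alignments:
        if a.mapping_quality < min_mapq:
            continue
        rpos = a.start          # 1-based reference cursor
        qpos = 0                # 0-based read cursor
        for op, n in a.cigar:
            if op == "M":
                for i in range(n):
                    key = (a.chrom, rpos + i)
                    pu.base_counts.setdefault(key, Counter())[a.sequence[qpos + i]] += 1
                rpos += n
                qpos += n
            elif op == "I":
                ins = a.sequence[qpos:qpos + n]
                key = normalize_indel(reference, a.chrom, rpos - 1, ins=ins)
                pu.indel_counts[key] = pu.indel_counts.get(key, 0) + 1
                qpos += n
            elif op == "D":
                key = normalize_indel(reference, a.chrom, rpos - 1, del_len=n)
                pu.indel_counts[key] = pu.indel_counts.get(key, 0) + 1
                rpos += n
    return pu


def normalize_indel(reference: dict[str, str], chrom: str, anchor: int,
                    ins: str = "", del_len: int = 0) -> tuple[str, int, str, str]:
    """Left-normalize an indel anchored at 1-based position ``anchor``.

    Returns a VCF-style (chrom, pos, ref, alt) with the anchor base
    included, shifted left while the flanking sequence repeats.
    """
    seq = reference[chrom]
    if del_len:
        # deletion of seq[anchor .. anchor+del_len-1] (0-based anchor..)
        start0 = anchor  # 0-based index of first deleted base
        while start0 > 0 and seq[start0 - 1] == seq[start0 + del_len - 1]:
            start0 -= 1
        pos = start0      # anchor base is seq[start0-1], 1-based pos = start0
        if pos < 1:
            pos = 1
            return (chrom, pos, seq[0:del_len + 1], seq[del_len])
        return (chrom, pos, seq[pos - 1:pos - 1 + del_len + 1], seq[pos - 1])
    else:
        start0 = anchor  # insertion after 1-based `anchor` = after 0-based anchor-1
        allele = ins
        while start0 > 0 and allele and seq[start0 - 1] == allele[-1]:
            allele = seq[start0 - 1] + allele[:-1]
            start0 -= 1
        pos = start0 if start0 >= 1 else 1
        return (chrom, pos, seq[pos - 1], seq[pos - 1] + allele)


def call_snvs_pileup(alignments: list[Alignment], reference: dict[str, str],
                     min_depth: int = DEFAULT_MIN_DEPTH, min_vaf: float = DEFAULT_MIN_VAF,
                     min_mapq: int = DEFAULT_MIN_MAPQ) -> VariantSet:
    """Emit an SNV wherever the most frequent non-reference base passes
    the depth and allele-fraction thresholds."""
    pu = build_pileup(alignments, reference, min_mapq=min_mapq)
    out = []
    for (chrom, pos), counts in pu.base_counts.items():
        depth = sum(counts.values())
        if depth < min_depth:
            continue
        ref_base = reference[chrom][pos - 1]
        alts = [(n, b) for b, n in counts.items() if b != ref_base and b in BASES]
        if not alts:
            continue
        best_n, best_b = max(alts, key=lambda t: (t[0], t[1]))
        # tie on count -> lexicographically smallest base, deterministic
        ties = [b for n, b in alts if n == best_n]
        best_b = min(ties)
        if best_n / depth >= min_vaf:
            out.append(Variant(chrom, pos, ref_base, best_b, depth=depth, alt_count=best_n))
    return VariantSet(out)


def call_indels_pileup(alignments: list[Alignment], reference: dict[str, str],
                       min_depth: int = DEFAULT_MIN_DEPTH, min_vaf: float = DEFAULT_MIN_VAF,
                       min_mapq: int = DEFAULT_MIN_MAPQ) -> VariantSet:
    """Emit left-normalized indels carried by alignment CIGARs, subject to
    the same depth/fraction thresholds (depth taken at the anchor base)."""
    pu = build_pileup(alignments, reference, min_mapq=min_mapq)
    out = []
    for (chrom, pos, ref, alt), n in pu.indel_counts.items():
        depth = max(pu.depth(chrom, pos), n)
        if depth < min_depth or n / depth < min_vaf:
            continue
        out.append(Variant(chrom, pos, ref, alt, depth=depth, alt_count=n))
    return VariantSet(out)


def somatic_subtract(tumor_set: VariantSet, normal_set: VariantSet,
                     normal_pileup: Pileup,
                     max_normal_vaf: float = DEFAULT_MAX_NORMAL_VAF,
                     log=None) -> VariantSet:
    """Retain tumor variants absent from the normal callset whose
    supporting-allele fraction in the normal pileup is <= max_normal_vaf.
    Retained variants are flagged somatic.  Positions with no normal
    coverage are treated as fraction 0 and logged."""
    normal_keys = normal_set.keys()
    out = []
    for v in tumor_set:
        if v.key() in normal_keys:
            continue
        if len(v.ref) == 1 and len(v.alt) == 1:
            frac = normal_pileup.allele_fraction(v.chrom, v.pos, v.alt)
        else:
            n = normal_pileup.indel_counts.get(v.key(), 0)
            d = normal_pileup.depth(v.chrom, v.pos)
            frac = (n / d) if d else None
        if frac is None:
            if log:
                log(f"no normal coverage at {v.chrom}:{v.pos}; assuming VAF 0")
            frac = 0.0
        if frac <= max_normal_vaf:
            out.append(v.with_flags("SOMATIC"))
    return VariantSet(out)


def loh_annotate(germline_het_set: VariantSet, tumor_set: VariantSet,
                 hom_vaf_threshold: float = DEFAULT_HOM_VAF, log=None) -> VariantSet:
    """Flag loss of heterozygosity: sites heterozygous in the normal
    sample whose tumor allele fraction is effectively homozygous
    (>= hom_vaf_threshold).  Returns the tumor set with LOH flags added;
    het sites missing from the tumor set are logged and left unflagged."""
    het_keys = {v.key() for v in germline_het_set
                if HET_BAND[0] <= v.vaf <= HET_BAND[1]}
    out = []
    for v in tumor_set:
        if v.key() in het_keys:
            het_keys.discard(v.key())
            if v.depth and v.vaf >= hom_vaf_threshold:
                v = v.with_flags("LOH")
        out.append(v)
    if log:
        for key in sorted(het_keys):
            log(f"germline het site {key[0]}:{key[1]} absent from tumor calls")
    return VariantSet(out)


def loh_segments(flagged: VariantSet, max_gap: int = 10000) -> list[tuple[str, int, int, int]]:
    """Summarize LOH-flagged sites into segments (chrom, start, end, n_sites),
    merging consecutive flagged sites closer than ``max_gap``."""
    sites = [(v.chrom, v.pos) for v in flagged if "LOH" in v.flags]
    segs: list[list] = []
    for chrom, pos in sites:
        if segs and segs[-1][0] == chrom and pos - segs[-1][2] <= max_gap:
            segs[-1][2] = pos
            segs[-1][3] += 1
        else:
            segs.append([chrom, pos, pos, 1])
    return [tuple(s) for s in segs]


def cnv_depth_ratio(tumor_alignments: list[Alignment], normal_alignments: list[Alignment],
                    window_size: int = 1000,
                    chrom_lengths: dict[str, int] | None = None
                    ) -> list[tuple[str, int, float]]:
    """Per-window log2 tumor/normal read-start ratio.

    Counts read starts per window, scales tumor counts so library sizes
    match, and reports log2((t+0.5)/(n+0.5)).  Windows are 1-based
    starts at 1, 1+w, ...  Returns (chrom, window_start, log2_ratio).
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")

    def counts(alns):
        c: dict[tuple[str, int], int] = defaultdict(int)
        for a in alns:
            win = ((a.start - 1) // window_size) * window_size + 1
            c[(a.chrom, win)] += 1
        return c

    tc, nc = counts(tumor_alignments), counts(normal_alignments)
    total_t, total_n = sum(tc.values()), sum(nc.values())
    scale = (total_n / total_t) if total_t and total_n else 1.0

    if chrom_lengths:
        windows = [(c, w) for c in sorted(chrom_lengths)
                   for w in range(1, chrom_lengths[c] + 1, window_size)]
    else:
        windows = sorted(set(tc) | set(nc))
    return [(c, w, math.log2((tc.get((c, w), 0) * scale + 0.5) / (nc.get((c, w), 0) + 0.5)))
            for c, w in windows]


# region classes in priority order; tier is 1 + index (tier1=coding ... tier4=other)
REGION_PRIORITY = ("coding", "utr", "intron", "intergenic-proximal")


def region_tier(region_class: str) -> int:
    try:
        return REGION_PRIORITY.index(region_class) + 1
    except ValueError:
        return 4


@dataclass
class GeneAnnotation:
    """Gene region intervals, internal 1-based inclusive coordinates."""

    intervals: list[tuple[str, int, int, str, str]]  # chrom, start, end, gene, class

    @classmethod
    def from_bed_rows(cls, rows: VariantSet) -> "GeneAnnotation":
        """BED rows with name ``gene|class`` (half-open input already
        converted to 1-based inclusive by the BED reader)."""
        iv = []
        for r in rows:
            gene, _, rclass = r.alt.partition("|")
            iv.append((r.chrom, r.pos, r.end if r.end is not None else r.pos,
                       gene, rclass or "intergenic-proximal"))
        return cls(sorted(iv))

    def classify(self, chrom: str, pos: int) -> tuple[str, str]:
        """(gene, region class) for a position; best class wins on overlap."""
        hits = [(region_tier(rc), g, rc) for c, s, e, g, rc in self.intervals
                if c == chrom and s <= pos <= e]
        if not hits:
            return (".", "intergenic")
        _, gene, rclass = min(hits)
        return (gene, rclass)


def annotate_effects(variants: VariantSet, annotation: GeneAnnotation) -> VariantSet:
    """Label each variant with overlapping gene, region class and tier."""
    out = []
    for v in variants:
        gene, rclass = annotation.classify(v.chrom, v.pos)
        out.append(v.with_info(GENE=gene, RCLASS=rclass, TIER=str(region_tier(rclass))))
    return VariantSet(out)


def sv_deletion_candidates(tumor_alignments: list[Alignment],
                           normal_alignments: list[Alignment],
                           window_size: int = 200, min_normal_reads: int = 4
                           ) -> VariantSet:
    """Toy structural-variant detector: windows covered in the normal
    sample but with zero tumor read starts become DEL candidates."""
    def counts(alns):
        c: dict[tuple[str, int], int] = defaultdict(int)
        for a in alns:
            c[(a.chrom, ((a.start - 1) // window_size) * window_size + 1)] += 1
        return c

    tc, nc = counts(tumor_alignments), counts(normal_alignments)
    out = []
    for (chrom, w), n in sorted(nc.items()):
        if n >= min_normal_reads and tc.get((chrom, w), 0) == 0:
            out.append(Variant(chrom, w, ".", "DEL", end=w + window_size - 1))
    return VariantSet(out)
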