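"""Deterministic synthetic tumor/normal fixtures.

Everything a somatic pipeline needs with no download: a random
reference genome with a tiled gene annotation, diploid normal and tumor
genomes with planted germline/somatic/LOH variants, simulated reads
split into instrument-data units, and a ready-to-import metadata bundle
(patient1 with tumor/normal/relapse samples, shipped processing
profiles for the reference-alignment and somatic-variation pipelines).

Samples are diploid: each carries two haplotype sequences, and reads
are drawn from the haplotypes with equal probability, so heterozygous
allele fractions near 0.5 emerge from sampling rather than by
construction.  All randomness flows from a single seed per operation,
recorded in the bundle, so fixture-driven builds are reproducible.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import entities as E
from .formats import write_fasta, write_reads_tsv
from .store import MetadataStore

BASES = np.frombuffer(b"ACGT", dtype="S1")

#: annotation tiling repeated along each chromosome (class, width);
#: "intergenic" blocks produce no BED row
GENE_TILE = (("intergenic", 400), ("intergenic-proximal", 100), ("utr", 100),
             ("coding", 400), ("intron", 200), ("coding", 400), ("utr", 100),
             ("intergenic-proximal", 100))


@dataclass
class PlantedVariant:
    chrom: str
    pos: int                 # 1-based reference position (anchor for indels)
    ref: str
    alt: str
    zygosity: str = "het"    # het | hom (germline genotype in the normal)
    somatic: bool = False
    loh: bool = False
    expected_normal_vaf: float = 0.0
    expected_tumor_vaf: float = 0.0


@dataclass
class TruthSet:
    germline: list[PlantedVariant] = field(default_factory=list)
    somatic: list[PlantedVariant] = field(default_factory=list)
    cnv_segments: list[tuple[str, int, int, float]] = field(default_factory=list)
    # (chrom, start, end, expected log2 ratio), 1-based inclusive

    def somatic_snv_keys(self) -> set[tuple]:
        return {(v.chrom, v.pos, v.ref, v.alt) for v in self.somatic
                if len(v.ref) == 1 and len(v.alt) == 1}

    def loh_keys(self) -> set[tuple]:
        return {(v.chrom, v.pos, v.ref, v.alt) for v in self.germline if v.loh}


def generate_reference(n_chroms: int = 2, chrom_length: int = 15000,
                       gc_bias: float = 0.5, seed: int = 0
                       ) -> tuple[dict[str, str], list[tuple[str, int, int, str]]]:
    """Random reference + tiled gene annotation.

    Returns (sequences, BED rows (chrom, start0, end0, "gene|class")).
    ``gc_bias`` is the total G+C fraction.
    """
    if chrom_length < 1000:
        raise ValueError("chromosome length must be >= 1 kb")
    rng = np.random.default_rng(seed)
    p_gc = gc_bias / 2
    p = [0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc]        # A C G T
    seqs = {}
    for i in range(n_chroms):
        arr = rng.choice(np.array(list("ACGT")), size=chrom_length, p=p)
        seqs[f"chr{i + 1}"] = "".join(arr)

    bed_rows = []
    for chrom in sorted(seqs):
        cursor, gene_i = 0, 0
        L = len(seqs[chrom])
        while cursor < L:
            gene_i += 1
            gene = f"g{chrom}_{gene_i}"
            for rclass, width in GENE_TILE:
                end = min(cursor + width, L)
                if rclass != "intergenic" and end > cursor:
                    bed_rows.append((chrom, cursor, end, f"{gene}|{rclass}"))
                cursor = end
                if cursor >= L:
                    break
    return seqs, bed_rows


def _apply_variants(seq: str, variants: list[PlantedVariant]) -> str:
    """Apply variants (reference coordinates) to one haplotype string."""
    out = seq
    for v in sorted(variants, key=lambda v: -v.pos):
        i = v.pos - 1
        if len(v.ref) == 1 and len(v.alt) == 1:          # SNV
            out = out[:i] + v.alt + out[i + 1:]
        elif len(v.ref) < len(v.alt):                    # insertion after anchor
            out = out[:i + 1] + v.alt[1:] + out[i + 1:]
        else:                                            # deletion
            out = out[:i + 1] + out[i + len(v.ref):]
    return out


def plant_variants(reference: dict[str, str], n_germline: int = 100,
                   n_somatic: int = 50, indel_fraction: float = 0.0,
                   n_loh: int = 10, hom_fraction: float = 0.3, seed: int = 0,
                   edge_margin: int = 150, min_spacing: int = 20
                   ) -> tuple[dict, dict, TruthSet]:
    """Plant germline and somatic variants; build diploid genomes.

    Returns (normal_haplotypes, tumor_haplotypes, truth): haplotype maps
    chrom -> (hap0, hap1).  Germline variants appear in both samples
    (het or hom per truth); ``n_loh`` of the germline hets lose the
    reference allele in the tumor; somatic variants are tumor-only hets.
    Positions are pairwise separated by ``min_spacing`` and avoid
    ``edge_margin`` bases at the chromosome ends.
    """
    rng = np.random.default_rng(seed)
    total = n_germline + n_somatic
    if n_loh > n_germline:
        raise ValueError("n_loh cannot exceed n_germline")

    slots: list[tuple[str, int]] = []
    for chrom in sorted(reference):
        L = len(reference[chrom])
        for pos in range(edge_margin + 1, L - edge_margin, min_spacing):
            slots.append((chrom, pos))
    if total > len(slots):
        raise ValueError(f"cannot plant {total} variants: only {len(slots)} "
                         f"usable positions at spacing {min_spacing}")
    chosen = rng.choice(len(slots), size=total, replace=False)
    jitter = rng.integers(0, max(1, min_spacing - 10), size=total)

    def make_variant(idx: int, jit: int) -> PlantedVariant:
        chrom, pos = slots[idx]
        pos += int(jit)
        ref_base = reference[chrom][pos - 1]
        if rng.random() < indel_fraction:
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:   # insertion
                ins = "".join(str(b, "ascii") for b in rng.choice(BASES, size=length))
                return PlantedVariant(chrom, pos, ref_base, ref_base + ins)
            del_seq = reference[chrom][pos - 1: pos + length]
            return PlantedVariant(chrom, pos, del_seq, ref_base)
        alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        return PlantedVariant(chrom, pos, ref_base, alt)

    truth = TruthSet()
    norm_h: dict[str, tuple[list, list]] = {c: ([], []) for c in reference}
    tum_h: dict[str, tuple[list, list]] = {c: ([], []) for c in reference}

    germline = [make_variant(chosen[i], jitter[i]) for i in range(n_germline)]
    het_indices = []
    for i, v in enumerate(germline):
        hom = rng.random() < hom_fraction
        v.zygosity = "hom" if hom else "het"
        v.expected_normal_vaf = 1.0 if hom else 0.5
        v.expected_tumor_vaf = v.expected_normal_vaf
        if not hom:
            het_indices.append(i)
    if n_loh > len(het_indices):
        raise ValueError(f"only {len(het_indices)} het germline sites; cannot "
                         f"plant {n_loh} LOH events")
    loh_pick = set(int(j) for j in rng.choice(het_indices, size=n_loh, replace=False))
    for i, v in enumerate(germline):
        hap = int(rng.integers(2))
        if v.zygosity == "hom":
            haps_normal, haps_tumor = (0, 1), (0, 1)
        elif i in loh_pick:
            v.loh = True
            v.expected_tumor_vaf = 1.0
            haps_normal, haps_tumor = (hap,), (0, 1)
        else:
            haps_normal, haps_tumor = (hap,), (hap,)
        for h in haps_normal:
            norm_h[v.chrom][h].append(v)
        for h in haps_tumor:
            tum_h[v.chrom][h].append(v)
        truth.germline.append(v)

    for i in range(n_germline, total):
        v = make_variant(chosen[i], jitter[i])
        v.somatic = True
        v.zygosity = "het"
        v.expected_normal_vaf = 0.0
        v.expected_tumor_vaf = 0.5
        tum_h[v.chrom][int(rng.integers(2))].append(v)
        truth.somatic.append(v)

    normal = {c: tuple(_apply_variants(reference[c], norm_h[c][h]) for h in (0, 1))
              for c in reference}
    tumor = {c: tuple(_apply_variants(reference[c], tum_h[c][h]) for h in (0, 1))
             for c in reference}
    return normal, tumor, truth


def simulate_reads(genome: dict[str, tuple[str, str]], depth: float,
                   read_length: int = 100, error_rate: float = 0.005,
                   seed: int = 0, read_prefix: str = "r",
                   depth_multipliers: list[tuple[str, int, int, float]] | None = None
                   ) -> list[tuple[str, str]]:
    """Uniform single-end reads from a diploid genome.

    Haplotypes are sampled with equal probability; each base substitutes
    with probability ``error_rate``.  ``depth_multipliers`` adds extra
    coverage over segments (chrom, start, end, factor) to emulate copy
    number amplification.
    """
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    counter = 0
    for chrom in sorted(genome):
        haps = genome[chrom]
        if read_length > min(len(h) for h in haps):
            raise ValueError("read_length exceeds chromosome length")
        n = round(depth * len(haps[0]) / read_length)
        jobs = [(haps, None, n)]
        for seg in (depth_multipliers or []):
            s_chrom, s_start, s_end, factor = seg
            if s_chrom != chrom or factor <= 1.0:
                continue
            s_end = min(s_end, len(haps[0]))
            if s_start - 1 > len(haps[0]) - read_length:
                continue
            extra = round((factor - 1.0) * depth * (s_end - s_start + 1) / read_length)
            jobs.append((haps, (s_start, s_end), extra))
        for haps_j, window, count in jobs:
            for _ in range(count):
                hap = haps_j[int(rng.integers(2))]
                if window is None:
                    lo, hi = 0, len(hap) - read_length
                else:
                    lo = window[0] - 1
                    hi = max(lo, min(window[1] - read_length, len(hap) - read_length))
                start = int(rng.integers(lo, hi + 1))
                seq = hap[start:start + read_length]
                n_err = rng.binomial(read_length, error_rate)
                if n_err:
                    s = list(seq)
                    for p in rng.choice(read_length, size=n_err, replace=False):
                        cur = s[p]
                        s[p] = str(rng.choice([b for b in "ACGT" if b != cur]))
                    seq = "".join(s)
                counter += 1
                reads.append((f"{read_prefix}{counter:06d}", seq))
    return reads


SHIPPED_PROFILES = [
    dict(id="P1", name="naive-align strict and naive-snv", type_name="reference alignment",
         params={"seed_length": "20", "max_mismatches": "2",
                 "snv_detection_strategy": "naive-snv 1.0",
                 "indel_detection_strategy": "naive-indel 1.0"}),
    dict(id="P2", name="naive-align and naive-snv", type_name="reference alignment",
         params={"seed_length": "16", "max_mismatches": "4",
                 "snv_detection_strategy": "naive-snv 1.0",
                 "indel_detection_strategy": "naive-indel 1.0"}),
    dict(id="P3", name="naive somatic wgs", type_name="somatic variation",
         params={"snv_detection_strategy":
                     "naive-snv 1.0 filtered by depth-filter 1.0 [min_depth=8]",
                 "indel_detection_strategy": "naive-indel 1.0",
                 "cnv_detection_strategy": "naive-cnv 1.0 [window_size=1000]",
                 "sv_detection_strategy":
                     "naive-sv 1.0 filtered by sv-assembly-validate 1.0",
                 "max_normal_vaf": "0.05", "hom_vaf_threshold": "0.9"}),
    dict(id="P4", name="naive somatic wgs, fine-grained SV windows",
         type_name="somatic variation",
         params={"snv_detection_strategy":
                     "naive-snv 1.0 filtered by depth-filter 1.0 [min_depth=8]",
                 "indel_detection_strategy": "naive-indel 1.0",
                 "cnv_detection_strategy": "naive-cnv 1.0 [window_size=1000]",
                 "sv_detection_strategy":
                     "naive-sv 1.0 [window_size=250] filtered by sv-assembly-validate 1.0",
                 "max_normal_vaf": "0.05", "hom_vaf_threshold": "0.9"}),
]

#: instrument-data layout of the demo bundle: (sample, flow cell, lane, index)
DEMO_UNITS = [
    ("tumor", "ABC123", 1, None),
    ("tumor", "ABC123", 2, "AGCT"),
    ("tumor", "ABC123", 2, "TCAG"),
    ("normal", "DEF456", 1, None),
    ("normal", "DEF456", 2, None),
]


def make_bundle(out_dir: str | Path, seed: int = 1, n_chroms: int = 2,
                chrom_length: int = 15000, n_germline: int = 100,
                n_somatic: int = 50, n_loh: int = 10, indel_fraction: float = 0.0,
                tumor_depth: float = 40.0, normal_depth: float = 30.0,
                read_length: int = 100, error_rate: float = 0.005,
                cnv_segments: list[tuple[str, int, int, float]] | None = None
                ) -> TruthSet:
    """Write a complete importable fixture bundle to ``out_dir``.

    Layout: reference.fa, annotation.bed, truth.vcf, truth_cnv.bed,
    reads/*.tsv and metadata.jsonl (patient1 with tumor/normal/relapse
    samples and the shipped processing profiles).
    """
    out = Path(out_dir)
    (out / "reads").mkdir(parents=True, exist_ok=True)
    if cnv_segments is None:
        # a 2x amplification over the middle third of chr1
        cnv_segments = [("chr1", chrom_length // 3 + 1, 2 * chrom_length // 3, 2.0)]

    reference, bed_rows = generate_reference(n_chroms, chrom_length, seed=seed)
    write_fasta(reference, out / "reference.fa")
    with open(out / "annotation.bed", "w", encoding="ascii", newline="\n") as fh:
        for chrom, s0, e0, name in bed_rows:
            fh.write(f"{chrom}\t{s0}\t{e0}\t{name}\n")

    normal, tumor, truth = plant_variants(
        reference, n_germline=n_germline, n_somatic=n_somatic,
        indel_fraction=indel_fraction, n_loh=n_loh, seed=seed + 1)
    truth.cnv_segments = [(c, s, e, math.log2(f)) for c, s, e, f in cnv_segments]
    _write_truth(truth, out)

    tumor_reads = simulate_reads(tumor, tumor_depth, read_length, error_rate,
                                 seed=seed + 2, read_prefix="t",
                                 depth_multipliers=cnv_segments)
    normal_reads = simulate_reads(normal, normal_depth, read_length, error_rate,
                                  seed=seed + 3, read_prefix="n")

    by_sample = {"tumor": tumor_reads, "normal": normal_reads}
    unit_files: list[tuple[dict, str, int]] = []
    for sample_name in ("tumor", "normal"):
        units = [u for u in DEMO_UNITS if u[0] == sample_name]
        reads = by_sample[sample_name]
        per = len(reads) // len(units)
        for j, (_, fc, lane, index) in enumerate(units):
            chunk = reads[j * per:] if j == len(units) - 1 else reads[j * per:(j + 1) * per]
            fname = f"reads/{sample_name}_{j + 1}.tsv"
            write_reads_tsv(chunk, out / fname)
            unit_files.append(({"flow_cell_id": fc, "lane": lane,
                                "index_sequence": index, "sample": sample_name},
                               fname, len(chunk)))

    entities: list[dict] = [
        {"kind": "individual", "id": "IND1", "common_name": "patient1",
         "species": "human"},
        {"kind": "sample", "id": "S1", "common_name": "tumor",
         "individual_id": "IND1", "extraction_type": "dna"},
        {"kind": "sample", "id": "S2", "common_name": "normal",
         "individual_id": "IND1", "extraction_type": "dna"},
        {"kind": "sample", "id": "S3", "common_name": "relapse",
         "individual_id": "IND1", "extraction_type": "dna"},
        {"kind": "reference_sequence", "id": "R1", "name": f"toyref (seed {seed})",
         "fasta_path": str((out / "reference.fa").resolve())},
        {"kind": "annotation", "id": "A1", "name": "toy gene tiling",
         "bed_path": str((out / "annotation.bed").resolve())},
    ]
    sample_ids = {"tumor": "S1", "normal": "S2"}
    for i, (meta, fname, n_reads) in enumerate(unit_files):
        entities.append({"kind": "instrument_data", "id": f"I{i + 1}",
                         "sample_id": sample_ids[meta["sample"]],
                         "flow_cell_id": meta["flow_cell_id"], "lane": meta["lane"],
                         "index_sequence": meta["index_sequence"],
                         "read_path": str((out / fname).resolve()),
                         "read_count": n_reads})
    for prof in SHIPPED_PROFILES:
        entities.append(dict(prof, kind="processing_profile"))

    with open(out / "metadata.jsonl", "w", encoding="ascii", newline="\n") as fh:
        for ent in entities:
            fh.write(json.dumps(ent, sort_keys=True) + "\n")
    with open(out / "bundle.json", "w", encoding="ascii", newline="\n") as fh:
        json.dump({"seed": seed, "tumor_depth": tumor_depth,
                   "normal_depth": normal_depth, "read_length": read_length,
                   "error_rate": error_rate, "n_germline": n_germline,
                   "n_somatic": n_somatic, "n_loh": n_loh,
                   "indel_fraction": indel_fraction,
                   "cnv_segments": cnv_segments}, fh, indent=1, sort_keys=True)
    return truth


def _write_truth(truth: TruthSet, out: Path) -> None:
    from .variants import Variant, VariantSet
    from .formats import write_vcf
    records = []
    for v in truth.germline + truth.somatic:
        flags = set()
        if v.somatic:
            flags.add("SOMATIC")
        else:
            flags.add("GERMLINE")
        if v.loh:
            flags.add("LOH")
        records.append(Variant(
            v.chrom, v.pos, v.ref, v.alt, flags=frozenset(flags),
            info=(("NVAF", f"{v.expected_normal_vaf:.2f}"),
                  ("TVAF", f"{v.expected_tumor_vaf:.2f}"),
                  ("ZYG", v.zygosity))))
    write_vcf(VariantSet(records), out / "truth.vcf")
    with open(out / "truth_cnv.bed", "w", encoding="ascii", newline="\n") as fh:
        for chrom, s, e, log2 in truth.cnv_segments:
            fh.write(f"{chrom}\t{s - 1}\t{e}\tlog2={log2:.4f}\n")


def load_truth(bundle_dir: str | Path) -> TruthSet:
    """Reconstruct the truth set from a written bundle."""
    from .formats import read_vcf, read_bed
    truth = TruthSet()
    for v in read_vcf(Path(bundle_dir) / "truth.vcf"):
        info = v.info_dict()
        pv = PlantedVariant(v.chrom, v.pos, v.ref, v.alt,
                            zygosity=info.get("ZYG", "het"),
                            somatic="SOMATIC" in v.flags, loh="LOH" in v.flags,
                            expected_normal_vaf=float(info.get("NVAF", 0)),
                            expected_tumor_vaf=float(info.get("TVAF", 0)))
        (truth.somatic if pv.somatic else truth.germline).append(pv)
    for r in read_bed(Path(bundle_dir) / "truth_cnv.bed"):
        log2 = float(r.alt.split("=", 1)[1])
        truth.cnv_segments.append((r.chrom, r.pos, r.end, log2))
    return truth


def install_bundle(store: MetadataStore, bundle_dir: str | Path) -> int:
    """Import a bundle's metadata into a store."""
    return store.import_snapshot(Path(bundle_dir))
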