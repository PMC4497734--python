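"""Readers/writers for the formats that cross step boundaries.

Dialects are deliberately small and byte-deterministic, because the
build engine's determinism contract hashes every output file:

* **VCF** — a minimal VCF 4.1 subset: fixed header block, columns
  CHROM..INFO, INFO keys DP/AC/VAF plus bare flags (SOMATIC, LOH,
  GERMLINE) and arbitrary ``KEY=value`` annotations.  VAF is printed to
  4 decimals; lines end in LF.  Genotype/FORMAT columns are out of
  scope.
* **BED4** — 0-based half-open intervals; converted to the internal
  1-based inclusive convention on read.
* **FASTA** — read through Biopython, case-folded to upper case.
* **Alignment TSV** — a plain-text dump of toy alignments (the
  desk-scale stand-in for BAM).
"""
from __future__ import annotations

import os
from pathlib import Path

from Bio import SeqIO

from .align import Alignment, cigar_to_string, cigar_from_string
from .variants import Variant, VariantSet

KNOWN_FLAGS = ("GERMLINE", "LOH", "SOMATIC")

VCF_HEADER = (
    "##fileformat=VCFv4.1\n"
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
    '##INFO=<ID=AC,Number=1,Type=Integer,Description="Alt-supporting read count">\n'
    '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">\n'
    '##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Present in tumor, absent in normal">\n'
    '##INFO=<ID=LOH,Number=0,Type=Flag,Description="Loss of heterozygosity">\n'
    '##INFO=<ID=GERMLINE,Number=0,Type=Flag,Description="Germline variant">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


class FormatError(ValueError):
    pass


def _info_string(v: Variant) -> str:
    parts = [f"DP={v.depth}", f"AC={v.alt_count}", f"VAF={v.vaf:.4f}"]
    parts += sorted(v.flags)
    parts += [f"{k}={val}" for k, val in sorted(v.info)]
    return ";".join(parts) if parts else "."


def write_vcf(vs: VariantSet, path: str | Path) -> None:
    lines = [VCF_HEADER]
    for v in vs:
        if v.is_interval:
            raise FormatError(f"interval record {v.chrom}:{v.pos} cannot be written as VCF")
        lines.append(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{_info_string(v)}\n")
    Path(path).write_bytes("".join(lines).encode("ascii"))


def read_vcf(path: str | Path) -> VariantSet:
    out = []
    with open(path, encoding="ascii") as fh:
        saw_header = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(f"{path}:{lineno}: expected 8 columns, got {len(fields)}")
            chrom, pos, _id, ref, alt, _qual, _filt, info = fields[:8]
            try:
                pos_i = int(pos)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad POS {pos!r}") from None
            depth = alt_count = 0
            flags: set[str] = set()
            extra: dict[str, str] = {}
            if info != ".":
                for item in info.split(";"):
                    if "=" in item:
                        k, val = item.split("=", 1)
                        if k == "DP":
                            depth = int(val)
                        elif k == "AC":
                            alt_count = int(val)
                        elif k == "VAF":
                            pass  # derived from DP/AC
                        else:
                            extra[k] = val
                    elif item in KNOWN_FLAGS:
                        flags.add(item)
                    elif item:
                        extra[item] = ""
            out.append(Variant(chrom, pos_i, ref, alt, depth=depth, alt_count=alt_count,
                               flags=frozenset(flags), info=tuple(sorted(extra.items()))))
        if not saw_header:
            raise FormatError(f"{path}: missing #CHROM header line")
    return VariantSet(out)


def write_bed(vs: VariantSet, path: str | Path) -> None:
    """Interval records as BED4 (0-based half-open), name column = label."""
    lines = []
    for v in vs:
        end = v.end if v.end is not None else v.pos
        lines.append(f"{v.chrom}\t{v.pos - 1}\t{end}\t{v.alt}\n")
    Path(path).write_bytes("".join(lines).encode("ascii"))


def read_bed(path: str | Path) -> VariantSet:
    out = []
    with open(path, encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            chrom = fields[0]
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad BED coordinates") from None
            name = fields[3] if len(fields) > 3 else "interval"
            out.append(Variant(chrom, start0 + 1, ".", name, end=end0))
    return VariantSet(out)


def read_variants(path: str | Path, format: str) -> VariantSet:
    if format == "vcf":
        return read_vcf(path)
    if format == "bed":
        return read_bed(path)
    raise FormatError(f"unknown variant format {format!r}")


def write_variants(vs: VariantSet, path: str | Path, format: str) -> None:
    if format == "vcf":
        write_vcf(vs, path)
    elif format == "bed":
        write_bed(vs, path)
    else:
        raise FormatError(f"unknown variant format {format!r}")


def variant_format_for(path: str | Path) -> str:
    return "bed" if str(path).endswith(".bed") else "vcf"


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load reference sequences; upper-cased, duplicate names rejected."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


ALN_COLUMNS = ("read_id", "chrom", "start", "strand", "cigar", "mapq", "sequence")


def write_alignments(alignments: list[Alignment], path: str | Path) -> None:
    lines = ["\t".join(ALN_COLUMNS) + "\n"]
    for a in alignments:
        lines.append(f"{a.read_id}\t{a.chrom}\t{a.start}\t{a.strand}\t"
                     f"{cigar_to_string(a.cigar)}\t{a.mapping_quality}\t{a.sequence}\n")
    Path(path).write_bytes("".join(lines).encode("ascii"))


def read_alignments(path: str | Path) -> list[Alignment]:
    out = []
    with open(path, encoding="ascii") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ALN_COLUMNS:
            raise FormatError(f"{path}: unexpected alignment TSV header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(ALN_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected {len(ALN_COLUMNS)} columns")
            out.append(Alignment(read_id=f[0], chrom=f[1], start=int(f[2]), strand=f[3],
                                 cigar=cigar_from_string(f[4]), mapping_quality=int(f[5]),
                                 sequence=f[6]))
    return out


def read_reads_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Read file: one ``read_id<TAB>sequence`` pair per line."""
    out = []
    with open(path, encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected read_id<TAB>sequence")
            out.append((parts[0], parts[1].upper()))
    return out


def write_reads_tsv(reads: list[tuple[str, str]], path: str | Path) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    Path(path).write_bytes("".join(f"{rid}\t{seq}\n" for rid, seq in reads).encode("ascii"))
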