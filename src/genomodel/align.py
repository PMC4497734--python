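"""Toy seed-and-extend read aligner.

This is a deliberately small, exact, deterministic aligner for
desk-scale synthetic genomes — it is what the shipped ``naive-align``
tool runs.  The algorithm:

1. Index the reference by non-overlapping k-mers of ``seed_length``.
2. For each read, look up seeds at offsets 0, k, 2k, ... (pigeonhole:
   a read with fewer mismatches than seeds always has a clean seed).
3. Score every candidate start position by Hamming distance; keep the
   minimum if it is <= ``max_mismatches``.  Ties are broken by the
   leftmost (chrom, pos) and reported with mapping quality 0; unique
   best hits get mapping quality 60.
4. If no ungapped placement passes, attempt a single-gap alignment by
   anchoring the first and last seed: a consistent offset difference d
   implies one deletion (d>0) or insertion (d<0) of |d| bases, placed
   at the split point that minimizes mismatches (leftmost on ties).

Reads are single-ended and strand "+" only: the synthetic read
simulator emits forward-strand reads, so reverse-complement search is
not needed here.
"""
from __future__ import annotations

from dataclasses import dataclass, field

MAX_GAP = 10

CigarOp = tuple[str, int]   # op in {"M", "I", "D"}


@dataclass
class Alignment:
    read_id: str
    chrom: str
    start: int                      # 1-based inclusive
    strand: str = "+"
    cigar: list[CigarOp] = field(default_factory=list)
    sequence: str = ""
    mapping_quality: int = 60

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"alignment start {self.start} < 1")

    def reference_span(self) -> int:
        return sum(n for op, n in self.cigar if op in ("M", "D"))

    def end(self) -> int:
        """1-based inclusive last reference base covered."""
        return self.start + self.reference_span() - 1


def cigar_to_string(cigar: list[CigarOp]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def cigar_from_string(s: str) -> list[CigarOp]:
    out: list[CigarOp] = []
    num = ""
    for ch in s:
        if ch.isdigit():
            num += ch
        else:
            if not num or ch not in "MID":
                raise ValueError(f"bad CIGAR string {s!r}")
            out.append((ch, int(num)))
            num = ""
    if num:
        raise ValueError(f"bad CIGAR string {s!r}")
    return out


def index_reference(reference: dict[str, str], seed_length: int) -> dict[str, list[tuple[str, int]]]:
    """k-mer -> list of (chrom, 0-based offset), every position."""
    idx: dict[str, list[tuple[str, int]]] = {}
    for chrom in sorted(reference):
        seq = reference[chrom]
        for i in range(len(seq) - seed_length + 1):
            idx.setdefault(seq[i:i + seed_length], []).append((chrom, i))
    return idx


def _hamming(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def _gapped_candidate(read: str, refseq: str, left: int, shift: int,
                      max_mismatches: int) -> tuple[int, list[CigarOp]] | None:
    """One-gap alignment starting at 0-based ``left`` with net reference
    shift ``shift`` (>0 deletion from read / extra ref bases, <0 insertion)."""
    L = len(read)
    gap = abs(shift)
    best = None
    # split point s: read[:s] matches ref[left:left+s]; read[s:] matches shifted tail
    for s in range(1, L):
        if shift > 0:
            tail_ref = refseq[left + s + gap: left + s + gap + (L - s)]
        else:
            tail_ref = refseq[left + s - gap: left + s - gap + (L - s)]
            if s < gap:
                continue
        if len(tail_ref) != L - s:
            continue
        head = read[:s] if shift > 0 else read[:s - gap]
        head_ref = refseq[left: left + len(head)]
        if len(head_ref) != len(head):
            continue
        tail = read[s:]
        mm = _hamming(head, head_ref, max_mismatches) + _hamming(tail, tail_ref, max_mismatches)
        if mm <= max_mismatches and (best is None or mm < best[0]):
            if shift > 0:
                cigar = [("M", s), ("D", gap), ("M", L - s)]
            else:
                cigar = [("M", s - gap), ("I", gap), ("M", L - s)]
            best = (mm, cigar)
            if mm == 0:
                break
    return best


def align_reads(reads: list[tuple[str, str]], reference: dict[str, str],
                seed_length: int = 16, max_mismatches: int = 4,
                index: dict | None = None) -> list[Alignment]:
    """Place each read at its unique best position, or drop it as unmapped."""
    if reads and seed_length > min(len(seq) for _, seq in reads):
        raise ValueError("seed_length exceeds read length")
    if index is None:
        index = index_reference(reference, seed_length)

    alignments: list[Alignment] = []
    for read_id, seq in reads:
        L = len(seq)
        offsets = list(range(0, L - seed_length + 1, seed_length))
        if offsets[-1] != L - seed_length:
            offsets.append(L - seed_length)
        candidates: set[tuple[str, int]] = set()
        for off in offsets:
            for chrom, hit in index.get(seq[off:off + seed_length], ()):
                start0 = hit - off
                if 0 <= start0 <= len(reference[chrom]) - L:
                    candidates.add((chrom, start0))

        best_mm, best_hits = None, []
        for chrom, start0 in sorted(candidates):
            mm = _hamming(seq, reference[chrom][start0:start0 + L], max_mismatches)
            if mm > max_mismatches:
                continue
            if best_mm is None or mm < best_mm:
                best_mm, best_hits = mm, [(chrom, start0)]
            elif mm == best_mm:
                best_hits.append((chrom, start0))

        if best_hits:
            chrom, start0 = min(best_hits)
            mapq = 60 if len(best_hits) == 1 else 0
            alignments.append(Alignment(read_id, chrom, start0 + 1, "+",
                                        [("M", L)], seq, mapq))
            continue

        # single-gap rescue using first/last seed anchors
        gapped = None
        first = {(c, h) for c, h in index.get(seq[:seed_length], ())}
        last_off = L - seed_length
        for c2, h2 in index.get(seq[last_off:], ()):
            for c1, h1 in sorted(first):
                if c1 != c2:
                    continue
                shift = (h2 - last_off) - h1
                if shift == 0 or abs(shift) > MAX_GAP:
                    continue
                cand = _gapped_candidate(seq, reference[c1], h1, shift, max_mismatches)
                if cand and (gapped is None or (cand[0], c1, h1) < (gapped[0], gapped[1], gapped[2])):
                    gapped = (cand[0], c1, h1, cand[1])
        if gapped:
            _, chrom, start0, cigar = gapped
            alignments.append(Alignment(read_id, chrom, start0 + 1, "+", cigar, seq, 60))

    alignments.sort(key=lambda a: (a.chrom, a.start, a.read_id))
    return alignments
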