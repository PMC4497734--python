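"""Genomic variant records and the callset algebra.

A :class:`Variant` is a single called event on the internal coordinate
convention (1-based, inclusive).  Point variants (SNVs, small indels)
carry explicit ref/alt alleles; interval records (SV/CNV candidates)
carry a label in ``alt`` and an inclusive ``end``.

:class:`VariantSet` is the currency that flows between detection,
filtering and combination steps.  Union/intersection of two callsets is
defined by a *matching policy*: allele-aware identity for point
variants, reciprocal overlap for intervals.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

INTERNAL_CONVENTION = "1-based-inclusive"

#: reciprocal-overlap fraction two intervals must share to be "the same" event
RECIPROCAL_OVERLAP = 0.5


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int                     # 1-based position (interval start for intervals)
    ref: str
    alt: str
    depth: int = 0
    alt_count: int = 0
    end: int | None = None       # 1-based inclusive end; interval records only
    flags: frozenset[str] = frozenset()
    info: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.alt_count < 0 or (self.depth and self.alt_count > self.depth):
            raise ValueError(f"alt_count {self.alt_count} outside [0, depth={self.depth}]")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position {self.pos} not 1-based")

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def is_interval(self) -> bool:
        return self.end is not None

    def key(self) -> tuple:
        """Allele-aware identity key (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def sort_key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt, self.end or 0)

    def with_flags(self, *names: str) -> "Variant":
        return replace(self, flags=self.flags | frozenset(names))

    def with_info(self, **kv: str) -> "Variant":
        d = dict(self.info)
        d.update({k: str(v) for k, v in kv.items()})
        return replace(self, info=tuple(sorted(d.items())))

    def info_dict(self) -> dict[str, str]:
        return dict(self.info)


@dataclass
class VariantSet:
    """An ordered (sorted) collection of variants on one coordinate convention."""

    variants: list[Variant] = field(default_factory=list)
    convention: str = INTERNAL_CONVENTION

    def __post_init__(self):
        self.variants = sorted(self.variants, key=Variant.sort_key)

    def __len__(self):
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def __eq__(self, other):
        return (isinstance(other, VariantSet)
                and self.convention == other.convention
                and self.variants == other.variants)

    def keys(self) -> set[tuple]:
        return {v.key() for v in self.variants}

    def get(self, key: tuple) -> Variant | None:
        for v in self.variants:
            if v.key() == key:
                return v
        return None


def _interval_span(v: Variant) -> tuple[int, int]:
    return (v.pos, v.end if v.end is not None else v.pos)


def _intervals_match(a: Variant, b: Variant) -> bool:
    """Same chromosome + label, reciprocal overlap >= RECIPROCAL_OVERLAP."""
    if a.chrom != b.chrom or a.alt != b.alt:
        return False
    a0, a1 = _interval_span(a)
    b0, b1 = _interval_span(b)
    ov = min(a1, b1) - max(a0, b0) + 1
    if ov <= 0:
        return False
    return ov >= RECIPROCAL_OVERLAP * (a1 - a0 + 1) and ov >= RECIPROCAL_OVERLAP * (b1 - b0 + 1)


def _match(a: Variant, b: Variant, matching: str) -> bool:
    if matching == "allele":
        return a.key() == b.key()
    if matching == "interval":
        return _intervals_match(a, b)
    raise ValueError(f"unknown matching policy {matching!r}")


def _merge(left: Variant, right: Variant) -> Variant:
    """Merge metadata left-priority: keep left's counts/info, union flags."""
    return replace(left, flags=left.flags | right.flags)


def combine_variant_sets(op: str, left: VariantSet, right: VariantSet,
                         matching: str = "allele") -> VariantSet:
    """Union or intersect two callsets under a matching policy.

    ``union`` keeps every event present in either set, deduplicated under
    the policy with left-priority metadata merging.  ``intersect`` keeps
    left events that have a match in the right set.  Output is sorted.
    """
    if left.convention != right.convention:
        raise ValueError(
            f"mixed coordinate conventions: {left.convention!r} vs {right.convention!r}")
    if op not in ("union", "intersect"):
        raise ValueError(f"unknown combine op {op!r}")

    if matching == "allele":
        rmap = {v.key(): v for v in right.variants}
        if op == "intersect":
            out = [_merge(v, rmap[v.key()]) for v in left.variants if v.key() in rmap]
        else:
            lkeys = {v.key() for v in left.variants}
            out = [(_merge(v, rmap[v.key()]) if v.key() in rmap else v)
                   for v in left.variants]
            out += [v for v in right.variants if v.key() not in lkeys]
    else:
        if op == "intersect":
            out = []
            for v in left.variants:
                m = next((r for r in right.variants if _match(v, r, matching)), None)
                if m is not None:
                    out.append(_merge(v, m))
        else:
            out = []
            for v in left.variants:
                m = next((r for r in right.variants if _match(v, r, matching)), None)
                out.append(_merge(v, m) if m is not None else v)
            for r in right.variants:
                if not any(_match(r, v, matching) for v in left.variants):
                    out.append(r)
    return VariantSet(out, convention=left.convention)
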