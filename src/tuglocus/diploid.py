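"""Strain-specific (diploid) genome and transcriptome construction.

A haploid reference plus a table of strain variants (SNPs and short indels)
yields a personalized genome for each parental strain, together with a
piecewise-linear coordinate map that lifts annotation from reference to
personalized coordinates.  Multi-source annotation sets are merged with
biotype filtering and a same-strand exonic-overlap rule.

All internal coordinates are 0-based, half-open.  Variant TSV input is
1-based and converted on load.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Variant:
    """One substitution or indel: ``ref`` replaced by ``alt`` at ``pos`` (0-based)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    strain: str

    @property
    def end(self) -> int:
        return self.pos + len(self.ref)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


class VariantTable:
    """Sorted, per-strain non-overlapping variant records on a haploid reference."""

    def __init__(self, variants: list[Variant], reference: dict[str, str] | None = None):
        self.variants = sorted(variants, key=lambda v: (v.chrom, v.pos, v.strain))
        for v in self.variants:
            if v.ref == v.alt:
                raise ValueError(f"variant at {v.chrom}:{v.pos + 1} has ref == alt")
        # no two records overlap on the same strain
        last: dict[tuple[str, str], int] = {}
        for v in self.variants:
            key = (v.strain, v.chrom)
            if key in last and v.pos < last[key]:
                raise ValueError(
                    f"overlapping variants on strain {v.strain} at {v.chrom}:{v.pos + 1}"
                )
            last[key] = v.end
        if reference is not None:
            self.validate(reference)

    def validate(self, reference: dict[str, str]) -> None:
        """Check every ref allele against the reference sequence (hard error)."""
        for v in self.variants:
            if v.chrom not in reference:
                raise ValueError(f"variant on unknown chromosome {v.chrom}")
            seq = reference[v.chrom]
            if seq[v.pos : v.pos + len(v.ref)] != v.ref:
                raise ValueError(
                    f"ref-allele mismatch at {v.chrom}:{v.pos + 1}: "
                    f"expected {v.ref!r}, reference has {seq[v.pos:v.pos + len(v.ref)]!r}"
                )

    def for_strain(self, strain: str) -> list[Variant]:
        return [v for v in self.variants if v.strain == strain]

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)


@dataclass
class CoordinateMap:
    """Piecewise-linear liftover map: blocks of (src_start, src_end, offset) per chromosome.

    Positions inside a block map to ``pos + offset``; positions falling in a
    gap between blocks (bases deleted in the target) are unmapped (``None``).
    """

    blocks: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)

    @classmethod
    def identity(cls, lengths: dict[str, int]) -> "CoordinateMap":
        return cls({c: [(0, n, 0)] for c, n in lengths.items()})

    def map_position(self, chrom: str, pos: int) -> int | None:
        if chrom not in self.blocks:
            raise KeyError(f"unknown chromosome {chrom}")
        blocks = self.blocks[chrom]
        i = bisect.bisect_right(blocks, pos, key=lambda b: b[0]) - 1
        if i < 0:
            return None
        s, e, off = blocks[i]
        if s <= pos < e:
            return pos + off
        return None

    def map_interval(self, chrom: str, start: int, end: int) -> tuple[int, int] | None:
        """Map a half-open interval by its boundary bases; None if either is deleted."""
        a = self.map_position(chrom, start)
        b = self.map_position(chrom, end - 1)
        if a is None or b is None:
            return None
        return a, b + 1

    def inverse(self) -> "CoordinateMap":
        inv: dict[str, list[tuple[int, int, int]]] = {}
        for chrom, blocks in self.blocks.items():
            inv[chrom] = [(s + off, e + off, -off) for s, e, off in blocks]
            inv[chrom].sort()
        return CoordinateMap(inv)


@dataclass(frozen=True)
class Transcript:
    """A transcript model: ordered half-open exons on one strand."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "protein_coding"
    locus: str | None = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def sequence(self, genome: dict[str, str]) -> str:
        seq = "".join(genome[self.chrom][s:e] for s, e in self.exons)
        return reverse_complement(seq) if self.strand == "-" else seq


def apply_variants(
    reference: dict[str, str], variants: VariantTable, strain: str
) -> tuple[dict[str, str], CoordinateMap]:
    """Substitute SNPs and apply indels for one strain; return sequences + liftover map.

    The coordinate map records, for every reference base not deleted in the
    personalized sequence, its new position.  Net sequence-length change per
    chromosome equals the net indel length.
    """
    variants.validate(reference)
    out: dict[str, str] = {}
    cmap = CoordinateMap()
    selected = variants.for_strain(strain)
    by_chrom: dict[str, list[Variant]] = {}
    for v in selected:
        by_chrom.setdefault(v.chrom, []).append(v)
    for chrom, seq in reference.items():
        if len(seq) == 0:
            raise ValueError(f"zero-length reference sequence {chrom}")
        pieces: list[str] = []
        blocks: list[tuple[int, int, int]] = []
        cursor = 0  # reference position up to which output is built
        offset = 0
        block_start = 0
        for v in by_chrom.get(chrom, []):
            pieces.append(seq[cursor : v.pos])
            pieces.append(v.alt)
            r, a = len(v.ref), len(v.alt)
            if r != a:
                # aligned prefix of min(r, a) bases keeps the current offset;
                # for deletions the remaining ref bases are unmapped
                aligned_end = v.pos + min(r, a)
                if aligned_end > block_start:
                    blocks.append((block_start, aligned_end, offset))
                offset += a - r
                block_start = v.pos + r
            cursor = v.end
        pieces.append(seq[cursor:])
        if len(seq) > block_start:
            blocks.append((block_start, len(seq), offset))
        out[chrom] = "".join(pieces)
        cmap.blocks[chrom] = blocks
    return out, cmap


def lift_annotation(transcripts: list[Transcript], cmap: CoordinateMap) -> list[Transcript]:
    """Shift exon boundaries through a coordinate map.

    Transcripts with any exon boundary falling inside a deleted span are
    dropped with a logged warning (the feature cannot be represented on the
    personalized sequence without arbitrary truncation).
    """
    lifted: list[Transcript] = []
    for tx in transcripts:
        new_exons = []
        ok = True
        for s, e in tx.exons:
            mapped = cmap.map_interval(tx.chrom, s, e)
            if mapped is None:
                ok = False
                break
            new_exons.append(mapped)
        if not ok:
            logger.warning(
                "dropping %s: exon boundary falls in a deleted span", tx.transcript_id
            )
            continue
        lifted.append(replace(tx, exons=tuple(new_exons)))
    return lifted


def _exonic_overlap(tx: Transcript, index: dict[tuple[str, str], list[tuple[int, int]]]) -> bool:
    """>=1 bp same-strand exonic overlap against an accumulated exon index."""
    key = (tx.chrom, tx.strand)
    if key not in index:
        return False
    intervals = index[key]  # sorted by start
    starts = [iv[0] for iv in intervals]
    for s, e in tx.exons:
        # candidates start before e; overlap iff any of them ends after s
        i = bisect.bisect_left(starts, e)
        for j in range(i):
            if intervals[j][1] > s:
                return True
    return False


def merge_annotations(
    primary: list[Transcript],
    additions: list[list[Transcript]],
    excluded_biotypes: set[str] = frozenset(),
) -> list[Transcript]:
    """Biotype-filter the primary set, then add non-overlapping transcripts in order.

    From each addition set, a transcript enters the merged set only if it has
    no same-strand exonic overlap (>= 1 bp) with anything already merged,
    mirroring the "not represented / did not intersect" accretion of multiple
    annotation sources.  Biotype filtering is applied to the primary set
    before overlap testing.
    """
    merged = [t for t in primary if t.biotype not in excluded_biotypes]
    index: dict[tuple[str, str], list[tuple[int, int]]] = {}

    def _add_to_index(tx: Transcript) -> None:
        key = (tx.chrom, tx.strand)
        lst = index.setdefault(key, [])
        for iv in tx.exons:
            bisect.insort(lst, iv)

    for tx in merged:
        _add_to_index(tx)
    for addition in additions:
        for tx in addition:
            if not _exonic_overlap(tx, index):
                merged.append(tx)
                _add_to_index(tx)
    return merged
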