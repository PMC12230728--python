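"""Apply phased variants to a reference chromosome; allelic FASTA + liftover.

A haplotype sequence is the left-to-right splice of reference segments and
ALT alleles.  The coordinate map records the collinear segments so site
coordinates can be lifted between the haplotype frame and the reference
frame.  Conventions:

* substituted spans of equal length (SNVs, MNPs) stay collinear — the map
  answers "where", not "what";
* an indel's shared anchor base is collinear, only the inserted/deleted
  tail is not;
* positions inside inserted sequence have no reference image and deleted
  reference positions have no haplotype image (both map to ``None``).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .variants import HaplotypeVariantSet, VariantRecord


class CoordinateMap:
    """Invertible partial map between reference and haplotype coordinates.

    Stored as sorted collinear blocks ``(ref_start, hap_start, length)``,
    non-overlapping and strictly increasing in both frames.
    """

    def __init__(self, blocks: list[tuple[int, int, int]], edits: list[VariantRecord] | None = None):
        self.blocks = [b for b in blocks if b[2] > 0]
        self.edits = list(edits or [])
        self._ref_starts = [b[0] for b in self.blocks]
        self._hap_starts = [b[1] for b in self.blocks]
        for prev, cur in zip(self.blocks, self.blocks[1:]):
            if cur[0] < prev[0] + prev[2] or cur[1] < prev[1] + prev[2]:
                raise ValueError("coordinate map blocks overlap or are unsorted")

    @classmethod
    def identity(cls, length: int) -> "CoordinateMap":
        return cls([(0, 0, length)])

    def to_reference(self, hap_pos: int) -> int | None:
        """Reference coordinate of a haplotype position, or None if inserted."""
        if hap_pos < 0:
            raise ValueError(f"haplotype position {hap_pos} out of range")
        i = bisect_right(self._hap_starts, hap_pos) - 1
        if i < 0:
            return None
        ref_start, hap_start, length = self.blocks[i]
        off = hap_pos - hap_start
        return ref_start + off if off < length else None

    def from_reference(self, ref_pos: int) -> int | None:
        """Haplotype coordinate of a reference position, or None if deleted."""
        if ref_pos < 0:
            raise ValueError(f"reference position {ref_pos} out of range")
        i = bisect_right(self._ref_starts, ref_pos) - 1
        if i < 0:
            return None
        ref_start, hap_start, length = self.blocks[i]
        off = ref_pos - ref_start
        return hap_start + off if off < length else None


@dataclass
class HaplotypeSequence:
    """One reconstructed allelic chromosome plus its coordinate map."""

    label: str
    chrom: str
    seq: str
    coord_map: CoordinateMap


def build_haplotype(
    ref_seq: str,
    variants: HaplotypeVariantSet,
    chrom: str | None = None,
) -> HaplotypeSequence:
    """Splice *variants* into *ref_seq*, producing sequence + coordinate map.

    Variants must be sorted, non-overlapping, and reference-matching (the
    mismatch guard catches a wrong FASTA/VCF pairing).  Length conservation
    is asserted after the build.
    """
    chrom = chrom or (variants.variants[0].chrom if variants.variants else "?")
    parts: list[str] = []
    blocks: list[tuple[int, int, int]] = []
    r = 0  # reference cursor
    h = 0  # haplotype cursor
    for v in variants.variants:
        if v.pos < r:
            raise ValueError(
                f"variant at {v.chrom}:{v.pos} (line {v.source_line}) overlaps the previous variant"
            )
        observed = ref_seq[v.pos : v.pos + len(v.ref_allele)]
        if observed != v.ref_allele:
            raise ValueError(
                f"reference mismatch at {v.chrom}:{v.pos} (line {v.source_line}): "
                f"VCF REF {v.ref_allele!r} vs reference {observed!r} — wrong FASTA/VCF pairing?"
            )
        # intervening collinear reference segment
        seg = v.pos - r
        parts.append(ref_seq[r : v.pos])
        if seg:
            blocks.append((r, h, seg))
        r, h = v.pos, h + seg
        # the substituted/anchored prefix of the edit stays collinear
        lr, la = len(v.ref_allele), len(v.alt_allele)
        parts.append(v.alt_allele)
        anchored = min(lr, la)
        blocks.append((r, h, anchored))
        r += lr
        h += la
    parts.append(ref_seq[r:])
    if len(ref_seq) - r:
        blocks.append((r, h, len(ref_seq) - r))
    seq = "".join(parts)

    expected = len(ref_seq) + sum(
        len(v.alt_allele) - len(v.ref_allele) for v in variants.variants
    )
    assert len(seq) == expected, "length conservation violated"
    return HaplotypeSequence(
        label=variants.haplotype_label,
        chrom=chrom,
        seq=seq,
        coord_map=CoordinateMap(blocks, edits=list(variants.variants)),
    )


def map_to_reference(m: CoordinateMap, hap_pos: int) -> int | None:
    return m.to_reference(hap_pos)


def map_from_reference(m: CoordinateMap, ref_pos: int) -> int | None:
    return m.from_reference(ref_pos)


def allelic_record_name(chrom: str, label: str) -> str:
    """FASTA header for one allelic chromosome: ``<chrom>_<label>``.

    The final ``_allele<k>`` suffix is the delimiter, so chromosome names
    containing underscores remain unambiguous.
    """
    return f"{chrom}_{label}"


def parse_allelic_record_name(name: str) -> tuple[str, str]:
    """Invert :func:`allelic_record_name` on the final ``_allele<k>`` suffix."""
    chrom, sep, label = name.rpartition("_")
    if not sep or not label.startswith("allele"):
        raise ValueError(f"not an allelic record name: {name!r}")
    return chrom, label


def write_allelic_fasta(haps: list[HaplotypeSequence], path: str | Path) -> Path:
    """Write one FASTA record per chromosome per haplotype, 60-column wrapped."""
    path = Path(path)
    records = [
        SeqRecord(Seq(h.seq), id=allelic_record_name(h.chrom, h.label), description="")
        for h in haps
    ]
    with open(path, "w") as fh:
        seqio_write(records, fh, "fasta")
    return path
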