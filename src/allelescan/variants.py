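"""Phased single-sample VCF handling: parsing, decomposition, normalization.

The pipeline canonicalizes every record into per-haplotype *allelic
primitives*:

1. ``parse_vcf`` reads records for one sample and enforces phasing and a
   constant ploidy;
2. ``split_multiallelic`` gives each haplotype exactly the ALT its
   genotype index selects;
3. ``decompose_primitives`` splits MNPs and complex substitutions into
   SNVs plus at most one indel by end-anchored REF/ALT alignment;
4. ``normalize_left_align`` produces the parsimonious, leftmost-aligned
   representation of each edit.

All coordinates are 0-based half-open internally; the 1-based VCF POS is
converted once, at the parser boundary.  Because the internal
representation is per-haplotype, no multi-allelic re-merge step is
needed afterwards — an intentional simplification.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from cyvcf2 import VCF

logger = logging.getLogger(__name__)

_DNA = frozenset("ACGTN")


class VcfInputError(ValueError):
    """Invalid or unsupported VCF content."""


@dataclass(frozen=True)
class VariantRecord:
    """One normalized, per-haplotype applicable variant.

    ``pos`` is the 0-based reference coordinate of the first REF base.
    Alleles are uppercase, non-empty (indels carry one shared anchor
    base).  ``source_line`` is the 1-based record index in the VCF body,
    kept for diagnostics.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    source_line: int = 0

    def __post_init__(self):
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("empty alleles are forbidden after canonicalization")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele must differ from alt_allele")

    @property
    def end(self) -> int:
        """Reference end (exclusive) of the replaced interval."""
        return self.pos + len(self.ref_allele)


@dataclass(frozen=True)
class PhasedGenotype:
    """Ordered per-haplotype allele indices (0 = REF, k = k-th ALT)."""

    allele_indices: tuple[int, ...]
    phased: bool

    @property
    def ploidy(self) -> int:
        return len(self.allele_indices)


@dataclass(frozen=True)
class RawVariant:
    """One VCF record (possibly multiallelic) for the chosen sample."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    genotype: PhasedGenotype
    source_line: int
    filter: Optional[str] = None  # None == PASS/'.'


@dataclass
class HaplotypeVariantSet:
    """All variants applicable to one haplotype, sorted, non-overlapping."""

    haplotype_label: str
    variants: list[VariantRecord] = field(default_factory=list)


@dataclass
class ParseStats:
    """Counted warnings so skipped records are never silently lost."""

    skipped: Counter = field(default_factory=Counter)

    def warn(self, reason: str, message: str) -> None:
        self.skipped[reason] += 1
        logger.warning(message)

    def summary(self) -> str:
        if not self.skipped:
            return "no records skipped"
        parts = ", ".join(f"{k}={v}" for k, v in sorted(self.skipped.items()))
        return f"records skipped: {parts}"


def _is_symbolic(alt: str) -> bool:
    return alt.startswith("<") or "[" in alt or "]" in alt or alt in ("*", ".")


def parse_vcf(
    path: str | Path,
    sample: Optional[str] = None,
    assume_phased: bool = False,
    pass_only: bool = False,
    stats: Optional[ParseStats] = None,
) -> tuple[list[RawVariant], ParseStats]:
    """Read phased genotype records for one sample from a VCF (plain or bgzip).

    Records with missing alleles ('.') are dropped with a counted warning.
    Unphased heterozygous genotypes raise unless *assume_phased*; ploidy is
    inferred from the first genotype and enforced thereafter.
    """
    stats = stats if stats is not None else ParseStats()
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise VcfInputError(f"{path}: VCF has no samples")
    if sample is None:
        if len(samples) > 1:
            raise VcfInputError(
                f"{path}: multi-sample VCF; choose one of {samples} with --sample"
            )
        sample_idx = 0
    else:
        if sample not in samples:
            raise VcfInputError(f"{path}: sample {sample!r} not in {samples}")
        sample_idx = samples.index(sample)

    records: list[RawVariant] = []
    ploidy: Optional[int] = None
    for line_no, v in enumerate(vcf, start=1):
        gt = v.genotypes[sample_idx]
        alleles, phased = tuple(gt[:-1]), bool(gt[-1])
        if ploidy is None:
            ploidy = len(alleles)
        elif len(alleles) != ploidy:
            raise VcfInputError(
                f"{path} record {line_no}: ploidy changed from {ploidy} to {len(alleles)}"
            )
        if any(a < 0 for a in alleles):
            stats.warn(
                "missing_genotype",
                f"record {line_no} at {v.CHROM}:{v.POS}: missing genotype, dropped",
            )
            continue
        if not phased and not assume_phased and len(alleles) > 1:
            raise VcfInputError(
                f"{path} record {line_no} at {v.CHROM}:{v.POS}: unphased genotype "
                "(use assume-phased to override)"
            )
        if pass_only and v.FILTER is not None:  # cyvcf2: None == PASS or '.'
            stats.warn(
                "filtered",
                f"record {line_no} at {v.CHROM}:{v.POS}: FILTER={v.FILTER}, dropped",
            )
            continue
        records.append(
            RawVariant(
                chrom=v.CHROM,
                pos=v.POS - 1,
                ref=v.REF.upper(),
                alts=tuple(a.upper() for a in v.ALT),
                genotype=PhasedGenotype(alleles, phased),
                source_line=line_no,
                filter=v.FILTER,
            )
        )
    return records, stats


def split_multiallelic(
    record: RawVariant,
    genotype: Optional[PhasedGenotype] = None,
    stats: Optional[ParseStats] = None,
) -> list[Optional[tuple[int, str, str]]]:
    """Per-haplotype (pos, REF, ALT) assignment selected by the genotype.

    Index 0 (reference allele) yields ``None`` for that haplotype.
    Symbolic ALTs (structural variants, breakends, spanning deletions) are
    skipped with a counted warning — small-variant scope only.
    """
    gt = genotype or record.genotype
    out: list[Optional[tuple[int, str, str]]] = []
    for idx in gt.allele_indices:
        if idx == 0:
            out.append(None)
            continue
        if idx > len(record.alts):
            raise VcfInputError(
                f"record {record.source_line} at {record.chrom}:{record.pos + 1}: "
                f"genotype index {idx} exceeds ALT count {len(record.alts)}"
            )
        alt = record.alts[idx - 1]
        if _is_symbolic(alt):
            if stats is not None:
                stats.warn(
                    "symbolic_alt",
                    f"record {record.source_line} at {record.chrom}:{record.pos + 1}: "
                    f"symbolic ALT {alt!r} skipped (structural variants unsupported)",
                )
            out.append(None)
            continue
        out.append((record.pos, record.ref, alt))
    return out


def _decompose_pair(pos: int, ref: str, alt: str) -> list[tuple[int, str, str]]:
    """End-anchored decomposition of one REF/ALT pair into primitives.

    Shared suffix then prefix are trimmed (each allele keeps >= 1 base);
    equal-length remainders become per-position SNVs; unequal remainders
    stay as a single indel / block substitution.
    """
    if ref == alt:
        return []
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if len(ref) == len(alt):
        return [
            (pos + i, r, a) for i, (r, a) in enumerate(zip(ref, alt)) if r != a
        ]
    return [(pos, ref, alt)]


def decompose_primitives(record: RawVariant) -> list[RawVariant]:
    """Split an MNP or complex substitution into primitive records.

    Requires a biallelic record (run :func:`split_multiallelic` first);
    the genotype column is carried to every product record.
    """
    if len(record.alts) != 1:
        raise VcfInputError(
            f"record {record.source_line}: decompose_primitives requires a "
            "biallelic record; split multiallelic records first"
        )
    alt = record.alts[0]
    if _is_symbolic(alt):
        raise VcfInputError(
            f"record {record.source_line}: symbolic ALT {alt!r} cannot be decomposed"
        )
    _check_dna(record.ref, record.source_line)
    _check_dna(alt, record.source_line)
    return [
        RawVariant(
            chrom=record.chrom,
            pos=p,
            ref=r,
            alts=(a,),
            genotype=record.genotype,
            source_line=record.source_line,
            filter=record.filter,
        )
        for (p, r, a) in _decompose_pair(record.pos, record.ref, alt)
    ]


def _check_dna(s: str, line_no: int) -> None:
    bad = set(s) - _DNA
    if bad:
        raise VcfInputError(
            f"record {line_no}: non-ACGTN allele character(s) {sorted(bad)}"
        )


def normalize_left_align(v: VariantRecord, ref_seq: str) -> VariantRecord:
    """Parsimonious, leftmost-aligned representation of one variant.

    Shared suffix is trimmed, indels are shifted left while the edit stays
    sequence-equivalent, then the shared prefix is trimmed down to the
    anchor base.  SNVs are fixed points; the operation is idempotent.
    """
    pos, ref, alt = v.pos, v.ref_allele, v.alt_allele
    if pos < 0 or pos + len(ref) > len(ref_seq):
        raise ValueError(
            f"variant at {v.chrom}:{pos} (line {v.source_line}) outside chromosome bounds"
        )
    if ref_seq[pos : pos + len(ref)] != ref:
        raise ValueError(
            f"variant at {v.chrom}:{pos} (line {v.source_line}): REF does not match reference"
        )
    if len(ref) == len(alt):
        while len(ref) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        while len(ref) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
    else:
        while True:
            if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
                ref, alt = ref[:-1], alt[:-1]
            elif ref[-1] == alt[-1] and pos > 0:
                base = ref_seq[pos - 1]
                ref, alt = base + ref[:-1], base + alt[:-1]
                pos -= 1
            else:
                break
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
    return VariantRecord(
        chrom=v.chrom, pos=pos, ref_allele=ref, alt_allele=alt, source_line=v.source_line
    )


def build_haplotype_sets(
    per_haplotype: Sequence[Sequence[VariantRecord]],
    labels: Optional[Sequence[str]] = None,
    strict: bool = True,
    stats: Optional[ParseStats] = None,
) -> list[HaplotypeVariantSet]:
    """Assemble sorted, overlap-checked variant sets, one per haplotype.

    Overlapping variants within a haplotype raise in strict mode (listing
    both source lines); otherwise the first is kept and the rest skipped
    with counted warnings.
    """
    labels = list(labels) if labels else [f"allele{i + 1}" for i in range(len(per_haplotype))]
    sets: list[HaplotypeVariantSet] = []
    for label, variants in zip(labels, per_haplotype):
        ordered = sorted(variants, key=lambda v: (v.chrom, v.pos, v.end))
        kept: list[VariantRecord] = []
        for v in ordered:
            prev = kept[-1] if kept and kept[-1].chrom == v.chrom else None
            if prev is not None and v.pos < prev.end:
                msg = (
                    f"{label}: variants overlap on {v.chrom} "
                    f"(lines {prev.source_line} and {v.source_line}, "
                    f"positions {prev.pos}-{prev.end} and {v.pos}-{v.end})"
                )
                if strict:
                    raise VcfInputError(msg)
                if stats is not None:
                    stats.warn("overlap_skipped", msg + " — later variant skipped")
                continue
            kept.append(v)
        sets.append(HaplotypeVariantSet(haplotype_label=label, variants=kept))
    return sets


def haplotype_sets_from_vcf(
    path: str | Path,
    reference: Mapping[str, str],
    sample: Optional[str] = None,
    assume_phased: bool = False,
    pass_only: bool = False,
    strict_overlaps: bool = True,
) -> tuple[list[HaplotypeVariantSet], ParseStats]:
    """Full canonicalization: parse, split, decompose, normalize, assemble.

    *reference* maps chromosome name to its uppercase sequence; chromosomes
    absent from it raise (wrong FASTA/VCF pairing guard).
    """
    records, stats = parse_vcf(
        path, sample=sample, assume_phased=assume_phased, pass_only=pass_only
    )
    ploidy = records[0].genotype.ploidy if records else 2
    per_hap: list[list[VariantRecord]] = [[] for _ in range(ploidy)]
    for rec in records:
        if rec.chrom not in reference:
            raise VcfInputError(
                f"record {rec.source_line}: chromosome {rec.chrom!r} absent from reference FASTA"
            )
        ref_seq = reference[rec.chrom]
        assignments = split_multiallelic(rec, stats=stats)
        for hap_idx, assignment in enumerate(assignments):
            if assignment is None:
                continue
            pos, ref, alt = assignment
            biallelic = RawVariant(
                chrom=rec.chrom,
                pos=pos,
                ref=ref,
                alts=(alt,),
                genotype=rec.genotype,
                source_line=rec.source_line,
                filter=rec.filter,
            )
            for prim in decompose_primitives(biallelic):
                v = VariantRecord(
                    chrom=prim.chrom,
                    pos=prim.pos,
                    ref_allele=prim.ref,
                    alt_allele=prim.alts[0],
                    source_line=prim.source_line,
                )
                per_hap[hap_idx].append(normalize_left_align(v, ref_seq))
    sets = build_haplotype_sets(per_hap, strict=strict_overlaps, stats=stats)
    return sets, stats
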