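"""End-to-end orchestration: VCF + FASTA + guides -> hits, counts, report.

Stages: parse -> decompose -> split -> normalize -> build haplotypes ->
scan the reference and every allele -> compare -> write TSVs.  With no
VCF the run degrades to plain reference-only off-target finding.
Chromosomes absent from the VCF pass through verbatim with identity
coordinate maps, so every chromosome is scanned on every allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from pyfaidx import Fasta

from .compare import REFERENCE_LABEL, ComparisonReport, classify_sites, summarize_per_chromosome
from .reconstruct import (
    CoordinateMap,
    HaplotypeSequence,
    allelic_record_name,
    build_haplotype,
    parse_allelic_record_name,
    write_allelic_fasta,
)
from .search import GuideQuery, OffTargetHit, scan_sequence
from .variants import HaplotypeVariantSet, ParseStats, haplotype_sets_from_vcf

logger = logging.getLogger(__name__)


def load_reference(path: str | Path) -> dict[str, str]:
    """Read a (possibly bgzipped) FASTA into uppercase sequences.

    Soft-masked lowercase bases are uppercased on load; search semantics
    are case-insensitive and masking is not preserved.
    """
    fasta = Fasta(str(path), sequence_always_upper=True)
    return {name: str(fasta[name][:]) for name in fasta.keys()}


@dataclass
class PipelineResult:
    labels: list
    # label -> list of (chrom, hit); hit positions in that sequence's frame
    hits_by_label: dict
    report: ComparisonReport
    count_table: pd.DataFrame
    haplotypes: list  # list[HaplotypeSequence]
    stats: ParseStats

    def all_hits(self) -> list[OffTargetHit]:
        return [h for pairs in self.hits_by_label.values() for _, h in pairs]


def reconstruct_haplotypes(
    reference: Mapping[str, str],
    hap_sets: Sequence[HaplotypeVariantSet],
) -> list[HaplotypeSequence]:
    """Build every allelic chromosome (identity where the VCF is silent)."""
    haps = []
    for hs in hap_sets:
        by_chrom: dict[str, list] = {}
        for v in hs.variants:
            by_chrom.setdefault(v.chrom, []).append(v)
        for chrom, ref_seq in reference.items():
            subset = HaplotypeVariantSet(hs.haplotype_label, by_chrom.get(chrom, []))
            haps.append(build_haplotype(ref_seq, subset, chrom=chrom))
    return haps


def run_pipeline(
    reference: Mapping[str, str] | str | Path,
    queries: Sequence[GuideQuery],
    vcf: Optional[str | Path] = None,
    sample: Optional[str] = None,
    assume_phased: bool = False,
    pass_only: bool = False,
    strict_overlaps: bool = True,
    out_dir: Optional[str | Path] = None,
    one_based: bool = False,
) -> PipelineResult:
    """Run the full variant-aware off-target analysis.

    *reference* may be a FASTA path or an in-memory chrom->sequence
    mapping.  Without a VCF only the reference is scanned (plain
    off-target finding); otherwise each haplotype is reconstructed and
    scanned, and sites are classified across sequences.
    """
    if not queries:
        raise ValueError("no guide queries given")
    if isinstance(reference, (str, Path)):
        reference = load_reference(reference)

    if vcf is not None:
        hap_sets, stats = haplotype_sets_from_vcf(
            vcf,
            reference,
            sample=sample,
            assume_phased=assume_phased,
            pass_only=pass_only,
            strict_overlaps=strict_overlaps,
        )
    else:
        hap_sets, stats = [], ParseStats()

    haplotypes = reconstruct_haplotypes(reference, hap_sets)
    labels = [REFERENCE_LABEL] + [hs.haplotype_label for hs in hap_sets]

    hits_by_label: dict[str, list] = {lab: [] for lab in labels}
    for q in queries:
        for chrom, seq in reference.items():
            identity = CoordinateMap.identity(len(seq))
            for hit in scan_sequence(chrom, seq, q, coord_map=identity):
                hits_by_label[REFERENCE_LABEL].append((chrom, hit))
        for hap in haplotypes:
            label = allelic_record_name(hap.chrom, hap.label)
            for hit in scan_sequence(label, hap.seq, q, coord_map=hap.coord_map):
                hits_by_label[hap.label].append((hap.chrom, hit))

    report = classify_sites(hits_by_label, labels=labels)
    count_table = summarize_per_chromosome(
        report, queries=[q.query_id for q in queries], chroms=list(reference)
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_hits_tsv(
            out_dir / "hits.tsv", hits_by_label, labels, one_based,
            chroms=list(reference), queries=[q.query_id for q in queries],
        )
        write_counts_tsv(out_dir / "counts.tsv", count_table)
        write_sites_tsv(out_dir / "sites.tsv", report, one_based)
    logger.info("pipeline finished: %s", stats.summary())
    return PipelineResult(
        labels=labels,
        hits_by_label=hits_by_label,
        report=report,
        count_table=count_table,
        haplotypes=haplotypes,
        stats=stats,
    )


# ---------------------------------------------------------------------------
# TSV input/output

_HIT_COLUMNS = (
    "query_id",
    "target_label",
    "position",
    "matched_seq",
    "strand",
    "mismatches",
    "ref_position",
)


def _dialect(one_based: bool) -> tuple[int, str]:
    return (1, "1-based") if one_based else (0, "0-based")


def write_hits_tsv(
    path: str | Path,
    hits_by_label: Mapping[str, Sequence],
    labels: Sequence[str],
    one_based: bool = False,
    chroms: Optional[Sequence[str]] = None,
    queries: Optional[Sequence[str]] = None,
) -> Path:
    offset, dialect = _dialect(one_based)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# coordinates: {dialect}\n")
        if chroms is not None:
            fh.write(f"# chromosomes: {','.join(chroms)}\n")
        if queries is not None:
            fh.write(f"# queries: {','.join(queries)}\n")
        fh.write("#" + "\t".join(_HIT_COLUMNS) + "\n")
        for label in labels:
            for _, h in hits_by_label[label]:
                ref_pos = "." if h.ref_position is None else str(h.ref_position + offset)
                fh.write(
                    f"{h.query_id}\t{h.target_label}\t{h.position + offset}\t"
                    f"{h.matched_seq}\t{h.strand}\t{h.mismatches}\t{ref_pos}\n"
                )
    return path


def read_hits_tsv(path: str | Path) -> tuple[dict[str, list], dict]:
    """Read a hits TSV back into label -> [(chrom, hit)] form, plus metadata.

    The sequence label is recovered from ``target_label``: names with a
    final ``_allele<k>`` suffix are allelic, anything else is the
    reference.  Metadata carries the scanned chromosome and query
    universes when the writer recorded them.
    """
    hits_by_label: dict[str, list] = {}
    meta: dict = {}
    offset = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# coordinates:"):
                offset = 1 if "1-based" in line else 0
                continue
            if line.startswith("# chromosomes:"):
                meta["chroms"] = line.split(":", 1)[1].strip().split(",")
                continue
            if line.startswith("# queries:"):
                meta["queries"] = line.split(":", 1)[1].strip().split(",")
                continue
            if line.startswith("#") or not line:
                continue
            qid, target, pos, matched, strand, mm, ref_pos = line.split("\t")
            try:
                chrom, label = parse_allelic_record_name(target)
            except ValueError:
                chrom, label = target, REFERENCE_LABEL
            hit = OffTargetHit(
                query_id=qid,
                target_label=target,
                position=int(pos) - offset,
                strand=strand,
                matched_seq=matched,
                mismatches=int(mm),
                ref_position=None if ref_pos == "." else int(ref_pos) - offset,
            )
            hits_by_label.setdefault(label, []).append((chrom, hit))
    return hits_by_label, meta


def write_counts_tsv(path: str | Path, count_table: pd.DataFrame) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(count_table.columns) + "\n")
        count_table.to_csv(fh, sep="\t", header=False, index=False)
    return path


def write_sites_tsv(path: str | Path, report: ComparisonReport, one_based: bool = False) -> Path:
    offset, dialect = _dialect(one_based)
    path = Path(path)
    columns = ["query", "chrom", "anchor", "strand", "class", "present_in"] + [
        f"pos_{lab}" for lab in report.labels
    ]
    with open(path, "w") as fh:
        fh.write(f"# coordinates: {dialect}\n")
        fh.write("#" + "\t".join(columns) + "\n")
        def _order(kv):
            qid, key = kv[0]
            if key.mappable:
                return (qid, key.chrom, 0, "", key.anchor[1], key.strand)
            return (qid, key.chrom, 1, key.anchor[1], key.anchor[2], key.strand)

        for (qid, key), rec in sorted(report.sites.items(), key=_order):
            if key.mappable:
                anchor = str(key.anchor[1] + offset)
            else:
                anchor = f"{key.anchor[1]}:{key.anchor[2] + offset}"
            row = [
                qid,
                key.chrom,
                anchor,
                key.strand,
                rec.classification,
                ",".join(sorted(rec.present_in)),
            ] + [
                str(rec.coordinates[lab] + offset) if lab in rec.coordinates else "."
                for lab in report.labels
            ]
            fh.write("\t".join(row) + "\n")
    return path
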