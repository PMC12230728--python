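"""Classify off-target sites across the reference and reconstructed alleles.

Site identity across sequences uses the strand-aware *reference* anchor:
hits whose window start lifts to the same reference coordinate are the
same site even when their haplotype-frame positions differ (e.g.
downstream of a heterozygous deletion).  Hits inside inserted sequence
have no reference image; they are keyed in their own frame and never
merged across alleles.

Per-chromosome counts are per-allele totals (a homozygous site counts
once on each allele), matching how haplotype-aware off-target tables are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .search import OffTargetHit

REFERENCE_LABEL = "reference"

SHARED_ALL = "shared_all"
REFERENCE_ONLY = "reference_only"
ALLELE_SUBSET = "allele_subset"


@dataclass(frozen=True)
class SiteKey:
    """Identity of a site: chromosome + strand + anchor.

    ``anchor`` is ``("ref", ref_pos)`` for mappable hits and
    ``("hap", label, hap_pos)`` for hits inside inserted sequence.
    """

    chrom: str
    anchor: tuple
    strand: str

    @property
    def mappable(self) -> bool:
        return self.anchor[0] == "ref"


@dataclass
class SiteRecord:
    key: SiteKey
    query_id: str
    present_in: set = field(default_factory=set)
    # label -> window-start position in that sequence's own frame
    coordinates: dict = field(default_factory=dict)
    mismatches: dict = field(default_factory=dict)

    @property
    def classification(self) -> str:
        if self.present_in == {REFERENCE_LABEL}:
            return REFERENCE_ONLY
        return SHARED_ALL if self._all_labels <= self.present_in else ALLELE_SUBSET

    _all_labels: frozenset = frozenset()


@dataclass
class ComparisonReport:
    """Per-site classifications plus per-(query, chrom, label) hit totals."""

    labels: list  # [reference, allele1, ...]
    sites: dict  # SiteKey -> SiteRecord
    counts: dict  # (query_id, chrom, label) -> int

    def class_counts(self) -> dict:
        out: dict[str, int] = {SHARED_ALL: 0, REFERENCE_ONLY: 0, ALLELE_SUBSET: 0}
        for rec in self.sites.values():
            out[rec.classification] += 1
        return out


def assign_site_keys(
    chrom: str, label: str, hits: Sequence[OffTargetHit]
) -> list[tuple[SiteKey, OffTargetHit]]:
    """Key each hit by its lifted reference coordinate where collinear."""
    keyed = []
    for h in hits:
        if h.ref_position is not None:
            key = SiteKey(chrom=chrom, anchor=("ref", h.ref_position), strand=h.strand)
        else:
            key = SiteKey(chrom=chrom, anchor=("hap", label, h.position), strand=h.strand)
        keyed.append((key, h))
    return keyed


def classify_sites(
    hits_by_label: Mapping[str, Sequence[tuple[str, OffTargetHit]]],
    labels: Optional[Sequence[str]] = None,
) -> ComparisonReport:
    """Merge keyed hits from the reference and every allele into one report.

    *hits_by_label* maps a sequence label (``reference``, ``allele1``, ...)
    to ``(chrom, hit)`` pairs; all hit lists must come from the same query
    set and mismatch budget.
    """
    labels = list(labels) if labels is not None else list(hits_by_label)
    all_labels = frozenset(labels)
    query_ids = {
        h.query_id for pairs in hits_by_label.values() for _, h in pairs
    }

    sites: dict[tuple, SiteRecord] = {}
    counts: dict[tuple, int] = {}
    for label in labels:
        for chrom, hit in hits_by_label.get(label, []):
            counts[(hit.query_id, chrom, label)] = (
                counts.get((hit.query_id, chrom, label), 0) + 1
            )
            keyed = assign_site_keys(chrom, label, [hit])
            for key, h in keyed:
                full_key = (h.query_id, key)
                rec = sites.get(full_key)
                if rec is None:
                    rec = SiteRecord(key=key, query_id=h.query_id)
                    rec._all_labels = all_labels
                    sites[full_key] = rec
                elif rec.query_id != h.query_id:
                    raise ValueError(
                        f"inconsistent query ids at {key}: {rec.query_id} vs {h.query_id}"
                    )
                rec.present_in.add(label)
                rec.coordinates[label] = h.position
                rec.mismatches[label] = h.mismatches
    return ComparisonReport(labels=labels, sites=sites, counts=counts)


def summarize_per_chromosome(
    report: ComparisonReport,
    queries: Optional[Sequence[str]] = None,
    chroms: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Count table: rows (query, chromosome) x columns (reference, alleles).

    *queries* and *chroms* give the full row universe (so chromosomes
    with zero hits still appear); by default both are derived from the
    hits present.  A ``total`` row is appended per query.  Row sums
    equal hit-list lengths by construction (count conservation).
    """
    queries = sorted(queries) if queries is not None else sorted({q for (q, _, _) in report.counts})
    chroms = sorted(chroms) if chroms is not None else sorted({c for (_, c, _) in report.counts})
    rows = []
    for q in queries:
        for c in chroms:
            rows.append(
                [q, c] + [report.counts.get((q, c, lab), 0) for lab in report.labels]
            )
        rows.append(
            [q, "total"]
            + [
                sum(report.counts.get((q, c, lab), 0) for c in chroms)
                for lab in report.labels
            ]
        )
    df = pd.DataFrame(rows, columns=["query", "chrom"] + list(report.labels))
    return df
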