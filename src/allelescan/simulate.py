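"""Seeded synthetic genomes, phased VCFs, and planted off-target truth.

Every stage of the pipeline is testable offline: the generator emits a
multi-chromosome random reference, a phased diploid (or higher-ploidy)
VCF with SNPs, MNPs, indels and multiallelic records, and *planted*
off-target sites that variants create or destroy on chosen haplotypes.
Ground truth is recorded at planting time and verified by construction
(the generator re-checks each planted claim against a local brute-force
match before emitting it), so downstream classification can be compared
to truth exactly.

This module also houses the brute-force scan oracle used by the test
suite as the independent reference for the vectorized scanner.

All randomness flows from a single integer seed through one
``numpy.random.Generator`` stream; no wall-clock or OS entropy is used
anywhere, so identical specs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .iupac import IUPAC_SETS, reverse_complement
from .search import (
    FIVE_PRIME,
    THREE_PRIME,
    CompiledPattern,
    GuideQuery,
    OffTargetHit,
    PamSpec,
    compile_pattern,
)

BASES = "ACGT"

# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_scan(target_label: str, seq: str, query: GuideQuery) -> list[OffTargetHit]:
    """Test every window on both strands by direct per-base set membership.

    Asymptotically slow but obviously correct; the equivalence oracle for
    ``scan_sequence``.  Match rule: a genome base matches a pattern code
    iff it is in the code's IUPAC set; genome ``N`` matches only pattern
    ``N`` (pattern ``N`` matches everything).
    """
    if query.pam.orientation == THREE_PRIME:
        pattern = query.spacer + query.pam.pattern
        is_spacer = [True] * len(query.spacer) + [False] * len(query.pam.pattern)
    else:
        pattern = query.pam.pattern + query.spacer
        is_spacer = [False] * len(query.pam.pattern) + [True] * len(query.spacer)
    plen = len(pattern)
    k = query.max_mismatches

    def matches(p: str, g: str) -> bool:
        if p == "N":
            return True
        if g == "N":
            return False
        return g in IUPAC_SETS[p]

    hits = []
    for strand in "+-":
        for i in range(len(seq) - plen + 1):
            window = seq[i : i + plen]
            gw = window if strand == "+" else reverse_complement(window)
            mm = 0
            pam_ok = True
            for p, g, sp in zip(pattern, gw, is_spacer):
                if not matches(p, g):
                    if sp:
                        mm += 1
                        if mm > k:  # early reject; membership unaffected
                            break
                    else:
                        pam_ok = False
                        break
            if pam_ok and mm <= k:
                shown = "".join(
                    g.lower() if sp and not matches(p, g) else g
                    for p, g, sp in zip(pattern, gw, is_spacer)
                )
                hits.append(
                    OffTargetHit(
                        query_id=query.query_id,
                        target_label=target_label,
                        position=i,
                        strand=strand,
                        matched_seq=shown,
                        mismatches=mm,
                        ref_position=None,
                    )
                )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def naive_apply_variants(ref_seq: str, variants) -> str:
    """Independent haplotype-building oracle: right-to-left edit replay."""
    seq = ref_seq
    for v in sorted(variants, key=lambda v: v.pos, reverse=True):
        assert seq[v.pos : v.pos + len(v.ref_allele)] == v.ref_allele
        seq = seq[: v.pos] + v.alt_allele + seq[v.pos + len(v.ref_allele) :]
    return seq


def plant_site(
    genome: dict,
    chrom: str,
    query: GuideQuery,
    rng: np.random.Generator,
    pos: Optional[int] = None,
    mismatches: int = 0,
    strand: str = "+",
):
    """Write a window matching *query* at the requested mismatch count and
    strand into *genome* (in place); returns the ground-truth record.

    *pos* must leave the full pattern within the chromosome, at least one
    pattern length from each edge (drawn at random when omitted).
    """
    compiled = compile_pattern(query)
    plen = compiled.length
    seq = genome[chrom]
    if pos is None:
        pos = int(rng.integers(plen, len(seq) - 2 * plen))
    if not plen <= pos <= len(seq) - 2 * plen:
        raise ValueError(f"site at {pos} too close to the edge of {chrom}")
    window = _orient(_make_window(compiled, mismatches, rng), strand)
    genome[chrom] = seq[:pos] + window + seq[pos + plen :]
    return PlantedTruth(
        kind="site",
        query_id=query.query_id,
        chrom=chrom,
        strand=strand,
        ref_position=pos,
        expected_present=frozenset(["reference"]),
        mismatches=mismatches,
    )


# ---------------------------------------------------------------------------
# fixture specification


@dataclass(frozen=True)
class PlantSpec:
    """One planted event.

    kinds: ``site`` (present everywhere), ``gain_snp`` / ``gain_pam_snp``
    (variant creates the site on a haplotype subset), ``loss_snp`` /
    ``loss_del`` (variant destroys a reference site on a subset), and
    ``gain_ins`` (exact site inside an inserted sequence, unmappable).
    ``haplotypes`` are 0-based indices; ``None`` draws a random proper,
    non-empty subset.
    """

    kind: str
    chrom: Optional[str] = None
    strand: Optional[str] = None
    haplotypes: Optional[tuple[int, ...]] = None
    mismatches: Optional[int] = None


KINDS = ("site", "gain_snp", "gain_pam_snp", "loss_snp", "loss_del", "gain_ins")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic fixture; all randomness from seed."""

    n_chroms: int = 2
    chrom_length: int = 3000
    gc_fraction: float = 0.41
    n_snps: int = 12
    n_insertions: int = 4
    n_deletions: int = 4
    n_mnps: int = 2
    n_multiallelic: int = 2
    ins_size: tuple[int, int] = (1, 20)
    del_size: tuple[int, int] = (1, 20)
    ploidy: int = 2
    spacer: Optional[str] = None
    spacer_length: int = 20
    pam_name: str = "NGG"
    pam_pattern: str = "NGG"
    pam_orientation: str = THREE_PRIME
    max_mismatches: int = 2
    planted: Optional[tuple[PlantSpec, ...]] = None
    seed: int = 0

    def __post_init__(self):
        if self.chrom_length < 200:
            raise ValueError("chrom_length must be >= 200")
        if not (0.0 < self.gc_fraction < 1.0):
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one planted event, in reference coordinates.

    ``ref_position`` is the window start on the reference forward strand,
    or ``None`` for sites inside inserted sequence; ``expected_present``
    lists the sequence labels ('reference', 'allele1', ...) on which the
    site must be found.
    """

    kind: str
    query_id: str
    chrom: str
    strand: str
    ref_position: Optional[int]
    expected_present: frozenset
    mismatches: Optional[int] = None


@dataclass
class Fixture:
    """A generated study: genome + phased VCF records + planted truth."""

    spec: FixtureSpec
    genome: dict  # chrom -> uppercase sequence
    query: GuideQuery
    vcf_records: list  # (chrom, pos1, ref, alts, gt_string)
    truths: list  # list[PlantedTruth]

    @property
    def allele_labels(self) -> list[str]:
        return [f"allele{i + 1}" for i in range(self.spec.ploidy)]

    def write(self, outdir: str | Path) -> dict:
        """Write ref.fa, sample.vcf and truth.tsv; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ref = outdir / "ref.fa"
        with open(ref, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        vcf = outdir / "sample.vcf"
        write_vcf(vcf, {c: len(s) for c, s in self.genome.items()}, self.vcf_records)
        truth = outdir / "truth.tsv"
        with open(truth, "w") as fh:
            fh.write("#kind\tquery\tchrom\tstrand\tref_position\texpected_present\tmismatches\n")
            for t in self.truths:
                fh.write(
                    "\t".join(
                        [
                            t.kind,
                            t.query_id,
                            t.chrom,
                            t.strand,
                            "." if t.ref_position is None else str(t.ref_position),
                            ",".join(sorted(t.expected_present)),
                            "." if t.mismatches is None else str(t.mismatches),
                        ]
                    )
                    + "\n"
                )
        return {"ref_fasta": ref, "vcf": vcf, "truth": truth}


def write_vcf(path: str | Path, contig_lengths: dict, records: Sequence[tuple], sample: str = "SAMPLE") -> Path:
    """Write a minimal valid, sorted single-sample VCF 4.2 text file."""
    path = Path(path)
    order = {c: i for i, c in enumerate(contig_lengths)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for chrom, pos1, ref, alts, gt in sorted(
            records, key=lambda r: (order[r[0]], r[1])
        ):
            fh.write(
                f"{chrom}\t{pos1}\t.\t{ref}\t{','.join(alts)}\t.\t.\t.\tGT\t{gt}\n"
            )
    return path


# ---------------------------------------------------------------------------
# generation


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=p))


def generate_genome(spec: FixtureSpec, rng: Optional[np.random.Generator] = None) -> dict:
    """Reproducible random multi-chromosome genome at the requested GC."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    return {
        f"chr{i + 1}": _random_dna(rng, spec.chrom_length, spec.gc_fraction)
        for i in range(spec.n_chroms)
    }


def _realize(pattern: str, rng: np.random.Generator) -> str:
    """A concrete ACGT sequence drawn from an IUPAC pattern."""
    return "".join(rng.choice(list(IUPAC_SETS[c])) for c in pattern)


def _corrupt_base(pattern_char: str, rng: np.random.Generator) -> str:
    """A base NOT matching *pattern_char* (pattern_char must not be N)."""
    choices = [b for b in BASES if b not in IUPAC_SETS[pattern_char]]
    return str(rng.choice(choices))


def _make_window(
    compiled: CompiledPattern, mismatches: int, rng: np.random.Generator
) -> str:
    """Guide-oriented window with exactly *mismatches* spacer mismatches."""
    window = list(_realize(compiled.forward, rng))
    eligible = [
        j
        for j in range(compiled.length)
        if compiled.is_spacer[j] and compiled.forward[j] != "N"
    ]
    if mismatches > len(eligible):
        raise ValueError("requested mismatches exceed corruptible spacer length")
    for j in rng.choice(eligible, size=mismatches, replace=False):
        window[j] = _corrupt_base(compiled.forward[j], rng)
    return "".join(window)


def _extra_corruption(
    compiled: CompiledPattern, window: str, rng: np.random.Generator
) -> str:
    """Corrupt one additional, currently-matching spacer position."""
    eligible = [
        j
        for j in range(compiled.length)
        if compiled.is_spacer[j]
        and compiled.forward[j] != "N"
        and window[j] in IUPAC_SETS[compiled.forward[j]]
    ]
    j = int(rng.choice(eligible))
    return window[:j] + _corrupt_base(compiled.forward[j], rng) + window[j + 1 :]


def _orient(guide_window: str, strand: str) -> str:
    return guide_window if strand == "+" else reverse_complement(guide_window)


class _Occupancy:
    """Per-chromosome reserved intervals so events never interact."""

    def __init__(self):
        self.intervals: dict[str, list[tuple[int, int]]] = {}

    def reserve(self, chrom: str, start: int, end: int) -> None:
        self.intervals.setdefault(chrom, []).append((start, end))

    def free(self, chrom: str, start: int, end: int) -> bool:
        return all(
            end <= s or start >= e for s, e in self.intervals.get(chrom, [])
        )

    def find_slot(
        self, rng: np.random.Generator, chrom: str, chrom_len: int, width: int, margin: int
    ) -> int:
        for _ in range(500):
            pos = int(rng.integers(margin, chrom_len - width - margin))
            if self.free(chrom, pos - margin, pos + width + margin):
                self.reserve(chrom, pos - margin, pos + width + margin)
                return pos
        raise ValueError("infeasible density: no free slot for a planted event")


def _gt_string(spec: FixtureSpec, alt_haps: Sequence[int], alt_index: int = 1) -> str:
    return "|".join(
        str(alt_index) if h in alt_haps else "0" for h in range(spec.ploidy)
    )


def _window_mismatch_count(compiled: CompiledPattern, guide_window: str) -> Optional[int]:
    """Spacer mismatches if the PAM passes, else None (oracle-side check)."""
    mm = 0
    for p, g, sp in zip(compiled.forward, guide_window, compiled.is_spacer):
        ok = p == "N" or (g != "N" and g in IUPAC_SETS[p])
        if not ok:
            if sp:
                mm += 1
            else:
                return None
    return mm


def build_fixture(spec: FixtureSpec) -> Fixture:
    """Generate genome, planted events, background variants and truth."""
    rng = np.random.default_rng(spec.seed)
    genome = generate_genome(spec, rng)
    chroms = list(genome)

    pam = PamSpec(spec.pam_name, spec.pam_pattern, spec.pam_orientation)
    spacer = spec.spacer if spec.spacer is not None else _realize("N" * spec.spacer_length, rng)
    query = GuideQuery(
        query_id="g1", spacer=spacer, pam=pam, max_mismatches=spec.max_mismatches
    )
    compiled = compile_pattern(query)
    plen = compiled.length
    k = spec.max_mismatches
    margin = plen + 10

    labels = [f"allele{i + 1}" for i in range(spec.ploidy)]
    all_labels = frozenset(["reference", *labels])

    planted = spec.planted if spec.planted is not None else _default_events(spec, rng)

    occupancy = _Occupancy()
    vcf_records: list[tuple] = []
    truths: list[PlantedTruth] = []

    def _resolve(ps: PlantSpec) -> tuple[str, str, tuple[int, ...], int]:
        chrom = ps.chrom or chroms[int(rng.integers(len(chroms)))]
        strand = ps.strand or ("+" if rng.random() < 0.5 else "-")
        if ps.haplotypes is not None:
            haps = tuple(ps.haplotypes)
        else:
            n = int(rng.integers(1, spec.ploidy)) if spec.ploidy > 1 else 1
            haps = tuple(sorted(rng.choice(spec.ploidy, size=n, replace=False).tolist()))
        mm = ps.mismatches if ps.mismatches is not None else int(rng.integers(0, k + 1))
        return chrom, strand, haps, mm

    def _embed(chrom: str, pos: int, genome_window: str) -> None:
        seq = genome[chrom]
        genome[chrom] = seq[:pos] + genome_window + seq[pos + len(genome_window) :]

    for ps in planted:
        chrom, strand, haps, mm = _resolve(ps)
        hap_labels = frozenset(labels[h] for h in haps)
        if ps.kind == "site":
            pos = occupancy.find_slot(rng, chrom, len(genome[chrom]), plen, margin)
            _embed(chrom, pos, _orient(_make_window(compiled, mm, rng), strand))
            truths.append(
                PlantedTruth("site", query.query_id, chrom, strand, pos, all_labels, mm)
            )
        elif ps.kind in ("gain_snp", "gain_pam_snp", "loss_snp"):
            pos = occupancy.find_slot(rng, chrom, len(genome[chrom]), plen, margin)
            if ps.kind == "gain_pam_snp":
                # PAM breakage removes the site regardless of spacer mismatches
                good = _make_window(compiled, min(mm, k), rng)
                pam_positions = [
                    j
                    for j in range(plen)
                    if not compiled.is_spacer[j] and len(IUPAC_SETS[compiled.forward[j]]) < 4
                ]
                j = int(rng.choice(pam_positions))
                bad = good[:j] + _corrupt_base(compiled.forward[j], rng) + good[j + 1 :]
                mm_out = min(mm, k)
            else:
                # the matching window sits exactly at the budget so that one
                # extra spacer mismatch pushes it out
                good = _make_window(compiled, k, rng)
                bad = _extra_corruption(compiled, good, rng)
                mm_out = k
            if ps.kind == "loss_snp":
                ref_w, alt_w, expected = good, bad, (all_labels - hap_labels)
            else:
                ref_w, alt_w, expected = bad, good, hap_labels
            g_ref, g_alt = _orient(ref_w, strand), _orient(alt_w, strand)
            _embed(chrom, pos, g_ref)
            diffs = [i for i, (a, b) in enumerate(zip(g_ref, g_alt)) if a != b]
            assert len(diffs) == 1
            i = diffs[0]
            vcf_records.append(
                (chrom, pos + i + 1, g_ref[i], (g_alt[i],), _gt_string(spec, haps))
            )
            truths.append(
                PlantedTruth(ps.kind, query.query_id, chrom, strand, pos, expected, mm_out)
            )
        elif ps.kind == "loss_del":
            pos = occupancy.find_slot(rng, chrom, len(genome[chrom]), plen, margin)
            for _ in range(50):  # redraw until the claim verifies locally
                window = _make_window(compiled, 0, rng)
                gw = _orient(window, strand)
                off = plen // 2
                d = int(rng.integers(3, 7))
                trial = genome[chrom][:pos] + gw + genome[chrom][pos + plen :]
                # haplotype-local window at the same anchor after the deletion
                hap_local = trial[pos:pos + off] + trial[pos + off + d : pos + off + d + plen]
                hap_win = hap_local[:plen]
                guide_view = hap_win if strand == "+" else reverse_complement(hap_win)
                residual = _window_mismatch_count(compiled, guide_view)
                if residual is None or residual > k:
                    genome[chrom] = trial
                    anchor = pos + off - 1
                    ref_allele = genome[chrom][anchor : anchor + d + 1]
                    vcf_records.append(
                        (chrom, anchor + 1, ref_allele, (ref_allele[0],), _gt_string(spec, haps))
                    )
                    truths.append(
                        PlantedTruth(
                            "loss_del", query.query_id, chrom, strand, pos,
                            all_labels - hap_labels, 0,
                        )
                    )
                    break
            else:
                raise ValueError("could not plant a verifiable deletion loss")
        elif ps.kind == "gain_ins":
            pos = occupancy.find_slot(rng, chrom, len(genome[chrom]), plen + 2, margin)
            window = _make_window(compiled, 0, rng)
            pad_l = _random_dna(rng, int(rng.integers(2, 6)), spec.gc_fraction)
            pad_r = _random_dna(rng, int(rng.integers(2, 6)), spec.gc_fraction)
            anchor_base = genome[chrom][pos]
            inserted = pad_l + _orient(window, strand) + pad_r
            vcf_records.append(
                (chrom, pos + 1, anchor_base, (anchor_base + inserted,), _gt_string(spec, haps))
            )
            truths.append(
                PlantedTruth("gain_ins", query.query_id, chrom, strand, None, hap_labels, 0)
            )
        else:
            raise ValueError(f"unknown planted event kind {ps.kind!r}")

    _add_background_variants(spec, rng, genome, occupancy, vcf_records)
    return Fixture(spec=spec, genome=genome, query=query, vcf_records=vcf_records, truths=truths)


def _default_events(spec: FixtureSpec, rng: np.random.Generator) -> tuple[PlantSpec, ...]:
    """Standard mix: one shared site per chromosome plus each gain/loss kind."""
    events = [PlantSpec("site", chrom=f"chr{i + 1}") for i in range(spec.n_chroms)]
    events += [PlantSpec(kind) for kind in KINDS[1:]]
    return tuple(events)


def _random_genotype(
    spec: FixtureSpec, rng: np.random.Generator, n_alts: int = 1
) -> tuple[str, list[int]]:
    """Random phased GT with at least one non-reference allele."""
    while True:
        idx = [int(rng.integers(0, n_alts + 1)) for _ in range(spec.ploidy)]
        if any(i > 0 for i in idx):
            return "|".join(map(str, idx)), idx


def _add_background_variants(
    spec: FixtureSpec,
    rng: np.random.Generator,
    genome: dict,
    occupancy: _Occupancy,
    vcf_records: list,
) -> None:
    margin = 30

    def place(width: int) -> tuple[str, int]:
        for _ in range(1000):
            chrom = list(genome)[int(rng.integers(len(genome)))]
            pos = int(rng.integers(margin, len(genome[chrom]) - width - margin))
            if occupancy.free(chrom, pos - margin, pos + width + margin):
                occupancy.reserve(chrom, pos - margin, pos + width + margin)
                return chrom, pos
        raise ValueError("infeasible density: cannot place background variants")

    for _ in range(spec.n_snps):
        chrom, pos = place(1)
        ref = genome[chrom][pos]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        gt, _ = _random_genotype(spec, rng)
        vcf_records.append((chrom, pos + 1, ref, (alt,), gt))

    for _ in range(spec.n_insertions):
        chrom, pos = place(1)
        anchor = genome[chrom][pos]
        ins = _random_dna(rng, int(rng.integers(spec.ins_size[0], spec.ins_size[1] + 1)), spec.gc_fraction)
        gt, _ = _random_genotype(spec, rng)
        vcf_records.append((chrom, pos + 1, anchor, (anchor + ins,), gt))

    for _ in range(spec.n_deletions):
        d = int(rng.integers(spec.del_size[0], spec.del_size[1] + 1))
        chrom, pos = place(d + 1)
        ref = genome[chrom][pos : pos + d + 1]
        gt, _ = _random_genotype(spec, rng)
        vcf_records.append((chrom, pos + 1, ref, (ref[0],), gt))

    for _ in range(spec.n_mnps):
        width = int(rng.integers(2, 4))
        chrom, pos = place(width)
        ref = genome[chrom][pos : pos + width]
        alt = "".join(str(rng.choice([b for b in BASES if b != r])) for r in ref)
        gt, _ = _random_genotype(spec, rng)
        vcf_records.append((chrom, pos + 1, ref, (alt,), gt))

    for _ in range(spec.n_multiallelic):
        chrom, pos = place(1)
        ref = genome[chrom][pos]
        alts = tuple(rng.permutation([b for b in BASES if b != ref]).tolist()[:2])
        gt, _ = _random_genotype(spec, rng, n_alts=2)
        vcf_records.append((chrom, pos + 1, ref, alts, gt))


# ---------------------------------------------------------------------------
# truth verification


def verify_planted(report, truths: Sequence[PlantedTruth]) -> list[str]:
    """Compare a ComparisonReport against planted truth; return discrepancies."""
    from .compare import SiteKey  # local import to avoid cycles

    discrepancies = []
    for t in truths:
        if t.ref_position is not None:
            key = (t.query_id, SiteKey(t.chrom, ("ref", t.ref_position), t.strand))
            rec = report.sites.get(key)
            present = frozenset(rec.present_in) if rec else frozenset()
            if present != t.expected_present:
                discrepancies.append(
                    f"{t.kind} at {t.chrom}:{t.ref_position}{t.strand}: "
                    f"expected {sorted(t.expected_present)}, found {sorted(present)}"
                )
        else:
            for label in sorted(t.expected_present):
                found = [
                    rec
                    for rec in report.sites.values()
                    if rec.query_id == t.query_id
                    and not rec.key.mappable
                    and rec.key.chrom == t.chrom
                    and rec.key.strand == t.strand
                    and rec.key.anchor[1] == label
                    and rec.present_in == {label}
                ]
                if not found:
                    discrepancies.append(
                        f"{t.kind} on {t.chrom}{t.strand}: no inserted-sequence site on {label}"
                    )
    return discrepancies
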