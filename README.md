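# allelescan

Haplotype-aware CRISPR off-target site discovery from phased VCFs.

Off-target screens usually scan the reference assembly for every window
matching `spacer + PAM` within a mismatch budget. But an individual's
genome is not the reference: SNPs and small indels can create PAMs and
protospacers the reference lacks, or destroy sites the reference has —
and the phased copies of each chromosome can differ from *each other*.
`allelescan` is for anyone designing or auditing guide RNAs against a
specific genome (a patient, a crop cultivar, a model-organism strain):
it reconstructs each haplotype from a phased single-sample VCF, scans
reference and every allele, and reports which sites are shared, gained,
or lost per allele.

## Method

Given reference $R$, phased variants, spacer $s$ (length $L$), PAM
pattern $P$ over the IUPAC alphabet, and budget $k$:

1. **Canonicalize** each VCF record per haplotype: select the ALT by
   genotype index, decompose MNPs/complex substitutions into SNVs plus
   at most one anchored indel (end-anchored trim), and left-align
   indels to their parsimonious leftmost representation.
2. **Reconstruct** each allelic sequence $H_a$ by splicing the
   haplotype's variants into $R$, recording collinear blocks so
   positions lift both ways between frames (undefined inside
   inserted/deleted tails).
3. **Scan** every sequence on both strands: a window $w$ at position
   $i$ is a hit iff every PAM position matches degenerately (zero
   tolerance) and $\#\{j \le L : w_j \notin \mathrm{set}(s_j)\} \le k$.
   Matching follows Cas-OFFinder semantics; mismatched spacer bases are
   lowercased in the output.
4. **Classify** sites across sequences by strand-aware lifted reference
   anchor: `shared_all`, `reference_only`, or `allele_subset` (with the
   exact member set), plus per-chromosome per-allele count tables.

PAM types (NGG, NRG, TTTN, …) and genome registries are user-editable
YAML; ploidy ≥ 2 is supported throughout.

## Worked example

Generate a seeded synthetic study (2 × 3 kb diploid genome, 29 phased
variants including MNPs and multiallelics, planted gain/loss sites) and
run the full pipeline with SpCas9 NGG and up to two mismatches:

```sh
allelescan simulate --seed 7 --out-dir fx
allelescan run --ref fx/ref.fa --vcf fx/sample.vcf \
    --guide g1=GCTAAGACGCCAATGCATAC --pam NGG -k 2 --out-dir out
```

`out/counts.tsv` — per-chromosome, per-allele site totals:

```text
#query	chrom	reference	allele1	allele2
g1	chr1	1	1	2
g1	chr2	3	2	4
g1	total	4	3	6
```

Allele 2 carries two extra sites on chr2 and one on chr1 that the
reference screen would miss. `out/sites.tsv` explains each site:

```text
#query	chrom	anchor	strand	class	present_in	pos_reference	pos_allele1	pos_allele2
g1	chr1	98	+	shared_all	allele1,allele2,reference	98	98	98
g1	chr1	1902	+	allele_subset	allele2	.	.	1901
g1	chr2	746	+	allele_subset	allele1	.	761	.
g1	chr2	1667	-	allele_subset	allele2,reference	1667	.	1695
g1	chr2	2114	-	allele_subset	allele2,reference	2114	.	2142
g1	chr2	2787	-	shared_all	allele1,allele2,reference	2787	2781	2815
g1	chr2	allele2:77	-	allele_subset	allele2	.	.	77
```

Reading the rows: the chr1:98 site is intact everywhere; chr1:1902 was
*gained* on allele 2 (a phased SNP completes its PAM); the two
`allele2,reference` rows were *lost* on allele 1 (a spacer-breaking SNP
and a deletion); the shared chr2:2787 site sits downstream of
heterozygous indels, so its per-allele coordinates shift (2781/2815)
while the lifted anchor proves it is one and the same locus; and
`allele2:77` lies inside an inserted sequence — it has no reference
coordinate at all. `out/hits.tsv` lists every hit with its matched
sequence, e.g. `GCTtAGAgGCCAATGCATACTGG` (mismatches lowercased, PAM
`TGG` at the 3′ end).

Staged subcommands compose the same way: `reconstruct` writes allelic
FASTAs, `search` scans any FASTA, and `compare` rebuilds the reports
from hit TSVs.

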