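import textwrap
from pathlib import Path

import pytest

from allelescan.search import GuideQuery, PamSpec

NGG = PamSpec("NGG", "NGG", "three_prime")
NRG = PamSpec("NRG", "NRG", "three_prime")
TTTN = PamSpec("TTTN", "TTTN", "five_prime")


@pytest.fixture
def ngg():
    return NGG


def make_query(spacer, pam=NGG, k=0, query_id="g1"):
    return GuideQuery(query_id=query_id, spacer=spacer, pam=pam, max_mismatches=k)


def write_fasta(path: Path, seqs: dict) -> Path:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, 60)) + "\n")
    return path


def write_vcf_text(path: Path, body: str, contigs: dict) -> Path:
    """Write a VCF from a dedented body of record lines (may be empty)."""
    header = ["##fileformat=VCFv4.2"]
    header += [f"##contig=<ID={c},length={n}>" for c, n in contigs.items()]
    header += ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    header += ["#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1"]
    body = textwrap.dedent(body).strip("\n")
    lines = header + ([body] if body else [])
    path.write_text("\n".join(lines) + "\n")
    return path
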