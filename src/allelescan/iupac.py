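"""IUPAC degenerate nucleotide alphabet: sets, complements, bit masks.

Pattern characters (guide spacer and PAM) may use the full degenerate
alphabet; genome characters are restricted to ``ACGTN``.  An ``N`` in the
genome is an *unknown* base and therefore matches only a pattern ``N``
(which asserts nothing), never a concrete pattern base.
"""

from __future__ import annotations

import numpy as np

#: Concrete bases denoted by each IUPAC code.
IUPAC_SETS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

IUPAC_ALPHABET = frozenset(IUPAC_SETS)
GENOME_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

# One bit per genome symbol; a pattern code's mask is the union of the bits
# of the bases it accepts.  Pattern N additionally accepts genome N.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 16}

#: genome character -> bit, as a 256-entry lookup for byte-coded sequences.
GENOME_BITS = np.zeros(256, dtype=np.uint8)
for _b, _bit in _BASE_BIT.items():
    GENOME_BITS[ord(_b)] = _bit

#: pattern character -> acceptance mask (uint8), 256-entry lookup.
PATTERN_MASKS = np.zeros(256, dtype=np.uint8)
for _code, _bases in IUPAC_SETS.items():
    _mask = 0
    for _b in _bases:
        _mask |= _BASE_BIT[_b]
    if _code == "N":
        _mask |= _BASE_BIT["N"]
    PATTERN_MASKS[ord(_code)] = _mask


def iupac_match(pattern_base: str, genome_base: str) -> bool:
    """True iff *genome_base* is within the set denoted by *pattern_base*.

    Genome ``N`` matches only pattern ``N``.
    """
    if pattern_base not in IUPAC_ALPHABET:
        raise ValueError(f"invalid IUPAC pattern character {pattern_base!r}")
    if genome_base not in GENOME_ALPHABET:
        raise ValueError(f"invalid genome character {genome_base!r}")
    if pattern_base == "N":
        return True
    if genome_base == "N":
        return False
    return genome_base in IUPAC_SETS[pattern_base]


def complement(base: str) -> str:
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"invalid IUPAC character {base!r}") from None


def reverse_complement(s: str) -> str:
    """Reverse complement of an IUPAC string (degenerate codes included)."""
    return "".join(complement(b) for b in reversed(s))


def validate_iupac(s: str, what: str = "pattern") -> str:
    """Uppercase *s* and verify every character is an IUPAC code."""
    s = s.upper()
    bad = set(s) - IUPAC_ALPHABET
    if bad:
        raise ValueError(
            f"invalid IUPAC character(s) {sorted(bad)} in {what} {s!r}"
        )
    if not s:
        raise ValueError(f"empty {what}")
    return s
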