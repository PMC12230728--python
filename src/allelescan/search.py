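"""Mismatch-tolerant degenerate-pattern scanning of DNA sequences.

The scan follows Cas-OFFinder matching semantics: a query is a spacer
(the guide-programmed protospacer) concatenated with a PAM pattern, the
PAM is matched degenerately with zero tolerance, and the mismatch budget
applies to the spacer positions only.  Both strands are scanned; hit
positions are always reported as the window start on the forward strand
of the scanned sequence, in that sequence's own coordinate frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .iupac import (
    GENOME_BITS,
    PATTERN_MASKS,
    iupac_match,
    reverse_complement,
    validate_iupac,
)

THREE_PRIME = "three_prime"
FIVE_PRIME = "five_prime"
ORIENTATIONS = (THREE_PRIME, FIVE_PRIME)


@dataclass(frozen=True)
class PamSpec:
    """A named PAM: IUPAC pattern plus its placement relative to the spacer.

    ``three_prime`` means the PAM lies downstream (3') of the spacer, as for
    SpCas9 (NGG/NRG); ``five_prime`` means upstream (5'), as for Cas12a/Cpf1
    (TTTN/TTTV).
    """

    name: str
    pattern: str
    orientation: str

    def __post_init__(self):
        object.__setattr__(self, "pattern", validate_iupac(self.pattern, "PAM"))
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"PAM {self.name!r}: orientation must be one of {ORIENTATIONS},"
                f" got {self.orientation!r}"
            )


@dataclass(frozen=True)
class GuideQuery:
    """A guide RNA query: spacer + PAM + spacer-mismatch budget."""

    query_id: str
    spacer: str
    pam: PamSpec
    max_mismatches: int = 0

    def __post_init__(self):
        object.__setattr__(self, "spacer", validate_iupac(self.spacer, "spacer"))
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    @property
    def pattern_length(self) -> int:
        return len(self.spacer) + len(self.pam.pattern)


@dataclass(frozen=True)
class OffTargetHit:
    """One located site.

    ``position`` is the 0-based start of the full pattern window on the
    forward strand of the scanned sequence.  ``matched_seq`` is the window
    read 5'->3' along the guide (reverse-complemented for '-' hits) with
    mismatched spacer bases lowercased.  ``ref_position`` is the window
    start lifted to the reference frame where the coordinate map is
    collinear, else None.
    """

    query_id: str
    target_label: str
    position: int
    strand: str
    matched_seq: str
    mismatches: int
    ref_position: Optional[int] = None


class CompiledPattern:
    """A guide query compiled for scanning: forward/reverse masks + layout."""

    def __init__(self, query: GuideQuery):
        self.query = query
        if query.pam.orientation == THREE_PRIME:
            self.forward = query.spacer + query.pam.pattern
            spacer_flags = [True] * len(query.spacer) + [False] * len(query.pam.pattern)
        else:
            self.forward = query.pam.pattern + query.spacer
            spacer_flags = [False] * len(query.pam.pattern) + [True] * len(query.spacer)
        self.length = len(self.forward)
        self.is_spacer = np.array(spacer_flags, dtype=bool)
        self.reverse = reverse_complement(self.forward)

        fwd_bytes = np.frombuffer(self.forward.encode("ascii"), dtype=np.uint8)
        rev_bytes = np.frombuffer(self.reverse.encode("ascii"), dtype=np.uint8)
        self.fwd_masks = PATTERN_MASKS[fwd_bytes]
        self.rev_masks = PATTERN_MASKS[rev_bytes]
        self.rev_is_spacer = self.is_spacer[::-1].copy()


def compile_pattern(query: GuideQuery) -> CompiledPattern:
    """Compile a query into forward- and reverse-strand scan patterns."""
    return CompiledPattern(query)


def count_mismatches(compiled: CompiledPattern, window: str) -> tuple[int, bool]:
    """Spacer mismatch count and PAM pass/fail for one guide-oriented window.

    The window must be given 5'->3' along the guide (i.e. already
    reverse-complemented for a '-' strand candidate) and have the compiled
    pattern's length.
    """
    if len(window) != compiled.length:
        raise ValueError(
            f"window length {len(window)} != pattern length {compiled.length}"
        )
    mm = 0
    pam_ok = True
    for p, g, is_sp in zip(compiled.forward, window, compiled.is_spacer):
        if not iupac_match(p, g):
            if is_sp:
                mm += 1
            else:
                pam_ok = False
    return mm, pam_ok


def _format_matched(pattern: str, window: str, is_spacer: np.ndarray) -> str:
    """Lowercase spacer positions of *window* that mismatch *pattern*."""
    out = []
    for p, g, is_sp in zip(pattern, window, is_spacer):
        if is_sp and not iupac_match(p, g):
            out.append(g.lower())
        else:
            out.append(g)
    return "".join(out)


def _strand_candidates(
    codes: np.ndarray, masks: np.ndarray, is_spacer: np.ndarray, k: int
) -> Iterable[tuple[int, int]]:
    """Yield (window_start, spacer_mismatches) for one strand pattern.

    PAM positions are gated at zero tolerance; spacer mismatches are
    counted and filtered against *k*.  Vectorized over all windows.
    """
    plen = len(masks)
    n_win = len(codes) - plen + 1
    if n_win <= 0:
        return
    spacer_mm = np.zeros(n_win, dtype=np.int32)
    pam_fail = np.zeros(n_win, dtype=bool)
    for j in range(plen):
        miss = (masks[j] & codes[j : j + n_win]) == 0
        if is_spacer[j]:
            spacer_mm += miss
        else:
            pam_fail |= miss
    keep = np.flatnonzero(~pam_fail & (spacer_mm <= k))
    for i in keep:
        yield int(i), int(spacer_mm[i])


def scan_sequence(
    target_label: str,
    seq: str,
    query: GuideQuery,
    coord_map=None,
) -> list[OffTargetHit]:
    """Locate every window of *seq* matching *query* on either strand.

    *seq* must be uppercase ACGTN.  Hits are sorted by position, '+'
    before '-'.  When *coord_map* is given (an object with a
    ``to_reference`` method) the window start is lifted to the reference
    frame for collinear positions.
    """
    compiled = compile_pattern(query)
    k = query.max_mismatches
    codes = GENOME_BITS[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    hits: list[OffTargetHit] = []

    for strand, masks, flags in (
        ("+", compiled.fwd_masks, compiled.is_spacer),
        ("-", compiled.rev_masks, compiled.rev_is_spacer),
    ):
        for pos, mm in _strand_candidates(codes, masks, flags, k):
            window = seq[pos : pos + compiled.length]
            guide_window = window if strand == "+" else reverse_complement(window)
            matched = _format_matched(compiled.forward, guide_window, compiled.is_spacer)
            ref_pos = coord_map.to_reference(pos) if coord_map is not None else None
            hits.append(
                OffTargetHit(
                    query_id=query.query_id,
                    target_label=target_label,
                    position=pos,
                    strand=strand,
                    matched_seq=matched,
                    mismatches=mm,
                    ref_position=ref_pos,
                )
            )

    hits.sort(key=lambda h: (h.position, h.strand))  # '+' < '-' in ASCII
    return hits
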