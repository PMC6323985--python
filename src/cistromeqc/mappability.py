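"""Minimal-unique-length (MUL) mappability tracks.

For every genome position ``i``, ``MUL[i]`` is the length of the shortest
read that maps uniquely to ``i`` under exact matching against the genome and
its reverse complement, or -1 if no read of any length starting at ``i`` is
unique (the suffix runs into a sequence boundary while still ambiguous).
Position ``i`` is then unmappable for read length ``k`` iff ``MUL[i] == -1``
or ``MUL[i] > k``.

The computation concatenates every chromosome and its reverse complement
into one symbol string, separated by separator symbols, builds a suffix
array (SA-IS) and LCP array (Kasai), and reads MUL off adjacent-rank LCP
maxima: with ``L = max(LCP[i], LCP[i+1])``,

    MUL[SA[i]] = L + 1   if the symbol at SA[i]+L is a real base,
    MUL[SA[i]] = -1      otherwise (the extension hits a separator).

Each separator is a distinct symbol ordered below A < C < G < T, so no
common prefix — and hence no reported unique match — can span one. Non-ACGT
bases (N runs, IUPAC codes) are likewise replaced by separators: a k-mer
containing them is never mappable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GenomicInterval
from .suffix import build_lcp, build_suffix_array

__all__ = [
    "revcomp",
    "ConcatenatedText",
    "build_concatenated_text",
    "build_suffix_array",
    "build_lcp",
    "compute_mul",
    "mul_for_genome",
    "unmappable_regions",
    "unmappable_fraction",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement; non-ACGT symbols map to themselves reversed."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ConcatenatedText:
    """Integer-encoded concatenation of all chromosomes and their reverse
    complements, each segment followed by a separator.

    Symbols: values ``< num_separators`` are separators (each value occurs
    exactly once in the text); values ``num_separators + {0,1,2,3}`` are
    A, C, G, T. ``boundaries`` lists ``(chrom, strand, text_start, length)``
    per segment, with strand '+' segments mapping text offsets directly onto
    forward-genome coordinates.
    """

    text: np.ndarray  # int64 symbols
    boundaries: list[tuple[str, str, int, int]]
    num_separators: int
    genome_lengths: dict[str, int]

    def is_base(self, value: int) -> bool:
        return value >= self.num_separators


def build_concatenated_text(genome: dict[str, str]) -> ConcatenatedText:
    """Encode ``chr1 + sep + revcomp(chr1) + sep + chr2 + ...`` as integers.

    Every non-ACGT character becomes its own separator symbol, as does the
    terminator after each segment.
    """
    if not genome:
        raise ValueError("empty genome")
    segments: list[tuple[str, str, str]] = []  # (chrom, strand, sequence)
    for chrom, seq in genome.items():
        if not seq:
            raise ValueError(f"chromosome {chrom} has empty sequence")
        seq = seq.upper()
        segments.append((chrom, "+", seq))
        segments.append((chrom, "-", revcomp(seq)))

    # first pass: count separators (one per non-ACGT base, one per segment end)
    num_sep = 0
    for _, _, seq in segments:
        num_sep += 1 + sum(1 for c in seq if c not in "ACGT")

    base_code = {b: num_sep + i for i, b in enumerate("ACGT")}
    text: list[int] = []
    boundaries: list[tuple[str, str, int, int]] = []
    next_sep = 0
    for chrom, strand, seq in segments:
        boundaries.append((chrom, strand, len(text), len(seq)))
        for c in seq:
            code = base_code.get(c)
            if code is None:
                code = next_sep
                next_sep += 1
            text.append(code)
        text.append(next_sep)
        next_sep += 1
    assert next_sep == num_sep
    return ConcatenatedText(
        text=np.asarray(text, dtype=np.int64),
        boundaries=boundaries,
        num_separators=num_sep,
        genome_lengths={chrom: len(seq) for chrom, seq in genome.items()},
    )


def compute_mul(
    ctext: ConcatenatedText, sa: np.ndarray, lcp: np.ndarray
) -> dict[str, np.ndarray]:
    """MUL per forward-strand chromosome position from SA and LCP.

    Applies the adjacent-rank rule (L+1 when the L-extension is a base, -1
    when it is a separator), then projects text positions back onto the
    forward segments; reverse-complement copies and separators are dropped.
    """
    text = ctext.text
    n = len(text)
    if len(sa) != n or len(lcp) != n:
        raise ValueError("SA/LCP length does not match text")
    L = np.maximum(lcp, np.append(lcp[1:], 0))
    ext = sa + L
    in_range = ext < n
    ext_clipped = np.minimum(ext, n - 1)
    is_base_at_ext = in_range & (text[ext_clipped] >= ctext.num_separators)
    mul_text = np.full(n, -1, dtype=np.int64)
    mul_text[sa] = np.where(is_base_at_ext, L + 1, -1)

    out: dict[str, np.ndarray] = {}
    for chrom, strand, start, length in ctext.boundaries:
        if strand == "+":
            out[chrom] = mul_text[start : start + length].copy()
    return out


def mul_for_genome(genome: dict[str, str]) -> dict[str, np.ndarray]:
    """Convenience pipeline: concatenate, build SA and LCP, compute MUL."""
    ctext = build_concatenated_text(genome)
    sa = build_suffix_array(ctext.text)
    lcp = build_lcp(ctext.text, sa)
    return compute_mul(ctext, sa, lcp)


def unmappable_regions(
    mul: dict[str, np.ndarray], k: int
) -> list[GenomicInterval]:
    """Maximal runs of positions unmappable for read length ``k``.

    A position is unmappable iff ``MUL == -1`` or ``MUL > k``.
    """
    if k < 1:
        raise ValueError(f"read length k must be >= 1, got {k}")
    regions: list[GenomicInterval] = []
    for chrom in sorted(mul):
        arr = np.asarray(mul[chrom])
        mask = (arr == -1) | (arr > k)
        if not mask.any():
            continue
        padded = np.concatenate(([False], mask, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for start, end in zip(edges[::2], edges[1::2]):
            regions.append(GenomicInterval(chrom, int(start), int(end)))
    return regions


def unmappable_fraction(mul: dict[str, np.ndarray], k: int) -> float:
    """Fraction of the genome (all positions, N runs included) that is
    unmappable for read length ``k``."""
    if k < 1:
        raise ValueError(f"read length k must be >= 1, got {k}")
    total = sum(len(np.asarray(arr)) for arr in mul.values())
    if total == 0:
        raise ValueError("empty genome")
    bad = sum(
        int((((a := np.asarray(arr)) == -1) | (a > k)).sum())
        for arr in mul.values()
    )
    return bad / total
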