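"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the code paths they check: suffix arrays via
Python ``sorted`` over materialised suffixes, LCP by direct pairwise
comparison, MUL by per-position substring counting, and peak merging via
connected components of the explicit overlap graph (networkx).
"""

from __future__ import annotations

import numpy as np
import pytest

from cistromeqc.io_formats import GenomicInterval, Peak
from cistromeqc.mappability import revcomp


# ---------------------------------------------------------------- suffix/MUL


def oracle_suffix_array(text) -> list[int]:
    """Sort all suffixes (sentinel-free semantics: shorter prefix first)."""
    seq = list(text)
    return sorted(range(len(seq)), key=lambda i: seq[i:])


def oracle_lcp(text, sa) -> list[int]:
    seq = list(text)
    out = [0]
    for prev, cur in zip(sa, sa[1:]):
        a, b = seq[prev:], seq[cur:]
        h = 0
        while h < len(a) and h < len(b) and a[h] == b[h]:
            h += 1
        out.append(h)
    return out


def oracle_mul(genome: dict[str, str]) -> dict[str, list[int]]:
    """Positionwise smallest m whose m-mer occurs exactly once in the
    forward + reverse-complement segment collection; -1 when none exists
    (boundary reached, or the position sits in a non-ACGT run)."""
    segments: list[str] = []
    for seq in genome.values():
        seq = seq.upper()
        segments.append(seq)
        segments.append(revcomp(seq))

    def occurrences(kmer: str) -> int:
        total = 0
        for seg in segments:
            i = seg.find(kmer)
            while i != -1:
                total += 1
                i = seg.find(kmer, i + 1)
        return total

    out: dict[str, list[int]] = {}
    for chrom, seq in genome.items():
        seq = seq.upper()
        arr = []
        for i in range(len(seq)):
            value = -1
            for m in range(1, len(seq) - i + 1):
                kmer = seq[i : i + m]
                if any(c not in "ACGT" for c in kmer):
                    break
                if occurrences(kmer) == 1:
                    value = m
                    break
            arr.append(value)
        out[chrom] = arr
    return out


def random_genome(
    rng: np.random.Generator,
    length: int,
    *,
    with_repeat: bool = False,
    with_n_run: bool = False,
    alphabet: str = "ACGT",
) -> dict[str, str]:
    seq = list(
        np.array(list(alphabet))[rng.integers(0, len(alphabet), size=length)]
    )
    if with_repeat and length >= 60:
        rep = length // 5
        src = int(rng.integers(0, length // 2 - rep))
        dst = int(rng.integers(length // 2, length - rep))
        seq[dst : dst + rep] = seq[src : src + rep]
    if with_n_run and length >= 40:
        run = int(rng.integers(3, 10))
        start = int(rng.integers(0, length - run))
        seq[start : start + run] = ["N"] * run
    return {"chr1": "".join(seq)}


# ------------------------------------------------------------------- merging


def oracle_merge(peaks: list[Peak]) -> list[tuple[str, int, int, int]]:
    """Connected components of the pairwise-overlap graph.

    Returns sorted (chrom, start, end, n_constituents) tuples.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(peaks)))
    for i, a in enumerate(peaks):
        for j in range(i + 1, len(peaks)):
            if a.interval.overlaps(peaks[j].interval):
                g.add_edge(i, j)
    out = []
    for comp in nx.connected_components(g):
        ivs = [peaks[i].interval for i in comp]
        out.append(
            (
                ivs[0].chrom,
                min(iv.start for iv in ivs),
                max(iv.end for iv in ivs),
                len(comp),
            )
        )
    return sorted(out)


def random_peaks(
    rng: np.random.Generator,
    n: int,
    *,
    callers: tuple[str, ...] = ("MACS", "GEM", "SISSRs", "PICS"),
    chroms: tuple[str, ...] = ("chr1", "chr2"),
    span: int = 2000,
) -> list[Peak]:
    peaks = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        width = int(rng.integers(1, 120))
        peaks.append(
            Peak(
                interval=GenomicInterval(
                    str(rng.choice(list(chroms))), start, start + width
                ),
                caller=str(rng.choice(list(callers))),
            )
        )
    return peaks


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
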