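"""Linear-time suffix array (SA-IS) and LCP array (Kasai) construction.

Both operate on integer sequences. The input to :func:`build_suffix_array`
may be a ``str`` or a sequence of non-negative integers; internally a unique
terminal sentinel (0, strictly smaller than every other symbol) is appended,
and the suffix of the sentinel itself is dropped from the returned array, so
``SA`` is a permutation of ``range(len(text))`` sorting the suffixes of the
text as given.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["build_suffix_array", "build_lcp"]


def _sais(s: list[int], K: int) -> list[int]:
    """SA-IS induced-sorting suffix array of ``s`` over alphabet [0, K).

    ``s`` must end with a unique smallest symbol (the sentinel).
    """
    n = len(s)
    sa = [-1] * n
    if n == 1:
        return [0]
    if n == 2:
        return [1, 0]

    # classify suffixes: True = S-type, False = L-type
    t = [False] * n
    t[n - 1] = True
    for i in range(n - 2, -1, -1):
        t[i] = s[i] < s[i + 1] or (s[i] == s[i + 1] and t[i + 1])

    lms = [i for i in range(1, n) if t[i] and not t[i - 1]]

    bucket = [0] * K
    for c in s:
        bucket[c] += 1

    def bucket_ends() -> list[int]:
        ends, total = [0] * K, 0
        for c in range(K):
            total += bucket[c]
            ends[c] = total
        return ends

    def bucket_starts() -> list[int]:
        starts, total = [0] * K, 0
        for c in range(K):
            starts[c] = total
            total += bucket[c]
        return starts

    def induce(lms_order: list[int]) -> None:
        for i in range(n):
            sa[i] = -1
        ends = bucket_ends()
        for i in reversed(lms_order):
            c = s[i]
            ends[c] -= 1
            sa[ends[c]] = i
        starts = bucket_starts()
        for k in range(n):
            i = sa[k]
            if i > 0 and not t[i - 1]:
                c = s[i - 1]
                sa[starts[c]] = i - 1
                starts[c] += 1
        ends = bucket_ends()
        for k in range(n - 1, -1, -1):
            i = sa[k]
            if i > 0 and t[i - 1]:
                c = s[i - 1]
                ends[c] -= 1
                sa[ends[c]] = i - 1

    induce(lms)

    # name LMS substrings in their sorted order
    lms_sorted = [i for i in sa if i > 0 and t[i] and not t[i - 1]]
    name = [-1] * n
    cur = 0
    prev = -1
    for i in lms_sorted:
        if prev >= 0:
            # compare LMS substrings at prev and i (inclusive of closing LMS)
            a, b = prev, i
            same = True
            first = True
            while True:
                if s[a] != s[b] or t[a] != t[b]:
                    same = False
                    break
                a_lms = a > 0 and t[a] and not t[a - 1]
                b_lms = b > 0 and t[b] and not t[b - 1]
                if not first and (a_lms or b_lms):
                    same = a_lms and b_lms
                    break
                first = False
                a += 1
                b += 1
                if a >= n or b >= n:
                    same = a >= n and b >= n
                    break
            if not same:
                cur += 1
        name[i] = cur
        prev = i
    reduced = [name[i] for i in lms]

    if cur + 1 == len(lms):
        order = [0] * len(lms)
        for idx, nm in enumerate(reduced):
            order[nm] = lms[idx]
    else:
        sub_sa = _sais(reduced, cur + 1)
        order = [lms[j] for j in sub_sa]

    induce(order)
    return sa


def build_suffix_array(text: str | Sequence[int]) -> np.ndarray:
    """Suffix array of ``text``: positions of suffixes in lexicographic order.

    A sentinel smaller than every symbol is appended internally and excluded
    from the result, so the output is a permutation of ``range(len(text))``.
    """
    if len(text) == 0:
        raise ValueError("cannot build a suffix array of empty text")
    if isinstance(text, str):
        codes = [ord(c) + 1 for c in text]
        K = max(codes) + 1
    else:
        codes = [int(c) + 1 for c in text]
        if min(codes) < 1:
            raise ValueError("integer text symbols must be non-negative")
        K = max(codes) + 1
    codes.append(0)  # unique smallest sentinel
    sa = _sais(codes, K)
    # sa[0] is the sentinel suffix; drop it
    return np.asarray(sa[1:], dtype=np.int64)


def build_lcp(text: str | Sequence[int], sa: np.ndarray) -> np.ndarray:
    """Kasai LCP array: ``lcp[i]`` = LCP of suffixes ``sa[i-1]`` and ``sa[i]``.

    ``lcp[0] = 0`` by convention.
    """
    n = len(text)
    if n != len(sa):
        raise ValueError("suffix array length does not match text length")
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and text[i + h] == text[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp
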