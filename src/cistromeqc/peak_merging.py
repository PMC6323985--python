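"""Union-of-overlaps peak merging, clusters, and meta-clusters.

Peaks from several callers on one experiment are merged single-linkage
(two intervals join when they share at least one base; chains propagate),
and each merged peak records how many constituent peaks formed it — its
*frequency*. The histogram of frequencies f_k over merged peaks is the
capture-recapture input: a merged peak seen by few callers is weak evidence,
one seen by all is strong. Clusters merge one TF/one caller across
experiments; meta-clusters merge clusters across callers and are the
non-redundant binding-site set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import GenomicInterval, Peak

__all__ = [
    "MergedPeak",
    "FrequencySpectrum",
    "MetaCluster",
    "merge_peaks",
    "frequency_spectrum",
    "presence_counts",
    "build_clusters",
    "build_metaclusters",
]


@dataclass
class MergedPeak:
    """Union span of a connected set of mutually/chained-overlapping peaks."""

    interval: GenomicInterval
    constituents: list[Peak]

    @property
    def frequency(self) -> int:
        """Number of constituent peaks (not distinct callers)."""
        return len(self.constituents)

    @property
    def callers(self) -> frozenset[str]:
        return frozenset(p.caller for p in self.constituents)

    @property
    def experiments(self) -> frozenset[str]:
        return frozenset(
            p.experiment_id for p in self.constituents if p.experiment_id
        )


@dataclass
class FrequencySpectrum:
    """Histogram f_k = #{merged peaks formed by exactly k constituents}.

    S is the number of merged peaks, T = sum k*f_k the total constituent
    count; conservation T == number of input peaks always holds.
    """

    f: dict[int, int]

    @property
    def S(self) -> int:
        return sum(self.f.values())

    @property
    def T(self) -> int:
        return sum(k * v for k, v in self.f.items())

    def __getitem__(self, k: int) -> int:
        return self.f.get(k, 0)


@dataclass
class MetaCluster:
    interval: GenomicInterval
    tf: str
    supporting_callers: frozenset[str]
    supporting_experiments: frozenset[str]
    member_clusters: list[MergedPeak] = field(default_factory=list)


def _merge_sorted(peaks: list[Peak]) -> list[MergedPeak]:
    """Single-linkage sweep over peaks sorted by (chrom, start, end).

    Overlap is strict under half-open coordinates: abutting intervals
    ([0,10) and [10,20)) do not merge.
    """
    merged: list[MergedPeak] = []
    cur: list[Peak] = []
    cur_chrom = None
    cur_end = -1
    for p in peaks:
        iv = p.interval
        if cur and iv.chrom == cur_chrom and iv.start < cur_end:
            cur.append(p)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                merged.append(_finish(cur_chrom, cur))
            cur = [p]
            cur_chrom = iv.chrom
            cur_end = iv.end
    if cur:
        merged.append(_finish(cur_chrom, cur))
    return merged


def _finish(chrom: str, peaks: list[Peak]) -> MergedPeak:
    start = min(p.interval.start for p in peaks)
    end = max(p.interval.end for p in peaks)
    return MergedPeak(interval=GenomicInterval(chrom, start, end), constituents=peaks)


def merge_peaks(
    peak_sets: Mapping[str, Sequence[Peak]] | Sequence[Sequence[Peak]],
) -> list[MergedPeak]:
    """Merge per-caller peak sets into union-of-overlaps merged peaks.

    ``peak_sets`` is either a mapping caller -> peaks (the caller label is
    stamped onto peaks that lack one) or a plain sequence of peak lists.
    Returns merged peaks sorted by (chrom, start, end); each records its
    constituents, and the result is independent of input order.
    """
    pooled: list[Peak] = []
    if isinstance(peak_sets, Mapping):
        for caller, peaks in peak_sets.items():
            for p in peaks:
                if not p.caller:
                    p = Peak(
                        interval=p.interval,
                        caller=caller,
                        experiment_id=p.experiment_id,
                        tf=p.tf,
                        score=p.score,
                        summit_offset=p.summit_offset,
                    )
                pooled.append(p)
    else:
        for peaks in peak_sets:
            pooled.extend(peaks)
    if not pooled:
        return []
    pooled.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    return _merge_sorted(pooled)


def frequency_spectrum(merged: Iterable[MergedPeak]) -> FrequencySpectrum:
    """f_k histogram of merged-peak frequencies (empty input -> S = 0)."""
    counts = Counter(m.frequency for m in merged)
    return FrequencySpectrum(f=dict(sorted(counts.items())))


def presence_counts(
    merged: Iterable[MergedPeak], callers: Sequence[str]
) -> dict[tuple[str, str], tuple[int, int, int]]:
    """Per-caller-pair (n1, n2, m) capture counts for Chapman's estimator.

    n_i counts merged peaks containing at least one peak from caller i;
    m counts merged peaks seen by both callers of the pair.
    """
    merged = list(merged)
    seen = {c: [c in mp.callers for mp in merged] for c in callers}
    out: dict[tuple[str, str], tuple[int, int, int]] = {}
    for i, c1 in enumerate(callers):
        for c2 in callers[i + 1 :]:
            n1 = sum(seen[c1])
            n2 = sum(seen[c2])
            m = sum(a and b for a, b in zip(seen[c1], seen[c2]))
            out[(c1, c2)] = (n1, n2, m)
    return out


def build_clusters(peaks: Sequence[Peak]) -> list[MergedPeak]:
    """Merge one TF's peaks from one caller across experiments into clusters.

    All peaks must share the same tf and caller; provenance (experiment ids)
    is preserved on the constituents.
    """
    if not peaks:
        return []
    callers = {p.caller for p in peaks}
    tfs = {p.tf for p in peaks}
    if len(callers) > 1:
        raise ValueError(f"clusters require a single caller, got {sorted(callers)}")
    if len(tfs) > 1:
        raise ValueError(f"clusters require a single TF, got {sorted(tfs)}")
    return merge_peaks([list(peaks)])


def build_metaclusters(
    clusters_per_caller: Mapping[str, Sequence[MergedPeak]],
    *,
    min_callers: int = 1,
) -> list[MetaCluster]:
    """Merge per-caller clusters for one TF into meta-clusters.

    Meta-cluster coordinates are the union span of the member clusters;
    ``min_callers`` drops meta-clusters supported by fewer distinct callers.
    """
    flat: list[tuple[GenomicInterval, str, MergedPeak]] = []
    for caller, clusters in clusters_per_caller.items():
        for cl in clusters:
            flat.append((cl.interval, caller, cl))
    if not flat:
        return []
    tfs = {p.tf for _, _, cl in flat for p in cl.constituents if p.tf}
    if len(tfs) > 1:
        raise ValueError(f"meta-clusters require a single TF, got {sorted(tfs)}")
    tf = next(iter(tfs), "")
    flat.sort(key=lambda x: (x[0].chrom, x[0].start, x[0].end))

    metas: list[MetaCluster] = []
    group: list[tuple[GenomicInterval, str, MergedPeak]] = []
    cur_chrom, cur_end = None, -1

    def finish() -> None:
        iv = GenomicInterval(
            cur_chrom,
            min(g[0].start for g in group),
            max(g[0].end for g in group),
        )
        callers = frozenset(g[1] for g in group)
        experiments = frozenset(
            e for g in group for e in g[2].experiments
        )
        metas.append(
            MetaCluster(
                interval=iv,
                tf=tf,
                supporting_callers=callers,
                supporting_experiments=experiments,
                member_clusters=[g[2] for g in group],
            )
        )

    for item in flat:
        iv = item[0]
        if group and iv.chrom == cur_chrom and iv.start < cur_end:
            group.append(item)
            cur_end = max(cur_end, iv.end)
        else:
            if group:
                finish()
            group = [item]
            cur_chrom, cur_end = iv.chrom, iv.end
    if group:
        finish()
    return [m for m in metas if len(m.supporting_callers) >= min_callers]
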