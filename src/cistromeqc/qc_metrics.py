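"""ChIP-seq quality metrics: ENCODE library/signal metrics plus the
capture-recapture FNCM / FPCM peak-level controls.

Library complexity (from deduplication-eligible tag positions):
  NRF   distinct (chrom, pos5, strand) fraction of all tags
  PBC1  single-tag positions / distinct positions
  PBC2  single-tag positions / two-tag positions (inf when none)

Signal (from the +/- strand 5'-start cross-correlation profile):
  NSC   cc(fragment length) / min cc
  RSC   (cc(fragment length) - min cc) / (cc(read length) - min cc)
  FRiP  fraction of tags whose 5' position falls in a called peak

Peak-level controls (against capture-recapture expectations):
  FNCM  observed / expected peak count for one caller; << 1 flags missed
        peaks (false negatives)
  FPCM  observed / expected unit-frequency merged peaks, with the expected
        singleton count from the Poisson model E[f1] = N * lambda * e^-lambda;
        >> 1 flags excess caller-specific peaks (false positives)
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np

from .capture_recapture import (
    expected_peak_count,
    mle_ztp_estimate,
    zelterman_estimate,
)
from .io_formats import Peak, TagRecord
from .peak_merging import (
    FrequencySpectrum,
    frequency_spectrum,
    merge_peaks,
    presence_counts,
)

__all__ = [
    "CrossCorrelationResult",
    "QCReport",
    "fncm",
    "fpcm",
    "nrf",
    "pbc",
    "frip",
    "cross_correlation",
    "qc_report",
]


def nrf(tags: Sequence[TagRecord]) -> float:
    """Non-redundancy fraction: distinct tag positions / total tags."""
    if not tags:
        raise ValueError("NRF undefined for empty tag list")
    distinct = len({(t.chrom, t.pos5, t.strand) for t in tags})
    return distinct / len(tags)


def pbc(tags: Sequence[TagRecord]) -> tuple[float, float]:
    """PCR bottlenecking coefficients (PBC1, PBC2).

    M1 = positions with exactly one tag, M2 = with exactly two;
    PBC1 = M1 / #distinct positions, PBC2 = M1 / M2 (inf when M2 = 0).
    """
    if not tags:
        raise ValueError("PBC undefined for empty tag list")
    counts = Counter((t.chrom, t.pos5, t.strand) for t in tags)
    m1 = sum(1 for c in counts.values() if c == 1)
    m2 = sum(1 for c in counts.values() if c == 2)
    pbc1 = m1 / len(counts)
    pbc2 = m1 / m2 if m2 > 0 else math.inf
    return pbc1, pbc2


def frip(tags: Sequence[TagRecord], peaks: Sequence[Peak]) -> float:
    """Fraction of tags whose 5' position lies inside any peak (half-open)."""
    if not tags:
        raise ValueError("FRiP undefined for empty tag list")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(
            (p.interval.start, p.interval.end)
        )
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        # flatten to disjoint sorted spans so a single searchsorted decides
        ivs.sort()
        flat: list[tuple[int, int]] = []
        for s, e in ivs:
            if flat and s <= flat[-1][1]:
                flat[-1] = (flat[-1][0], max(flat[-1][1], e))
            else:
                flat.append((s, e))
        starts[chrom] = np.array([s for s, _ in flat])
        ends[chrom] = np.array([e for _, e in flat])
    inside = 0
    for t in tags:
        if t.chrom not in starts:
            continue
        i = np.searchsorted(starts[t.chrom], t.pos5, side="right") - 1
        if i >= 0 and t.pos5 < ends[t.chrom][i]:
            inside += 1
    return inside / len(tags)


@dataclass
class CrossCorrelationResult:
    shifts: np.ndarray
    cc: np.ndarray
    fragment_length: int  # argmax shift outside the phantom exclusion zone
    cc_frag: float
    cc_read: float
    cc_min: float
    nsc: float
    rsc: float


# half-width of the phantom-peak exclusion zone around the read length
_PHANTOM_EXCLUSION = 5


def cross_correlation(
    tags: Sequence[TagRecord],
    max_shift: int,
    read_length: int,
) -> CrossCorrelationResult:
    """Strand cross-correlation profile with NSC/RSC.

    For each shift d in [0, max_shift], the Pearson correlation between the
    per-position + strand 5'-count vector and the - strand vector shifted by
    d, computed per chromosome over the covered span and combined across
    chromosomes by overlap-length-weighted average. The fragment-length peak
    cc_frag is the maximum outside a +-5 bp exclusion zone around the read
    length (the "phantom peak"); NSC = cc_frag / cc_min and
    RSC = (cc_frag - cc_min) / (cc_read - cc_min).
    """
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    by_chrom: dict[str, list[TagRecord]] = {}
    for t in tags:
        by_chrom.setdefault(t.chrom, []).append(t)

    shifts = np.arange(max_shift + 1)
    weighted = np.zeros(max_shift + 1)
    weights = np.zeros(max_shift + 1)
    any_plus = any_minus = False
    for chrom, ctags in sorted(by_chrom.items()):
        plus_pos = np.array([t.pos5 for t in ctags if t.strand == "+"])
        minus_pos = np.array([t.pos5 for t in ctags if t.strand == "-"])
        if plus_pos.size:
            any_plus = True
        if minus_pos.size:
            any_minus = True
        if plus_pos.size == 0 or minus_pos.size == 0:
            continue
        lo = int(min(plus_pos.min(), minus_pos.min()))
        hi = int(max(plus_pos.max(), minus_pos.max())) + 1
        span = hi - lo
        plus = np.bincount(plus_pos - lo, minlength=span).astype(float)
        minus = np.bincount(minus_pos - lo, minlength=span).astype(float)
        for d in shifts:
            if span - d < 2:
                continue
            a = plus[: span - d]
            b = minus[d:]
            sa_ = a.std()
            sb = b.std()
            if sa_ == 0 or sb == 0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            weighted[d] += r * (span - d)
            weights[d] += span - d
    if not (any_plus and any_minus):
        raise ValueError("cross-correlation requires tags on both strands")
    if not (weights > 0).all():
        raise ValueError(
            "cross-correlation undefined: constant coverage or span shorter "
            "than max_shift"
        )
    cc = weighted / weights

    exclusion = np.abs(shifts - read_length) <= _PHANTOM_EXCLUSION
    if exclusion.all():
        raise ValueError("max_shift leaves no shifts outside the exclusion zone")
    cc_masked = np.where(exclusion, -np.inf, cc)
    frag_len = int(np.argmax(cc_masked))
    cc_frag = float(cc[frag_len])
    if read_length > max_shift:
        raise ValueError("read_length must be <= max_shift")
    cc_read = float(cc[read_length])
    cc_min = float(cc.min())
    nsc = cc_frag / cc_min if cc_min != 0 else math.inf
    denom = cc_read - cc_min
    rsc = (cc_frag - cc_min) / denom if denom != 0 else math.inf
    return CrossCorrelationResult(
        shifts=shifts,
        cc=cc,
        fragment_length=frag_len,
        cc_frag=cc_frag,
        cc_read=cc_read,
        cc_min=cc_min,
        nsc=nsc,
        rsc=rsc,
    )


def fncm(observed_peaks: int, expected_N: float) -> float:
    """False-negative control metric: observed / expected peak count.

    Values well below 1 mean the caller reported far fewer peaks than
    capture-recapture expects — it is missing true sites.
    """
    if observed_peaks < 0:
        raise ValueError("observed peak count must be >= 0")
    if expected_N <= 0:
        raise ValueError(f"expected peak count must be > 0, got {expected_N}")
    return observed_peaks / expected_N


def fpcm(
    spectrum: FrequencySpectrum, lambda_hat: float, N_hat: float
) -> float:
    """False-positive control metric: observed f1 / expected f1.

    Under Poisson(lambda) captures of N true sites the expected number of
    unit-frequency merged peaks is E[f1] = N * lambda * e^-lambda (Poisson
    pmf at 1 scaled by the population size). Excess observed singletons
    (FPCM >> 1) indicate caller-specific false positives.
    """
    if lambda_hat <= 0 or N_hat <= 0:
        raise ValueError("FPCM requires lambda_hat > 0 and N_hat > 0")
    expected_f1 = N_hat * lambda_hat * math.exp(-lambda_hat)
    if expected_f1 <= 0:
        raise ValueError("expected unit-frequency count is zero")
    return spectrum[1] / expected_f1


@dataclass
class QCReport:
    """All metrics for one experiment; None marks a metric that could not
    be computed (e.g. NSC/RSC with single-stranded tags)."""

    nrf: float | None = None
    pbc1: float | None = None
    pbc2: float | None = None
    nsc: float | None = None
    rsc: float | None = None
    fragment_length: int | None = None
    frip: float | None = None
    fncm: dict[str, float] | None = None  # per caller
    fpcm: float | None = None
    expected_peak_count: float | None = None
    estimates: dict[str, float | None] | None = None
    warnings: list[str] | None = None

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, float) and math.isinf(o):
                return "inf"
            raise TypeError(type(o))

        d = asdict(self)
        d = {
            k: ("inf" if isinstance(v, float) and math.isinf(v) else v)
            for k, v in d.items()
        }
        return json.dumps(d, indent=2, default=default)

    @classmethod
    def from_json(cls, text: str) -> "QCReport":
        d = json.loads(text)
        for k, v in d.items():
            if v == "inf":
                d[k] = math.inf
        return cls(**d)


def qc_report(
    tags: Sequence[TagRecord],
    peaks_per_caller: Mapping[str, Sequence[Peak]],
    *,
    read_length: int,
    max_shift: int = 400,
) -> QCReport:
    """Assemble the full QC report for one experiment.

    FNCM is computed per caller against the mean of the defined population
    estimators; FPCM uses lambda and N from the zero-truncated Poisson MLE,
    falling back to Zelterman when the MLE is undefined (the MLE's lambda
    comes from the mean capture count T/S, which stays stable when
    caller-specific singleton noise contaminates f1 — exactly the situation
    FPCM must detect). FRiP is taken against the union of all callers'
    peaks.
    """
    report = QCReport(warnings=[])
    report.nrf = nrf(tags)
    report.pbc1, report.pbc2 = pbc(tags)

    all_peaks = [p for peaks in peaks_per_caller.values() for p in peaks]
    report.frip = frip(tags, all_peaks)

    try:
        ccr = cross_correlation(tags, max_shift=max_shift, read_length=read_length)
        report.nsc = ccr.nsc
        report.rsc = ccr.rsc
        report.fragment_length = ccr.fragment_length
    except ValueError as exc:
        report.warnings.append(f"cross-correlation: {exc}")

    merged = merge_peaks(dict(peaks_per_caller))
    spectrum = frequency_spectrum(merged)
    pairs = presence_counts(merged, list(peaks_per_caller))
    try:
        mean_N, ests = expected_peak_count(spectrum, pairs)
        report.expected_peak_count = mean_N
        report.estimates = {
            e.estimator: (e.N_hat if e.defined else None) for e in ests
        }
        report.fncm = {
            caller: fncm(len(peaks), mean_N)
            for caller, peaks in peaks_per_caller.items()
        }
    except ValueError as exc:
        report.warnings.append(f"expected peak count: {exc}")

    lam_src = mle_ztp_estimate(spectrum)
    if not lam_src.defined:
        lam_src = zelterman_estimate(spectrum)
    if lam_src.defined and lam_src.lambda_hat:
        try:
            report.fpcm = fpcm(spectrum, lam_src.lambda_hat, lam_src.N_hat)
        except ValueError as exc:
            report.warnings.append(f"FPCM: {exc}")
    else:
        report.warnings.append("FPCM: no defined lambda estimator")
    return report
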