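"""Population-size estimators over the merged-peak frequency spectrum.

Peak callers play the role of capture occasions in an ecological
capture-recapture design: a true binding site "captured" k times appears as
a merged peak of frequency k, and sites captured zero times are unobserved.
Under a homogeneous Poisson capture model with rate lambda, the observed
frequencies f_1, f_2, f_3, ... estimate the number of unseen sites f_0 and
hence the total number of true peaks N = S + f_0 (S = observed merged
peaks). Five classical estimators are provided; the expected true peak
count used by the QC metrics is their arithmetic mean over those that are
defined for the given spectrum.

Estimators
----------
chao                 N = S + f1^2 / (2 f2)             (lower bound)
lanumteang_bohning   N = S + 3 f1^3 f3 / (4 f2^3)      (3-frequency extension)
zelterman            lambda = 2 f2 / f1; N = S / (1 - exp(-lambda))
mle_ztp              zero-truncated Poisson ML: solve lambda/(1-e^-lambda) = T/S
chapman              two-source: N = (n1+1)(n2+1)/(m+1) - 1
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .peak_merging import FrequencySpectrum

__all__ = [
    "PopulationEstimate",
    "chao_estimate",
    "lanumteang_bohning_estimate",
    "zelterman_estimate",
    "mle_ztp_estimate",
    "chapman_estimate",
    "chapman_from_pairs",
    "expected_peak_count",
    "all_estimates",
]

ESTIMATOR_NAMES = ("chao", "lanumteang_bohning", "zelterman", "mle_ztp", "chapman")


@dataclass(frozen=True)
class PopulationEstimate:
    """One estimator's result: N_hat = S + f0_hat when spectrum-based.

    ``defined`` is False when the spectrum lacks the frequencies the
    estimator needs (it is then excluded from the average).
    """

    estimator: str
    N_hat: float = math.nan
    f0_hat: float = math.nan
    lambda_hat: float | None = None
    defined: bool = True
    reason: str = ""

    @classmethod
    def undefined(cls, estimator: str, reason: str) -> "PopulationEstimate":
        return cls(estimator=estimator, defined=False, reason=reason)


def chao_estimate(spectrum: FrequencySpectrum) -> PopulationEstimate:
    """Chao's lower-bound estimator, f0 = f1^2 / (2 f2).

    With no doubletons the bias-corrected form f1(f1-1)/(2(f2+1)) applies,
    so the estimate is always defined (f1 = 0 gives N = S).
    """
    S = spectrum.S
    if S < 1:
        return PopulationEstimate.undefined("chao", "empty spectrum")
    f1, f2 = spectrum[1], spectrum[2]
    if f2 > 0:
        f0 = f1 * f1 / (2.0 * f2)
    else:
        f0 = f1 * (f1 - 1) / 2.0  # bias-corrected, f2 = 0
    return PopulationEstimate("chao", N_hat=S + f0, f0_hat=f0)


def lanumteang_bohning_estimate(spectrum: FrequencySpectrum) -> PopulationEstimate:
    """Three-frequency extension of Chao's estimator.

    Chao's f1^2/(2 f2) is scaled by the ratio 3 f1 f3 / (2 f2^2), which has
    expectation 1 under homogeneous Poisson captures and exceeds 1 under
    capture-rate heterogeneity:

        f0 = 3 f1^3 f3 / (4 f2^3).

    Requires f1, f2, f3 > 0; undefined otherwise.
    """
    S = spectrum.S
    if S < 1:
        return PopulationEstimate.undefined("lanumteang_bohning", "empty spectrum")
    f1, f2, f3 = spectrum[1], spectrum[2], spectrum[3]
    if f1 == 0 or f2 == 0 or f3 == 0:
        return PopulationEstimate.undefined(
            "lanumteang_bohning", "requires f1, f2, f3 > 0"
        )
    f0 = 3.0 * f1**3 * f3 / (4.0 * f2**3)
    return PopulationEstimate("lanumteang_bohning", N_hat=S + f0, f0_hat=f0)


def zelterman_estimate(spectrum: FrequencySpectrum) -> PopulationEstimate:
    """Zelterman's estimator: lambda = 2 f2 / f1, N = S / (1 - e^-lambda)."""
    S = spectrum.S
    if S < 1:
        return PopulationEstimate.undefined("zelterman", "empty spectrum")
    f1, f2 = spectrum[1], spectrum[2]
    if f1 == 0 or f2 == 0:
        return PopulationEstimate.undefined("zelterman", "requires f1, f2 > 0")
    lam = 2.0 * f2 / f1
    N = S / (1.0 - math.exp(-lam))
    return PopulationEstimate("zelterman", N_hat=N, f0_hat=N - S, lambda_hat=lam)


def ztp_mean(lam: float) -> float:
    """Mean of the zero-truncated Poisson: lambda / (1 - e^-lambda)."""
    return lam / (1.0 - math.exp(-lam))


_BISECT_LO = 1e-8
_BISECT_HI = 50.0
_BISECT_TOL = 1e-9


def mle_ztp_estimate(spectrum: FrequencySpectrum) -> PopulationEstimate:
    """Zero-truncated Poisson maximum-likelihood estimator.

    The ZTP MLE of lambda solves lambda / (1 - e^-lambda) = T/S (the mean
    capture count among observed sites). The left side is strictly
    increasing, so the root is found by bisection on (1e-8, 50] to absolute
    tolerance 1e-9; N = S / (1 - e^-lambda). Undefined when T/S <= 1 (all
    singletons: lambda -> 0 and N is unbounded) or the mean exceeds the
    bracket.
    """
    S = spectrum.S
    if S < 1:
        return PopulationEstimate.undefined("mle_ztp", "empty spectrum")
    mbar = spectrum.T / S
    if mbar <= 1.0 + 1e-12:
        return PopulationEstimate.undefined(
            "mle_ztp", f"mean capture count {mbar:.4g} <= 1"
        )
    lo, hi = _BISECT_LO, _BISECT_HI
    if ztp_mean(hi) < mbar:
        return PopulationEstimate.undefined(
            "mle_ztp", f"mean capture count {mbar:.4g} beyond bracket"
        )
    while hi - lo > _BISECT_TOL:
        mid = 0.5 * (lo + hi)
        if ztp_mean(mid) < mbar:
            lo = mid
        else:
            hi = mid
    lam = 0.5 * (lo + hi)
    N = S / (1.0 - math.exp(-lam))
    return PopulationEstimate("mle_ztp", N_hat=N, f0_hat=N - S, lambda_hat=lam)


def chapman_estimate(n1: int, n2: int, m: int) -> PopulationEstimate:
    """Chapman's bias-corrected two-source (Lincoln-Petersen) estimator:

        N = (n1 + 1)(n2 + 1) / (m + 1) - 1.

    The +1 corrections keep the estimate finite when the sources share no
    captures (m = 0).
    """
    if n1 < 0 or n2 < 0 or not (0 <= m <= min(n1, n2)):
        raise ValueError(f"invalid capture counts n1={n1}, n2={n2}, m={m}")
    N = (n1 + 1) * (n2 + 1) / (m + 1) - 1.0
    return PopulationEstimate("chapman", N_hat=N, f0_hat=math.nan)


def chapman_from_pairs(
    pairs: Mapping[tuple[str, str], tuple[int, int, int]],
) -> PopulationEstimate:
    """Generalise Chapman to >2 callers: unweighted mean of the pairwise
    estimates over all caller pairs (from per-caller presence counts)."""
    if not pairs:
        return PopulationEstimate.undefined("chapman", "no caller pairs")
    values = [chapman_estimate(*counts).N_hat for counts in pairs.values()]
    return PopulationEstimate("chapman", N_hat=sum(values) / len(values),
                              f0_hat=math.nan)


def all_estimates(
    spectrum: FrequencySpectrum,
    presence_pairs: Mapping[tuple[str, str], tuple[int, int, int]] | None = None,
) -> list[PopulationEstimate]:
    """Every estimator applied to one spectrum (Chapman only with pairs)."""
    ests = [
        chao_estimate(spectrum),
        lanumteang_bohning_estimate(spectrum),
        zelterman_estimate(spectrum),
        mle_ztp_estimate(spectrum),
    ]
    if presence_pairs is not None:
        ests.append(chapman_from_pairs(presence_pairs))
    return ests


def expected_peak_count(
    spectrum: FrequencySpectrum,
    presence_pairs: Mapping[tuple[str, str], tuple[int, int, int]] | None = None,
) -> tuple[float, list[PopulationEstimate]]:
    """Expected true peak count: the arithmetic mean of all defined
    estimators' N_hat (undefined estimators are excluded, not imputed).

    Returns (mean, individual estimates). Raises when no estimator is
    defined; callers should then fall back to the observed count S.
    """
    if spectrum.S < 1:
        raise ValueError("empty spectrum: no merged peaks observed")
    ests = all_estimates(spectrum, presence_pairs)
    defined = [e for e in ests if e.defined and math.isfinite(e.N_hat)]
    if not defined:
        raise ValueError(
            "all population estimators undefined for this spectrum; "
            "fall back to the observed merged-peak count S"
        )
    mean = sum(e.N_hat for e in defined) / len(defined)
    return mean, ests
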