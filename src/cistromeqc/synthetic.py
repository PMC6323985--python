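"""Synthetic genomes, binding sites, caller peak sets and tag alignments.

The generators emit data with exactly the statistical structure the QC
mathematics assumes, so every estimator and metric can be tested against a
known ground truth without downloading anything:

* genomes are i.i.d. ACGT with optional planted exact repeats and N runs
  (the features mappability must detect);
* true binding sites are placed without overlap and "captured" by peak
  callers either under a homogeneous Poisson(lambda) model — each capture
  becomes one peak attributed to a uniformly random caller, so the
  merged-peak frequency spectrum is exactly zero-truncated Poisson — or
  under an independent per-caller Bernoulli(p) model;
* each caller additionally emits Poisson(noise_rate * n_true_sites) false
  peaks at random positions;
* tags are fragment ends around sites plus uniform background, with PCR
  duplicates injected at a configurable rate, so the strand cross-correlation
  peaks near the fragment length.

Everything is driven by one integer seed and is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import GenomicInterval, Peak, TagRecord

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_peak_sets",
    "simulate_tags",
]

DEFAULT_CALLERS = ("MACS", "GEM", "SISSRs", "PICS")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic world.

    Defaults describe a small but realistically structured experiment:
    four callers (MACS, GEM, SISSRs, PICS), Poisson(1.5) captures, 200 bp sites with
    10 bp placement jitter, 147 bp fragments sequenced as 36 bp reads.
    """

    seed: int = 0
    genome_length: int = 1_000_000
    chrom: str = "chrS"
    n_true_sites: int = 500
    capture_model: str = "poisson"  # "poisson" | "per_caller_bernoulli"
    capture_lambda: float = 1.5
    detection_probs: dict[str, float] | None = None
    callers: tuple[str, ...] = DEFAULT_CALLERS
    noise_rate: float = 0.0  # false peaks per true site, per caller
    site_width: int = 200
    width_sd: float = 20.0
    jitter_sd: float = 10.0
    min_gap: int = 100
    fragment_length: int = 147
    read_length: int = 36
    duplicate_rate: float = 0.0
    frags_per_site: int = 20
    background_tags: int = 2000
    background_block_width: int = 2000
    background_block_density: float = 0.2  # fraction of genome in blocks

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_genome(
    length: int,
    rng: np.random.Generator,
    *,
    repeat_length: int = 0,
    n_run_length: int = 0,
) -> str:
    """Random i.i.d. ACGT sequence with an optional planted exact repeat
    (the same substring copied to a second location) and one N run."""
    if length < 100:
        raise ValueError("genome length must be >= 100")
    seq = np.array(list("ACGT"))[rng.integers(0, 4, size=length)]
    if repeat_length:
        if 2 * repeat_length >= length:
            raise ValueError("repeat does not fit twice in the genome")
        src = int(rng.integers(0, length // 2 - repeat_length))
        dst = int(rng.integers(length // 2, length - repeat_length))
        seq[dst : dst + repeat_length] = seq[src : src + repeat_length]
    if n_run_length:
        start = int(rng.integers(0, length - n_run_length))
        seq[start : start + n_run_length] = "N"
    return "".join(seq)


def _place_sites(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping site start positions with >= min_gap spacing."""
    n, w, gap = config.n_true_sites, config.site_width, config.min_gap
    needed = n * (w + gap)
    extra = config.genome_length - needed
    if extra < 0:
        raise ValueError(
            f"cannot place {n} non-overlapping {w} bp sites in a "
            f"{config.genome_length} bp genome; increase genome_length"
        )
    # distribute the slack among the n+1 gaps
    slack = rng.multinomial(extra, np.full(n + 1, 1.0 / (n + 1)))
    starts = np.cumsum(slack[:-1] + gap + w) - w
    return starts.astype(np.int64)


def simulate_peak_sets(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[GenomicInterval], dict[str, list[Peak]]]:
    """True sites plus per-caller peak lists under the capture model.

    Returns (true_sites, peaks_per_caller). Detected peaks are jittered in
    position (Normal(0, jitter_sd)) and width (Normal(0, width_sd), floored
    at 50 bp); each caller adds Poisson(noise_rate * n_true_sites) false
    peaks uniformly over the genome.
    """
    rng = config.rng() if rng is None else rng
    starts = _place_sites(config, rng)
    w = config.site_width
    true_sites = [
        GenomicInterval(config.chrom, int(s), int(s) + w) for s in starts
    ]
    callers = list(config.callers)
    peaks: dict[str, list[Peak]] = {c: [] for c in callers}

    def emit(caller: str, site_start: int, exp_id: str) -> None:
        jitter = int(round(rng.normal(0.0, config.jitter_sd)))
        width = max(50, int(round(w + rng.normal(0.0, config.width_sd))))
        start = max(0, site_start + jitter)
        end = min(config.genome_length, start + width)
        if end <= start:
            return
        peaks[caller].append(
            Peak(
                interval=GenomicInterval(config.chrom, start, end),
                caller=caller,
                experiment_id=exp_id,
            )
        )

    if config.capture_model == "poisson":
        counts = rng.poisson(config.capture_lambda, size=len(starts))
        for s, k in zip(starts, counts):
            for _ in range(int(k)):
                emit(callers[int(rng.integers(len(callers)))], int(s), "sim")
    elif config.capture_model == "per_caller_bernoulli":
        probs = config.detection_probs or {c: 0.8 for c in callers}
        for s in starts:
            for c in callers:
                if rng.random() < probs.get(c, 0.8):
                    emit(c, int(s), "sim")
    else:
        raise ValueError(f"unknown capture model {config.capture_model!r}")

    if config.noise_rate > 0:
        for c in callers:
            n_noise = int(rng.poisson(config.noise_rate * config.n_true_sites))
            for _ in range(n_noise):
                pos = int(rng.integers(0, config.genome_length - w))
                emit(c, pos, "sim")
    return true_sites, peaks


def simulate_tags(
    config: SimulationConfig,
    sites: list[GenomicInterval],
    rng: np.random.Generator | None = None,
) -> list[TagRecord]:
    """Tag 5'-start records from fragments centred on sites plus background.

    Each site sheds ``frags_per_site`` fragments of ``fragment_length`` bp
    whose centres jitter around the site centre; the + strand tag sits at
    the fragment start and the - strand tag at the fragment end, so the
    strand cross-correlation peaks near the fragment length. Background
    tags fall in broad accessible blocks covering
    ``background_block_density`` of the genome (random strand): real
    libraries concentrate in mappable open chromatin, and this large-scale
    covariation of the two strands is what keeps the baseline
    cross-correlation — hence cc_min — positive. Duplicates are injected by
    re-emitting already drawn tags at rate ``duplicate_rate``.
    """
    rng = config.rng() if rng is None else rng
    if config.fragment_length <= config.read_length:
        raise ValueError("fragment_length must exceed read_length")
    flen = config.fragment_length
    tags: list[TagRecord] = []
    for site in sites:
        centre = (site.start + site.end) // 2
        for _ in range(config.frags_per_site):
            shift = int(round(rng.normal(0.0, config.jitter_sd)))
            frag_start = centre + shift - flen // 2
            if frag_start < 0 or frag_start + flen > config.genome_length:
                continue
            if rng.random() < 0.5:
                tags.append(TagRecord(site.chrom, frag_start, "+"))
            else:
                tags.append(TagRecord(site.chrom, frag_start + flen - 1, "-"))
    block_w = max(1, config.background_block_width)
    n_blocks = max(
        1,
        int(config.background_block_density * config.genome_length / block_w),
    )
    block_starts = rng.integers(
        0, max(1, config.genome_length - block_w), size=n_blocks
    )
    for _ in range(config.background_tags):
        block = int(block_starts[int(rng.integers(n_blocks))])
        pos = block + int(rng.integers(0, block_w))
        strand = "+" if rng.random() < 0.5 else "-"
        tags.append(TagRecord(config.chrom, pos, strand))
    if config.duplicate_rate > 0 and tags:
        n_dup = int(round(config.duplicate_rate * len(tags)))
        for idx in rng.integers(0, len(tags), size=n_dup):
            tags.append(tags[int(idx)])
    order = rng.permutation(len(tags))
    return [tags[i] for i in order]
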