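"""From raw coverage/read data to normalized probability tracks and a
consensus nucleosome/linker reference map.

Peak calling follows the GeneTrack scheme: Gaussian-kernel smoothing of
read midpoints, greedy selection of local maxima in decreasing height with
an exclusion zone, and a minimum-height cutoff.  The reference map is a
second pass of the same machinery over the per-dataset calls ("as if each
annotated nucleosome were a read"), keeping consensus nucleosomes supported
by enough datasets; linkers are the maximal gaps covered by no dataset's
calls, subclassified into short linkers and NFRs by a length threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, stats

from .io_formats import CoverageTrack, GenomicRegion

logger = logging.getLogger(__name__)

NUC_WIDTH = 147

# GeneTrack-style defaults; results are insensitive to sigma and the cutoff
# within reason, and all are configurable.
DEFAULT_SIGMA = 20.0
DEFAULT_EXCLUSION = 147
DEFAULT_PEAK_HALFWIDTH = 73
DEFAULT_HEIGHT_CUTOFF = 3.0
DEFAULT_LINKER_THRESHOLD = 50
DEFAULT_TARGET_MEAN = 0.81
DEFAULT_TRIM = 0.001


@dataclass
class NormalizedCoverage:
    track: CoverageTrack
    a: float
    b: float
    trim_frac: float


@dataclass
class NucleosomeCall:
    chrom: str
    dyad: int
    height: float
    dataset: str


@dataclass
class ReferenceMap:
    nucleosomes: list[GenomicRegion]
    linkers: list[GenomicRegion]
    support: list[int]

    def regions(self) -> list[GenomicRegion]:
        return sorted(self.nucleosomes + self.linkers, key=lambda r: r.start)


# ---------------------------------------------------------------------------
# Coverage normalization (signal -> probability)
# ---------------------------------------------------------------------------


def normalize_coverage(signal: CoverageTrack, target_mean: float = DEFAULT_TARGET_MEAN,
                       trim_frac: float = DEFAULT_TRIM) -> NormalizedCoverage:
    """Map signal s to coverage probability p = exp((s - b) / a).

    b is the maximum retained (outlier-trimmed) signal so the largest signal
    maps to p = 1; a > 0 is solved so that mean(p) = target_mean.  Trimmed
    outliers are clamped into [0, 1] afterwards.
    """
    if not (0 < target_mean < 1):
        raise ValueError("target_mean must be in (0,1)")
    s = np.asarray(signal.values, dtype=float)
    if s.size == 0:
        raise ValueError("empty signal")
    lo, hi = np.quantile(s, [trim_frac, 1 - trim_frac])
    retained = s[(s >= lo) & (s <= hi)]
    if retained.size == 0:
        raise ValueError("all positions trimmed")
    b = float(retained.max())
    if np.ptp(retained) == 0:
        p = np.full_like(s, target_mean)
        return NormalizedCoverage(CoverageTrack(signal.chrom, np.clip(p, 0, 1),
                                                "probability"), np.inf, b, trim_frac)

    def mean_p(a: float) -> float:
        # clamped mean over all positions (outliers included after clamping)
        return float(np.mean(np.clip(np.exp(np.minimum((s - b) / a, 0.0)), 0.0, 1.0)))

    # mean_p is increasing in a: bracket then root-find
    a_lo, a_hi = 1e-9, 1.0
    while mean_p(a_hi) < target_mean:
        a_hi *= 2
        if a_hi > 1e12:
            raise ValueError("no slope a achieves the target mean")
    a = optimize.brentq(lambda x: mean_p(x) - target_mean, a_lo, a_hi, xtol=1e-12)
    p = np.exp((s - b) / a)
    p = np.clip(p, 0.0, 1.0)
    return NormalizedCoverage(CoverageTrack(signal.chrom, p, "probability"),
                              float(a), b, trim_frac)


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------


def _smoothed_density(midpoints: np.ndarray, length: int, sigma: float) -> np.ndarray:
    counts = np.bincount(midpoints, minlength=length).astype(float)
    return ndimage.gaussian_filter1d(counts, sigma, mode="constant")


def call_nucleosomes(midpoints: np.ndarray, genome_length: int,
                     sigma: float = DEFAULT_SIGMA,
                     exclusion_w: int = DEFAULT_EXCLUSION,
                     peak_halfwidth: int = DEFAULT_PEAK_HALFWIDTH,
                     height_cutoff: float = DEFAULT_HEIGHT_CUTOFF,
                     chrom: str = "chr", dataset: str = "ds") -> list[NucleosomeCall]:
    """GeneTrack-style calling on read midpoints.

    Height is reported in reads-equivalent units (smoothed density times
    sigma*sqrt(2*pi)), so the cutoff is roughly "at least this many reads
    under the peak".
    """
    if sigma <= 0 or exclusion_w < 1:
        raise ValueError("sigma > 0 and exclusion_w >= 1 required")
    midpoints = np.asarray(midpoints, dtype=int)
    midpoints = midpoints[(midpoints >= 0) & (midpoints < genome_length)]
    if midpoints.size == 0:
        logger.warning("no midpoints for %s/%s", chrom, dataset)
        return []
    dens = _smoothed_density(midpoints, genome_length, sigma)
    height = dens * sigma * np.sqrt(2 * np.pi)
    # candidate peaks: local maxima (plateau-safe)
    left = np.r_[height[0] - 1, height[:-1]]
    right = np.r_[height[1:], height[-1] - 1]
    cand = np.flatnonzero((height >= left) & (height > right) & (height >= height_cutoff))
    order = cand[np.argsort(height[cand])[::-1]]
    accepted: list[int] = []
    blocked = np.zeros(genome_length, dtype=bool)
    for pos in order:
        if blocked[pos]:
            continue
        accepted.append(int(pos))
        lo = max(pos - exclusion_w + 1, 0)
        hi = min(pos + exclusion_w, genome_length)
        blocked[lo:hi] = True
    accepted.sort()
    calls = [NucleosomeCall(chrom, p, float(height[p]), dataset) for p in accepted]
    _assert_exclusion(calls, exclusion_w)
    return calls


def _assert_exclusion(calls: list[NucleosomeCall], exclusion_w: int) -> None:
    dyads = np.array(sorted(c.dyad for c in calls))
    if len(dyads) > 1 and np.min(np.diff(dyads)) < exclusion_w:
        raise AssertionError("exclusion zone violated in call set")


# ---------------------------------------------------------------------------
# Reference map construction
# ---------------------------------------------------------------------------


def build_reference_map(per_dataset_calls: list[list[NucleosomeCall]],
                        genome_length: int,
                        min_support: int | None = None,
                        length_threshold: int = DEFAULT_LINKER_THRESHOLD,
                        sigma: float = DEFAULT_SIGMA,
                        exclusion_w: int = DEFAULT_EXCLUSION,
                        chrom: str = "chr") -> ReferenceMap:
    """Consensus nucleosomes from per-dataset calls plus linker gaps.

    Consensus dyads come from re-running the peak caller on the pooled call
    dyads (each call treated as one read); a consensus nucleosome is
    retained only if at least ``min_support`` datasets (default: all) have
    a call within exclusion_w/2 of its dyad.  Linkers are maximal intervals
    covered by no dataset's 147 bp call footprint; a linker shorter than
    ``length_threshold`` is a short linker, otherwise an NFR.
    """
    n_ds = len(per_dataset_calls)
    if n_ds < 2:
        raise ValueError("need at least 2 datasets")
    if min_support is None:
        min_support = n_ds
    if min_support > n_ds:
        raise ValueError("min_support exceeds number of datasets")
    pooled = np.concatenate([[c.dyad for c in calls] for calls in per_dataset_calls]
                            ) if any(per_dataset_calls) else np.empty(0, dtype=int)
    consensus = call_nucleosomes(pooled.astype(int), genome_length, sigma=sigma,
                                 exclusion_w=exclusion_w,
                                 height_cutoff=float(min_support) - 0.5,
                                 chrom=chrom, dataset="consensus")
    half = exclusion_w // 2
    nucleosomes: list[GenomicRegion] = []
    support: list[int] = []
    for call in consensus:
        n_sup = sum(1 for calls in per_dataset_calls
                    if _nearest_call(calls, call.dyad, half) is not None)
        if n_sup < min_support:
            continue
        start = max(call.dyad - NUC_WIDTH // 2, 0)
        end = min(start + NUC_WIDTH, genome_length)
        nucleosomes.append(GenomicRegion(chrom, start, end, "nucleosome",
                                         score=call.height))
        support.append(n_sup)
    # linkers: complement of the union of every dataset's call footprints
    covered = np.zeros(genome_length, dtype=bool)
    for calls in per_dataset_calls:
        for c in calls:
            lo = max(c.dyad - NUC_WIDTH // 2, 0)
            covered[lo:min(lo + NUC_WIDTH, genome_length)] = True
    linkers: list[GenomicRegion] = []
    edges = np.flatnonzero(np.diff(np.r_[True, covered, True].astype(int)))
    for s, e in zip(edges[::2], edges[1::2]):
        s, e = int(s), int(e)
        if e <= s:
            continue
        subclass = "short_linker" if (e - s) < length_threshold else "NFR"
        linkers.append(GenomicRegion(chrom, s, e, "linker", subclass))
    # a retained consensus nucleosome can slightly overlap the covered-union
    # complement never (it is inside some dataset's footprint), so regions
    # are disjoint by construction
    return ReferenceMap(nucleosomes, linkers, support)


def _nearest_call(calls: list[NucleosomeCall], dyad: int, tol: int) -> int | None:
    """Nearest call dyad within tol; ties broken toward the smaller coordinate."""
    best, best_d = None, tol + 1
    for c in calls:
        d = abs(c.dyad - dyad)
        if d < best_d or (d == best_d and best is not None and c.dyad < best):
            best, best_d = c.dyad, d
    return best if best_d <= tol else None


# ---------------------------------------------------------------------------
# Reproducibility and track diagnostics
# ---------------------------------------------------------------------------


def position_reproducibility(reference: ReferenceMap,
                             per_dataset_calls: list[list[NucleosomeCall]],
                             exclusion_w: int = DEFAULT_EXCLUSION
                             ) -> tuple[np.ndarray, int]:
    """Population SD of matched per-dataset dyads for each reference
    nucleosome; returns (sds, n_excluded) where nucleosomes matched in
    fewer than two datasets are excluded."""
    half = exclusion_w // 2
    sds, excluded = [], 0
    for region in reference.nucleosomes:
        dyad = (region.start + region.end) // 2
        matched = [m for calls in per_dataset_calls
                   if (m := _nearest_call(calls, dyad, half)) is not None]
        if len(matched) < 2:
            excluded += 1
            continue
        sds.append(float(np.std(matched, ddof=1)))  # sample SD (divide by n-1)
    if excluded:
        logger.info("%d reference nucleosomes unmatched", excluded)
    return np.array(sds), excluded


def randomize_midpoints(midpoints: np.ndarray, genome_length: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Control: every read remapped to a uniformly random position."""
    return rng.integers(0, genome_length, size=len(midpoints))


def trimmed_pearson(track_a: np.ndarray, track_b: np.ndarray,
                    trim_frac: float = 0.0005) -> float:
    """Pearson r after excluding positions in the extreme tails of either
    track (outlier robustness for per-base comparisons)."""
    a = np.asarray(track_a, dtype=float)
    b = np.asarray(track_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tracks differ in length")
    keep = np.ones(a.shape, dtype=bool)
    for t in (a, b):
        lo, hi = np.quantile(t, [trim_frac, 1 - trim_frac])
        keep &= (t >= lo) & (t <= hi)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 positions remain after trimming")
    r, _ = stats.pearsonr(a[keep], b[keep])
    return float(r)


def coverage_cdf(track: CoverageTrack) -> np.ndarray:
    """Empirical CDF of a probability-basis coverage track:
    rows of (value, cumulative fraction)."""
    if track.basis != "probability":
        raise ValueError("coverage_cdf expects a probability-basis track")
    v = np.sort(track.values)
    frac = np.arange(1, len(v) + 1) / len(v)
    return np.column_stack([v, frac])
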