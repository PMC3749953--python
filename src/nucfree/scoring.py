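"""Agreement between predicted occupancy and a reference map.

Each annotated region (nucleosome or linker) is summarized by the median
predicted nucleosome occupancy across its bases.  A critical occupancy c
classifies a region as "nucleosome" when its median is strictly larger
than c; the mutual information between that classification and the
annotation, maximized over c, normalized by the annotation entropy, is the
quality score rho in [0, 1].  Natural logs are used internally; rho is
base-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GeneAnnotation, GenomicRegion

DEFAULT_PROMOTER_UPSTREAM = 500
DEFAULT_PROMOTER_DOWNSTREAM = 100


@dataclass
class ContingencyFractions:
    f_nn: float
    f_nl: float
    f_ln: float
    f_ll: float
    n_regions: int

    def __post_init__(self) -> None:
        total = self.f_nn + self.f_nl + self.f_ln + self.f_ll
        if min(self.f_nn, self.f_nl, self.f_ln, self.f_ll) < 0 or not np.isclose(total, 1.0):
            raise ValueError("fractions must be >= 0 and sum to 1")


@dataclass
class QualityResult:
    mi: float  # nats, at c_star
    mi_star: float  # nats
    c_star: float
    entropy: float  # nats
    rho: float
    auc: float | None = None
    n_regions: int = 0


def region_medians(occupancy: np.ndarray, regions: list[GenomicRegion]) -> np.ndarray:
    """Exact median of per-base occupancy within each region."""
    out = np.empty(len(regions))
    for i, r in enumerate(regions):
        if r.end > len(occupancy) or r.start >= r.end:
            raise ValueError(f"region [{r.start},{r.end}) outside track")
        out[i] = np.median(occupancy[r.start:r.end])
    return out


def mutual_information(fractions: ContingencyFractions) -> float:
    """I = sum_xy f_xy ln(f_xy / (f_x. f_.y)), 0*ln(0) = 0; in nats."""
    f = np.array([[fractions.f_nn, fractions.f_nl],
                  [fractions.f_ln, fractions.f_ll]])
    fx = f.sum(axis=1, keepdims=True)
    fy = f.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = f * np.log(f / (fx * fy))
    return float(np.nansum(terms))


def label_entropy(labels: np.ndarray) -> float:
    """Binary entropy (nats) of the nucleosome/linker annotation."""
    p = np.mean(labels)
    if p in (0.0, 1.0):
        return 0.0
    return float(-p * np.log(p) - (1 - p) * np.log(1 - p))


def _mi_scan(medians: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MI (nats) at every candidate threshold (midpoints between distinct
    sorted medians, plus -inf and +inf); vectorized over thresholds."""
    order = np.argsort(medians, kind="mergesort")
    m = medians[order]
    y = labels[order].astype(float)
    n = len(m)
    # thresholds: below all, between each pair of distinct values, above all
    distinct = np.flatnonzero(np.diff(m) > 0)
    mids = (m[distinct] + m[distinct + 1]) / 2
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    # for threshold c: predicted nucleosome when median > c
    # count of medians <= c for each threshold
    counts_le = np.searchsorted(m, thresholds, side="right")
    cum_y = np.concatenate(([0.0], np.cumsum(y)))
    n_pos = cum_y[-1]
    # among the counts_le lowest medians (predicted linker): positives
    pos_in_linkerpred = cum_y[counts_le]
    f_ln = pos_in_linkerpred / n          # predicted linker, annotated nucleosome
    f_ll = (counts_le - pos_in_linkerpred) / n
    f_nn = (n_pos - pos_in_linkerpred) / n
    f_nl = (n - counts_le - (n_pos - pos_in_linkerpred)) / n
    mi = np.zeros(len(thresholds))
    for fxy, fx, fy in (
        (f_nn, f_nn + f_nl, f_nn + f_ln),
        (f_nl, f_nn + f_nl, f_nl + f_ll),
        (f_ln, f_ln + f_ll, f_nn + f_ln),
        (f_ll, f_ln + f_ll, f_nl + f_ll),
    ):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = fxy * np.log(fxy / (fx * fy))
        mi += np.where(fxy > 0, np.nan_to_num(t), 0.0)
    return mi, thresholds


def max_mi_threshold(medians: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(mi_star, c_star): maximal MI over the critical occupancy, with ties
    resolved toward the smallest threshold."""
    medians = np.asarray(medians, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if len(medians) < 2:
        raise ValueError("need at least 2 regions")
    if labels.all() or not labels.any():
        raise ValueError("both labels must be present (entropy is 0 otherwise)")
    mi, thresholds = _mi_scan(medians, labels)
    best = int(np.argmax(mi + 0.0))  # argmax returns first (=smallest c) on ties
    return float(mi[best]), float(thresholds[best])


def quality_score(medians: np.ndarray, labels: np.ndarray,
                  with_auc: bool = True) -> QualityResult:
    """rho = mi_star / H(labels); labels True = nucleosome."""
    medians = np.asarray(medians, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    mi_star, c_star = max_mi_threshold(medians, labels)
    h = label_entropy(labels)
    rho = mi_star / h
    auc = roc_auc(medians, labels) if with_auc else None
    return QualityResult(mi_star, mi_star, c_star, h, float(rho), auc, len(medians))


def roc_auc(medians: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: probability a random nucleosome region outranks a
    random linker region, ties counting one half."""
    medians = np.asarray(medians, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both labels must be present")
    from scipy.stats import rankdata

    ranks = rankdata(medians)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def subset_regions(regions: list[GenomicRegion], genes: list[GeneAnnotation] | None = None,
                   promoter_upstream: int = DEFAULT_PROMOTER_UPSTREAM,
                   promoter_downstream: int = DEFAULT_PROMOTER_DOWNSTREAM,
                   classes: set[str] | None = None) -> list[GenomicRegion]:
    """Keep regions whose midpoint falls in a promoter window of any gene
    (strand-aware), optionally filtered to a set of classes.

    Class names: "nucleosome", "short_linker", "NFR".
    """
    kept = regions
    if classes is not None:
        kept = [r for r in kept
                if (r.label if r.label == "nucleosome" else r.subclass) in classes]
    if genes is not None:
        windows = []
        for g in genes:
            if g.strand == "+":
                windows.append((g.tss - promoter_upstream, g.tss + promoter_downstream + 1))
            else:
                windows.append((g.tss - promoter_downstream, g.tss + promoter_upstream + 1))
        windows.sort()
        starts = np.array([w[0] for w in windows])
        ends = np.array([w[1] for w in windows])
        out = []
        for r in kept:
            mid = r.midpoint
            i = np.searchsorted(starts, mid, side="right") - 1
            # check the window starting at or before mid, and any earlier
            # window that might still span it
            hit = False
            j = i
            while j >= 0 and starts[j] <= mid:
                if mid < ends[j]:
                    hit = True
                    break
                if ends[: j + 1].max() <= mid:
                    break
                j -= 1
            if hit:
                out.append(r)
        kept = out
    return kept


def labels_from_regions(regions: list[GenomicRegion]) -> np.ndarray:
    """Boolean labels: True where the annotation is nucleosome."""
    return np.array([r.label == "nucleosome" for r in regions])
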