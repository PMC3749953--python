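"""Over-representation statistics: hypergeometric category tests and
protein-link enrichment among top-ranked TFs."""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .io_formats import LinkTable


@dataclass
class EnrichmentResult:
    k: int  # successes in the selection
    n: int  # selection size (category test) or total links (link test)
    K: int  # background successes
    N: int  # background size
    fold: float
    p: float
    approximate: bool = False


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    if k > K:
        return 0.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): observed over expected success fraction."""
    if n <= 0 or K <= 0 or N <= 0:
        raise ValueError("n, K and N must be positive")
    return (k / n) / (K / N)


def category_enrichment(top_set: set[str], tf_set: set[str],
                        annotated_set: set[str]) -> EnrichmentResult:
    """Classic gene-set test: how over-represented is an annotated category
    among the top TFs, against the full TF collection."""
    if not annotated_set <= tf_set:
        raise ValueError("annotated_set must be a subset of tf_set")
    if not top_set <= tf_set:
        raise ValueError("top_set must be a subset of tf_set")
    N, K, n = len(tf_set), len(annotated_set), len(top_set)
    k = len(top_set & annotated_set)
    fold = fold_enrichment(k, n, K, N) if k else 0.0
    return EnrichmentResult(k, n, K, N, fold, hypergeom_tail(k, n, K, N))


def link_enrichment(links: LinkTable, tf_set: set[str], top_set: set[str],
                    category_set: set[str], score_cutoff: int = 400) -> EnrichmentResult:
    """Enrichment of TF/category protein links among the top TFs.

    n = links (score >= cutoff) between any TF and the category; k = those
    links whose TF is in the top set.  The fold is exact:
    (k/n)/(|top|/|TFs|).  The p-value treats each link as an exchangeable
    draw with success probability |top|/|TFs| (a binomial tail), and is
    labeled approximate.
    """
    if not category_set:
        raise ValueError("empty category")
    if not top_set <= tf_set:
        raise ValueError("top_set must be a subset of tf_set")
    df = links.filtered(score_cutoff)
    k = n = 0
    for a, b in zip(df["protein_a"], df["protein_b"]):
        tf, other = (a, b) if a in tf_set else (b, a)
        if tf not in tf_set or other not in category_set:
            continue
        n += 1
        if tf in top_set:
            k += 1
    if n == 0:
        raise ValueError("no TF-category links above the cutoff")
    K, N = len(top_set), len(tf_set)
    fold = fold_enrichment(k, n, K, N)
    p = float(stats.binom.sf(k - 1, n, K / N))
    return EnrichmentResult(k, n, K, N, fold, p, approximate=True)
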