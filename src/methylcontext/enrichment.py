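"""Gene-set over-representation of differentially methylated genes.

For each gene set (KEGG-style, read from GMT), the differentially methylated
gene (DMG) list is tested for over-representation against a background gene
universe with a one-sided Fisher's exact test on the 2x2 table
``[[k, n-k], [K-k, N-n-K+k]]`` (k DMGs in the set, n DMGs total, K set size,
N background size), plus the fold enrichment (k/n)/(K/N). Benjamini-Hochberg
adjusts across tested sets. Gene sets are intersected with the background
before testing; empty sets are skipped and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # DMGs in the set
    n: int  # DMGs in the background
    K: int  # set size within the background
    N: int  # background size
    fold: float
    p: float
    q: float


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N); 0 when k = 0. Undefined margins raise."""
    if n <= 0 or K <= 0 or N <= 0:
        raise ValueError("n, K and N must be positive")
    if k < 0 or k > n or k > K or K > N or n > N:
        raise ValueError("inconsistent contingency margins")
    if k == 0:
        return 0.0
    return (k / n) / (K / N)


def enrich(
    dmg_set: set[str],
    gene_sets: dict[str, set[str]],
    background: list[str] | set[str],
    q_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided (over-representation) Fisher enrichment of DMGs per gene set.

    Returns results for every tested set sorted by p (then name), each with
    fold enrichment and BH-adjusted q; ``q_threshold`` is a convenience for
    callers filtering significant sets and does not affect the computation.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background gene universe is empty")
    dmgs = set(dmg_set) & bg
    if dmgs != set(dmg_set):
        missing = set(dmg_set) - bg
        logger.warning("%d DMGs absent from the background were dropped", len(missing))
    n, N = len(dmgs), len(bg)
    if n == 0:
        raise ValueError("no DMGs inside the background")

    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & bg
        K = len(members)
        if K == 0:
            logger.info("gene set %s empty after background intersection; skipped", name)
            continue
        k = len(dmgs & members)
        table = [[k, n - k], [K - k, N - n - K + k]]
        p = float(stats.fisher_exact(table, alternative="greater")[1])
        rows.append((name, k, K, p))
    if not rows:
        return []
    qvals = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(name, k, n, K, N, fold_enrichment(k, n, K, N), p, float(q))
        for (name, k, K, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.set_name,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "fold": r.fold,
                "p": r.p,
                "q": r.q,
            }
            for r in results
        ],
        columns=["set", "k", "n", "K", "N", "fold", "p", "q"],
    )
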