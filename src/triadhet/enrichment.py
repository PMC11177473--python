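"""Hypergeometric over-representation analysis over flat term annotations.

Given a query gene set (e.g. the up-regulated overdominant DEGs) and a
background universe, each term is scored with the upper tail
P(X >= k), X ~ Hypergeometric(N, K, n), where k is the query/term overlap,
K the term size within the background, n the query size and N the
background size.  P-values are Benjamini-Hochberg adjusted across terms.
Term maps are flat (no ontology-graph propagation); callers may
pre-propagate ancestors if they need it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def read_term_map_tsv(path) -> dict[str, set[str]]:
    """Read a 2-column gene_id<TAB>term_id file into term -> gene set."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["gene", "term"])
    return {term: set(sub["gene"]) for term, sub in df.groupby("term")}


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), stable in log space."""
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: set[str],
    background: set[str],
    terms: dict[str, set[str]],
    alpha: float = 0.05,
    use_adjusted: bool = False,
    term_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Score every term with overlap >= 1 against the query.

    Significance is flagged at raw p <= alpha (inclusive) by default, or at
    padj <= alpha with ``use_adjusted``.  Rows are sorted by ascending p
    (ties by term id).  Returns columns term, name, k, n, K, N, p, padj,
    rich_factor, significant.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    if not query:
        warnings.warn("empty query gene set", RuntimeWarning, stacklevel=2)
    N = len(background)
    n = len(query)

    rows = []
    for term, genes in terms.items():
        members = genes & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        if k == 0:
            continue
        rows.append((term, k, K))
    if not rows:
        return pd.DataFrame(
            columns=["term", "name", "k", "n", "K", "N", "p", "padj",
                     "rich_factor", "significant"]
        )
    terms_arr = [r[0] for r in rows]
    k_arr = np.array([r[1] for r in rows])
    K_arr = np.array([r[2] for r in rows])
    p = stats.hypergeom.sf(k_arr - 1, N, K_arr, n)
    p = np.clip(p, 0.0, 1.0)
    padj = bh_adjust(p)
    screen = padj if use_adjusted else p
    df = pd.DataFrame(
        {
            "term": terms_arr,
            "name": [
                (term_names or {}).get(t, t) for t in terms_arr
            ],
            "k": k_arr,
            "n": n,
            "K": K_arr,
            "N": N,
            "p": p,
            "padj": padj,
            "rich_factor": k_arr / K_arr,
            "significant": screen <= alpha,
        }
    )
    return df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
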