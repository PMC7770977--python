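"""Flat over-representation analysis of gene sets.

One-sided hypergeometric tail per term (is the term over-represented among
the selected genes relative to the tested universe?), Benjamini–Hochberg
across terms.  Term sets are flat gene -> term pairs; no ontology-graph
propagation is performed — curated groupings are supplied by the user, and
the universe is the set of transcripts actually tested for rhythmicity,
not a genome.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .detect import bh_adjust


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def ora(selected_ids, annotation: pd.DataFrame, universe_ids,
        min_term_size: int = 5) -> pd.DataFrame:
    """Over-representation of each term among the selected genes.

    Parameters
    ----------
    selected_ids:
        Genes of interest (must be a subset of the universe; non-empty).
    annotation:
        Two columns, ``gene_id`` and ``term_id``; genes outside the universe
        are ignored.
    universe_ids:
        All genes the selection was drawn from (e.g. every transcript tested).
    min_term_size:
        Terms with fewer in-universe genes are dropped.

    Returns a table (term_id, k, K, n, N, odds_ratio, p, adj_p) sorted by
    adjusted p, then term id.
    """
    universe = set(universe_ids)
    selected = set(selected_ids)
    if not selected:
        raise ValueError("empty selection")
    stray = sorted(selected - universe)
    if stray:
        shown = ", ".join(stray[:5])
        raise ValueError(
            f"{len(stray)} selected genes are outside the universe: {shown}"
            + ("..." if len(stray) > 5 else "")
        )
    if not {"gene_id", "term_id"}.issubset(annotation.columns):
        raise ValueError("annotation needs gene_id and term_id columns")

    ann = annotation[annotation["gene_id"].isin(universe)].drop_duplicates()
    N, n = len(universe), len(selected)
    rows = []
    for term, genes in ann.groupby("term_id")["gene_id"]:
        gset = set(genes)
        K = len(gset)
        if K < min_term_size:
            continue
        k = len(gset & selected)
        p = hypergeom_tail(k, K, n, N)
        a, b = k, n - k
        c, d = K - k, N - K - n + k
        odds = np.inf if b * c == 0 and a * d > 0 else (
            np.nan if b * c == 0 else (a * d) / (b * c)
        )
        rows.append((term, k, K, n, N, odds, p))
    out = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "odds_ratio", "p"])
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].values)
        out = out.sort_values(["adj_p", "term_id"]).reset_index(drop=True)
    else:
        out["adj_p"] = pd.Series(dtype=float)
    return out
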