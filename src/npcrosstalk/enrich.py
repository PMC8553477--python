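"""Crosstalk-gene intersection and hypergeometric over-representation tests.

A crosstalk gene is a gene differentially expressed in both diseases; the
crosstalk set is the intersection of the two DEG sets (directions per disease
retained).  Enrichment against user-supplied GMT collections uses the
one-sided hypergeometric tail P(X ≥ k) — the classic over-representation
test — with an unadjusted p < 0.05 significance flag and an optional
Benjamini-Hochberg column.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats


def intersect_degs(
    degs_a: dict[str, str],
    degs_b: dict[str, str],
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Intersect two per-disease DEG direction maps (gene → 'up'/'down').

    Parameters
    ----------
    degs_a, degs_b
        Gene → direction for each disease (the union of that disease's up and
        down sets).
    exclude
        Genes removed from the result (e.g. a curated signaling-peptide panel
        handled by its own downstream screen, kept disjoint from the
        crosstalk set).

    Returns
    -------
    DataFrame indexed by gene with columns ``direction_a``, ``direction_b``,
    sorted by gene symbol.
    """
    shared = sorted(set(degs_a) & set(degs_b) - (exclude or set()))
    return pd.DataFrame(
        {
            "direction_a": [degs_a[g] for g in shared],
            "direction_b": [degs_b[g] for g in shared],
        },
        index=pd.Index(shared, name="gene"),
    )


def hypergeometric_enrichment(
    query: set[str],
    collections: dict[str, list[str]],
    universe: set[str],
    p_cut: float = 0.05,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """One-sided over-representation test of *query* against each gene set.

    With universe size N, set size K (after intersecting the set with the
    universe), query size n and overlap k, p = P(X ≥ k) for
    X ~ Hypergeometric(N, K, n).

    Returns a DataFrame sorted by p with columns ``k``, ``K``, ``n``, ``N``,
    ``p``, ``significant``, ``genes`` (and ``p_bh`` when requested).
    """
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n = len(query)
    N = len(universe)
    rows = []
    for name, members in collections.items():
        in_universe = set(members) & universe
        K = len(in_universe)
        overlap = sorted(query & in_universe)
        k = len(overlap)
        # P(X >= k); survival function at k-1
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        p = min(p, 1.0)
        rows.append((name, k, K, n, N, p, ";".join(overlap)))
    table = pd.DataFrame(
        rows, columns=["set", "k", "K", "n", "N", "p", "genes"]
    ).set_index("set")
    if bh_adjust and len(table):
        table["p_bh"] = _benjamini_hochberg(table["p"])
    table["significant"] = table["p"] < p_cut
    return table.sort_values(["p", "set"], kind="mergesort")


def _benjamini_hochberg(p: pd.Series) -> pd.Series:
    m = len(p)
    order = p.sort_values(kind="mergesort")
    adj = order.to_numpy() * m / (pd.RangeIndex(1, m + 1).to_numpy())
    # enforce monotonicity from the largest p downwards
    for i in range(m - 2, -1, -1):
        adj[i] = min(adj[i], adj[i + 1])
    out = pd.Series(adj.clip(max=1.0), index=order.index)
    return out.reindex(p.index)
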