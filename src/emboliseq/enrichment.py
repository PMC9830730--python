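"""Over-representation analysis of gene sets against term→gene maps.

One-sided hypergeometric tail per term (equivalently Fisher's exact test
on the 2×2 membership table), BH correction within each namespace, FDR <
0.05 significance, and the up/down trend z-score per term.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import benjamini_hochberg

ENRICHMENT_FDR = 0.05


def fisher_enrichment(query_genes, annotation_map: pd.DataFrame,
                      universe=None) -> pd.DataFrame:
    """Term over-representation per namespace.

    ``annotation_map`` has columns namespace, term_id, term_name, gene_id.
    The universe defaults to all genes with at least one annotation in the
    namespace; p is the hypergeometric upper tail P(X >= k); BH within
    namespace.
    """
    query = set(query_genes)
    out = []
    for namespace, sub in annotation_map.groupby("namespace", sort=True):
        ns_universe = set(sub["gene_id"]) if universe is None else set(universe)
        n_universe = len(ns_universe)
        ns_query = query & ns_universe
        n_query = len(ns_query)
        rows = []
        for (term_id, term_name), genes in sub.groupby(["term_id", "term_name"],
                                                       sort=True):
            term_genes = set(genes["gene_id"]) & ns_universe
            K = len(term_genes)
            if K == 0:
                continue
            k = len(term_genes & ns_query)
            # P(X >= k) with X ~ Hypergeom(N, K, n)
            p = float(sps.hypergeom.sf(k - 1, n_universe, K, n_query))
            rows.append(
                {"namespace": namespace, "term_id": term_id,
                 "term_name": term_name, "k": k, "query_size": n_query,
                 "term_size": K, "universe_size": n_universe, "pvalue": p}
            )
        if not rows:
            continue
        ns_df = pd.DataFrame(rows)
        ns_df["fdr"] = benjamini_hochberg(ns_df["pvalue"].to_numpy())
        out.append(ns_df)
    if not out:
        return pd.DataFrame(
            columns=["namespace", "term_id", "term_name", "k", "query_size",
                     "term_size", "universe_size", "pvalue", "fdr", "significant"]
        )
    df = pd.concat(out, ignore_index=True)
    df["significant"] = df["fdr"] < ENRICHMENT_FDR
    return df


def trend_zscore(term_genes, de_table: pd.DataFrame) -> float:
    """Direction trend z = (n_up − n_down) / sqrt(n_up + n_down) over the
    term's differentially expressed genes; NaN when none overlap."""
    sub = de_table[de_table["gene_id"].isin(set(term_genes)) & de_table["is_deg"]]
    n_up = int((sub["direction"] == "up").sum())
    n_down = int((sub["direction"] == "down").sum())
    k = n_up + n_down
    if k == 0:
        return float("nan")
    return (n_up - n_down) / np.sqrt(k)


def add_trend_zscores(enrichment: pd.DataFrame, annotation_map: pd.DataFrame,
                      de_table: pd.DataFrame) -> pd.DataFrame:
    """Attach the trend z-score to every enrichment row."""
    by_term = annotation_map.groupby(["namespace", "term_id"])["gene_id"].apply(set)
    z = [
        trend_zscore(by_term.get((row.namespace, row.term_id), set()), de_table)
        for row in enrichment.itertuples()
    ]
    out = enrichment.copy()
    out["z_trend"] = z
    return out


def signature_report(deg_table: pd.DataFrame, annotation_map: pd.DataFrame,
                     term_ids) -> pd.DataFrame:
    """Membership table of DEGs in the requested (HP) terms with direction."""
    degs = deg_table[deg_table["is_deg"]]
    direction = dict(zip(degs["gene_id"], degs["direction"]))
    rows = []
    for term_id in term_ids:
        sub = annotation_map[annotation_map["term_id"] == term_id]
        for row in sub.itertuples():
            if row.gene_id in direction:
                rows.append(
                    {"term_id": term_id, "term_name": row.term_name,
                     "gene_id": row.gene_id, "direction": direction[row.gene_id]}
                )
    return pd.DataFrame(rows, columns=["term_id", "term_name", "gene_id", "direction"])
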