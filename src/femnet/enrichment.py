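"""Gene-set overlap enrichment (hypergeometric test over GMT collections)."""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def overlap_enrichment(
    members: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric p per gene set, BH-adjusted across sets.

    ``members`` must be a subset of ``universe``; gene sets are intersected
    with the universe before testing.  Returns one row per set with the
    overlap size, the overlapping genes (comma-joined, sorted), raw p and
    BH-adjusted q, sorted by p ascending.
    """
    if not universe:
        raise ValueError("empty universe")
    members = set(members)
    if not members <= set(universe):
        raise ValueError("module members must lie inside the universe")
    M, n_draw = len(universe), len(members)
    rows = []
    for name, genes in gene_sets.items():
        in_universe = set(genes) & set(universe)
        overlap = sorted(members & in_universe)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, M, len(in_universe), n_draw)) if in_universe else 1.0
        rows.append(
            {
                "gene_set": name,
                "set_size": len(in_universe),
                "overlap": k,
                "overlap_genes": ",".join(overlap),
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values(["p_value", "gene_set"]).set_index("gene_set")
    return df
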