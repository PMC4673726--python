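"""Readers and writers for the plain-text formats the pipeline consumes.

All matrices are TSV with the feature identifier (probe or gene) in the first
column and sample identifiers in the header row; missing values are written as
``NA``.  The protein-protein interactome is a two-column edge list of gene
symbols; gene sets use the GMT dialect (name, description, then members).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

REGIONS = ("TSS200", "FirstExon", "TSS1500", "Body")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")


def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    """Read a probe annotation table with columns probe_id, gene, region."""
    annot = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "gene", "region"}
    missing = required - set(annot.columns)
    if missing:
        raise ValueError(f"probe annotation missing columns: {sorted(missing)}")
    bad = set(annot["region"]) - set(REGIONS)
    if bad:
        raise ValueError(f"unknown probe regions: {sorted(bad)}")
    return annot


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read the sample table (sample_id, group in {normal, tumour}, subtype)."""
    phen = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    missing = required - set(phen.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    bad = set(phen["group"]) - {"normal", "tumour"}
    if bad:
        raise ValueError(f"unknown phenotype groups: {sorted(bad)}")
    if "subtype" not in phen.columns:
        phen["subtype"] = "none"
    phen["subtype"] = phen["subtype"].fillna("none")
    return phen.set_index("sample_id", drop=False)


def read_ppi(path: str | Path) -> nx.Graph:
    """Read an undirected PPI edge list; self-loops and duplicates dropped."""
    edges = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    g = nx.Graph()
    for a, b in edges.iloc[:, :2].itertuples(index=False):
        if a != b:
            g.add_edge(a, b)
    return g


def write_ppi(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: name <tab> description <tab> member genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
        fh.write("\n")
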