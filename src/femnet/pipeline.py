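"""End-to-end orchestration: raw matrices in, module/score/report tables out.

``run_pipeline`` executes the full analysis in the discovery order —
preprocessing and gene-level statistics, weighted-network hotspot discovery,
per-sample deviation scoring and coordination testing, integrative
subtyping, and (when a copy-number statistic is supplied) the shortest-path
contrast — and writes every result plus a manifest capturing the exact
configuration, seed and per-stage counts so a run is reproducible from the
manifest and inputs alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io
from .preprocessing import preprocess_expression, filter_and_impute, summarize_gene_methylation
from .diffstats import moderated_t, scale_statistics, combine_stats
from .discovery import FEMDetector, validate_modules
from .deviation import DeviationScorer
from .enrichment import overlap_enrichment
from .subtypes import joint_cluster_standin, NearestCentroidSubtyper
from .distances import top_ranked, pairwise_shortest_paths, compare_distance_sets

log = logging.getLogger("femnet")


@dataclass
class RunConfig:
    """Paths, thresholds and the seed for one pipeline run.

    All defaults are written into the run manifest so every run is
    reproducible from the manifest plus the inputs.
    """

    beta: str = ""
    annotation: str = ""
    expression: str = ""
    phenotype: str = ""
    ppi: str = ""
    gmt: str = ""
    cnv: str = ""
    outdir: str = "femnet_run"
    expression_is_log: bool = False
    max_missing_frac: float = 0.5
    impute_k: int = 5
    n_seeds: int = 10
    max_size: int = 100
    n_perm: int = 1000
    overlap_threshold: float = 0.5
    significance_alpha: float = 0.05
    p_threshold: float = 0.1
    n_clusters: int = 2
    n_top_ranked: int = 100
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Flat key = value text config; unknown keys rejected."""
        cfg: dict = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in fields:
                    raise ValueError(f"unknown config key {key!r}")
                cfg[key] = value
        cfg.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**_coerce(cls, cfg))


def _coerce(cls, cfg: dict) -> dict:
    out = {}
    for f in dataclasses.fields(cls):
        if f.name not in cfg:
            continue
        v = cfg[f.name]
        if isinstance(v, str) and f.type in ("int", "float", "bool"):
            v = {"int": int, "float": float}.get(f.type, lambda s: s.lower() in ("1", "true", "yes"))(v)
        out[f.name] = v
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the run directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "counts": {}}
    counts = manifest["counts"]
    rng = np.random.default_rng(config.seed)

    def stage(name):
        log.info("stage: %s", name)
        return name

    try:
        stage("load")
        beta = io.read_matrix(config.beta)
        annot = io.read_probe_annotation(config.annotation)
        expr_raw = io.read_matrix(config.expression)
        phen = io.read_phenotype(config.phenotype)
        ppi = io.read_ppi(config.ppi)
        counts["probes_in"] = len(beta)
        counts["genes_expression_in"] = len(expr_raw)
        counts["ppi_nodes"] = ppi.number_of_nodes()

        stage("preprocess")
        beta = filter_and_impute(beta, config.max_missing_frac, config.impute_k)
        counts["probes_retained"] = len(beta)
        expr = expr_raw if config.expression_is_log else preprocess_expression(expr_raw)
        meth = summarize_gene_methylation(beta, annot)
        counts["genes_methylation"] = len(meth)

        stage("diffstats")
        stats_D = moderated_t(meth, phen)
        stats_R = scale_statistics(stats_D, moderated_t(expr, phen))
        stats = combine_stats(stats_D, stats_R)
        counts["genes_with_both_stats"] = len(stats)
        stats.to_csv(out / "gene_stats.tsv", sep="\t")

        stage("fem")
        detector = FEMDetector(
            n_seeds=config.n_seeds,
            max_size=config.max_size,
            n_perm=config.n_perm,
            overlap_threshold=config.overlap_threshold,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(stats, ppi)
        modules = detector.modules_
        counts["network_genes"] = detector.network_.number_of_nodes()
        counts["modules_candidate"] = len(detector.candidates_)
        counts["modules_retained"] = len(modules)
        detector.module_table().to_csv(out / "modules.tsv", sep="\t")

        stage("score")
        scorer = DeviationScorer(
            alpha_sig=config.significance_alpha, p_threshold=config.p_threshold
        ).fit(meth, expr, phen)
        manifest["alpha"] = scorer.alpha_
        fem_scores = scorer.score_modules(modules, stats)
        counts["modules_scored"] = len(fem_scores)
        fem_scores.to_csv(out / "fem_scores.tsv", sep="\t")

        stage("coordinate")
        coord_rows = []
        for mod in modules:
            binmat = scorer.binary_matrix(mod, stats)
            counts[f"eligible_genes_{mod.seed}"] = len(binmat)
            binmat.to_csv(out / f"binary_matrix_{mod.seed}.tsv", sep="\t")
            if len(binmat) >= 2:
                res = scorer.coordination(
                    mod, stats, n_perm=config.n_perm,
                    rng=np.random.default_rng(int(rng.integers(2**31 - 1))),
                )
                coord_rows.append({"seed": mod.seed, **res})
        pd.DataFrame(coord_rows).to_csv(out / "coordination.tsv", sep="\t", index=False)

        stage("classify")
        sig_genes = sorted({
            g for mod in modules for g in mod.members
            if g in stats.index
            and (stats.at[g, "p_D"] < config.significance_alpha
                 or stats.at[g, "p_R"] < config.significance_alpha)
            and g in meth.index and g in expr.index
        })
        counts["clustering_genes"] = len(sig_genes)
        tumours = [s for s in phen.loc[phen["group"] == "tumour", "sample_id"]
                   if s in meth.columns and s in expr.columns]
        if len(sig_genes) >= 3 and len(tumours) >= config.n_clusters:
            part = joint_cluster_standin(
                meth.loc[sig_genes, tumours], expr.loc[sig_genes, tumours],
                k=config.n_clusters, random_state=config.seed,
            )
            part.rename("cluster").to_csv(out / "partition.tsv", sep="\t")
            subtyper = NearestCentroidSubtyper().fit(
                meth.loc[sig_genes], expr.loc[sig_genes], part, genes=sig_genes
            )
            cent = subtyper.centroids_
            rows = []
            for tag in ("D", "R"):
                mat = cent.for_type(tag)
                for g in mat.index:
                    for c in mat.columns:
                        rows.append({"gene": g, "data_type": tag, "cluster": c,
                                     "value": mat.at[g, c]})
            pd.DataFrame(rows).to_csv(out / "centroids.tsv", sep="\t", index=False)

        if config.gmt:
            stage("enrich")
            gene_sets = io.read_gmt(config.gmt)
            universe = set(stats.index)
            enr = []
            for mod in modules:
                table = overlap_enrichment(set(mod.members) & universe, gene_sets, universe)
                table = table.reset_index()
                table.insert(0, "seed", mod.seed)
                enr.append(table)
            if enr:
                pd.concat(enr).to_csv(out / "enrichment.tsv", sep="\t", index=False)

        if config.cnv:
            stage("pathdist")
            cnv = pd.read_csv(config.cnv, sep="\t", index_col=0).iloc[:, 0]
            net = ppi.subgraph(max(nx.connected_components(ppi), key=len))
            dm_list = top_ranked(stats["t_D"], config.n_top_ranked, net)
            cnv_list = top_ranked(cnv, config.n_top_ranked, net)
            d_dm = pairwise_shortest_paths(dm_list, net)
            d_cnv = pairwise_shortest_paths(cnv_list, net)
            cmp = compare_distance_sets(d_dm, d_cnv)
            pd.DataFrame([
                {"source": "DNAm", "n": len(dm_list), "mean_distance": d_dm.mean,
                 "n_pairs": d_dm.n_pairs, "n_disconnected": d_dm.n_disconnected},
                {"source": "CNV", "n": len(cnv_list), "mean_distance": d_cnv.mean,
                 "n_pairs": d_cnv.n_pairs, "n_disconnected": d_cnv.n_disconnected},
            ]).to_csv(out / "path_distances.tsv", sep="\t", index=False)
            manifest["distance_comparison"] = cmp
    except Exception as exc:  # attach the failing stage to the error
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    import femnet
    manifest["version"] = femnet.__version__
    io.write_json(manifest, out / "manifest.json")
    return out


def validate_run(
    modules_path: str | Path,
    discovery_stats: pd.DataFrame,
    validation_stats: pd.DataFrame,
    ppi,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-score previously discovered modules (from a modules.tsv table) with
    independent-cohort statistics; convenience wrapper for the CLI."""
    from .discovery import FemModule

    table = pd.read_csv(modules_path, sep="\t")
    modules = [
        FemModule(row["seed"], tuple(sorted(str(row["members"]).split(","))), row["modularity"])
        for _, row in table.iterrows()
    ]
    return validate_modules(
        modules, validation_stats, ppi, n_perm=n_perm, rng=np.random.default_rng(seed)
    )
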