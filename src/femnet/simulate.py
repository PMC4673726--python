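"""Synthetic matched-cohort generator with planted interactome hotspots.

Emulates the statistical structure of a matched promoter-methylation /
expression tumour study: beta-valued probe-level methylation (logit-normal
around region-specific baselines — promoter probes low, gene-body probes
high), log2-scale expression, an interactome with planted dense modules, and
a normal / luminal-A / luminal-B phenotype gradient in which luminal-B
tumours deviate further from normal than luminal-A (controlled by
``lumB_multiplier``).  Planted modules shift methylation up and expression
down (or vice versa — the deltas must have opposite signs), and a
coordination mode controls WHICH tumours deviate per gene: ``coordinated``
(one shared affected sample set per module), ``exclusive`` (disjoint sets per
gene) or ``independent`` (i.i.d. per gene).  A truth record makes recovery
exactly scorable.  Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
from scipy.special import expit, logit
from scipy.stats import norm

from . import io

REGION_CHOICES = ("TSS200", "FirstExon", "TSS1500", "Body")
# first probe of a gene is always promoter-mapped; the rest may be Body decoys
FIRST_PROBE_P = (0.6, 0.25, 0.15, 0.0)
OTHER_PROBE_P = (0.35, 0.2, 0.15, 0.3)


@dataclass
class PlantedModule:
    """One planted hotspot: size, logit-scale methylation shift, log2-scale
    expression shift (opposite signs required), coordination mode and the
    fraction of tumours affected per gene."""

    size: int = 15
    delta_D: float = 1.0
    delta_R: float = -1.0
    mode: str = "coordinated"
    affected_fraction: float = 1.0

    def validate(self) -> None:
        if self.size < 2:
            raise ValueError("planted module size must be >= 2")
        if self.delta_D * self.delta_R >= 0:
            raise ValueError("planted deltas must have opposite signs (anti-correlation)")
        if self.mode not in ("coordinated", "exclusive", "independent"):
            raise ValueError(f"unknown coordination mode {self.mode!r}")
        if not 0 < self.affected_fraction <= 1:
            raise ValueError("affected_fraction must be in (0, 1]")


@dataclass
class CohortSpec:
    """Generator configuration; the defaults are the study conditions every
    simulation-based test runs under."""

    n_normal: int = 50
    n_lumA: int = 30
    n_lumB: int = 30
    n_genes: int = 500
    probes_per_gene: int = 4
    network_model: str = "smallworld"  # or "scalefree"
    network_degree: int = 6
    rewiring: float = 0.1
    module_density: float = 0.8
    planted_modules: list[PlantedModule] = field(default_factory=lambda: [PlantedModule()])
    lumB_multiplier: float = 2.0
    promoter_baseline: float = 0.15   # beta scale
    body_baseline: float = 0.7
    baseline_sd: float = 0.5          # gene-to-gene logit spread
    probe_offset_sd: float = 0.2
    noise_sd_beta: float = 0.5        # per-observation logit noise
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 2.0
    noise_sd_expr: float = 1.0
    n_cnv_genes: int = 15
    cnv_effect: float = 5.0
    raw_expression: bool = False
    zero_frac: float = 0.01           # raw-scale zeros (raw_expression only)
    missing_frac: float = 0.0         # random missing beta entries
    n_bad_probes: int = 0             # probes missing in >half the samples
    seed: int = 0

    def validate(self) -> None:
        for mod in self.planted_modules:
            mod.validate()
            if mod.size > self.n_genes:
                raise ValueError("planted module larger than the gene universe")
        if sum(m.size for m in self.planted_modules) > self.n_genes:
            raise ValueError("planted modules exceed the gene universe")
        if self.lumB_multiplier < 1:
            raise ValueError("lumB_multiplier must be >= 1")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")


def gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def generate_network(spec: CohortSpec) -> tuple[nx.Graph, list[list[str]]]:
    """Connected background graph with each planted module rewired as a dense
    connected subgraph; nodes carry stable synthetic gene symbols."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    if spec.network_model == "smallworld":
        g = nx.connected_watts_strogatz_graph(
            n, k=max(2, spec.network_degree), p=spec.rewiring, seed=int(spec.seed)
        )
    elif spec.network_model == "scalefree":
        g = nx.barabasi_albert_graph(n, m=max(1, spec.network_degree // 2), seed=int(spec.seed))
    else:
        raise ValueError(f"unknown network model {spec.network_model!r}")

    names = gene_names(n)
    g = nx.relabel_nodes(g, dict(enumerate(names)))

    all_members = rng.choice(n, size=sum(m.size for m in spec.planted_modules), replace=False)
    planted: list[list[str]] = []
    offset = 0
    for mod in spec.planted_modules:
        idx = all_members[offset:offset + mod.size]
        offset += mod.size
        members = sorted(names[i] for i in idx)
        # spanning path guarantees connectivity; extra edges reach the density
        order = rng.permutation(members)
        for a, b in zip(order, order[1:]):
            g.add_edge(a, b)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if not g.has_edge(a, b) and rng.random() < spec.module_density:
                    g.add_edge(a, b)
        planted.append(members)
    return g, planted


@dataclass
class SyntheticCohort:
    """A complete generated data set plus the ground truth needed to score
    recovery of the planted structure."""

    beta: pd.DataFrame
    annotation: pd.DataFrame
    expression: pd.DataFrame
    phenotype: pd.DataFrame
    network: nx.Graph
    cnv: pd.Series
    truth: dict
    spec: CohortSpec

    def to_dir(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        io.write_matrix(self.beta, path / "beta.tsv")
        self.annotation.to_csv(path / "probe_annotation.tsv", sep="\t", index=False)
        io.write_matrix(self.expression, path / "expression.tsv")
        self.phenotype.to_csv(path / "phenotype.tsv", sep="\t", index=False)
        io.write_ppi(self.network, path / "ppi.tsv")
        self.cnv.rename("cnv_stat").to_csv(path / "cnv_stats.tsv", sep="\t")
        io.write_json(self.truth, path / "truth.json")
        io.write_json(dataclasses.asdict(self.spec), path / "cohort_spec.json")
        return path


def _affected_sets(
    mod: PlantedModule, members: list[str], tumours: list[str], rng: np.random.Generator
) -> dict[str, list[str]]:
    n_t = len(tumours)
    n_aff = max(1, round(mod.affected_fraction * n_t))
    tumours = np.asarray(tumours)
    if mod.mode == "coordinated":
        shared = sorted(rng.choice(tumours, size=n_aff, replace=False))
        return {g: list(shared) for g in members}
    if mod.mode == "exclusive":
        per_gene = max(1, min(n_aff, n_t // len(members)))
        perm = rng.permutation(tumours)
        return {
            g: sorted(perm[i * per_gene:(i + 1) * per_gene]) for i, g in enumerate(members)
        }
    return {g: sorted(rng.choice(tumours, size=n_aff, replace=False)) for g in members}


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full matched cohort (methylation, expression, phenotype,
    network, CNV statistic) with the planted structure recorded in ``truth``."""
    spec.validate()
    network, planted = generate_network(spec)
    rng = np.random.default_rng(spec.seed + 1)  # generation stream, distinct from wiring
    genes = gene_names(spec.n_genes)
    normals = [f"N{i:03d}" for i in range(spec.n_normal)]
    lumA = [f"A{i:03d}" for i in range(spec.n_lumA)]
    lumB = [f"B{i:03d}" for i in range(spec.n_lumB)]
    tumours = lumA + lumB
    samples = normals + tumours

    phen = pd.DataFrame({
        "sample_id": samples,
        "group": ["normal"] * len(normals) + ["tumour"] * len(tumours),
        "subtype": ["none"] * len(normals) + ["lumA"] * len(lumA) + ["lumB"] * len(lumB),
    }).set_index(pd.Index(samples, name=None), drop=False)
    phen.index.name = None

    # planted shift bookkeeping: per gene, affected samples and deltas
    shift_D = pd.DataFrame(0.0, index=genes, columns=samples)
    shift_R = pd.DataFrame(0.0, index=genes, columns=samples)
    lumB_set = set(lumB)
    truth_modules = []
    for mod, members in zip(spec.planted_modules, planted):
        affected = _affected_sets(mod, members, tumours, rng)
        for g, samp in affected.items():
            for s in samp:
                mult = spec.lumB_multiplier if s in lumB_set else 1.0
                shift_D.at[g, s] = mult * mod.delta_D
                shift_R.at[g, s] = mult * mod.delta_R
        truth_modules.append({
            "members": members,
            "delta_D": mod.delta_D,
            "delta_R": mod.delta_R,
            "mode": mod.mode,
            "affected_fraction": mod.affected_fraction,
            "affected_samples": affected,
        })

    # --- probe-level methylation ---
    probe_rows, probe_ids, probe_genes, probe_regions = [], [], [], []
    prom_base = logit(spec.promoter_baseline) + rng.normal(0, spec.baseline_sd, spec.n_genes)
    body_base = logit(spec.body_baseline) + rng.normal(0, spec.baseline_sd, spec.n_genes)
    shift_arr = shift_D.to_numpy()
    pid = 0
    for gi, g in enumerate(genes):
        for j in range(spec.probes_per_gene):
            p = FIRST_PROBE_P if j == 0 else OTHER_PROBE_P
            region = REGION_CHOICES[rng.choice(4, p=p)]
            base = body_base[gi] if region == "Body" else prom_base[gi]
            offset = rng.normal(0, spec.probe_offset_sd)
            noise = rng.normal(0, spec.noise_sd_beta, len(samples))
            vals = base + offset + noise
            if region != "Body":  # planted shifts act on promoter methylation
                vals = vals + shift_arr[gi]
            probe_rows.append(expit(vals))
            probe_ids.append(f"cg{pid:06d}")
            probe_genes.append(g)
            probe_regions.append(region)
            pid += 1
    beta = pd.DataFrame(np.vstack(probe_rows), index=probe_ids, columns=samples)
    annot = pd.DataFrame({"probe_id": probe_ids, "gene": probe_genes, "region": probe_regions})

    if spec.missing_frac > 0:
        mask = rng.random(beta.shape) < spec.missing_frac
        beta = beta.mask(mask)
    if spec.n_bad_probes > 0:
        bad = rng.choice(beta.index, size=spec.n_bad_probes, replace=False)
        for probe in bad:
            drop = rng.random(len(samples)) < 0.75
            beta.loc[probe, beta.columns[drop]] = np.nan

    # --- gene-level expression (log2 scale) ---
    expr_base = rng.normal(spec.expr_baseline_mean, spec.expr_baseline_sd, spec.n_genes)
    expr = (
        expr_base[:, None]
        + rng.normal(0, spec.noise_sd_expr, (spec.n_genes, len(samples)))
        + shift_R.to_numpy()
    )
    expression = pd.DataFrame(expr, index=genes, columns=samples)
    if spec.raw_expression:
        raw = np.power(2.0, expression.to_numpy())
        zeros = rng.random(raw.shape) < spec.zero_frac
        raw[zeros] = 0.0
        expression = pd.DataFrame(raw, index=genes, columns=samples)

    # --- gene-level copy-number statistic, spatially uncorrelated ---
    cnv = pd.Series(rng.normal(0, 1, spec.n_genes), index=genes, name="cnv_stat")
    cnv_genes = sorted(rng.choice(genes, size=min(spec.n_cnv_genes, spec.n_genes), replace=False))
    signs = rng.choice([-1.0, 1.0], size=len(cnv_genes))
    cnv[cnv_genes] = signs * rng.normal(spec.cnv_effect, 0.5, len(cnv_genes))

    truth = {
        "planted_modules": truth_modules,
        "cnv_genes": cnv_genes,
        "seed": spec.seed,
    }
    return SyntheticCohort(beta, annot, expression, phen, network, cnv, truth, spec)


def planted_stats_for_network(
    n_genes: int,
    members: list[str],
    effect: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw one statistic replicate: planted members t_D ~ N(+effect, 1) and
    t_R ~ N(-effect, 1), background N(0, 1); p from the Gaussian tail."""
    genes = gene_names(n_genes)
    t_D = pd.Series(rng.normal(0, 1, n_genes), index=genes)
    t_R = pd.Series(rng.normal(0, 1, n_genes), index=genes)
    t_D[members] = rng.normal(effect, 1, len(members))
    t_R[members] = rng.normal(-effect, 1, len(members))
    return pd.DataFrame({
        "t_D": t_D,
        "p_D": 2 * norm.sf(np.abs(t_D)),
        "t_R": t_R,
        "p_R": 2 * norm.sf(np.abs(t_R)),
    })


def simulate_planted_stats(
    n_genes: int = 500,
    module_size: int = 15,
    effect: float = 3.0,
    seed: int = 0,
    spec: CohortSpec | None = None,
) -> tuple[pd.DataFrame, nx.Graph, list[str]]:
    """Statistic-level planting: members get t_D ~ N(+effect, 1) and
    t_R ~ N(-effect, 1) against an N(0, 1) background, on a network with the
    module wired densely.  Returns (stats frame, network, planted members).
    Independent replicates on the same network come from
    :func:`planted_stats_for_network`.
    """
    if spec is None:
        spec = CohortSpec(
            n_genes=n_genes,
            planted_modules=[PlantedModule(size=module_size, delta_D=1.0, delta_R=-1.0)],
            seed=seed,
        )
    network, planted = generate_network(spec)
    members = planted[0]
    rng = np.random.default_rng(spec.seed + 2)
    stats = planted_stats_for_network(spec.n_genes, members, effect, rng)
    return stats, network, members


def load_spec(path: str | Path) -> CohortSpec:
    """Read a CohortSpec from a JSON config file."""
    with open(path) as fh:
        cfg = json.load(fh)
    mods = [PlantedModule(**m) for m in cfg.pop("planted_modules", [])]
    spec = CohortSpec(**cfg)
    if mods:
        spec.planted_modules = mods
    spec.validate()
    return spec
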