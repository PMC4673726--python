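"""Hotspot (FEM) discovery on the weighted interactome.

Modules are grown greedily around high-statistic seed genes: starting from
the seed, the neighbouring gene whose addition most increases the module's
modularity (mean induced edge weight) is added until no addition strictly
increases it or a size cap is hit — a local greedy variant of spin-glass
community search.  Significance comes from permuting the node statistics over
the network and re-scoring the fixed member set; redundant modules (high
overlap coefficient with a better-scoring module) are pruned.  Validation
re-weights the network with statistics from an independent cohort and
re-scores the previously inferred member sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .network import build_weighted_network, induced_degree_profile, modularity


@dataclass
class FemModule:
    """A discovered module: seed gene, member set, modularity, permutation p."""

    seed: str
    members: tuple[str, ...]
    modularity: float
    p_value: float = float("nan")
    extra: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "size": self.size,
            "modularity": self.modularity,
            "p_value": self.p_value,
            "members": ",".join(self.members),
            **self.extra,
        }


def select_seeds(net: nx.Graph, n_seeds: int) -> list[str]:
    """The n_seeds network genes with the largest integrated statistic,
    ties broken lexicographically by gene symbol."""
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if n_seeds > net.number_of_nodes():
        warnings.warn("n_seeds exceeds network size; truncating", stacklevel=2)
        n_seeds = net.number_of_nodes()
    ranked = sorted(net.nodes, key=lambda g: (-net.nodes[g]["t_I"], g))
    return ranked[:n_seeds]


def grow_module(seed: str, net: nx.Graph, max_size: int = 100) -> FemModule:
    """Greedy local module growth around ``seed``.

    Growth maximises the local spin-glass density, the induced edge-weight
    sum divided by the module size: at each step the adjacent node whose
    addition most increases this density is added, stopping when no addition
    strictly increases it or ``max_size`` is reached.  (The density is the
    objective a local spin-glass community search optimises; a greedy rule on
    the *mean induced edge weight* itself would always terminate at the
    single heaviest pair, because for node-additive weights the mean edge
    weight of any superset is bounded by the best pair.)  The reported
    ``modularity`` is the module's mean induced edge weight.  Candidate ties
    break lexicographically.  An isolated seed yields a degenerate size-1
    module with p_value 1.
    """
    if seed not in net:
        raise ValueError(f"seed {seed!r} not in network")
    if max_size < 2:
        raise ValueError("max_size must be >= 2")
    if net.degree(seed) == 0:
        return FemModule(seed, (seed,), float("nan"), 1.0, {"degenerate": True})

    members = {seed}
    # incremental state: sum and count of induced edge weights
    edge_sum, edge_count = 0.0, 0
    density = 0.0  # edge_sum / |members|
    frontier = set(net.neighbors(seed))
    while len(members) < max_size and frontier:
        best, best_density, best_ds, best_dc = None, density, 0.0, 0
        for cand in sorted(frontier):
            ds = sum(net.edges[cand, m]["weight"] for m in net.neighbors(cand) if m in members)
            dc = sum(1 for m in net.neighbors(cand) if m in members)
            new_density = (edge_sum + ds) / (len(members) + 1)
            if new_density > best_density + 1e-15:
                best, best_density, best_ds, best_dc = cand, new_density, ds, dc
        if best is None:
            break
        members.add(best)
        edge_sum += best_ds
        edge_count += best_dc
        density = best_density
        frontier.discard(best)
        frontier.update(n for n in net.neighbors(best) if n not in members)
    mod_score = edge_sum / edge_count if edge_count else float("nan")
    return FemModule(seed, tuple(sorted(members)), mod_score)


def module_significance(
    module: FemModule,
    net: nx.Graph,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for a module's modularity.

    Node statistics are shuffled over all network nodes n_perm times, the
    edge weights implied by each shuffle are re-scored on the fixed member
    set, and p = (1 + #{permuted modularity >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    if module.size < 2:
        return 1.0
    members, deg, n_edges = induced_degree_profile(module.members, net)
    if n_edges == 0:
        return 1.0
    t_all = np.array([net.nodes[g]["t_I"] for g in net.nodes])
    observed = np.array([net.nodes[g]["t_I"] for g in members]) @ deg / (2 * n_edges)
    m = len(members)
    # a uniform random m-subset drawn in permutation order per replicate
    picks = np.argsort(rng.random((n_perm, t_all.size)), axis=1)[:, :m]
    perm_mod = (t_all[picks] @ deg) / (2 * n_edges)
    exceed = int(np.sum(perm_mod >= observed - 1e-12))
    return (1 + exceed) / (1 + n_perm)


def prune_redundant(
    modules: list[FemModule], overlap_threshold: float = 0.5
) -> list[FemModule]:
    """Drop modules whose overlap coefficient |A∩B| / min(|A|,|B|) with any
    retained higher-modularity module exceeds the threshold.  Modules are
    ranked by modularity descending, ties by seed symbol."""
    if not 0 < overlap_threshold <= 1:
        raise ValueError("overlap_threshold must be in (0, 1]")
    ranked = sorted(
        (m for m in modules if m.size >= 2),
        key=lambda m: (-m.modularity, m.seed),
    )
    kept: list[FemModule] = []
    for mod in ranked:
        a = set(mod.members)
        redundant = any(
            len(a & set(k.members)) / min(len(a), k.size) > overlap_threshold
            for k in kept
        )
        if not redundant:
            kept.append(mod)
    return kept


def validate_modules(
    modules: list[FemModule],
    validation_stats: pd.DataFrame,
    ppi: nx.Graph,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Re-score previously inferred modules with independent-cohort statistics.

    The network is re-weighted with the validation statistics (columns t_D,
    t_R, already rescaled); member genes absent from the validation network
    are dropped (and counted).  Returns one row per module with the
    validation modularity and permutation p; modules with fewer than two
    surviving members or no induced edge are flagged not validated.
    """
    rng = np.random.default_rng(rng)
    net = build_weighted_network(validation_stats, ppi)
    rows = []
    for mod in modules:
        surviving = tuple(g for g in mod.members if g in net)
        n_lost = mod.size - len(surviving)
        row = {
            "seed": mod.seed,
            "size": mod.size,
            "n_dropped": n_lost,
            "modularity": np.nan,
            "p_value": np.nan,
            "validated": False,
        }
        if len(surviving) >= 2:
            try:
                row["modularity"] = modularity(surviving, net)
            except ValueError:
                rows.append(row)
                continue
            probe = FemModule(mod.seed, surviving, row["modularity"])
            row["p_value"] = module_significance(probe, net, n_perm=n_perm, rng=rng)
            row["validated"] = True
        rows.append(row)
    return pd.DataFrame(rows).set_index("seed")


def consistency_correlation(
    discovery: pd.DataFrame, validation: pd.DataFrame, module: FemModule
) -> dict:
    """Pearson correlation of discovery vs validation t-statistics over the
    module's genes, separately for methylation (D) and expression (R)."""
    shared = [g for g in module.members if g in discovery.index and g in validation.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    out = {}
    for tag in ("D", "R"):
        r, p = sps.pearsonr(
            discovery.loc[shared, f"t_{tag}"], validation.loc[shared, f"t_{tag}"]
        )
        out[f"r_{tag}"], out[f"p_{tag}"] = float(r), float(p)
    out["n_genes"] = len(shared)
    return out


class FEMDetector(BaseEstimator):
    """End-to-end hotspot detector: weight network, seed, grow, test, prune.

    Parameters mirror the individual steps; ``fit(stats, ppi)`` expects a
    combined statistics frame (columns t_D, p_D, t_R, p_R with t_R already
    rescaled) and an unweighted PPI graph.

    Fitted attributes: ``network_`` (weighted largest component), ``seeds_``,
    ``modules_`` (pruned, significance-annotated), ``candidates_`` (all grown
    modules before pruning).
    """

    def __init__(
        self,
        n_seeds: int = 10,
        max_size: int = 100,
        n_perm: int = 1000,
        overlap_threshold: float = 0.5,
        random_state: int | None = 0,
    ):
        self.n_seeds = n_seeds
        self.max_size = max_size
        self.n_perm = n_perm
        self.overlap_threshold = overlap_threshold
        self.random_state = random_state

    def fit(self, stats: pd.DataFrame, ppi: nx.Graph) -> "FEMDetector":
        rng = np.random.default_rng(self.random_state)
        self.network_ = build_weighted_network(stats, ppi)
        self.seeds_ = select_seeds(self.network_, self.n_seeds)
        grown = [grow_module(s, self.network_, self.max_size) for s in self.seeds_]
        self.candidates_ = grown
        pruned = prune_redundant(grown, self.overlap_threshold)
        for mod in pruned:
            mod.p_value = module_significance(mod, self.network_, self.n_perm, rng)
        self.modules_ = pruned
        return self

    def module_table(self) -> pd.DataFrame:
        rows = [m.to_dict() for m in self.modules_]
        df = pd.DataFrame(rows)
        if len(df):
            df = df.set_index("seed")
        return df
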