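"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study's data shapes without touching any external
resource:

* a scale-free interaction network (preferential attachment) with planted
  cliques that give the dense-module detector a known answer;
* bulk expression (genes x samples, two groups) with one or more planted
  group-discriminative genes and a latent-factor correlated module
  ``x = lambda * f + sqrt(1 - lambda^2) * eps`` so the expected pairwise
  correlation among module genes is exactly lambda^2;
* a per-cell table whose cluster composition is reweighted in the disease
  condition so one cluster carries a known abundance fold change, plus QC
  metric columns with a configurable fraction of deliberate failures;
* a per-cell expression matrix with planted per-cluster marker genes;
* a drug-target map with one planted drug whose targets sit inside (or
  adjacent to) the disease gene set.

Every generator is a pure function of (config, seed): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GeneSet, as_gene_set

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "gen_network",
    "gen_expression",
    "gen_cell_table",
    "gen_cell_expression",
    "gen_drug_targets",
    "generate_all",
    "PLANTED_DRUG",
]

PLANTED_DRUG = "DRUG_PLANTED"
CASE = "T2DM"
CONTROL = "normal"

#: Default cluster composition: 11 clusters, heavy head, sums to 1.
_DEFAULT_PROPORTIONS = (0.30, 0.22, 0.12, 0.08, 0.07, 0.06, 0.05, 0.04, 0.03, 0.02, 0.01)


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic study, with the defaults acting as the
    documented study conditions (strong plants on realistic backgrounds)."""

    seed: int = 0
    # network
    n_nodes: int = 500
    attachment: int = 2
    planted_clique_sizes: tuple[int, ...] = (8, 6)
    # bulk expression
    n_genes: int = 200
    n_samples_per_group: int = 9
    effect_size: float = 3.0
    module_size: int = 6
    module_loading: float = 0.99
    # cells
    n_cells_per_condition: int = 2000
    cluster_proportions: tuple[float, ...] = _DEFAULT_PROPORTIONS
    enriched_cluster: str = "C2"
    enrichment_fc: float = 20.0
    qc_fail_fraction: float = 0.1
    n_genes_range: tuple[int, int] = (500, 5000)
    pct_mito_range: tuple[float, float] = (0.0, 20.0)
    n_umi_range: tuple[int, int] = (1500, 20000)
    # cell-level expression (marker plants)
    n_cell_genes: int = 60
    markers_per_cluster: int = 3
    marker_shift: float = 3.0
    # drugs
    n_drugs: int = 50
    targets_per_drug: int = 5
    planted_overlap: int = 5

    def __post_init__(self) -> None:
        counts = {
            "n_nodes": self.n_nodes,
            "attachment": self.attachment,
            "n_genes": self.n_genes,
            "n_samples_per_group": self.n_samples_per_group,
            "module_size": self.module_size,
            "n_cells_per_condition": self.n_cells_per_condition,
            "n_drugs": self.n_drugs,
            "targets_per_drug": self.targets_per_drug,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.planted_overlap < 0 or self.planted_overlap > self.targets_per_drug:
            raise ValueError("planted_overlap must be in [0, targets_per_drug]")
        if not 0 <= self.module_loading < 1:
            raise ValueError("module_loading must lie in [0, 1)")
        props = np.asarray(self.cluster_proportions, dtype=float)
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("cluster_proportions must be nonnegative and sum to 1")
        if self.enrichment_fc <= 0:
            raise ValueError("enrichment_fc must be > 0")
        if self.planted_clique_sizes and (
            sum(self.planted_clique_sizes) > self.n_nodes
            or max(self.planted_clique_sizes) > self.n_nodes
        ):
            raise ValueError("planted cliques do not fit in n_nodes")
        if self.enriched_cluster not in self.cluster_names():
            raise ValueError(f"enriched_cluster {self.enriched_cluster!r} is not a cluster id")
        if not 0 <= self.qc_fail_fraction <= 1:
            raise ValueError("qc_fail_fraction must lie in [0, 1]")

    def cluster_names(self) -> list[str]:
        return [f"C{i}" for i in range(len(self.cluster_proportions))]

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per generator."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


def gen_network(config: SyntheticConfig) -> nx.Graph:
    """Preferential-attachment background graph with planted cliques.

    Node ids are stable synthetic gene identifiers; each edge carries a
    confidence score drawn uniformly on (0, 1].  The planted clique node
    lists are stored in ``G.graph['planted_cliques']``.
    """
    rng = config.rng(1)
    G = nx.barabasi_albert_graph(config.n_nodes, config.attachment, seed=rng)
    G = nx.relabel_nodes(G, {i: _gene_id(i) for i in G.nodes})

    order = rng.permutation(config.n_nodes)
    cliques: list[list[str]] = []
    start = 0
    for size in config.planted_clique_sizes:
        members = sorted(_gene_id(i) for i in order[start : start + size])
        start += size
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                G.add_edge(a, b)
        cliques.append(members)

    for a, b in sorted(G.edges):
        G.edges[a, b]["score"] = 1.0 - rng.random()  # uniform on (0, 1]
    G.graph["planted_cliques"] = cliques
    return G


def gen_expression(
    config: SyntheticConfig,
    planted_genes: GeneSet | None = None,
    module_genes: GeneSet | None = None,
    genes: list[str] | None = None,
) -> ExpressionMatrix:
    """Bulk expression: standard-normal noise with two kinds of plants.

    Planted genes get ``+effect_size`` in the disease group.  Module genes
    share a per-sample latent factor f: ``x = lambda*f + sqrt(1-lambda^2)*eps``
    with ``lambda = module_loading``, so the expected pairwise Pearson r
    within the module is lambda^2.  A gene may carry both plants.
    """
    rng = config.rng(2)
    if genes is None:
        genes = [_gene_id(i) for i in range(config.n_genes)]
    if not genes:
        raise ValueError("empty gene universe")
    planted = set() if planted_genes is None else set(as_gene_set(planted_genes).genes)
    module = set() if module_genes is None else set(as_gene_set(module_genes).genes)
    unknown = (planted | module) - set(genes)
    if unknown:
        raise ValueError(f"planted/module genes not in the gene universe: {sorted(unknown)[:5]}")

    n = config.n_samples_per_group
    samples = [f"N{i + 1:02d}" for i in range(n)] + [f"T{i + 1:02d}" for i in range(n)]
    group = pd.Series([CONTROL] * n + [CASE] * n, index=samples, name="group")

    lam = config.module_loading
    factor = rng.standard_normal(2 * n)
    values = rng.standard_normal((len(genes), 2 * n))
    gene_index = {g: i for i, g in enumerate(genes)}
    for g in module:
        i = gene_index[g]
        values[i] = lam * factor + np.sqrt(1 - lam**2) * values[i]
    for g in planted:
        values[gene_index[g], n:] += config.effect_size

    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionMatrix(df, group)


def gen_cell_table(config: SyntheticConfig) -> pd.DataFrame:
    """Per-cell records with reweighted cluster composition and QC metrics.

    In the disease condition the enriched cluster's probability is multiplied
    by ``enrichment_fc`` and the vector renormalized.  A ``qc_fail_fraction``
    of cells get exactly one deliberately out-of-range QC metric.
    """
    rng = config.rng(3)
    names = config.cluster_names()
    base = np.asarray(config.cluster_proportions, dtype=float)
    enriched = names.index(config.enriched_cluster)

    frames = []
    for condition in (CONTROL, CASE):
        probs = base.copy()
        if condition == CASE:
            probs[enriched] *= config.enrichment_fc
            probs /= probs.sum()
        n = config.n_cells_per_condition
        labels = rng.choice(len(names), size=n, p=probs)
        n_genes = rng.integers(config.n_genes_range[0], config.n_genes_range[1] + 1, size=n)
        pct_mito = rng.uniform(*config.pct_mito_range, size=n)
        n_umi = rng.integers(config.n_umi_range[0], config.n_umi_range[1] + 1, size=n)

        fail = rng.random(n) < config.qc_fail_fraction
        modes = rng.integers(0, 4, size=n)
        for i in np.flatnonzero(fail):
            if modes[i] == 0:
                n_genes[i] = rng.integers(0, 100)  # below the minimum gene count
            elif modes[i] == 1:
                n_genes[i] = rng.integers(7501, 12000)
            elif modes[i] == 2:
                pct_mito[i] = rng.uniform(35.0, 100.0)
            else:
                n_umi[i] = rng.integers(0, 1001)

        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{condition}_{i:05d}" for i in range(n)],
                    "cluster": [names[j] for j in labels],
                    "condition": condition,
                    "n_genes": n_genes,
                    "pct_mito": pct_mito,
                    "n_umi": n_umi,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def gen_cell_expression(config: SyntheticConfig, cells: pd.DataFrame) -> pd.DataFrame:
    """Cell-level counts with planted per-cluster marker genes.

    Background counts are Poisson(0.3); each cluster's markers (disjoint
    blocks of ``markers_per_cluster`` genes named ``SC####``) get their rate
    raised by ``marker_shift`` inside the cluster.  The cluster -> marker
    mapping is stored in ``df.attrs['marker_truth']``.
    """
    rng = config.rng(4)
    names = config.cluster_names()
    needed = config.markers_per_cluster * len(names)
    n_genes = max(config.n_cell_genes, needed)
    genes = [f"SC{i:04d}" for i in range(n_genes)]
    lam = np.full((n_genes, len(cells)), 0.3)
    cluster_idx = np.array([names.index(c) for c in cells["cluster"]])
    truth: dict[str, list[str]] = {}
    for j, name in enumerate(names):
        rows = range(j * config.markers_per_cluster, (j + 1) * config.markers_per_cluster)
        truth[name] = [genes[r] for r in rows]
        for r in rows:
            lam[r, cluster_idx == j] += config.marker_shift
    counts = rng.poisson(lam).astype(float)
    df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=list(cells["cell_id"]))
    df.attrs["marker_truth"] = truth
    return df


def gen_drug_targets(
    G: nx.Graph, disease_genes: GeneSet, config: SyntheticConfig
) -> dict[str, GeneSet]:
    """Background drugs with uniform random targets plus one planted drug.

    The planted drug draws ``planted_overlap`` targets inside the disease
    set and the remainder from nodes adjacent to it.
    """
    rng = config.rng(5)
    nodes = sorted(G.nodes, key=str)
    if config.targets_per_drug > len(nodes):
        raise ValueError("targets_per_drug exceeds the node count")
    disease = sorted(set(as_gene_set(disease_genes).genes))
    if not set(disease) <= set(nodes):
        raise ValueError("disease genes must be network nodes")

    drugs: dict[str, GeneSet] = {}
    for i in range(config.n_drugs):
        targets = rng.choice(nodes, size=config.targets_per_drug, replace=False)
        drugs[f"DRUG{i + 1:03d}"] = GeneSet(f"DRUG{i + 1:03d}", frozenset(targets))

    inside = list(rng.choice(disease, size=min(config.planted_overlap, len(disease)), replace=False))
    n_rest = config.targets_per_drug - len(inside)
    if n_rest > 0:
        adjacent = sorted({v for d in disease for v in G[d]} - set(disease))
        pool = adjacent if len(adjacent) >= n_rest else sorted(set(nodes) - set(disease))
        rest = list(rng.choice(pool, size=n_rest, replace=False))
    else:
        rest = []
    drugs[PLANTED_DRUG] = GeneSet(PLANTED_DRUG, frozenset(inside + rest))
    return drugs


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus the planted ground truth."""

    network: nx.Graph
    gene_sets: list[GeneSet]
    expression: ExpressionMatrix
    cells: pd.DataFrame
    cell_expression: pd.DataFrame
    drug_targets: dict[str, GeneSet]
    truth: dict = field(default_factory=dict)


def generate_all(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Wire all generators into one coherent study.

    The disease gene set and a second (pathway-activity) gene set both
    contain the planted cliques, so their intersection is exactly the clique
    genes; the correlated module and the planted discriminative (hub) gene
    live inside the first clique, which is also where the planted drug's
    targets sit.
    """
    G = gen_network(config)
    cliques = G.graph["planted_cliques"]
    core = [g for clique in cliques for g in clique]
    disease_module = cliques[0]

    rng = config.rng(6)
    others = sorted(set(G.nodes) - set(core))
    extras = list(rng.choice(others, size=min(40, len(others)), replace=False))
    set_a = GeneSet("disease", frozenset(core + extras[:20]))
    set_b = GeneSet("pathway_activity", frozenset(core + extras[20:40]))

    # The discriminative plant covers the whole correlated module: hub and
    # module share both the group shift and the latent factor, so the hub's
    # correlation to its module survives the group effect (a shift on the hub
    # alone would add variance uncorrelated with the factor and attenuate r).
    module = disease_module[: min(config.module_size, len(disease_module))]
    n_fill = max(config.n_genes - len(core), 0)
    fill = [n for n in others if n not in extras][:n_fill]
    genes = sorted(set(core) | set(fill))

    expr = gen_expression(
        config,
        planted_genes=GeneSet("planted", frozenset(module)),
        module_genes=GeneSet("module", frozenset(module)),
        genes=genes,
    )
    cells = gen_cell_table(config)
    cell_expr = gen_cell_expression(config, cells)
    drugs = gen_drug_targets(G, GeneSet("disease_module", frozenset(disease_module)), config)

    truth = {
        "planted_cliques": cliques,
        "disease_module": disease_module,
        "planted_genes": module,
        "module_genes": module,
        "enriched_cluster": config.enriched_cluster,
        "planted_drug": PLANTED_DRUG,
        "cluster_markers": cell_expr.attrs["marker_truth"],
    }
    return SyntheticDataset(G, [set_a, set_b], expr, cells, cell_expr, drugs, truth)


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Copy of a config with a different seed (convenience for replicates)."""
    return replace(config, seed=seed)
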