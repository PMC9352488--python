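"""End-to-end orchestration: QC -> abundance -> markers -> intersection ->
pruning -> dense modules -> diagnostics -> correlation expansion -> proximity.

Every stage writes a TSV into the output directory; a JSON manifest records
the tool version, a hash of the configuration, per-stage row counts and
timings, and the seed.  Rerunning with the same config and seed reproduces
byte-identical result tables (the manifest's timings naturally differ).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import diagnostics as dx
from . import io as nio
from . import network as net
from . import proximity as prox
from . import single_cell as sc
from .proximity import ProximityConfig
from .single_cell import QCThresholds
from .types import GeneSet

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.  Unknown YAML keys are rejected."""

    # inputs
    network: str = "network.tsv"
    genesets: str = "genesets.gmt"
    expression: str = "expression.tsv"
    samples: str = "samples.tsv"
    cells: str = "cells.tsv"
    cell_expression: str | None = "cell_expression.tsv"
    drug_targets: str = "drug_targets.tsv"
    geneset_names: list[str] | None = None
    # thresholds
    min_genes: int = 100
    max_genes: int = 7500
    max_pct_mito: float = 35.0
    min_umi: int = 1000
    alpha: float = 0.05
    fc_hi: float = 4.0
    fc_lo: float = 0.25
    min_log2fc: float = 0.5
    min_pct: float = 0.35
    confidence: float = 0.4
    min_degree: int = 1
    vwp: float = 0.2
    haircut: bool = True
    r_min: float = 0.95
    p_max: float = 0.001
    n_random: int = 1000
    fdr_max: float = 0.001
    weight_mode: str = "omega_degree"
    restrict_lcc: bool = True
    # run
    seed: int = 0
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, rows: int, seconds: float, note: str = "ok") -> None:
        self.stages[stage] = {"rows": rows, "seconds": round(seconds, 3), "status": note}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order, writing outputs under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(__version__, config.hash(), config.seed)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result, rows = fn()
            except Exception as exc:  # noqa: BLE001 - stage context is the contract
                raise StageError(name, exc) from exc
            manifest.record(name, rows, time.perf_counter() - t0)
            return result

        return wrap

    thresholds = QCThresholds(config.min_genes, config.max_genes, config.max_pct_mito, config.min_umi)

    def _qc():
        cells = nio.read_cells(config.cells)
        kept = sc.qc_filter(cells, thresholds)
        nio.write_cells(kept, outdir / "cells_qc.tsv")
        return kept, len(kept)

    cells = stage("qc")(_qc)

    def _abundance():
        table = sc.abundance_test(cells, config.alpha, config.fc_hi, config.fc_lo)
        table.to_csv(outdir / "abundance.tsv", sep="\t", index=False)
        return table, len(table)

    abundance = stage("abundance")(_abundance)

    # markers stage runs only when a cell-level expression matrix is given
    if config.cell_expression:

        def _markers():
            import pandas as pd

            cell_expr = pd.read_csv(config.cell_expression, sep="\t", index_col=0)
            cell_expr = cell_expr[[c for c in cell_expr.columns if c in set(cells["cell_id"])]]
            sub = cells[cells["cell_id"].isin(cell_expr.columns)]
            normalized = sc.log_normalize(cell_expr)
            markers = sc.find_markers(
                normalized, sub, config.min_log2fc, config.min_pct, config.alpha
            )
            markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
            sc.top_markers(markers).to_csv(outdir / "top_markers.tsv", sep="\t", index=False)
            return markers, len(markers)

        stage("markers")(_markers)

    def _intersect():
        sets = nio.read_gmt(config.genesets)
        if config.geneset_names:
            by_name = {s.name: s for s in sets}
            sets = [by_name[n] for n in config.geneset_names]
        inter = net.intersect_sets(sets)
        with open(outdir / "intersection.txt", "w") as fh:
            fh.writelines(f"{g}\n" for g in sorted(inter.genes))
        return inter, len(inter)

    intersection = stage("intersect")(_intersect)

    def _network():
        G = net.load_network(config.network, config.confidence)
        pruned = net.prune_low_degree(G, intersection, config.min_degree)
        net.write_network(pruned, outdir / "network_pruned.tsv")
        return (G, pruned), pruned.number_of_nodes()

    G, pruned = stage("network")(_network)

    def _mcode():
        complexes = net.mcode_find_complexes(pruned, config.vwp, config.haircut)
        with open(outdir / "complexes.tsv", "w") as fh:
            fh.write("complex_id\tseed\tscore\tmembers\n")
            for i, c in enumerate(complexes, start=1):
                fh.write(f"MCODE{i}\t{c.seed}\t{c.score:.6g}\t{','.join(sorted(c.members))}\n")
        return complexes, len(complexes)

    complexes = stage("mcode")(_mcode)

    def _diagnostics():
        expr = nio.read_expression(config.expression, config.samples)
        members = frozenset().union(*(c.members for c in complexes)) if complexes else frozenset()
        candidates = GeneSet("complex_members", members)
        ranked = dx.rank_candidates(expr, candidates, config.alpha)
        ranked.to_csv(outdir / "diagnostics.tsv", sep="\t", index=False)
        hub = dx.select_hub(ranked)
        return (expr, hub), len(ranked)

    expr, hub = stage("diagnostics")(_diagnostics)

    if hub is None:
        manifest.record("expand", 0, 0.0, "skipped: no hub")
        manifest.record("proximity", 0, 0.0, "skipped: no hub")
    else:

        def _expand():
            table = dx.expand_correlated(expr, hub, config.r_min, config.p_max)
            table.to_csv(outdir / "correlated.tsv", sep="\t", index=False)
            disease = frozenset({hub} | set(table.loc[table["selected"], "gene"]))
            return GeneSet("disease_set", disease), len(table)

        disease_set = stage("expand")(_expand)

        def _proximity():
            drugs = nio.read_drug_targets(config.drug_targets)
            pcfg = ProximityConfig(
                n_random=config.n_random,
                seed=config.seed,
                weight_mode=config.weight_mode,
                restrict_lcc=config.restrict_lcc,
            )
            table = prox.screen_drugs(G, disease_set, drugs, pcfg, config.fdr_max)
            table.to_csv(outdir / "proximity.tsv", sep="\t", index=False)
            return table, len(table)

        stage("proximity")(_proximity)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2)
    logger.info("pipeline complete: %s", {k: v["status"] for k, v in manifest.stages.items()})
    return manifest
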