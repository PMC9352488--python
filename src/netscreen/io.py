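"""Readers and writers for the plain-text formats the pipeline consumes.

Gene sets travel as GMT (tab-separated: name, description, genes...),
everything tabular as TSV.  Every writer's output round-trips through its
reader.
"""

from __future__ import annotations

import logging

import pandas as pd

from .types import ExpressionMatrix, GeneSet, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "read_expression",
    "write_expression",
    "read_cells",
    "write_cells",
    "read_drug_targets",
    "write_drug_targets",
]


def write_dataset(dataset, outdir) -> None:
    """Write a synthetic dataset as the standard pipeline input files."""
    import json
    from pathlib import Path

    from .network import write_network

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_network(dataset.network, outdir / "network.tsv")
    write_gmt(dataset.gene_sets, outdir / "genesets.gmt")
    write_expression(dataset.expression, outdir / "expression.tsv", outdir / "samples.tsv")
    write_cells(dataset.cells, outdir / "cells.tsv")
    dataset.cell_expression.to_csv(outdir / "cell_expression.tsv", sep="\t", index_label="gene")
    write_drug_targets(dataset.drug_targets, outdir / "drug_targets.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(dataset.truth, fh, indent=2, default=list)


def read_gmt(path) -> list[GeneSet]:
    """One gene set per line; duplicate genes within a line are collapsed."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(parts)}")
            name, _desc, genes = parts[0], parts[1], parts[2:]
            if len(set(genes)) < len(genes):
                logger.warning("%s:%d: duplicate genes in set %r collapsed", path, lineno, name)
            sets.append(GeneSet(name, frozenset(genes)))
    return sets


def write_gmt(sets: list[GeneSet], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *sorted(s.genes)]) + "\n")


def read_gene_list(path, name: str | None = None) -> GeneSet:
    """One gene per line (blank lines and '#' comments ignored)."""
    with open(path) as fh:
        genes = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    return GeneSet(name or str(path), frozenset(genes))


def read_expression(path, samples_path=None) -> ExpressionMatrix:
    """Genes x samples TSV (first column gene ids, header sample ids).

    ``samples_path`` is a two-column TSV (sample, group); every matrix
    sample must appear in it.  Missing values and duplicate gene ids are
    schema errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    group = None
    if samples_path is not None:
        samples = pd.read_csv(samples_path, sep="\t")
        if not {"sample", "group"} <= set(samples.columns):
            raise SchemaError(f"{samples_path}: needs 'sample' and 'group' columns")
        group = samples.set_index("sample")["group"]
    return ExpressionMatrix(df, group)


def write_expression(expr: ExpressionMatrix, path, samples_path=None) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")
    if samples_path is not None and expr.group is not None:
        expr.group.rename_axis("sample").rename("group").to_frame().to_csv(samples_path, sep="\t")


def read_cells(path) -> pd.DataFrame:
    cells = pd.read_csv(path, sep="\t")
    required = {"cell_id", "cluster", "condition"}
    missing = required - set(cells.columns)
    if missing:
        raise SchemaError(f"{path}: cell table missing columns {sorted(missing)}")
    return cells


def write_cells(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, sep="\t", index=False)


def read_drug_targets(path) -> dict[str, GeneSet]:
    """Two-column TSV (drug, target) -> drug id to target gene set."""
    df = pd.read_csv(path, sep="\t")
    if not {"drug", "target"} <= set(df.columns):
        raise SchemaError(f"{path}: needs 'drug' and 'target' columns")
    return {
        drug: GeneSet(drug, frozenset(sub["target"]))
        for drug, sub in df.groupby("drug", sort=True)
    }


def write_drug_targets(drugs: dict[str, GeneSet], path) -> None:
    with open(path, "w") as fh:
        fh.write("drug\ttarget\n")
        for drug in sorted(drugs):
            for target in sorted(drugs[drug].genes):
                fh.write(f"{drug}\t{target}\n")
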