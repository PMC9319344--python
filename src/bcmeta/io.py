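"""File formats: expression/phenotype TSV, edge lists, gene lists, models.

Formats are deliberately plain so synthetic runs and real runs share one
code path: expression matrices are TSV with a leading ``gene`` column and
one column per sample; phenotype tables are TSV with ``sample``, ``study``,
``group`` and optional ``time``/``event``/``response`` columns; interaction
graphs are STRING-style three-column edge TSVs; risk models are JSON.
Missing values fail fast.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd

from .harmonize import ExpressionStudy


def write_expression(values: pd.DataFrame, path) -> None:
    df = values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        bad = df.columns[df.isna().any()][0]
        raise ValueError(f"{path}: missing values (e.g. in column {bad!r})")
    df.index.name = "gene"
    return df


def write_phenotype(samples: pd.DataFrame, path) -> None:
    """``samples``: index = sample, columns ⊇ {study, group}."""
    df = samples.copy()
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_phenotype(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    for col in ("study", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: phenotype table lacks column {col!r}")
    if df[["study", "group"]].isna().any().any():
        raise ValueError(f"{path}: missing study/group values")
    return df


def write_study(study: ExpressionStudy, expr_path, pheno_path) -> None:
    write_expression(study.values, expr_path)
    pheno = pd.DataFrame(
        {"study": study.study_id, "group": study.phenotype.loc[study.samples]},
        index=pd.Index(study.samples, name="sample"),
    )
    write_phenotype(pheno, pheno_path)


def read_studies(expr_path, pheno_path) -> list[ExpressionStudy]:
    """Read one expression TSV plus a phenotype TSV into per-study objects.

    The phenotype ``study`` column may split the matrix's samples into any
    number of studies (including within-series splits).
    """
    values = read_expression(expr_path)
    pheno = read_phenotype(pheno_path)
    unknown = set(pheno.index) - set(values.columns)
    if unknown:
        raise ValueError(f"phenotype rows reference unknown samples: {sorted(unknown)}")
    missing = set(values.columns) - set(pheno.index)
    if missing:
        raise ValueError(f"samples without phenotype rows: {sorted(missing)}")
    studies = []
    for sid, sub in pheno.groupby("study", sort=False):
        cols = [s for s in values.columns if s in set(sub.index)]
        studies.append(
            ExpressionStudy(str(sid), values[cols], sub["group"].rename(None))
        )
    return studies


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [
        (u, v, d.get("combined_score", 1.0)) for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "combined_score"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_list(path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


def write_gene_list(genes: list[str], path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


# ---------------------------------------------------------------------------
# bundled reference hub-gene lists (printed inputs used by tests and reports)


def _data_text(name: str) -> str:
    return resources.files("bcmeta.data").joinpath(name).read_text()


def reference_rra_ranking() -> list[str]:
    """Aggregated centrality-ranking hub list (RRA p < 0.01)."""
    return [g for g in _data_text("rra_hub_ranking.txt").splitlines() if g]


def reference_mcode_clusters() -> pd.DataFrame:
    """Dense-cluster membership with printed node/edge-derived scores."""
    df = pd.read_csv(
        resources.files("bcmeta.data").joinpath("mcode_cluster_members.tsv"),
        sep="\t",
    )
    df["genes"] = df["genes"].str.split(",")
    return df


def reference_ppi_hubs() -> list[str]:
    """Intersection of the ranking-based and cluster-based hub lists."""
    return [g for g in _data_text("ppi_hub_intersection.txt").splitlines() if g]


def reference_key_hubs() -> dict[str, list[str]]:
    """Key hub genes per co-expression module (PPI ∩ module hubs)."""
    out: dict[str, list[str]] = {}
    for line in _data_text("key_hub_genes.tsv").splitlines()[1:]:
        mod, genes = line.split("\t")
        out[mod] = [g for g in genes.split(",") if g]
    return out
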