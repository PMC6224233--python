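"""Plain-text readers and writers for the pipeline's file formats.

All formats are tab-separated text: expression matrices (genes in rows,
header row = sample IDs), sample metadata (sample, study, group, age),
STRING-style edge lists (protein1, protein2, combined_score), qPCR Ct
tables, and GMT gene sets (see :mod:`agemeta.enrichment`).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .preprocess import StudyExpression


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    required = {"protein1", "protein2", "combined_score"}
    if not required <= set(edges.columns):
        raise ValueError(f"edge list needs columns {sorted(required)}")
    return edges


def write_qpcr(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_qpcr(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_study(study: StudyExpression, outdir: str | Path) -> tuple[Path, Path]:
    """Write one study's matrix and metadata TSVs; returns the two paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = outdir / f"{study.study_id}_expression.tsv"
    meta = outdir / f"{study.study_id}_samples.tsv"
    write_expression(study.matrix, expr)
    write_sample_meta(study.sample_meta, meta)
    return expr, meta


def read_study(expr_path: str | Path, meta_path: str | Path,
               study_id: str | None = None) -> StudyExpression:
    matrix = read_expression(expr_path)
    meta = read_sample_meta(meta_path)
    if study_id is None:
        study_id = str(meta["study"].iloc[0]) if "study" in meta else Path(expr_path).stem
    return StudyExpression(study_id=study_id, matrix=matrix, sample_meta=meta)
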