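"""Reading and writing the pipeline's on-disk formats.

Array studies are tab-separated gene x sample matrices; RNA-seq counts are
MatrixMarket coordinate files with plain-text row/column name sidecars;
sample sheets and survival tables are CSV; the truth manifest is JSON.
Everything written here round-trips losslessly through the readers (floats
to within 1e-9; counts exactly).
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import (
    NORMALIZED_LOG2,
    RAW_COUNTS,
    RNASEQ,
    ExpressionStudy,
    ValidationError,
)
from .synthetic import TruthManifest

FLOAT_FMT = "%.10g"


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_mtx(matrix: pd.DataFrame, prefix) -> list[str]:
    """Write integer counts as <prefix>.mtx with .genes.txt / .samples.txt."""
    mtx = f"{prefix}.mtx"
    genes = f"{prefix}.genes.txt"
    samples = f"{prefix}.samples.txt"
    spio.mmwrite(mtx, sparse.coo_matrix(matrix.to_numpy(dtype=np.int64)), field="integer")
    with open(genes, "w") as fh:
        fh.write("\n".join(map(str, matrix.index)) + "\n")
    with open(samples, "w") as fh:
        fh.write("\n".join(map(str, matrix.columns)) + "\n")
    return [mtx, genes, samples]


def read_counts_mtx(prefix) -> pd.DataFrame:
    m = spio.mmread(f"{prefix}.mtx").toarray().astype(np.int64)
    with open(f"{prefix}.genes.txt") as fh:
        genes = [line.strip() for line in fh if line.strip()]
    with open(f"{prefix}.samples.txt") as fh:
        samples = [line.strip() for line in fh if line.strip()]
    return pd.DataFrame(m, index=genes, columns=samples)


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_study(study: ExpressionStudy, out_dir) -> list[str]:
    """Write one study; returns the list of files created."""
    os.makedirs(out_dir, exist_ok=True)
    files = []
    sheet_path = os.path.join(out_dir, f"{study.study_id}.samples.csv")
    write_sample_sheet(study.samples, sheet_path)
    if study.platform == RNASEQ and study.normalization_state == RAW_COUNTS:
        prefix = os.path.join(out_dir, f"{study.study_id}.counts")
        files.extend(write_counts_mtx(study.matrix, prefix))
    else:
        mat_path = os.path.join(out_dir, f"{study.study_id}.expr.tsv")
        write_matrix_tsv(study.matrix, mat_path)
        files.append(mat_path)
    files.append(sheet_path)
    return files


def read_study(out_dir, study_id: str) -> ExpressionStudy:
    sheet = read_sample_sheet(os.path.join(out_dir, f"{study_id}.samples.csv"))
    counts_prefix = os.path.join(out_dir, f"{study_id}.counts")
    if os.path.exists(f"{counts_prefix}.mtx"):
        matrix = read_counts_mtx(counts_prefix)
        return ExpressionStudy(
            study_id=study_id,
            matrix=matrix,
            samples=sheet,
            platform=RNASEQ,
            normalization_state=RAW_COUNTS,
        )
    mat_path = os.path.join(out_dir, f"{study_id}.expr.tsv")
    if not os.path.exists(mat_path):
        raise ValidationError(f"no matrix found for study {study_id!r} in {out_dir}")
    matrix = read_matrix_tsv(mat_path)
    return ExpressionStudy(
        study_id=study_id,
        matrix=matrix,
        samples=sheet,
        platform="array",
        normalization_state=NORMALIZED_LOG2,
    )


def write_survival(cohort, out_dir) -> list[str]:
    """Write survival table CSV and z-score matrix TSV."""
    os.makedirs(out_dir, exist_ok=True)
    table_path = os.path.join(out_dir, "survival.csv")
    expr_path = os.path.join(out_dir, "survival.zscores.tsv")
    out = cohort.table.copy()
    out.index.name = "sample_id"
    out.to_csv(table_path, float_format=FLOAT_FMT)
    write_matrix_tsv(cohort.expression, expr_path)
    return [table_path, expr_path]


def read_survival(out_dir):
    from .survival import SurvivalCohort

    table = pd.read_csv(os.path.join(out_dir, "survival.csv"), index_col="sample_id")
    expression = read_matrix_tsv(os.path.join(out_dir, "survival.zscores.tsv"))
    return SurvivalCohort(table=table, expression=expression)


def write_fixtures(studies, cohort, out_dir, truth: TruthManifest | None = None) -> dict:
    """Write a whole simulated dataset; returns a manifest of created files.

    The manifest maps study IDs to their files and records the survival and
    truth files; all paths are relative to ``out_dir``.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"studies": {}, "files": []}
    for study in studies:
        files = write_study(study, out_dir)
        rel = [os.path.relpath(f, out_dir) for f in files]
        manifest["studies"][study.study_id] = rel
        manifest["files"].extend(rel)
    if cohort is not None:
        files = write_survival(cohort, out_dir)
        rel = [os.path.relpath(f, out_dir) for f in files]
        manifest["survival"] = rel
        manifest["files"].extend(rel)
    if truth is not None:
        truth_path = os.path.join(out_dir, "truth.json")
        truth.to_json(truth_path)
        manifest["truth"] = "truth.json"
        manifest["files"].append("truth.json")
    with open(os.path.join(out_dir, "fixtures.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
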