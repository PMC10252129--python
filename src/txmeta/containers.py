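"""Core data containers shared across the pipeline.

An :class:`ExpressionStudy` holds one study's gene x sample expression matrix
together with its sample sheet; a :class:`DGEResult` holds the per-gene
differential-expression table (effect, standard error, p, FDR) that the
meta-analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
CASE = "case"

ARRAY = "array"
RNASEQ = "rnaseq"

RAW_COUNTS = "raw_counts"
NORMALIZED_LOG2 = "normalized_log2"

#: minimum group size: studies with <= 4 samples in either arm are excluded
MIN_GROUP_SIZE = 5


class ValidationError(ValueError):
    """Raised when an input object violates a documented contract."""


@dataclass
class ExpressionStudy:
    """One study's expression matrix plus sample-level metadata.

    Parameters
    ----------
    study_id:
        Unique study label (e.g. an accession-like identifier).
    matrix:
        Gene x sample values: log2 intensities for arrays, raw counts for
        RNA-seq in the ``raw_counts`` state. Index = gene IDs, columns =
        sample IDs.
    samples:
        Sample sheet indexed by sample ID with a ``group`` column in
        {"control", "case"} and an optional ``pair_id`` column for paired
        designs.
    platform:
        "array" or "rnaseq".
    normalization_state:
        "raw_counts" or "normalized_log2".
    """

    study_id: str
    matrix: pd.DataFrame
    samples: pd.DataFrame
    platform: str = ARRAY
    normalization_state: str = NORMALIZED_LOG2

    def __post_init__(self) -> None:
        if self.platform not in (ARRAY, RNASEQ):
            raise ValidationError(f"unknown platform {self.platform!r}")
        if self.normalization_state not in (RAW_COUNTS, NORMALIZED_LOG2):
            raise ValidationError(
                f"unknown normalization state {self.normalization_state!r}"
            )
        if not self.matrix.index.is_unique:
            raise ValidationError(f"{self.study_id}: gene IDs are not unique")
        if "group" not in self.samples.columns:
            raise ValidationError(f"{self.study_id}: sample sheet lacks 'group'")
        if not set(self.matrix.columns) <= set(self.samples.index):
            missing = set(self.matrix.columns) - set(self.samples.index)
            raise ValidationError(
                f"{self.study_id}: samples missing from sheet: {sorted(missing)[:5]}"
            )
        groups = self.samples.loc[self.matrix.columns, "group"]
        bad = set(groups.unique()) - {CONTROL, CASE}
        if bad:
            raise ValidationError(f"{self.study_id}: unknown group labels {bad}")
        counts = groups.value_counts()
        for grp in (CONTROL, CASE):
            if counts.get(grp, 0) < MIN_GROUP_SIZE:
                raise ValidationError(
                    f"{self.study_id}: group {grp!r} has {counts.get(grp, 0)} "
                    f"samples; at least {MIN_GROUP_SIZE} per group required"
                )
        if self.platform == RNASEQ and self.normalization_state == RAW_COUNTS:
            values = self.matrix.to_numpy()
            if (values < 0).any():
                raise ValidationError(f"{self.study_id}: negative counts")
            if not np.allclose(values, np.round(values)):
                raise ValidationError(f"{self.study_id}: non-integer counts")

    @property
    def gene_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def control_samples(self) -> pd.Index:
        groups = self.samples.loc[self.matrix.columns, "group"]
        return self.matrix.columns[(groups == CONTROL).to_numpy()]

    @property
    def case_samples(self) -> pd.Index:
        groups = self.samples.loc[self.matrix.columns, "group"]
        return self.matrix.columns[(groups == CASE).to_numpy()]


@dataclass
class DGEResult:
    """Per-gene differential expression table for one study.

    ``table`` is indexed by gene ID with columns ``log2fc`` (case minus
    control effect, log2 units), ``se`` (its standard error), ``df``
    (residual degrees of freedom), ``t``, ``p`` and ``fdr``.
    """

    study_id: str
    table: pd.DataFrame
    paired: bool = False
    moderated: bool = False

    REQUIRED = ("log2fc", "se", "df", "t", "p", "fdr")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"{self.study_id}: DGE table lacks {missing}")

    @classmethod
    def from_tsv(cls, path, study_id: str | None = None) -> "DGEResult":
        table = pd.read_csv(path, sep="\t", index_col=0)
        if study_id is None:
            import os

            study_id = os.path.splitext(os.path.basename(str(path)))[0]
        return cls(study_id=study_id, table=table)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.10g")
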