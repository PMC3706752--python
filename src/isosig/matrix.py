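"""Core data containers: expression matrices, transcript-to-gene maps and
sample metadata.

An :class:`ExpressionMatrix` is a thin wrapper around a features x samples
:class:`pandas.DataFrame` carrying two tags: ``level`` ("isoform" or
"gene") and ``scale`` ("linear" or "log2").  Downstream operations check
these tags instead of guessing from the values.

All on-disk formats are plain TSV: matrices have a ``feature_id`` first
column and one column per sample; annotation files have two columns
``transcript_id`` and ``gene_id``; sample metadata has ``sample_id``,
``class`` and ``tissue`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

LEVELS = ("isoform", "gene")
SCALES = ("linear", "log2")


@dataclass
class ExpressionMatrix:
    """Nonnegative feature-by-sample expression estimates.

    Parameters
    ----------
    data
        DataFrame with feature ids as index and sample ids as columns.
    level
        Aggregation level of the rows, ``"isoform"`` or ``"gene"``.
    scale
        ``"linear"`` (raw estimates, must be >= 0) or ``"log2"``
        (log2(x+1)-transformed).
    """

    data: pd.DataFrame
    level: str = "isoform"
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("data must be a pandas DataFrame")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate feature ids")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise DataError("expression matrix contains NaN or infinite values")
        if self.scale == "linear" and values.size and (values < 0).any():
            raise DataError("linear-scale expression matrix contains negative values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise DataError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(sample_ids)].copy(), self.level, self.scale)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, level: str = "isoform", scale: str = "linear") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, level=level, scale=scale)


@dataclass
class AnnotationMap:
    """Many-to-one transcript-to-gene mapping.

    ``mapping`` is a Series indexed by transcript id with gene id values;
    each transcript maps to exactly one gene.
    """

    mapping: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.mapping.index.has_duplicates:
            dup = self.mapping.index[self.mapping.index.duplicated()][:5].tolist()
            raise ValidationError(f"transcripts mapped more than once: {dup}")
        if self.mapping.isna().any():
            raise DataError("annotation map contains missing gene ids")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.mapping.index)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.mapping.unique())

    @property
    def n_genes(self) -> int:
        return self.mapping.nunique()

    def gene_of(self, transcript_id: str) -> str:
        return self.mapping[transcript_id]

    def isoforms_of(self, gene_id: str) -> list[str]:
        return list(self.mapping.index[self.mapping == gene_id])

    def check_covers(self, feature_ids) -> None:
        missing = [f for f in feature_ids if f not in self.mapping.index]
        if missing:
            raise DataError(
                f"{len(missing)} transcripts absent from annotation, e.g. {missing[:5]}"
            )

    def to_tsv(self, path) -> None:
        df = self.mapping.rename("gene_id").to_frame()
        df.index.name = "transcript_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "AnnotationMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"transcript_id", "gene_id"} <= set(df.columns):
            raise ValidationError("annotation TSV needs 'transcript_id' and 'gene_id' columns")
        return cls(df.set_index("transcript_id")["gene_id"])


METADATA_COLUMNS = ("class", "tissue")


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-metadata frame (index sample_id, columns class/tissue)."""
    for col in METADATA_COLUMNS:
        if col not in metadata.columns:
            raise ValidationError(f"metadata missing column {col!r}")
    if metadata.index.has_duplicates:
        raise ValidationError("duplicate sample ids in metadata")
    if metadata["class"].nunique() < 2:
        raise DataError("metadata must contain at least two classes")
    return metadata


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValidationError("metadata TSV needs a 'sample_id' column")
    return validate_metadata(df.set_index("sample_id"))


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
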