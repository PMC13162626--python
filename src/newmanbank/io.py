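"""Tabular I/O for expression/mutation matrices, sample manifests and run configuration.

All matrices are pandas DataFrames with genes in rows (index = gene IDs) and
samples in columns (columns = sample IDs).  Files are plain UTF-8 TSV: a header
row of sample IDs and a first column of gene IDs.  Binary matrices (outlier
calls or mutation calls) use the same dialect with entries restricted to {0, 1}.

The sample manifest is a DataFrame indexed by ``sample_id`` with columns
``cohort`` (tissue/disease label), ``status`` (``tumor`` or ``normal``) and an
optional ``histology`` column.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ValidationError",
    "RunConfig",
    "CohortSplit",
    "read_matrix",
    "write_matrix",
    "read_manifest",
    "write_manifest",
    "validate_expression",
    "validate_binary",
    "align",
]


class FormatError(ValueError):
    """The file does not conform to the expected tabular format."""


class ValidationError(ValueError):
    """The parsed content violates a domain invariant."""


_STATUSES = ("tumor", "normal")


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.duplicated().any():
        dupes = sorted(set(ids[ids.duplicated()].astype(str)))
        raise FormatError(f"duplicate {what} ID(s): {', '.join(dupes[:10])}")


def validate_expression(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a continuous gene × sample matrix; returns the (float) frame."""
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    if df.shape[0] < 2 or df.shape[1] < 1:
        raise ValidationError(
            f"matrix must have at least 2 genes and 1 sample, got {df.shape}"
        )
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in matrix: {exc}") from exc
    if not np.isfinite(values.to_numpy()).all():
        bad = np.argwhere(~np.isfinite(values.to_numpy()))[0]
        raise ValidationError(
            f"non-finite value at gene {df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
        )
    return values


def validate_binary(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a 0/1 gene × sample call matrix; returns an int8 frame."""
    values = validate_expression(df)
    arr = values.to_numpy()
    if not np.isin(arr, (0.0, 1.0)).all():
        bad = np.argwhere(~np.isin(arr, (0.0, 1.0)))[0]
        raise ValidationError(
            f"non-binary value {arr[bad[0], bad[1]]!r} at gene "
            f"{df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
        )
    return values.astype(np.int8)


def read_matrix(path: str | Path, expect_binary: bool = False) -> pd.DataFrame:
    """Read a gene × sample TSV matrix.

    Parameters
    ----------
    path
        TSV file with a header row of sample IDs and first column of gene IDs.
    expect_binary
        If True, every entry must be 0 or 1 and an int8 frame is returned.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return validate_binary(df) if expect_binary else validate_expression(df)


def write_matrix(df: pd.DataFrame, path: str | Path, float_fmt: str = "%.6g") -> None:
    """Write a gene × sample matrix as TSV (floats at 6 significant digits)."""
    out = df.copy()
    out.index.name = out.index.name or "gene_id"
    out.to_csv(path, sep="\t", float_format=float_fmt)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest TSV (columns sample_id, cohort, status[, histology]).

    Status tokens are canonicalized case-insensitively to ``tumor``/``normal``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cohort", "status"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing column(s): {', '.join(sorted(missing))}")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dupes = sorted(set(df.loc[df["sample_id"].duplicated(), "sample_id"]))
        raise FormatError(f"duplicate sample_id(s): {', '.join(dupes[:10])}")
    df["status"] = df["status"].str.strip().str.lower()
    unknown = sorted(set(df["status"]) - set(_STATUSES))
    if unknown:
        raise ValidationError(
            f"unknown status token(s): {', '.join(unknown)}; expected tumor/normal"
        )
    if (df["cohort"].isna() | (df["cohort"].str.strip() == "")).any():
        raise ValidationError("every sample must have a non-empty cohort")
    if "histology" not in df.columns:
        df["histology"] = pd.NA
    return df.set_index("sample_id")[["cohort", "status", "histology"]]


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    out = manifest.reset_index()
    out = out.rename(columns={out.columns[0]: "sample_id"})
    out.to_csv(path, sep="\t", index=False)


class CohortSplit(NamedTuple):
    """Tumor and normal submatrices of one cohort (genes × samples)."""

    tumor: pd.DataFrame
    normal: pd.DataFrame


def align(matrix: pd.DataFrame, manifest: pd.DataFrame) -> dict[str, CohortSplit]:
    """Partition matrix samples by (cohort, tumor/normal status).

    Every matrix sample must appear in the manifest.  Gene order is preserved
    and no sample is lost or duplicated; a cohort with tumors but no normal
    samples yields an empty ``normal`` submatrix with a warning.
    """
    missing = [s for s in matrix.columns if s not in manifest.index]
    if missing:
        raise ValidationError(
            f"{len(missing)} matrix sample(s) absent from manifest: "
            + ", ".join(missing[:10])
        )
    sub = manifest.loc[matrix.columns]
    out: dict[str, CohortSplit] = {}
    for cohort in dict.fromkeys(sub["cohort"]):  # first-appearance order
        in_cohort = sub["cohort"] == cohort
        tum = matrix.loc[:, (in_cohort & (sub["status"] == "tumor")).to_numpy()]
        nor = matrix.loc[:, (in_cohort & (sub["status"] == "normal")).to_numpy()]
        if tum.shape[1] and not nor.shape[1]:
            warnings.warn(f"cohort {cohort!r} has tumors but no normal samples")
        out[cohort] = CohortSplit(tumor=tum, normal=nor)
    return out


@dataclass
class RunConfig:
    """Pipeline parameters.

    Attributes
    ----------
    threshold : float
        Dichotomization cutoff in bank-SD units (default 3).
    k : int
        Number of clusters to cut from the Ward tree (default 6, one per
        known disease category).
    loess_span : float
        Fraction of genes in each local window of the SD-vs-mean loess fit.
    loess_degree : int
        Local polynomial degree of the loess fit (1 or 2).
    log_scale_fit : bool
        If True, the loess regresses log SD on mean and exponentiates back.
    sd_floor : float
        Lower clamp for the smoothed SD, in expression units.
    seed : int
        Seed for any stochastic step (t-SNE).
    ward_dialect : str
        "squared" (Ward update on squared dissimilarities) or "raw".
    """

    threshold: float = 3.0
    k: int = 6
    loess_span: float = 0.5
    loess_degree: int = 2
    log_scale_fit: bool = False
    sd_floor: float = 1e-6
    seed: int = 0
    ward_dialect: str = "squared"

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValidationError("threshold must be > 0")
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if not 0 < self.loess_span <= 1:
            raise ValidationError("loess_span must be in (0, 1]")
        if self.loess_degree not in (1, 2):
            raise ValidationError("loess_degree must be 1 or 2")
        if not self.sd_floor > 0:
            raise ValidationError("sd_floor must be > 0")
        if self.ward_dialect not in ("squared", "raw"):
            raise ValidationError("ward_dialect must be 'squared' or 'raw'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = asdict(self)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))
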