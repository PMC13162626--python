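"""The Newman bank test: standardize tumors against a normal reference bank.

A "bank" is a cohort of tissue-matched normal samples.  For each gene g the
bank provides a reference mean, MeanBank(g), and an *independent* SD estimate,
SDBank(g), obtained by smoothing the per-gene raw SDs against the per-gene
means with loess — exploiting the empirical fact that the SD of gene
expression is a smooth function of the mean.  Borrowing strength across genes
with similar means keeps the SD estimate usable even for very small banks.

A tumor value x standardizes to the ν-score

    ν(g, s) = (x(g, s) − MeanBank(g)) / SDBank(g)

measured in bank-SD units.  Dichotomizing at a threshold t (default 3) turns
ν into a binary call: 0 when |ν| ≤ t ("within the normal range"), 1 when
|ν| > t ("outside the normal range").  The standardize-then-binarize process
is called Newmanization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import RunConfig, ValidationError, align
from .loess import loess_fit

__all__ = [
    "BankModel",
    "fit_bank",
    "newmanize",
    "dichotomize",
    "newmanize_cohorts",
]

_MIN_GENES = 30  # loess needs cross-gene support


@dataclass
class BankModel:
    """Per-gene reference mean and loess-smoothed SD of a normal bank."""

    gene_ids: pd.Index
    bank_mean: np.ndarray
    bank_sd_raw: np.ndarray
    bank_sd_smooth: np.ndarray
    n_bank: int
    span: float
    degree: int
    sd_floor: float

    def __post_init__(self) -> None:
        if self.n_bank < 2:
            raise ValidationError("bank must contain at least 2 samples")
        if not (self.bank_sd_smooth > 0).all():
            raise ValidationError("smoothed bank SD must be strictly positive")
        if (self.bank_sd_raw < 0).any():
            raise ValidationError("raw bank SD cannot be negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": self.bank_mean,
                "sd_raw": self.bank_sd_raw,
                "sd_smooth": self.bank_sd_smooth,
            },
            index=self.gene_ids.rename("gene_id"),
        )

    def to_tsv(self, path: str | Path, float_fmt: str = "%.6g") -> None:
        self.to_frame().to_csv(path, sep="\t", float_format=float_fmt)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        n_bank: int = 2,
        span: float = 0.5,
        degree: int = 2,
        sd_floor: float = 1e-6,
    ) -> "BankModel":
        return cls(
            gene_ids=frame.index,
            bank_mean=frame["mean"].to_numpy(float),
            bank_sd_raw=frame["sd_raw"].to_numpy(float),
            bank_sd_smooth=frame["sd_smooth"].to_numpy(float),
            n_bank=n_bank,
            span=span,
            degree=degree,
            sd_floor=sd_floor,
        )

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "BankModel":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0), **kwargs)


def fit_bank(
    normals: pd.DataFrame,
    span: float = 0.5,
    sd_floor: float = 1e-6,
    degree: int = 2,
    log_scale: bool = False,
) -> BankModel:
    """Fit the normal-bank model: per-gene mean and loess-smoothed SD.

    Parameters
    ----------
    normals
        Gene × sample matrix of normal (reference) samples; at least 2
        samples and 30 genes.
    span
        Loess span (fraction of genes per local window).
    sd_floor
        Lower clamp for the smoothed SD (prevents division by zero where
        the fitted curve is flat or negative).
    degree
        Local polynomial degree of the loess fit.
    log_scale
        Fit the loess on log SD instead of raw SD (exponentiated back).
    """
    n_bank = normals.shape[1]
    if n_bank < 2:
        raise ValidationError(
            "a bank of at least 2 normal samples is required for an "
            "independent SD estimate"
        )
    if normals.shape[0] < _MIN_GENES:
        raise ValidationError(
            f"loess smoothing needs at least {_MIN_GENES} genes, got {normals.shape[0]}"
        )
    values = normals.to_numpy(float)
    mean = values.mean(axis=1)
    sd_raw = values.std(axis=1, ddof=1)
    if log_scale:
        eps = max(sd_floor, 1e-12)
        curve = loess_fit(mean, np.log(sd_raw + eps), span=span, degree=degree)
        sd_smooth = np.exp(curve(mean))
    else:
        curve = loess_fit(mean, sd_raw, span=span, degree=degree)
        sd_smooth = curve(mean)
    sd_smooth = np.maximum(sd_smooth, sd_floor)
    return BankModel(
        gene_ids=normals.index,
        bank_mean=mean,
        bank_sd_raw=sd_raw,
        bank_sd_smooth=sd_smooth,
        n_bank=n_bank,
        span=span,
        degree=degree,
        sd_floor=sd_floor,
    )


def newmanize(tumors: pd.DataFrame, bank: BankModel) -> pd.DataFrame:
    """Standardize tumor expression to ν-scores against the bank.

    ν(g, s) = (x(g, s) − MeanBank(g)) / SDBank(g), elementwise, in SD units.
    The tumor gene set must equal the bank gene set.
    """
    missing = bank.gene_ids.difference(tumors.index)
    extra = tumors.index.difference(bank.gene_ids)
    if len(missing) or len(extra):
        parts = []
        if len(missing):
            parts.append(f"missing from tumors: {', '.join(map(str, missing[:10]))}")
        if len(extra):
            parts.append(f"absent from bank: {', '.join(map(str, extra[:10]))}")
        raise ValidationError("gene-set mismatch between tumors and bank; " + "; ".join(parts))
    x = tumors.loc[bank.gene_ids].to_numpy(float)
    nu = (x - bank.bank_mean[:, None]) / bank.bank_sd_smooth[:, None]
    out = pd.DataFrame(nu, index=bank.gene_ids, columns=tumors.columns)
    out.attrs["origin"] = "nu"
    return out


def dichotomize(nu: pd.DataFrame, threshold: float = 3.0) -> pd.DataFrame:
    """Binarize ν-scores: 1 when |ν| > threshold (above *or* below), else 0.

    The boundary |ν| == threshold counts as "within the normal range" (0).
    """
    if not threshold > 0:
        raise ValidationError("threshold must be > 0")
    calls = (nu.to_numpy(float).__abs__() > threshold).astype(np.int8)
    out = pd.DataFrame(calls, index=nu.index, columns=nu.columns)
    out.attrs["origin"] = "newmanized"
    return out


def newmanize_cohorts(
    matrix: pd.DataFrame,
    manifest: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, BankModel]]:
    """Newmanize every cohort's tumors against its own tissue bank.

    For each cohort in the manifest, fits the bank on that cohort's normal
    samples and standardizes that cohort's tumors; ν and binary matrices are
    column-concatenated across cohorts over the common gene set, preserving
    the tumor order of the input matrix.

    Returns ``(nu, calls, banks)`` with ``banks`` keyed by cohort.
    """
    config = config or RunConfig()
    split = align(matrix, manifest)
    nu_parts: list[pd.DataFrame] = []
    banks: dict[str, BankModel] = {}
    for cohort, part in split.items():
        if part.tumor.shape[1] == 0:
            continue
        if part.normal.shape[1] < 2:
            raise ValidationError(
                f"cohort {cohort!r} has {part.normal.shape[1]} normal sample(s); "
                "at least 2 are required to fit its bank"
            )
        bank = fit_bank(
            part.normal,
            span=config.loess_span,
            sd_floor=config.sd_floor,
            degree=config.loess_degree,
            log_scale=config.log_scale_fit,
        )
        banks[cohort] = bank
        nu_parts.append(newmanize(part.tumor, bank))
    if not nu_parts:
        raise ValidationError("no cohort contains tumor samples")
    nu = pd.concat(nu_parts, axis=1)
    # restore the original tumor column order of the input matrix
    tumor_order = [
        s for s in matrix.columns if manifest.loc[s, "status"] == "tumor"
    ]
    nu = nu.loc[:, tumor_order]
    nu.attrs["origin"] = "nu"
    calls = dichotomize(nu, config.threshold)
    return nu, calls, banks
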