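"""Descriptive phenotype statistics and the normality-suitability check.

Bulked-segregant mapping of a quantitative trait assumes the trait is
roughly normally distributed in the panel, so that the two tails are
genuinely extreme.  This module computes the per-year summary (max, min,
mean, sample SD, skewness, excess kurtosis) and flags a year as *suitable*
when both |skewness| and |excess kurtosis| are below 1.

Skewness and kurtosis use the adjusted Fisher–Pearson sample formulas
(bias-corrected G1 and G2, excess form); the uncorrected moment versions
are available via ``bias_corrected=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PhenotypeSummary", "summarize", "summarize_table", "read_phenotypes", "write_phenotypes"]


@dataclass(frozen=True)
class PhenotypeSummary:
    year: str
    max: float
    min: float
    mean: float
    sd: float
    kurtosis: float
    skewness: float
    suitable: bool


def summarize(
    values: Sequence[float], year: str, *, bias_corrected: bool = True
) -> PhenotypeSummary:
    """Summary statistics for one year's trait measurements.

    Requires at least 4 observations (sample kurtosis undefined below that)
    and a non-constant vector (skewness/kurtosis undefined at SD = 0).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError(f"need >= 4 observations for kurtosis, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant phenotype vector: skewness/kurtosis undefined")
    skew = float(stats.skew(x, bias=not bias_corrected))
    kurt = float(stats.kurtosis(x, fisher=True, bias=not bias_corrected))
    return PhenotypeSummary(
        year=str(year),
        max=float(x.max()),
        min=float(x.min()),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        kurtosis=kurt,
        skewness=skew,
        suitable=bool(abs(skew) < 1 and abs(kurt) < 1),
    )


def summarize_table(pheno: pd.DataFrame, *, bias_corrected: bool = True) -> pd.DataFrame:
    """Per-year summary of a long phenotype table (columns id, year, trait)."""
    rows = [
        summarize(g["trait"].to_numpy(), str(year), bias_corrected=bias_corrected)
        for year, g in pheno.groupby("year", sort=True)
    ]
    return pd.DataFrame([vars(s) for s in rows])


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"id", "year", "trait"} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
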