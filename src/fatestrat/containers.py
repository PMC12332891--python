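"""Core data containers shared across the pipeline.

The pipeline moves gene-by-sample matrices, survival tables and genomic
intervals between stages.  Containers here are thin, validated wrappers
around pandas objects: heavy lifting (linear algebra, model fits) is done
by the stage modules, while these classes guarantee the invariants every
stage relies on (unique names, consistent dimensions, declared layers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SurvivalTable",
    "RiskSignature",
    "PeakSet",
    "SegmentGrid",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with a declared layer.

    Parameters
    ----------
    values
        DataFrame indexed by gene name with sample names as columns.
    layer
        ``"raw"`` for count data (must be non-negative) or ``"normalised"``
        for library-size-scaled log values.
    sample_meta
        Optional per-sample metadata table indexed by sample name.
    """

    values: pd.DataFrame
    layer: str = "raw"
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.layer not in ("raw", "normalised"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene names")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample names")
        if self.layer == "raw" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw layer must be non-negative")
        if self.sample_meta is not None and not self.sample_meta.index.equals(
            self.values.columns
        ):
            self.sample_meta = self.sample_meta.reindex(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(
            self.values.loc[genes], layer=self.layer, sample_meta=self.sample_meta
        )


@dataclass
class SurvivalTable:
    """Per-sample follow-up: time-to-event, event indicator, covariates."""

    data: pd.DataFrame  # columns: time, event, plus optional covariates
    time_unit: str = "years"

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"survival table missing column {col!r}")
        if (self.data["time"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids")

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]

    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=["time", "event"])


@dataclass
class RiskSignature:
    """Ordered (gene, beta) pairs defining a linear risk score."""

    coefficients: list[tuple[str, float]]
    provenance: str = "fitted"  # "packaged" | "fitted"

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.coefficients]
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate genes in signature")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.coefficients]

    @property
    def betas(self) -> np.ndarray:
        return np.array([b for _, b in self.coefficients], dtype=float)

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.coefficients), name="beta")


@dataclass
class PeakSet:
    """Genomic intervals in 0-based half-open coordinates."""

    intervals: pd.DataFrame  # columns: chrom, start, end [, score]

    def __post_init__(self) -> None:
        df = self.intervals
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"peak table missing column {col!r}")
        if (df["start"] >= df["end"]).any():
            raise ValueError("peaks must satisfy start < end")
        if (df["start"] < 0).any():
            raise ValueError("peaks must satisfy start >= 0")

    def __len__(self) -> int:
        return len(self.intervals)

    def validate_bounds(self, chrom_sizes: dict[str, int]) -> None:
        df = self.intervals
        bad = sorted(set(df["chrom"]) - set(chrom_sizes))
        if bad:
            raise ValueError(f"peaks on undeclared chromosomes: {bad}")
        sizes = df["chrom"].map(chrom_sizes)
        if (df["end"] > sizes).any():
            raise ValueError("peaks extend past chromosome ends")


@dataclass
class SegmentGrid:
    """Evenly spaced per-chromosome segments with peak counts/densities.

    ``segments`` holds one row per segment with columns
    chrom, start, end, length, count, density; segments tile each
    chromosome exactly (no gaps, no overlaps).
    """

    segments: pd.DataFrame
    n_segments: int = 92
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def counts_for(self, chrom: str) -> np.ndarray:
        sub = self.segments[self.segments["chrom"] == chrom]
        return sub["count"].to_numpy()
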