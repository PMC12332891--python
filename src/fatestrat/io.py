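"""Readers and writers for the plain-text interchange formats.

Matrices travel as dense TSV or MatrixMarket (MTX + genes.tsv +
barcodes.tsv); survival, drug-response, chromosome-size and gene-locus
tables as TSV; marker panels as JSON; peaks as 0-based half-open BED;
ground truth as JSON.  Everything round-trips losslessly enough for the
CLI's byte-identical determinism contract.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import ExpressionMatrix, PeakSet, SurvivalTable
from .synth import GroundTruth

__all__ = [
    "read_expression",
    "write_expression",
    "read_survival",
    "write_survival",
    "read_panels",
    "read_chrom_sizes",
    "read_gene_loci",
    "write_bed",
    "write_truth",
]


def read_expression(path, layer: str = "raw") -> ExpressionMatrix:
    """Load a genes x samples matrix from TSV or an MTX triplet directory."""
    path = Path(path)
    if path.is_dir() or path.suffix == ".mtx":
        base = path if path.is_dir() else path.parent
        mtx = path if path.suffix == ".mtx" else base / "matrix.mtx"
        mat = spio.mmread(mtx).tocsr()
        genes = pd.read_csv(base / "genes.tsv", sep="\t", header=None)[0]
        samples = pd.read_csv(base / "barcodes.tsv", sep="\t", header=None)[0]
        values = pd.DataFrame(mat.toarray(), index=genes, columns=samples)
    else:
        values = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values, layer=layer)


def write_expression(expr: ExpressionMatrix, path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        out = expr.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.10g")
    elif fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(path / "matrix.mtx", sparse.csr_matrix(expr.values.to_numpy()))
        pd.Series(expr.genes).to_csv(
            path / "genes.tsv", sep="\t", header=False, index=False
        )
        pd.Series(expr.samples).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_survival(path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SurvivalTable(df)


def write_survival(surv: SurvivalTable, path) -> None:
    out = surv.data.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_panels(path) -> dict[str, list[str]]:
    with open(path) as fh:
        panels = json.load(fh)
    return {str(k): [str(g) for g in v] for k, v in panels.items()}


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def read_gene_loci(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"gene", "chrom", "position"}
    if not expected.issubset(df.columns):
        df = pd.read_csv(
            path, sep="\t", header=None, names=["gene", "chrom", "position"]
        )
    return df


def write_bed(peaks: PeakSet, path) -> None:
    peaks.intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def _jsonable(value):
    if isinstance(value, pd.Series):
        return value.to_dict()
    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value


def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        k: _jsonable(v) for k, v in vars(truth).items() if v is not None
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
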