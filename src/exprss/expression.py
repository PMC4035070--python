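"""TPM normalization, detection filtering, fold changes and replicate QC.

Tag counting yields one tag per transcript, so normalization needs no
transcript-length term: counts are simply scaled to tags per million (TPM)
against the sample's total assigned tags.  Sense and antisense layers share
one denominator because both come from the same sequencing pool.
Differential-expression testing itself is delegated to external
negative-binomial tools; this module exports rounded integer counts plus a
design table for them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tag_assignment import CountMatrix

__all__ = [
    "ExpressionMatrix",
    "DetectionResult",
    "compute_tpm",
    "detection_filter",
    "log2_fold_change",
    "replicate_correlation",
    "export_for_de",
]


class ExpressionMatrix:
    """Genes x samples TPM values with sense/antisense layers."""

    def __init__(self, df: pd.DataFrame, totals: dict[str, float]):
        self.df = df
        self.totals = totals

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns.get_level_values(0).unique())

    def layer(self, orientation: str) -> pd.DataFrame:
        return self.df.xs(orientation, axis=1, level=1)

    def to_tsv(self, path: str | Path) -> None:
        long = self.df.stack(level=1, future_stack=True).reset_index()
        long.columns = ["gene_id", "orientation", *self.samples]
        long.to_csv(path, sep="\t", index=False, float_format="%.4f")


def compute_tpm(counts: CountMatrix) -> ExpressionMatrix:
    """Scale counts to tags per million of each sample's assigned total.

    Both orientation layers are normalized against the same per-sample total,
    so each sample's TPM column (sense + antisense) sums to 1e6.
    """
    df = counts.df.copy()
    totals: dict[str, float] = {}
    for sample in counts.samples:
        total = float(df[sample].to_numpy().sum())
        if total <= 0:
            raise ValueError(f"sample {sample!r} has no assigned reads; cannot TPM-normalize")
        totals[sample] = total
        df[sample] = df[sample] / total * 1e6
    return ExpressionMatrix(df, totals)


@dataclass
class DetectionResult:
    """Detection call for one gene over a condition's replicates."""

    gene_id: str
    mean_tpm: float
    n_replicates_used: int
    detected: bool


def detection_filter(
    expr: ExpressionMatrix,
    samples: Sequence[str],
    min_tpm: float = 1.0,
    min_reps: int = 4,
    orientation: str = "sense",
    mode: str = "mean",
) -> list[DetectionResult]:
    """Flag genes expressed at >= ``min_tpm`` across >= ``min_reps`` replicates.

    ``mode="mean"`` requires the mean TPM over the replicates to reach the
    threshold (boundary inclusive); ``mode="each"`` requires every one of at
    least ``min_reps`` replicates to reach it individually.
    """
    if len(samples) < min_reps:
        raise ValueError(
            f"need at least {min_reps} replicates, got {len(samples)}"
        )
    if mode not in {"mean", "each"}:
        raise ValueError(f"unknown detection mode {mode!r}")
    layer = expr.layer(orientation)[list(samples)]
    results = []
    for gene_id, row in layer.iterrows():
        mean_tpm = float(row.mean())
        if mode == "mean":
            detected = mean_tpm >= min_tpm
        else:
            detected = int((row >= min_tpm).sum()) >= min_reps
        results.append(DetectionResult(gene_id, mean_tpm, len(samples), detected))
    return results


def log2_fold_change(
    control: pd.DataFrame | pd.Series,
    treatment: pd.DataFrame | pd.Series,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((mean treatment + pc) / (mean control + pc)).

    Inputs are genes x replicates frames (or precomputed per-gene means); the
    pseudocount (default 1 TPM) damps ratios of barely-detected genes.
    """
    mean_c = control.mean(axis=1) if isinstance(control, pd.DataFrame) else control
    mean_t = treatment.mean(axis=1) if isinstance(treatment, pd.DataFrame) else treatment
    mean_c, mean_t = mean_c.align(mean_t, join="inner")
    return np.log2((mean_t + pseudocount) / (mean_c + pseudocount))


def replicate_correlation(
    expr: ExpressionMatrix,
    samples: Sequence[str] | None = None,
    orientation: str = "sense",
) -> pd.DataFrame:
    """Pairwise Pearson correlation of log10(TPM + 1) between samples.

    The returned table is symmetric with unit diagonal; a zero-variance
    sample yields NaN entries (undefined correlation).
    """
    layer = expr.layer(orientation)
    if samples is not None:
        layer = layer[list(samples)]
    if layer.shape[1] < 2:
        raise ValueError("replicate correlation needs at least 2 samples")
    return np.log10(layer + 1.0).corr(method="pearson")


def export_for_de(
    counts: CountMatrix,
    design: Mapping[str, str],
    counts_path: str | Path,
    design_path: str | Path,
    orientation: str = "sense",
) -> None:
    """Write a rounded integer count table and condition design TSV.

    External negative-binomial differential-expression tools expect integer
    counts; fractional multi-gene weights are rounded here and only here.
    """
    layer = counts.layer(orientation)[list(design)]
    layer.round().astype(int).to_csv(counts_path, sep="\t", index_label="gene_id")
    with open(design_path, "w") as fh:
        fh.write("sample\tcondition\n")
        for sample, condition in design.items():
            fh.write(f"{sample}\t{condition}\n")
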