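"""TSV / TIFF readers and writers for the pipeline's tabular formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .annotation import ExpressionTable
from .clip import ClipPeakTable


def read_expression(values_path, samples_path) -> ExpressionTable:
    """Load a genes x samples RPKM TSV plus its sample sheet.

    The matrix TSV has gene_id as the first column; the sample sheet has
    columns sample_id, compartment, replicate and optionally condition.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    return ExpressionTable(values=values, samples=samples)


def write_expression(expr: ExpressionTable, values_path, samples_path) -> None:
    expr.values.rename_axis("gene_id").to_csv(values_path, sep="\t")
    expr.samples.rename_axis("sample_id").reset_index().to_csv(
        samples_path, sep="\t", index=False)


def read_features(path) -> pd.DataFrame:
    """Per-gene feature table (gene_id index)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_peaks(path, merge_tia: bool = True) -> ClipPeakTable:
    """Gene x RBP 3' UTR peak-count matrix."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    return ClipPeakTable.from_counts(counts, merge_tia=merge_tia)


def write_table(df: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    df.rename_axis(index_label).to_csv(path, sep="\t")


def read_image(path) -> np.ndarray:
    """Multichannel 2-D TIFF as a (C, H, W) float array."""
    arr = tifffile.imread(str(path)).astype(float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_image(image: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), np.asarray(image, np.float32))


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
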