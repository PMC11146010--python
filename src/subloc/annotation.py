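"""Per-gene annotation: membrane classification, canonical transcripts, expression gating.

Every downstream stage consumes the gene feature table built here.  Genes are
classified from UniProt-style signal-sequence / transmembrane-domain flags into
``membrane``, ``secretory`` and ``non_membrane``; one canonical transcript per
gene supplies the architecture features (mRNA length, CDS length, mean CDS exon
length, exon count), with the 3' UTR length taken from the longest annotated
3' UTR isoform; and an RPKM-based expression gate restricts the analysis to
expressed genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

COMPARTMENTS = ("TG", "ER", "CY")

MEMBRANE = "membrane"
SECRETORY = "secretory"
NON_MEMBRANE = "non_membrane"
MEMBRANE_CLASSES = (MEMBRANE, SECRETORY, NON_MEMBRANE)

#: Default RPKM threshold above which a gene counts as expressed.
EXPRESSION_RPKM_THRESHOLD = 3.0


class DuplicateGeneError(ValueError):
    """Raised when a gene identifier appears more than once in an input table."""

    def __init__(self, gene_ids):
        self.gene_ids = sorted(gene_ids)
        super().__init__(f"duplicate gene_ids: {', '.join(self.gene_ids[:10])}"
                         + ("..." if len(self.gene_ids) > 10 else ""))


@dataclass
class ExpressionTable:
    """Gene x sample RPKM matrix with per-sample compartment metadata.

    Parameters
    ----------
    values : DataFrame
        Non-negative RPKM values, indexed by gene_id, one column per sample.
    samples : DataFrame
        One row per sample with columns ``sample_id``, ``compartment``
        (TG/ER/CY), ``replicate`` (integer) and ``condition``
        (control/KO/whole_cell).  ``sample_id`` must match the columns of
        ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise DuplicateGeneError(dups)
        if "sample_id" in self.samples.columns:
            self.samples = self.samples.set_index("sample_id")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples sheet lacks metadata for: {sorted(missing)}")
        if "condition" not in self.samples.columns:
            self.samples = self.samples.assign(condition="control")
        bad = set(self.samples["compartment"]) - set(COMPARTMENTS)
        if bad:
            raise ValueError(f"unknown compartment labels: {sorted(bad)}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or (arr < 0).any():
            raise ValueError("RPKM values must be finite and >= 0")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def compartment_means(self, condition: str = "control") -> pd.DataFrame:
        """Mean RPKM per compartment (over replicates), genes x compartments."""
        meta = self.samples[self.samples["condition"] == condition]
        if meta.empty:
            raise ValueError(f"no samples with condition {condition!r}")
        out = {}
        for comp, rows in meta.groupby("compartment"):
            out[comp] = self.values[list(rows.index)].mean(axis=1)
        return pd.DataFrame(out)

    def compartments_present(self, condition: str = "control") -> set[str]:
        meta = self.samples[self.samples["condition"] == condition]
        return set(meta["compartment"])


def classify_membrane(features_raw: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene to membrane / secretory / non_membrane.

    A protein with a transmembrane domain is a membrane protein; one with a
    signal sequence but no transmembrane domain is secretory; everything else
    is non-membrane.  Missing flags are treated as False (absent annotation),
    which conservatively classifies such genes as non-membrane.

    Parameters
    ----------
    features_raw : DataFrame
        Indexed by gene_id (or with a ``gene_id`` column), with boolean
        columns ``has_signal_sequence`` and ``has_tm_domain``.

    Returns
    -------
    DataFrame
        The input with a ``membrane_class`` column added; class counts are
        available via ``result["membrane_class"].value_counts()``.
    """
    df = features_raw.copy()
    if "gene_id" in df.columns:
        df = df.set_index("gene_id")
    if df.index.has_duplicates:
        raise DuplicateGeneError(df.index[df.index.duplicated()].unique())
    for col in ("has_signal_sequence", "has_tm_domain"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
        n_missing = df[col].isna().sum()
        if n_missing:
            logger.info("%d genes with missing %s treated as False", n_missing, col)
        df[col] = df[col].astype("boolean").fillna(False).astype(bool)

    cls = np.where(df["has_tm_domain"], MEMBRANE,
                   np.where(df["has_signal_sequence"], SECRETORY, NON_MEMBRANE))
    df["membrane_class"] = pd.Categorical(cls, categories=MEMBRANE_CLASSES)
    counts = df["membrane_class"].value_counts()
    logger.info("membrane classification: %s", counts.to_dict())
    return df.sort_index()


def expression_gate(expr: ExpressionTable,
                    threshold: float = EXPRESSION_RPKM_THRESHOLD,
                    mode: str = "compartment_mean",
                    condition: str = "control") -> pd.Index:
    """Return genes that pass the expression gate.

    Parameters
    ----------
    threshold : float
        Minimum RPKM; genes at or above it are kept.
    mode : {"compartment_mean", "whole_cell"}
        ``compartment_mean`` (default) gates on the mean of the per-compartment
        replicate-mean RPKMs; ``whole_cell`` gates on the mean RPKM of
        whole-cell samples (condition ``whole_cell``).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if expr.values.empty:
        warnings.warn("empty expression table; gate returns no genes")
        return pd.Index([], name="gene_id")
    if mode == "compartment_mean":
        stat = expr.compartment_means(condition).mean(axis=1)
    elif mode == "whole_cell":
        meta = expr.samples[expr.samples["condition"] == "whole_cell"]
        if meta.empty:
            raise ValueError("no whole_cell samples for mode='whole_cell'")
        stat = expr.values[list(meta.index)].mean(axis=1)
    else:
        raise ValueError(f"unknown gating mode {mode!r}")
    return stat.index[stat >= threshold].sort_values()


def select_canonical_transcript(transcripts: pd.DataFrame) -> pd.DataFrame:
    """Pick one canonical transcript per gene and derive its features.

    mRNA-derived fields (mrna_length, cds_length, mean_cds_exon_length,
    exon_count) come from the transcript with the longest mRNA; ties break by
    lexicographically smallest transcript_id.  utr3_length is the longest
    annotated 3' UTR across all isoforms of the gene.  protein_length is
    cds_length / 3.

    Parameters
    ----------
    transcripts : DataFrame
        Columns gene_id, transcript_id, mrna_length, cds_length, exon_count,
        utr3_length, and optionally mean_cds_exon_length (computed as
        cds_length / exon_count when absent).
    """
    df = transcripts.copy()
    required = {"gene_id", "transcript_id", "mrna_length", "cds_length",
                "exon_count", "utr3_length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing transcript columns: {sorted(missing)}")
    if "mean_cds_exon_length" not in df.columns:
        df["mean_cds_exon_length"] = df["cds_length"] / df["exon_count"]

    empty = df["gene_id"].isna()
    if empty.any():
        logger.warning("dropping %d transcript rows without gene_id", empty.sum())
        df = df[~empty]

    # longest mRNA wins; ties by transcript_id
    df = df.sort_values(["gene_id", "mrna_length", "transcript_id"],
                        ascending=[True, False, True])
    canon = df.groupby("gene_id", sort=True).first()
    canon["utr3_length"] = df.groupby("gene_id")["utr3_length"].max()
    canon["protein_length"] = canon["cds_length"] / 3.0

    bad = canon["mrna_length"] < canon["cds_length"]
    if bad.any():
        raise ValueError(
            f"mrna_length < cds_length for genes: {list(canon.index[bad])[:10]}")
    return canon


def feature_contrasts(labels: pd.Series, values: pd.Series,
                      min_per_class: int = 2) -> dict:
    """Compare a per-gene feature across call classes with rank tests.

    Uses two-sided Mann-Whitney tests for each pair of classes and a
    Kruskal-Wallis omnibus test across all classes, plus per-class n and
    median.  Constant values across all genes yield p = 1 with a flag.

    Parameters
    ----------
    labels : Series
        Per-gene class label (e.g. compartment call), indexed by gene_id.
    values : Series
        Per-gene feature values, indexed by gene_id.

    Returns
    -------
    dict with keys ``per_class`` (DataFrame: n, median), ``pairwise``
    (DataFrame: class_a, class_b, statistic, p), ``omnibus_p`` and
    ``constant`` (bool flag).
    """
    common = labels.index.intersection(values.index)
    labels = labels.loc[common]
    values = values.loc[common].astype(float)
    groups = {cls: values[labels == cls].to_numpy()
              for cls in pd.unique(labels.dropna())}
    groups = {k: v for k, v in groups.items() if len(v) >= min_per_class}
    if len(groups) < 2:
        raise ValueError("need >= 2 classes with >= 2 genes each")

    per_class = pd.DataFrame(
        {cls: {"n": len(v), "median": float(np.median(v))}
         for cls, v in groups.items()}).T

    constant = bool(np.ptp(values.to_numpy()) == 0)
    rows = []
    for a, b in combinations(groups, 2):
        if constant:
            stat, p = np.nan, 1.0
        else:
            stat, p = stats.mannwhitneyu(groups[a], groups[b],
                                         alternative="two-sided")
        rows.append({"class_a": a, "class_b": b, "statistic": stat, "p": p})
    pairwise = pd.DataFrame(rows)
    if constant:
        warnings.warn("feature is constant across genes; p-values set to 1")
        omnibus_p = 1.0
    else:
        omnibus_p = float(stats.kruskal(*groups.values()).pvalue)
    return {"per_class": per_class, "pairwise": pairwise,
            "omnibus_p": omnibus_p, "constant": constant}


@dataclass
class GeneFeatures:
    """Canonical per-gene feature record."""

    gene_id: str
    membrane_class: str
    mrna_length: int
    cds_length: int
    mean_cds_exon_length: float
    exon_count: int
    utr3_length: int
    has_signal_sequence: bool = False
    has_tm_domain: bool = False
    protein_length: float = field(init=False)

    def __post_init__(self) -> None:
        if self.membrane_class not in MEMBRANE_CLASSES:
            raise ValueError(f"unknown membrane_class {self.membrane_class!r}")
        if self.mrna_length < self.cds_length:
            raise ValueError("mrna_length must be >= cds_length")
        self.protein_length = self.cds_length / 3.0
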