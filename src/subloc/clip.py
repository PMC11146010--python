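"""CLIP-derived RBP target calling on 3' UTR peak counts.

Per-RBP target sets come from a gene x RBP matrix of 3' UTR CLIP peak counts.
Two target definitions are used: the *median* rule (count strictly greater
than the RBP's median over the gene universe) for short-listing
compartment-informative RBPs, and the *stringent* top-third rule (top third of
genes with at least one peak, ranked by count) for the predominant-binding
partitions.  TIA1 and TIAL1 peaks are indistinguishable in CLIP data and are
merged into a single TIA1/L1 column by summing.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TIA_MERGED = "TIA1/L1"

#: The seven RBPs of the combinatorial localization code.
CODE_RBPS = ("TIS11B", "HuR", "PUM2", "HNRNPC", TIA_MERGED, "LARP4B", "METAP2")


@dataclass
class ClipPeakTable:
    """Gene x RBP matrix of non-negative integer 3' UTR peak counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("peak counts must be >= 0")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("peak counts must be integers")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene_ids in peak table")
        self.counts = self.counts.astype(int).sort_index()

    @classmethod
    def from_counts(cls, counts: pd.DataFrame,
                    merge_tia: bool = True) -> "ClipPeakTable":
        """Build a peak table, merging TIA1 + TIAL1 into TIA1/L1 if present."""
        counts = counts.copy()
        if merge_tia and {"TIA1", "TIAL1"} <= set(counts.columns):
            counts[TIA_MERGED] = counts["TIA1"] + counts["TIAL1"]
            counts = counts.drop(columns=["TIA1", "TIAL1"])
        return cls(counts)

    @property
    def rbp_names(self) -> list[str]:
        return list(self.counts.columns)

    def restrict(self, genes) -> "ClipPeakTable":
        idx = self.counts.index.intersection(pd.Index(genes))
        return ClipPeakTable(self.counts.loc[idx])


def median_targets(peaks: ClipPeakTable, universe=None) -> dict[str, set]:
    """Targets per RBP: genes whose peak count strictly exceeds the RBP median.

    The median is taken over the full gene universe (default: all genes in the
    table), so for sparse RBPs (median 0) any gene with a peak is a target,
    while for an all-equal column the target set is empty.
    """
    counts = peaks.counts if universe is None else peaks.restrict(universe).counts
    out = {}
    for rbp in counts.columns:
        col = counts[rbp]
        if (col == 0).all():
            warnings.warn(f"RBP {rbp!r} has no peaks; empty target set")
            out[rbp] = set()
            continue
        out[rbp] = set(col.index[col > col.median()])
    return out


def stringent_targets(peaks: ClipPeakTable, universe=None) -> dict[str, set]:
    """Stringent targets per RBP: top third of genes with >= 1 peak.

    Genes are ranked by (count descending, gene_id ascending) and the first
    ceil(n/3) are taken; with fewer than 3 peak-bearing genes all of them are
    returned with a warning.
    """
    counts = peaks.counts if universe is None else peaks.restrict(universe).counts
    out = {}
    for rbp in counts.columns:
        col = counts[rbp]
        col = col[col >= 1].sort_index()
        n = len(col)
        if n == 0:
            warnings.warn(f"RBP {rbp!r} has no peak-bearing genes")
            out[rbp] = set()
            continue
        if n < 3:
            warnings.warn(f"RBP {rbp!r} has only {n} peak-bearing genes; "
                          "returning all of them")
            out[rbp] = set(col.index)
            continue
        order = col.sort_values(ascending=False, kind="stable")
        out[rbp] = set(order.index[: math.ceil(n / 3)])
    return out


def shortlist_rbps(target_sets: dict[str, set], calls: pd.DataFrame,
                   ratio_cut: float = 1.5) -> pd.DataFrame:
    """Short-list RBPs whose targets are enriched in some compartment.

    For each RBP and compartment class the expected number of targets is
    |targets| times the fraction of the gene universe carrying that class
    label (computed from ``calls``, never hard-coded); the enrichment ratio is
    observed / expected and an RBP is short-listed when any class ratio
    exceeds ``ratio_cut``.

    Parameters
    ----------
    calls : DataFrame
        Non-membrane compartment calls with a ``label`` column (the universe
        over which target fractions are assessed).

    Returns
    -------
    DataFrame indexed by RBP with one ratio column per class, ``n_targets``,
    ``shortlisted`` and ``low_power`` (any expected count < 1).
    """
    labels = calls["label"]
    fractions = labels.value_counts(normalize=True)
    universe = set(calls.index)
    rows = {}
    for rbp, targets in target_sets.items():
        targets = targets & universe
        n = len(targets)
        row = {"n_targets": n, "low_power": False}
        best = 0.0
        target_labels = labels.loc[sorted(targets)].value_counts() if n else {}
        for cls, frac in fractions.items():
            expected = n * frac
            observed = int(target_labels.get(cls, 0)) if n else 0
            if expected == 0:
                ratio = np.nan
            else:
                ratio = observed / expected
                if expected < 1:
                    row["low_power"] = True
                best = max(best, ratio)
            row[f"ratio_{cls}"] = ratio
        row["shortlisted"] = bool(n > 0 and best > ratio_cut)
        if n == 0:
            warnings.warn(f"RBP {rbp!r} has no targets in the universe")
        rows[rbp] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.attrs["class_fractions"] = fractions.to_dict()
    out.attrs["ratio_cut"] = ratio_cut
    return out


def binding_partitions(stringent: dict[str, set], peaks: ClipPeakTable,
                       rbps: tuple[str, ...] = CODE_RBPS) -> dict[str, set]:
    """Predominant-binding partitions over the seven code RBPs.

    - ``larp4b_metap2_only``: stringent LARP4B or METAP2 targets bound by no
      other of the seven RBPs.
    - ``tis11b_predominant``: stringent TIS11B targets bound by none of the
      other six, or co-bound only by TIA1/L1 with peak-count ratio
      TIS11B / TIA1/L1 >= 2 (ratio +inf when the TIA1/L1 count is 0).
    - ``tia1l1_predominant``: the symmetric set with ratio < 2.

    "Bound by" uses membership in the stringent sets.  The three partitions
    are pairwise disjoint by construction (asserted).
    """
    missing = set(rbps) - set(stringent)
    if missing:
        raise ValueError(f"stringent sets missing for: {sorted(missing)}")
    sets = {r: stringent[r] for r in rbps}
    counts = peaks.counts

    def bound_by_others(gene: str, keep: set[str]) -> bool:
        return any(gene in sets[r] for r in rbps if r not in keep)

    larp = {g for g in (sets["LARP4B"] | sets["METAP2"])
            if not bound_by_others(g, {"LARP4B", "METAP2"})}

    def tis_tia_ratio(gene: str) -> float:
        tis = counts.at[gene, "TIS11B"] if gene in counts.index else 0
        tia = counts.at[gene, TIA_MERGED] if gene in counts.index else 0
        return np.inf if tia == 0 else tis / tia

    tis_pred, tia_pred = set(), set()
    for g in sets["TIS11B"]:
        others = {r for r in rbps if r not in ("TIS11B", TIA_MERGED)
                  and g in sets[r]}
        if others:
            continue
        if g not in sets[TIA_MERGED] or tis_tia_ratio(g) >= 2:
            tis_pred.add(g)
    for g in sets[TIA_MERGED]:
        others = {r for r in rbps if r not in ("TIS11B", TIA_MERGED)
                  and g in sets[r]}
        if others:
            continue
        if g not in sets["TIS11B"] or tis_tia_ratio(g) < 2:
            tia_pred.add(g)

    parts = {"larp4b_metap2_only": larp, "tis11b_predominant": tis_pred,
             "tia1l1_predominant": tia_pred}
    assert not (larp & tis_pred) and not (larp & tia_pred) \
        and not (tis_pred & tia_pred), "partitions must be disjoint"
    return parts
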