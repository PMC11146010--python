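"""Compartment localization scores, enrichment calls, and decay-rate estimates.

The localization score (LS) of a gene in a compartment is the fraction of its
cytoplasmic transcripts assigned to that compartment: the replicate-mean RPKM
in the compartment divided by the sum of the replicate-mean RPKMs over TG
granules, rough ER, and cytosol.  The three scores sum to 1.

Genes encoding non-membrane proteins are called compartment-enriched (TG+,
ER+, CY+) when their LS is at least ``fold`` (default 1.25) times the median
LS of that compartment over the gene universe; genes enriched in two
compartments go to the one with the higher LS, all others are ``unbiased``.

Genes encoding membrane or secretory proteins are called on the ER/TG score
ratio and the cytosolic score instead, because their strong ER association
makes the median-based rule uninformative.

Relative decay rates combine nuclear run-on (Pro-seq, a transcription-rate
proxy) with RNA-seq abundance: at steady state a high transcription-to-
abundance ratio implies fast decay.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .annotation import COMPARTMENTS, ExpressionTable

logger = logging.getLogger(__name__)

LS_COLUMNS = ("ls_tg", "ls_er", "ls_cy")

# non-membrane call labels
TG_PLUS = "TG_plus"
ER_PLUS = "ER_plus"
CY_PLUS = "CY_plus"
UNBIASED = "unbiased"
NONMEMBRANE_LABELS = (TG_PLUS, ER_PLUS, CY_PLUS, UNBIASED)

# membrane/secretory call labels
ER_ENR = "ER_enr"
TG_ENR = "TG_enr"
CY_ENR = "CY_enr"
NOT_LOCALIZED = "not_localized"
MEMBRANE_LABELS = (ER_ENR, TG_ENR, CY_ENR, NOT_LOCALIZED)

_LS_BY_COMP = dict(zip(COMPARTMENTS, LS_COLUMNS))
_PLUS_BY_COMP = {"TG": TG_PLUS, "ER": ER_PLUS, "CY": CY_PLUS}


def localization_scores(expr: ExpressionTable, genes=None,
                        condition: str = "control") -> pd.DataFrame:
    """Per-gene localization scores over the three compartments.

    LS_c = mean RPKM in compartment c / sum over compartments of mean RPKM.
    Genes with zero total cytoplasmic expression are dropped with a warning.

    Parameters
    ----------
    expr : ExpressionTable
        Must contain TG, ER and CY samples for ``condition``.
    genes : sequence of gene ids, optional
        Restrict to these genes (e.g. the expression-gated set).

    Returns
    -------
    DataFrame with columns ls_tg, ls_er, ls_cy, indexed by gene_id; each row
    sums to 1.
    """
    present = expr.compartments_present(condition)
    missing = set(COMPARTMENTS) - present
    if missing:
        raise ValueError(f"compartments missing from table: {sorted(missing)}")
    means = expr.compartment_means(condition)[list(COMPARTMENTS)]
    if genes is not None:
        means = means.loc[means.index.intersection(pd.Index(genes))]
    total = means.sum(axis=1)
    zero = total == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} genes with zero total "
                      "cytoplasmic expression")
        means, total = means[~zero], total[~zero]
    ls = means.div(total, axis=0)
    ls.columns = list(LS_COLUMNS)
    return ls.sort_index()


def classify_nonmembrane(profiles: pd.DataFrame, fold: float = 1.25,
                         medians: pd.Series | None = None) -> pd.DataFrame:
    """Call TG+/ER+/CY+/unbiased for non-membrane genes.

    A gene is enriched in a compartment when its LS is >= ``fold`` times the
    median LS of that compartment over the profile collection.  One passing
    compartment gives that label; two give the compartment with the higher LS;
    zero or (with skewed medians) all three give ``unbiased``.

    Parameters
    ----------
    profiles : DataFrame
        ls_tg/ls_er/ls_cy per gene.
    fold : float
        Enrichment fold over the compartment median (> 1).
    medians : Series, optional
        Pre-computed compartment medians (index ls_tg/ls_er/ls_cy); by default
        computed from ``profiles``.

    Returns
    -------
    DataFrame with the three LS columns, boolean pass_* evidence columns, a
    ``label`` column, and the thresholds in ``result.attrs["thresholds"]``.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if len(profiles) < 3 and medians is None:
        raise ValueError("need >= 3 profiles to compute compartment medians")
    ls = profiles[list(LS_COLUMNS)]
    if medians is None:
        medians = ls.median(axis=0)
    thresholds = fold * medians[list(LS_COLUMNS)]

    if float(ls.to_numpy().std()) < 1e-12:
        warnings.warn("degenerate (identical) profiles; all calls unbiased")

    passes = ls.ge(thresholds, axis=1)
    n_pass = passes.sum(axis=1)

    # label per gene: argmax LS among passing compartments, else unbiased;
    # triple enrichment (possible with skewed medians) maps to unbiased
    label = pd.Series(UNBIASED, index=ls.index, dtype=object)
    sel = (n_pass == 1) | (n_pass == 2)
    if sel.any():
        best = ls.where(passes).loc[sel].idxmax(axis=1)
        comp_of = {v: k for k, v in _LS_BY_COMP.items()}
        label[sel] = best.map(lambda c: _PLUS_BY_COMP[comp_of[c]])
    n_triple = int((n_pass == 3).sum())
    if n_triple:
        logger.info("%d genes enriched in all three compartments -> unbiased",
                    n_triple)

    out = ls.copy()
    out[["pass_tg", "pass_er", "pass_cy"]] = passes.to_numpy()
    out["label"] = pd.Categorical(label, categories=NONMEMBRANE_LABELS)
    out.attrs["thresholds"] = thresholds.to_dict()
    out.attrs["fold"] = fold
    return out


def classify_membrane(profiles: pd.DataFrame,
                      er_over_tg: float = 1.25,
                      tg_under: float = 0.8,
                      cy_enriched: float = 0.36,
                      cy_low: float = 0.18) -> pd.DataFrame:
    """Call ER/TG/CY enrichment for membrane and secretory genes.

    Precedence: (1) LS_cy > ``cy_enriched`` -> CY; (2) ER/TG ratio >
    ``er_over_tg`` -> ER; (3) ratio < ``tg_under`` -> TG; (4) ratio in
    [``tg_under``, ``er_over_tg``] ("similar") with LS_cy < ``cy_low`` -> ER;
    (5) otherwise not localized.  LS_tg == 0 makes the ratio +inf, so rule 2
    fires unless rule 1 already did.
    """
    ls = profiles[list(LS_COLUMNS)]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ls["ls_tg"].to_numpy() > 0,
                         ls["ls_er"].to_numpy() / ls["ls_tg"].to_numpy(),
                         np.inf)
    cy = ls["ls_cy"].to_numpy()
    label = np.full(len(ls), NOT_LOCALIZED, dtype=object)
    similar = (ratio >= tg_under) & (ratio <= er_over_tg)
    label[similar & (cy < cy_low)] = ER_ENR
    label[ratio < tg_under] = TG_ENR
    label[ratio > er_over_tg] = ER_ENR
    label[cy > cy_enriched] = CY_ENR

    out = ls.copy()
    out["er_tg_ratio"] = ratio
    out["label"] = pd.Categorical(label, categories=MEMBRANE_LABELS)
    out.attrs["thresholds"] = {"er_over_tg": er_over_tg, "tg_under": tg_under,
                               "cy_enriched": cy_enriched, "cy_low": cy_low}
    return out


def _log2_cpm(counts: pd.Series, pseudocount: float = 1.0) -> pd.Series:
    counts = counts.astype(float)
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    cpm = counts / counts.sum() * 1e6
    return np.log2(pseudocount + cpm)


def decay_scores(proseq: pd.Series, rnaseq: pd.Series) -> pd.DataFrame:
    """Relative mRNA decay rates from Pro-seq and RNA-seq counts.

    Each table is normalized to log2(1 + counts-per-million); the decay score
    is the Pro-seq value divided by the RNA-seq value, so a high score means
    high production relative to abundance, i.e. fast turnover.  Scores are
    invariant to library size.  Genes with zero normalized RNA-seq signal are
    dropped with a warning.

    Returns
    -------
    DataFrame with proseq_log2, rnaseq_log2, decay_score and half_life_rank
    (ascending decay_score rank: 1 = most stable).
    """
    common = proseq.index.intersection(rnaseq.index)
    if common.empty:
        raise ValueError("no shared genes between Pro-seq and RNA-seq tables")
    p = _log2_cpm(proseq.loc[common])
    r = _log2_cpm(rnaseq.loc[common])
    zero = r == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} genes with zero "
                      "log2-normalized RNA-seq signal")
        p, r = p[~zero], r[~zero]
    out = pd.DataFrame({"proseq_log2": p, "rnaseq_log2": r,
                        "decay_score": p / r})
    out["half_life_rank"] = out["decay_score"].rank(method="average")
    return out.sort_index()
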