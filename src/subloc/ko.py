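"""Localization shifts between knockout and control cells.

With the TG scaffold protein removed, only two compartments remain scoreable
(rough ER and cytosol), so each gene gets a two-compartment localization
score ls_er = ER / (ER + CY); the cytosolic score is its complement, so a
shift toward the ER of +x is identically a shift away from the cytosol of -x.
The per-gene shift is delta_er = ls_er(KO) - ls_er(control), computed over
genes whose average RPKM in the ER and cytosol samples exceeds an expression
threshold in both conditions.  The genes with the strongest shifts (top
quantile toward either side) are intersected with the TG+ set called in
wild-type cells.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

from .annotation import ExpressionTable

logger = logging.getLogger(__name__)

TOWARD_ER = "toward_ER"
TOWARD_CY = "toward_CY"
NO_CHANGE = "no_change"


def two_compartment_score(expr: ExpressionTable,
                          condition: str = "control") -> pd.Series:
    """ls_er = mean ER RPKM / (mean ER RPKM + mean CY RPKM) per gene."""
    means = expr.compartment_means(condition)
    for comp in ("ER", "CY"):
        if comp not in means.columns:
            raise ValueError(f"compartment {comp} missing")
    total = means["ER"] + means["CY"]
    ls = (means["ER"] / total).rename("ls_er")
    return ls[total > 0]


def ko_deltas(ctrl: ExpressionTable, ko: ExpressionTable,
              threshold: float = 3.0,
              ctrl_condition: str = "control",
              ko_condition: str = "control") -> pd.DataFrame:
    """Per-gene two-compartment localization shift, KO minus control.

    Genes must pass the expression gate (mean of the ER and CY compartment
    means > ``threshold``) in both conditions; genes missing from either
    table are excluded and logged.

    Returns
    -------
    DataFrame with ls_er_control, ls_er_ko, delta_er and shift_class
    (toward_ER / toward_CY / no_change by the sign of delta_er).
    """
    m_ctrl = ctrl.compartment_means(ctrl_condition)[["ER", "CY"]]
    m_ko = ko.compartment_means(ko_condition)[["ER", "CY"]]
    common = m_ctrl.index.intersection(m_ko.index)
    n_dropped = len(m_ctrl.index.symmetric_difference(m_ko.index))
    if n_dropped:
        logger.info("%d genes present in only one condition excluded", n_dropped)
    gate = (m_ctrl.loc[common].mean(axis=1) > threshold) & \
           (m_ko.loc[common].mean(axis=1) > threshold)
    common = common[gate]

    ls_ctrl = (m_ctrl["ER"] / m_ctrl.sum(axis=1)).loc[common]
    ls_ko = (m_ko["ER"] / m_ko.sum(axis=1)).loc[common]
    delta = ls_ko - ls_ctrl
    cls = np.where(delta > 0, TOWARD_ER, np.where(delta < 0, TOWARD_CY,
                                                  NO_CHANGE))
    return pd.DataFrame({"ls_er_control": ls_ctrl, "ls_er_ko": ls_ko,
                         "delta_er": delta, "shift_class": cls}).sort_index()


def top_shift_intersection(shifts: pd.DataFrame, tg_plus,
                           quantile: float = 0.20,
                           universe: str = "all") -> dict[str, set]:
    """Intersect the largest localization shifts with the TG+ gene set.

    The top ``quantile`` of genes by delta_er (descending) defines the
    ER-ward set and the top quantile by -delta_er the CY-ward set; each is
    intersected with ``tg_plus``, and the remaining TG+ genes form
    ``tg_no_change``.  Ties at the quantile boundary break by gene_id.

    Parameters
    ----------
    universe : {"all", "tg_only"}
        Rank shifts over all gated genes (default) or within TG+ only.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    if len(shifts) < 10:
        raise ValueError("too few genes for a meaningful quantile cut")
    tg_plus = set(tg_plus)
    ranked = shifts if universe == "all" else shifts.loc[
        shifts.index.intersection(pd.Index(sorted(tg_plus)))]
    if universe not in ("all", "tg_only"):
        raise ValueError(f"unknown universe {universe!r}")

    n_top = math.floor(quantile * len(ranked))
    if n_top == 0:
        warnings.warn("quantile cut selects zero genes")
    # sort by (delta desc, gene_id asc) for a deterministic boundary
    by_id = ranked.sort_index()
    order_er = by_id.sort_values("delta_er", ascending=False,
                                 kind="stable").index
    order_cy = by_id.sort_values("delta_er", ascending=True,
                                 kind="stable").index
    top_er = set(order_er[:n_top])
    top_cy = set(order_cy[:n_top])

    tg_to_er = tg_plus & top_er
    tg_to_cy = (tg_plus & top_cy) - tg_to_er
    tg_no_change = tg_plus - tg_to_er - tg_to_cy
    return {"tg_to_er": tg_to_er, "tg_to_cy": tg_to_cy,
            "tg_no_change": tg_no_change}
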