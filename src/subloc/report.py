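"""Headline arithmetic of the study's reported counts.

The published analysis reports class counts and cross-dataset overlaps as
integers; the percentages quoted alongside them are pure arithmetic on those
counts.  This module reproduces that arithmetic from printed inputs so the
derived shares are checkable, and computes the same summaries for any call
table the pipeline produces.
"""

from __future__ import annotations

import pandas as pd

from .localization import CY_PLUS, ER_PLUS, NONMEMBRANE_LABELS, TG_PLUS, UNBIASED

#: Published class counts for the non-membrane gene universe.
PUBLISHED_CLASS_COUNTS = {TG_PLUS: 1246, ER_PLUS: 919, CY_PLUS: 1481,
                          UNBIASED: 3369}

#: Published membrane-classification counts among expressed genes.
PUBLISHED_MEMBRANE_COUNTS = {"membrane_secretory": 2140, "non_membrane": 7015}

#: Published cross-dataset intersections: (ER+ hits, coexpressed total).
PUBLISHED_OVERLAPS = {
    "apex_seq": (673, 845),
    "biochemical_fractionation": (308, 385),
    "merfish_er_enriched": (511, 571),
    "merfish_er_deenriched": (8, 69),
}


def class_fractions(counts: dict[str, int], ndigits: int = 1) -> dict[str, float]:
    """Percentage of the universe in each class, rounded to ``ndigits``."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return {k: round(100.0 * v / total, ndigits) for k, v in counts.items()}


def enriched_share(counts: dict[str, int], ndigits: int = 0) -> float:
    """Percent of genes enriched in any compartment (everything but unbiased)."""
    total = sum(counts.values())
    enriched = total - counts.get(UNBIASED, 0)
    return round(100.0 * enriched / total, ndigits)


def expressed_total(membrane_counts: dict[str, int]) -> int:
    """Total expressed genes = membrane/secretory + non-membrane."""
    return sum(membrane_counts.values())


def overlap_fraction(hits: int, total: int, ndigits: int = 1) -> float:
    """Percent of a reference gene set recovered, from printed counts."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= hits <= total:
        raise ValueError("hits must lie in [0, total]")
    return round(100.0 * hits / total, ndigits)


def headline_numbers(class_counts: dict[str, int] | None = None,
                     membrane_counts: dict[str, int] | None = None,
                     overlaps: dict[str, tuple[int, int]] | None = None) -> dict:
    """All headline derived quantities from printed counts.

    Defaults to the published counts; pass pipeline-derived counts to get the
    same summaries for a new dataset.
    """
    class_counts = class_counts or PUBLISHED_CLASS_COUNTS
    membrane_counts = membrane_counts or PUBLISHED_MEMBRANE_COUNTS
    overlaps = overlaps or PUBLISHED_OVERLAPS
    out = {
        "expressed_total": expressed_total(membrane_counts),
        "enriched_share_pct": enriched_share(class_counts),
        "class_fraction_pct": class_fractions(class_counts),
    }
    ndig = {"merfish_er_deenriched": 1}
    out["overlap_pct"] = {name: overlap_fraction(h, t, ndig.get(name, 0))
                          for name, (h, t) in overlaps.items()}
    return out


def call_counts(calls: pd.DataFrame) -> dict[str, int]:
    """Class counts from a pipeline call table (label column)."""
    vc = calls["label"].value_counts()
    return {lab: int(vc.get(lab, 0)) for lab in NONMEMBRANE_LABELS}
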