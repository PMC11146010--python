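"""Synthetic data generators with recorded ground truth.

Every generator emulates one input of the fractionation-RNA-seq localization
study and records the planted truth, so the full pipeline can be exercised
and validated without any external download:

- :func:`simulate_expression` — replicate RPKM tables for the three
  compartments (TG granules, rough ER, cytosol) with planted per-gene
  compartment proportions and label composition matching the study
  (TG+ 17.8%, ER+ 13.1%, CY+ 21.1%, unbiased 48.0%).
- :func:`simulate_clip` — gene x RBP 3' UTR peak-count tables with
  class-dependent negative-binomial rates.
- :func:`simulate_code_dataset` — covariates plus labels drawn from a known
  multinomial-logit coefficient matrix, for parameter-recovery checks.
- :func:`simulate_ko` — paired control/knockout ER+cytosol tables where TG+
  genes redistribute their granule share, with the ER-vs-cytosol choice
  coupled to mRNA length.
- :func:`simulate_fish_field` — multichannel FISH fields (marker channels
  plus spot channel) over blob-shaped compartment masks with controlled
  colocalization fractions.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .annotation import ExpressionTable
from .clip import CODE_RBPS, ClipPeakTable
from .code import prepare_design
from .localization import CY_PLUS, ER_PLUS, TG_PLUS, UNBIASED

#: Class composition of the non-membrane gene universe in the study.
DEFAULT_LABEL_FRACTIONS = {TG_PLUS: 0.178, ER_PLUS: 0.131, CY_PLUS: 0.211,
                           UNBIASED: 0.480}

_LABEL_COMP = {TG_PLUS: "p_tg", ER_PLUS: "p_er", CY_PLUS: "p_cy"}


@dataclass
class SynthTruth:
    """Ground truth of a simulated gene universe."""

    genes: pd.DataFrame          # per-gene truth (label, proportions, features)
    params: dict = field(default_factory=dict)
    rbp_counts: pd.DataFrame | None = None
    ko_class: pd.Series | None = None

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index


def _architecture_features(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Plausible human mRNA architecture: CDS + UTRs, exon counts."""
    cds = 3 * np.maximum(60, rng.lognormal(np.log(430), 0.55, n)).astype(int)
    exon_count = 1 + rng.poisson(8.0, n)
    utr3 = np.maximum(20, rng.lognormal(np.log(800), 0.8, n)).astype(int)
    utr5 = np.maximum(10, rng.lognormal(np.log(150), 0.5, n)).astype(int)
    return pd.DataFrame({
        "mrna_length": cds + utr3 + utr5,
        "cds_length": cds,
        "mean_cds_exon_length": cds / exon_count,
        "exon_count": exon_count,
        "utr3_length": utr3,
        "membrane_class": "non_membrane",
    })


def _label_vector(n: int, fractions: dict, rng: np.random.Generator) -> np.ndarray:
    """Exact class composition (rounded counts), randomly permuted."""
    labels = list(fractions)
    counts = [int(round(fractions[l] * n)) for l in labels]
    counts[-1] = n - sum(counts[:-1])
    arr = np.repeat(labels, counts)
    return rng.permutation(arr)


def simulate_expression(n_genes: int = 2000, n_reps: int = 2,
                        enrichment_strength: float = 3.0,
                        noise_cv: float = 0.2,
                        label_fractions: dict | None = None,
                        dirichlet_alpha: float = 20.0,
                        abundance_median: float = 30.0,
                        abundance_sigma: float = 1.0,
                        seed: int = 0) -> tuple[ExpressionTable, SynthTruth]:
    """Replicate RPKM tables with planted compartment proportions.

    Unbiased genes draw their compartment proportions from a symmetric
    Dirichlet(``dirichlet_alpha``); enriched genes multiply the planted
    compartment's proportion by ``enrichment_strength`` and renormalize.
    Per-replicate RPKM = base abundance (log-normal) x proportion x
    multiplicative log-normal noise with coefficient of variation
    ``noise_cv``.
    """
    if n_genes < 100:
        raise ValueError("n_genes must be >= 100")
    if enrichment_strength < 1:
        raise ValueError("enrichment_strength must be >= 1")
    if dirichlet_alpha <= 0 or not 0 <= noise_cv:
        raise ValueError("invalid simplex/noise parameters")
    fractions = dict(label_fractions or DEFAULT_LABEL_FRACTIONS)
    rng = np.random.default_rng(seed)

    gene_ids = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id")
    labels = _label_vector(n_genes, fractions, rng)
    props = rng.dirichlet([dirichlet_alpha] * 3, size=n_genes)
    for j, lab in enumerate((TG_PLUS, ER_PLUS, CY_PLUS)):
        sel = labels == lab
        props[sel, j] *= enrichment_strength
    props /= props.sum(axis=1, keepdims=True)

    abundance = rng.lognormal(np.log(abundance_median), abundance_sigma,
                              n_genes)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))

    values, meta = {}, []
    for comp, j in (("TG", 0), ("ER", 1), ("CY", 2)):
        for rep in range(1, n_reps + 1):
            sid = f"{comp}_{rep}"
            noise = rng.lognormal(-sigma ** 2 / 2, sigma, n_genes) \
                if noise_cv > 0 else 1.0
            values[sid] = abundance * props[:, j] * noise
            meta.append({"sample_id": sid, "compartment": comp,
                         "replicate": rep, "condition": "control"})

    genes = _architecture_features(n_genes, rng)
    genes.index = gene_ids
    genes.insert(0, "true_label", labels)
    genes[["p_tg", "p_er", "p_cy"]] = props
    genes["abundance"] = abundance

    expr = ExpressionTable(values=pd.DataFrame(values, index=gene_ids),
                           samples=pd.DataFrame(meta))
    truth = SynthTruth(genes=genes, params={
        "seed": seed, "n_reps": n_reps, "noise_cv": noise_cv,
        "enrichment_strength": enrichment_strength,
        "dirichlet_alpha": dirichlet_alpha,
        "label_fractions": fractions})
    return expr, truth


def default_clip_effects() -> pd.DataFrame:
    """Class x RBP log-rate effects mirroring the study's qualitative code.

    TIS11B binding drives TG enrichment, TIA1/L1 (and HuR) ER enrichment,
    LARP4B/METAP2 cytosolic enrichment; PUM2 and HNRNPC carry weaker effects.
    """
    eff = pd.DataFrame(0.0, index=[TG_PLUS, ER_PLUS, CY_PLUS],
                       columns=list(CODE_RBPS))
    eff.loc[TG_PLUS, "TIS11B"] = 1.2
    eff.loc[TG_PLUS, "PUM2"] = 0.4
    eff.loc[ER_PLUS, "TIA1/L1"] = 1.0
    eff.loc[ER_PLUS, "HuR"] = 0.5
    eff.loc[CY_PLUS, "LARP4B"] = 1.0
    eff.loc[CY_PLUS, "METAP2"] = 0.8
    eff.loc[CY_PLUS, "HNRNPC"] = 0.4
    return eff


def simulate_clip(truth: SynthTruth,
                  effect_matrix: pd.DataFrame | None = None,
                  baseline_log_rate: float = 0.4,
                  dispersion: float = 5.0,
                  seed: int = 0) -> ClipPeakTable:
    """3' UTR peak counts per gene per RBP, negative-binomial.

    log mean count = ``baseline_log_rate`` + class effect +
    0.5 * log(utr3_length / 1 kb); counts are NB with size ``dispersion``
    (``np.inf`` gives Poisson).  Binding indicators (count > 0) are recorded
    on the truth object.
    """
    if effect_matrix is None:
        effect_matrix = default_clip_effects()
    missing = set(CODE_RBPS) - set(effect_matrix.columns)
    if missing:
        raise ValueError(f"effect matrix missing RBPs: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    genes = truth.genes
    utr_term = 0.5 * np.log(genes["utr3_length"].to_numpy() / 1000.0)

    counts = {}
    for rbp in effect_matrix.columns:
        cls_eff = genes["true_label"].map(
            lambda l: effect_matrix.at[l, rbp] if l in effect_matrix.index
            else 0.0).to_numpy()
        mu = np.exp(baseline_log_rate + cls_eff + utr_term)
        if np.isinf(dispersion):
            counts[rbp] = rng.poisson(mu)
        else:
            p = dispersion / (dispersion + mu)
            counts[rbp] = rng.negative_binomial(dispersion, p)
    table = pd.DataFrame(counts, index=genes.index)
    truth.rbp_counts = table
    truth.params.update({"clip_seed": seed, "dispersion": dispersion,
                         "baseline_log_rate": baseline_log_rate})
    return ClipPeakTable(table)


def default_code_coefficients(covariates: list[str],
                              label_fractions: dict | None = None
                              ) -> pd.DataFrame:
    """True multinomial-logit coefficients for :func:`simulate_code_dataset`.

    Standardized-scale effects: positive TIS11B -> TG, positive mRNA length
    -> ER, positive mean CDS exon length -> TG, LARP4B/METAP2 -> CY, negative
    mRNA length -> CY.  Intercepts reproduce the study's class composition at
    the covariate mean.
    """
    fractions = dict(label_fractions or DEFAULT_LABEL_FRACTIONS)
    coef = pd.DataFrame(0.0, index=[TG_PLUS, ER_PLUS, CY_PLUS],
                        columns=["intercept"] + list(covariates))
    for cls in coef.index:
        coef.at[cls, "intercept"] = np.log(fractions[cls]
                                           / fractions[UNBIASED])
    effects = {
        ("TIS11B", TG_PLUS): 0.8, ("PUM2", TG_PLUS): 0.3,
        ("TIA1/L1", ER_PLUS): 0.7, ("HuR", ER_PLUS): 0.3,
        ("LARP4B", CY_PLUS): 0.6, ("METAP2", CY_PLUS): 0.4,
        ("HNRNPC", CY_PLUS): 0.3,
        ("mrna_length", ER_PLUS): 0.6, ("mrna_length", CY_PLUS): -0.5,
        ("mean_cds_exon_length", TG_PLUS): 0.5,
        ("mean_cds_exon_length", CY_PLUS): -0.3,
    }
    for (cov, cls), val in effects.items():
        if cov in coef.columns:
            coef.at[cls, cov] = val
    return coef


def simulate_code_dataset(n_genes: int = 5000,
                          coef: pd.DataFrame | None = None,
                          covariate_set: str = "rbp_plus_architecture",
                          dispersion: float = 5.0,
                          seed: int = 0):
    """Labels drawn from a known multinomial-logit over realistic covariates.

    Raw RBP counts (NB) and architecture features are generated, prepared
    exactly as :func:`subloc.code.prepare_design` does, and labels are then
    sampled from the softmax of the true coefficient matrix applied to the
    standardized design.

    Returns
    -------
    (peaks, features, labels, design, true_coef)
    """
    rng = np.random.default_rng(seed)
    gene_ids = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id")
    features = _architecture_features(n_genes, rng)
    features.index = gene_ids

    utr_term = 0.5 * np.log(features["utr3_length"].to_numpy() / 1000.0)
    counts = {}
    for rbp in CODE_RBPS:
        mu = np.exp(0.4 + utr_term)
        p = dispersion / (dispersion + mu)
        counts[rbp] = rng.negative_binomial(dispersion, p)
    peaks = ClipPeakTable(pd.DataFrame(counts, index=gene_ids))

    design = prepare_design(peaks, features, covariate_set, genes=gene_ids)
    if coef is None:
        coef = default_code_coefficients(design.covariates)
    cols = ["intercept"] + design.covariates
    beta = coef[cols].to_numpy()                     # 3 x (1 + k)
    X1 = np.column_stack([np.ones(len(design.X)), design.X.to_numpy()])
    eta = X1 @ beta.T                                # n x 3 (vs unbiased)
    eta = np.column_stack([np.zeros(len(eta)), eta])  # base first
    prob = np.exp(eta - eta.max(axis=1, keepdims=True))
    prob /= prob.sum(axis=1, keepdims=True)
    classes = np.array([UNBIASED, TG_PLUS, ER_PLUS, CY_PLUS])
    u = rng.random(n_genes)
    idx = (prob.cumsum(axis=1) < u[:, None]).sum(axis=1)
    labels = pd.Series(classes[idx], index=gene_ids, name="label")
    return peaks, features, labels, design, coef[cols]


def simulate_ko(truth: SynthTruth, shift_magnitude: float = 0.8,
                architecture_coupling: float = 1.0,
                n_reps: int = 2, noise_cv: float = 0.1,
                seed: int = 0) -> tuple[ExpressionTable, ExpressionTable]:
    """Paired control / knockout ER+cytosol expression tables.

    In the knockout the TG compartment is gone: every gene's granule share
    is redistributed to ER and cytosol.  For genes not planted TG+ the share
    is split proportionally to their existing ER/CY shares, which leaves the
    two-compartment score unchanged in expectation.  Planted TG+ genes send a
    fraction ``shift_magnitude`` of their granule share entirely to one side,
    chosen ER-ward with probability sigmoid(``architecture_coupling`` *
    standardized log mRNA length) — long mRNAs drift to the ER, short ones to
    the cytosol.  The planted direction is recorded as ``truth.ko_class``.
    """
    rng = np.random.default_rng(seed)
    genes = truth.genes
    n = len(genes)
    p = genes[["p_tg", "p_er", "p_cy"]].to_numpy().copy()
    abundance = genes["abundance"].to_numpy()

    log_len = np.log(genes["mrna_length"].to_numpy(dtype=float))
    z_len = (log_len - log_len.mean()) / log_len.std()
    p_er_choice = 1.0 / (1.0 + np.exp(-architecture_coupling * z_len))

    is_tg = (genes["true_label"] == TG_PLUS).to_numpy()
    to_er = rng.random(n) < p_er_choice
    ko_class = np.where(is_tg & to_er, "to_ER",
                        np.where(is_tg, "to_CY", "none"))

    # knockout compartment shares over (ER, CY)
    er, cy, tg = p[:, 1], p[:, 2], p[:, 0]
    prop_er = np.where(er + cy > 0, er / (er + cy), 0.5)
    ko_er = er + tg * np.where(
        is_tg,
        shift_magnitude * to_er + (1 - shift_magnitude) * prop_er,
        prop_er)
    ko_cy = (er + cy + tg) - ko_er

    sigma = np.sqrt(np.log1p(noise_cv ** 2))

    def build(shares_er, shares_cy, condition_tag):
        values, meta = {}, []
        for comp, share in (("ER", shares_er), ("CY", shares_cy)):
            for rep in range(1, n_reps + 1):
                sid = f"{condition_tag}_{comp}_{rep}"
                noise = rng.lognormal(-sigma ** 2 / 2, sigma, n) \
                    if noise_cv > 0 else 1.0
                values[sid] = abundance * share * noise
                meta.append({"sample_id": sid, "compartment": comp,
                             "replicate": rep, "condition": "control"})
        return ExpressionTable(values=pd.DataFrame(values, index=genes.index),
                               samples=pd.DataFrame(meta))

    ctrl = build(er, cy, "ctrl")
    ko = build(ko_er, ko_cy, "ko")
    truth.ko_class = pd.Series(ko_class, index=genes.index, name="ko_class")
    truth.params.update({"ko_seed": seed, "shift_magnitude": shift_magnitude,
                         "architecture_coupling": architecture_coupling})
    return ctrl, ko


# --------------------------------------------------------------------------
# FISH field simulation

@dataclass
class FishFieldTruth:
    """Planted masks, foci and parameters of one synthetic FISH field."""

    cell_mask: np.ndarray
    tg_mask: np.ndarray
    er_mask: np.ndarray
    nuclear_mask: np.ndarray | None
    foci: np.ndarray              # planted (row, col) coordinates
    foci_compartment: np.ndarray  # "tg" / "er" / "cy" per planted focus
    params: dict


def _blob_mask(shape, inside, target_fraction, rng, smooth=6.0):
    """Smoothed-noise blob covering ``target_fraction`` of ``inside``."""
    if target_fraction <= 0:
        return np.zeros(shape, bool)
    fieldv = gaussian_filter(rng.standard_normal(shape), smooth)
    vals = fieldv[inside]
    thr = np.quantile(vals, 1.0 - target_fraction)
    return (fieldv > thr) & inside


def simulate_fish_field(f_tg: float = 0.11,
                        f_er: float = 0.29,
                        n_foci: int = 120,
                        coloc_fraction_tg: float | None = None,
                        coloc_fraction_er: float | None = None,
                        psf_sigma: float = 1.3,
                        noise_sd: float = 1.0,
                        spot_amplitude: float | None = None,
                        shape: tuple[int, int] = (256, 256),
                        nuclear_fraction: float = 0.0,
                        min_separation: float = 6.0,
                        seed: int = 0):
    """One synthetic multichannel FISH field with planted colocalization.

    Channels (C, H, W): 0 = TG marker, 1 = ER marker, 2 = FISH spots,
    3 = nuclear marker (only if ``nuclear_fraction`` > 0).  Compartment
    masks are smoothed random blobs hitting the requested area fractions of
    the cell (to within a pixel); foci compartments are multinomial with the
    requested colocalization fractions (defaults: the area fractions, i.e.
    the spatially unbiased null), positions uniform within the compartment,
    spots rendered as Gaussians of amplitude ``spot_amplitude`` (default
    10 x ``noise_sd``) over Gaussian background noise.
    """
    if f_tg + f_er > 1:
        raise ValueError("f_tg + f_er must be <= 1")
    rng = np.random.default_rng(seed)
    H, W = shape
    if spot_amplitude is None:
        spot_amplitude = 10.0 * noise_sd

    rr, cc = np.mgrid[0:H, 0:W]
    cy0, cx0 = (H - 1) / 2, (W - 1) / 2
    cell = ((rr - cy0) / (0.45 * H)) ** 2 + ((cc - cx0) / (0.45 * W)) ** 2 <= 1

    nuc = None
    if nuclear_fraction > 0:
        nuc = _blob_mask(shape, cell, nuclear_fraction, rng, smooth=10.0)

    tg = _blob_mask(shape, cell, f_tg, rng)
    # ER drawn from the non-TG part of the cell at a compensated fraction
    rest = cell & ~tg
    er_frac_rest = min(1.0, f_er * cell.sum() / max(rest.sum(), 1))
    er = _blob_mask(shape, rest, er_frac_rest, rng)
    cyto = cell & ~tg & ~er
    if nuc is not None:
        cyto = cyto & ~nuc

    p_tg = tg.sum() / cell.sum() if coloc_fraction_tg is None \
        else coloc_fraction_tg
    p_er = er.sum() / cell.sum() if coloc_fraction_er is None \
        else coloc_fraction_er
    if not (0 <= p_tg <= 1 and 0 <= p_er <= 1 and p_tg + p_er <= 1):
        raise ValueError("colocalization fractions must lie on the simplex")

    n_by_comp = rng.multinomial(n_foci, [p_tg, p_er, 1 - p_tg - p_er])
    # spots keep a minimum separation so every planted molecule resolves to
    # its own detected maximum (merged diffraction spots are not modelled)
    placed, comps = [], []
    for mask, n_c, tag in ((tg, n_by_comp[0], "tg"), (er, n_by_comp[1], "er"),
                           (cyto, n_by_comp[2], "cy")):
        pix = np.argwhere(mask)
        if n_c > 0 and len(pix) == 0:
            raise ValueError(f"cannot place foci in empty {tag} mask")
        n_placed = 0
        attempts = 0
        while n_placed < n_c:
            cand = pix[rng.integers(0, len(pix))]
            attempts += 1
            if attempts > 200 * n_c:
                raise ValueError(f"cannot place {n_c} separated foci in the "
                                 f"{tag} mask; lower n_foci or min_separation")
            if all((cand[0] - q[0]) ** 2 + (cand[1] - q[1]) ** 2
                   >= min_separation ** 2 for q in placed):
                placed.append(cand)
                comps.append(tag)
                n_placed += 1
    coords = np.array(placed, int).reshape(-1, 2)

    fishch = noise_sd * rng.standard_normal(shape) if noise_sd > 0 \
        else np.zeros(shape)
    half = int(np.ceil(4 * psf_sigma))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    kernel = spot_amplitude * np.exp(-(yy ** 2 + xx ** 2)
                                     / (2 * psf_sigma ** 2))
    for r, c in coords:
        r0, r1 = max(0, r - half), min(H, r + half + 1)
        c0, c1 = max(0, c - half), min(W, c + half + 1)
        fishch[r0:r1, c0:c1] += kernel[r0 - (r - half):r1 - (r - half),
                                       c0 - (c - half):c1 - (c - half)]

    marker_noise = 0.02
    chans = [100.0 * tg + marker_noise * rng.standard_normal(shape),
             100.0 * er + marker_noise * rng.standard_normal(shape),
             fishch]
    if nuc is not None:
        chans.append(100.0 * nuc + marker_noise * rng.standard_normal(shape))
    image = np.stack(chans)

    truth = FishFieldTruth(
        cell_mask=cell, tg_mask=tg, er_mask=er, nuclear_mask=nuc,
        foci=coords, foci_compartment=np.array(comps),
        params={"seed": seed, "f_tg": f_tg, "f_er": f_er, "n_foci": n_foci,
                "coloc_fraction_tg": p_tg, "coloc_fraction_er": p_er,
                "psf_sigma": psf_sigma, "noise_sd": noise_sd})
    return image, truth


def simulate_fish_cells(n_cells: int = 20, n_foci: int = 80,
                        f_tg: float = 0.11, f_er: float = 0.29,
                        size_concentration: float = 60.0,
                        coloc_fraction_tg: float | None = None,
                        coloc_fraction_er: float | None = None,
                        nuclear_fraction: float = 0.0,
                        shape: tuple[int, int] = (96, 96),
                        seed: int = 0) -> list:
    """A population of cells as mask+foci records, without image rendering.

    Compartment sizes vary across cells the way they do in real cell
    populations: each cell's TG and ER area fractions are Beta-distributed
    around ``f_tg`` / ``f_er`` with concentration ``size_concentration``
    (default gives a cell-to-cell SD of about 0.04 at a mean of 0.11).  Foci
    counts are Poisson around ``n_foci``; colocalization fractions default to
    each cell's own area fractions (the spatially unbiased null), or are
    fixed at ``coloc_fraction_tg`` / ``coloc_fraction_er``.

    Rendering and spot detection are bypassed, which makes this generator
    suitable for statistical calibration of the colocalization test.
    """
    from .fish import FishCellRecord

    rng = np.random.default_rng(seed)
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    cy0, cx0 = (H - 1) / 2, (W - 1) / 2
    cell = ((rr - cy0) / (0.45 * H)) ** 2 + ((cc - cx0) / (0.45 * W)) ** 2 <= 1

    k = size_concentration
    records = []
    for i in range(n_cells):
        ftg_c = rng.beta(f_tg * k, (1 - f_tg) * k)
        fer_c = rng.beta(f_er * k, (1 - f_er) * k)
        tg = _blob_mask(shape, cell, ftg_c, rng, smooth=4.0)
        rest = cell & ~tg
        er = _blob_mask(shape, rest,
                        min(1.0, fer_c * cell.sum() / max(rest.sum(), 1)),
                        rng, smooth=4.0)
        nuc = _blob_mask(shape, cell & ~tg & ~er, nuclear_fraction, rng,
                         smooth=6.0) if nuclear_fraction > 0 else None
        cyto = cell & ~tg & ~er
        if nuc is not None:
            cyto = cyto & ~nuc

        p_tg = tg.sum() / cell.sum() if coloc_fraction_tg is None \
            else coloc_fraction_tg
        p_er = er.sum() / cell.sum() if coloc_fraction_er is None \
            else coloc_fraction_er
        n_c = max(1, rng.poisson(n_foci))
        n_by = rng.multinomial(n_c, [p_tg, p_er, 1 - p_tg - p_er])
        coords = []
        for mask, n_m in ((tg, n_by[0]), (er, n_by[1]), (cyto, n_by[2])):
            pix = np.argwhere(mask)
            if n_m > 0:
                coords.append(pix[rng.integers(0, len(pix), n_m)])
        foci = np.vstack(coords) if coords else np.empty((0, 2), int)
        records.append(FishCellRecord(cell_id=f"cell{i:03d}", cell_mask=cell,
                                      tg_mask=tg, er_mask=er,
                                      nuclear_mask=nuc, foci=foci))
    return records


def fish_record_from_truth(truth: FishFieldTruth, cell_id: str = "cell"):
    """A FishCellRecord built from planted masks and foci (no imaging noise).

    Useful for fast statistical calibration of the colocalization test,
    bypassing rendering and detection.
    """
    from .fish import FishCellRecord

    return FishCellRecord(cell_id=cell_id, cell_mask=truth.cell_mask,
                          tg_mask=truth.tg_mask, er_mask=truth.er_mask,
                          nuclear_mask=truth.nuclear_mask, foci=truth.foci)
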