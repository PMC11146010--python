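"""The combinatorial localization code: a multinomial logistic model.

Compartment enrichment of non-membrane mRNAs (TG+/ER+/CY+ versus the
``unbiased`` base class) is modelled as a multinomial logit on 3' UTR RBP
binding (CLIP peak counts for the seven code RBPs) and mRNA architecture
(mRNA length, mean CDS exon length).  Covariates are sqrt-transformed and
then standardized; missing raw values are imputed as zero before the
transform.  The fitted coefficients are per-class log-odds (relative to
``unbiased``) per standard deviation of the sqrt-scale covariate, with Wald
standard errors and t-statistics from the observed information.

Usage follows the Model / Results convention::

    design = prepare_design(peaks, features, covariate_set="rbp_plus_architecture")
    model = LocalizationCode(design, calls["label"])
    res = model.fit()
    res.summary()
    res.propensity("TG_plus")
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .annotation import NON_MEMBRANE
from .clip import CODE_RBPS, ClipPeakTable
from .localization import NONMEMBRANE_LABELS, UNBIASED

logger = logging.getLogger(__name__)

ARCHITECTURE_COLUMNS = ("mrna_length", "mean_cds_exon_length")


@dataclass
class CodeDesignMatrix:
    """Standardized design matrix plus the transform state needed to reuse it.

    ``X`` holds the prepared covariates (sqrt then z-score, one column per
    covariate); ``transform_state`` records per column whether sqrt was
    applied and the centering mean / scaling SD on the sqrt scale, so the
    identical transform can be applied to new genes.
    """

    X: pd.DataFrame
    transform_state: pd.DataFrame
    dropped: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> pd.Index:
        return self.X.index

    @property
    def covariates(self) -> list[str]:
        return list(self.X.columns)

    def apply_to(self, raw: pd.DataFrame) -> pd.DataFrame:
        """Transform new raw covariate values with the stored state."""
        missing = set(self.covariates) - set(raw.columns)
        if missing:
            raise ValueError(f"missing covariate columns: {sorted(missing)}")
        out = {}
        for col in self.covariates:
            st = self.transform_state.loc[col]
            x = raw[col].fillna(0.0).astype(float)
            if st["sqrt"]:
                x = np.sqrt(x)
            out[col] = (x - st["mean"]) / st["sd"]
        return pd.DataFrame(out, index=raw.index)


def prepare_design(peaks: ClipPeakTable, features: pd.DataFrame,
                   covariate_set: str = "rbp_plus_architecture",
                   rbps: tuple[str, ...] = CODE_RBPS,
                   genes=None) -> CodeDesignMatrix:
    """Build the sqrt-then-standardized design matrix.

    Parameters
    ----------
    peaks : ClipPeakTable
        3' UTR peak counts; missing genes contribute zero counts.
    features : DataFrame
        Per-gene architecture table with mrna_length and mean_cds_exon_length
        (used only for ``rbp_plus_architecture``).
    covariate_set : {"rbp_only", "rbp_plus_architecture"}
    genes : sequence, optional
        Gene universe (default: the non-membrane genes of ``features`` if a
        membrane_class column is present, else all feature genes).

    Zero-variance columns are dropped with a warning and recorded in
    ``dropped``.
    """
    if covariate_set not in ("rbp_only", "rbp_plus_architecture"):
        raise ValueError(f"unknown covariate_set {covariate_set!r}")
    if genes is None:
        if "membrane_class" in features.columns:
            genes = features.index[features["membrane_class"] == NON_MEMBRANE]
        else:
            genes = features.index
    genes = pd.Index(genes)

    raw = peaks.counts.reindex(index=genes, columns=list(rbps)).astype(float)
    if covariate_set == "rbp_plus_architecture":
        arch = features.reindex(genes)[list(ARCHITECTURE_COLUMNS)].astype(float)
        raw = pd.concat([raw, arch], axis=1)
    raw = raw.fillna(0.0)  # missing values imputed as zeros before sqrt

    X, state, dropped = {}, {}, []
    for col in raw.columns:
        x = np.sqrt(raw[col])
        sd = float(x.std(ddof=0))
        if sd == 0:
            warnings.warn(f"covariate {col!r} has zero variance; dropped")
            dropped.append(col)
            continue
        mean = float(x.mean())
        X[col] = (x - mean) / sd
        state[col] = {"sqrt": True, "mean": mean, "sd": sd}
    return CodeDesignMatrix(X=pd.DataFrame(X, index=genes),
                            transform_state=pd.DataFrame(state).T,
                            dropped=dropped)


class LocalizationCode:
    """Multinomial logit of compartment label on the prepared covariates.

    Parameters
    ----------
    design : CodeDesignMatrix
    labels : Series
        Per-gene label in {TG_plus, ER_plus, CY_plus, unbiased}, indexed by
        gene_id; ``base`` (default ``unbiased``) is the reference class whose
        coefficients are fixed at zero.
    min_per_class : int
        Minimum genes required in every class.
    """

    def __init__(self, design: CodeDesignMatrix, labels: pd.Series,
                 base: str = UNBIASED, min_per_class: int = 20):
        common = design.gene_ids.intersection(labels.index)
        self.design = design
        self.X = design.X.loc[common]
        self.labels = labels.loc[common].astype(str)
        self.base = base
        classes = sorted(set(self.labels))
        if base not in classes:
            raise ValueError(f"base class {base!r} absent from labels")
        counts = self.labels.value_counts()
        thin = counts[counts < min_per_class]
        if len(thin):
            raise ValueError(f"classes with < {min_per_class} genes: "
                             f"{thin.to_dict()}")
        # base first so its coefficients are the fixed zero block
        self.classes = [base] + [c for c in NONMEMBRANE_LABELS if c in classes
                                 and c != base] \
            + [c for c in classes if c not in NONMEMBRANE_LABELS and c != base]

    @classmethod
    def from_tables(cls, peaks: ClipPeakTable, features: pd.DataFrame,
                    calls: pd.DataFrame,
                    covariate_set: str = "rbp_plus_architecture",
                    **kwargs) -> "LocalizationCode":
        design = prepare_design(peaks, features, covariate_set,
                                genes=calls.index)
        return cls(design, calls["label"], **kwargs)

    def fit(self, maxiter: int = 200, tol: float = 1e-8,
            method: str = "newton") -> "LocalizationCodeResults":
        """Maximum-likelihood fit; Wald SEs from the observed information.

        Newton iterations with log-likelihood based convergence; falls back
        to L-BFGS if the information matrix is ill-conditioned.
        """
        endog = pd.Categorical(self.labels, categories=self.classes).codes
        exog = sm.add_constant(self.X.to_numpy(), prepend=True)
        model = sm.MNLogit(endog, exog)
        opts = {"tol": tol} if method == "newton" else {"gtol": tol}
        try:
            res = model.fit(method=method, maxiter=maxiter, disp=False, **opts)
            if not res.mle_retvals.get("converged", True):
                raise np.linalg.LinAlgError("newton did not converge")
        except np.linalg.LinAlgError:
            warnings.warn("Newton fit failed (ill-conditioned information); "
                          "falling back to lbfgs")
            res = model.fit(method="lbfgs", maxiter=10 * maxiter, disp=False)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError(
                "multinomial fit did not converge; a covariate may "
                "perfectly separate a class")
        return LocalizationCodeResults(self, res)


class LocalizationCodeResults:
    """Fitted combinatorial-code coefficients and inference.

    Attributes
    ----------
    params, bse, tvalues : DataFrame
        class x covariate (plus ``intercept``); the base class is omitted
        (its coefficients are identically zero).
    """

    def __init__(self, model: LocalizationCode, smresults):
        self.model = model
        self._res = smresults
        names = ["intercept"] + model.design.covariates
        nonbase = model.classes[1:]
        self.params = pd.DataFrame(smresults.params.T, index=nonbase,
                                   columns=names)
        self.bse = pd.DataFrame(np.asarray(smresults.bse).T, index=nonbase,
                                columns=names)
        self.tvalues = self.params / self.bse
        self.llf = float(smresults.llf)
        self.converged = bool(smresults.mle_retvals.get("converged", True))

    @property
    def classes(self) -> list[str]:
        return self.model.classes

    def predict_proba(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        """Per-gene class probabilities (columns ordered base first)."""
        X = self.model.X if X is None else X[self.model.design.covariates]
        exog = sm.add_constant(X.to_numpy(), prepend=True, has_constant="add")
        proba = self._res.model.predict(self._res.params, exog)
        return pd.DataFrame(proba, index=X.index, columns=self.classes)

    def propensity(self, compartment: str,
                   X: pd.DataFrame | None = None) -> pd.Series:
        """Linear predictor: log-odds of ``compartment`` versus the base class.

        A gene at the covariate mean (all-zero standardized row) has
        propensity equal to the class intercept.
        """
        if compartment not in self.params.index:
            raise ValueError(f"unknown class {compartment!r}; choose from "
                             f"{list(self.params.index)}")
        X = self.model.X if X is None else X
        missing = set(self.model.design.covariates) - set(X.columns)
        if missing:
            raise ValueError(f"missing covariate columns: {sorted(missing)}")
        beta = self.params.loc[compartment]
        lin = beta["intercept"] + X[self.model.design.covariates].to_numpy() \
            @ beta[self.model.design.covariates].to_numpy()
        return pd.Series(lin, index=X.index, name=f"propensity_{compartment}")

    def top_covariates(self, k: int = 7, exclude=ARCHITECTURE_COLUMNS) -> list[str]:
        """The k covariates with the largest maximum |t| across classes."""
        t = self.tvalues.drop(columns="intercept").abs().max(axis=0)
        t = t.drop(index=[c for c in exclude if c in t.index])
        return list(t.sort_values(ascending=False).index[:k])

    def coefficient_table(self) -> pd.DataFrame:
        """Long-form (class, covariate, estimate, se, t) table."""
        rows = []
        for cls in self.params.index:
            for cov in self.params.columns:
                rows.append({"class": cls, "covariate": cov,
                             "estimate": self.params.at[cls, cov],
                             "se": self.bse.at[cls, cov],
                             "t": self.tvalues.at[cls, cov]})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable coefficient summary."""
        lines = [
            "Combinatorial localization code (multinomial logit)",
            f"  n genes: {len(self.model.X)}   log-likelihood: {self.llf:.2f}",
            f"  base class: {self.model.base}",
            "",
        ]
        tab = self.coefficient_table()
        tab["estimate"] = tab["estimate"].map("{:+.4f}".format)
        tab["se"] = tab["se"].map("{:.4f}".format)
        tab["t"] = tab["t"].map("{:+.2f}".format)
        lines.append(tab.to_string(index=False))
        return "\n".join(lines)

    def plot_coefficients(self, ax=None):
        """Dot plot of per-class coefficients with +-2 SE bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        covs = [c for c in self.params.columns if c != "intercept"]
        xs = np.arange(len(covs))
        for i, cls in enumerate(self.params.index):
            est = self.params.loc[cls, covs]
            err = 2 * self.bse.loc[cls, covs]
            ax.errorbar(xs + 0.15 * i, est, yerr=err, fmt="o", label=cls)
        ax.axhline(0, color="grey", lw=0.8)
        ax.set_xticks(xs + 0.15, covs, rotation=45, ha="right")
        ax.set_ylabel(f"log-odds vs {self.model.base}")
        ax.legend()
        return ax
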