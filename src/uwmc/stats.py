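"""Statistical pipeline linking UWMC to cognition.

Stages, in analysis order:

1. ``log_transform`` — natural log with the 0 -> 0.05 substitution (UWMC
   fractions and physical-activity hours both contain exact zeros).
2. ``stability_select`` — resampling elastic-net data reduction: 120
   refits, each on a fresh random 90% of participants, penalty chosen by
   cross-validated MSE, demographic/vascular covariates forced in
   unpenalised; a feature survives when it is selected (nonzero
   coefficient) in at least 90% of refits.
3. ``huber_regression`` — one robust linear model (Huber M-estimator,
   tuning constant 1.345, MAD scale) per surviving feature: MoCA on the
   log feature plus covariates, in the full sample and stratified by
   racialized group.  A coefficient divided by 100 is the MoCA difference
   per 1% greater UWMC (natural-log small-change approximation).
4. ``bh_fdr`` — Benjamini–Hochberg step-up at 5% within each analysis
   column; ``conditional_interaction`` fits a group-by-feature interaction
   only when exactly one stratum's test survived FDR.

``CognitionAnalysis`` packages stages 2-4 as a model object whose
``fit()`` returns an ``AnalysisResults`` with a table shaped like the
field's association tables.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_COVARIATES",
    "SelectionConfig",
    "SelectionResult",
    "RegressionResult",
    "FdrDecision",
    "log_transform",
    "stability_select",
    "huber_regression",
    "per_percent_effect",
    "bh_fdr",
    "conditional_interaction",
    "spearman_validation",
    "describe_groups",
    "median_split",
    "CognitionAnalysis",
    "AnalysisResults",
    "load_reference_associations",
]

#: forced covariates: the confounder set adjusted for in every model.
#: ``group`` (racialized group, 1 = Black American) enters full-sample
#: models only, never stratified ones.
DEFAULT_COVARIATES = (
    "age",
    "sex",
    "group",
    "education",
    "physical_activity",
    "diabetes",
    "hypertension",
    "high_cholesterol",
    "apoe4",
)

HUBER_T = 1.345  # 95% Gaussian efficiency


def log_transform(x, zero_substitute: float = 0.05):
    """Natural log of x, with exact zeros replaced by ``zero_substitute``.

    Accepts scalars or arrays; negative input is an error.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log_transform requires non-negative input")
    out = np.log(np.where(arr == 0, zero_substitute, arr))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def per_percent_effect(beta: float) -> float:
    """MoCA-point difference per 1% greater UWMC: beta / 100.

    Valid because features enter the models on the natural-log scale, where
    beta * ln(1.01) ~= beta / 100.
    """
    return beta / 100.0


# ---------------------------------------------------------------------------
# Stability selection
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SelectionConfig:
    """Resampling elastic-net settings.

    n_reps=120, holdout_fraction=0.10 and frequency_threshold=0.90 are the
    protocol constants; the mixing parameter and fold count are analysis
    defaults (0.9, 10 — see docs/methods.md for why the mixing leans
    lasso-ward).  ``n_alphas``/``alpha_eps`` control the resolution of the
    penalty path searched by cross-validation; the penalty applied is the
    largest one within one standard error of the CV-minimum MSE (the 1-SE
    rule), which keeps the per-repetition fits sparse enough for the
    selection frequencies to separate signal from noise.
    """

    n_reps: int = 120
    holdout_fraction: float = 0.10
    frequency_threshold: float = 0.90
    enet_mixing: float = 0.9
    cv_folds: int = 10
    master_seed: int = 0
    n_alphas: int = 40
    alpha_eps: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0,1)")
        if not 0 < self.frequency_threshold <= 1:
            raise ValueError("frequency_threshold must be in (0,1]")
        if not 0 < self.enet_mixing <= 1:
            raise ValueError("enet_mixing must be in (0,1]")


@dataclasses.dataclass
class SelectionResult:
    frequency: dict[str, float]
    selected: list[str]
    n_reps: int


def _covariate_design(df: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    Z = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in covariates]
    )
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("singular covariate matrix (collinear confounders)")
    return Z


def stability_select(
    cohort: pd.DataFrame,
    candidate_features: Sequence[str],
    cfg: SelectionConfig | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    outcome: str = "moca",
) -> SelectionResult:
    """Resampling elastic-net feature selection with forced covariates.

    For each repetition a fresh simple random 90% subsample is drawn
    (seeded ``master_seed + rep``), candidate features are standardised on
    that subsample, and an elastic net of the outcome on the features is
    fitted with the covariates forced in unpenalised; the penalty is chosen
    by k-fold cross-validated MSE.  Covariates stay unpenalised via exact
    partialling-out: minimising ||y - Z g - X b||^2 + pen(b) over the
    unpenalised g is equivalent to the elastic net of the Z-residualised
    outcome on the Z-residualised features.

    A feature counts as chosen in a rep iff its coefficient is nonzero;
    frequencies are chosen-rep fractions and the selected set is the
    features at or above the frequency threshold.
    """
    cfg = cfg or SelectionConfig()
    feats = list(candidate_features)
    X_full = cohort[feats].to_numpy(dtype=float)
    keep = X_full.std(axis=0) > 0
    if not keep.all():
        dropped = [f for f, k in zip(feats, keep) if not k]
        warnings.warn(f"excluding constant features: {dropped}", RuntimeWarning)
        feats = [f for f, k in zip(feats, keep) if k]
        X_full = X_full[:, keep]
    y_full = cohort[outcome].to_numpy(dtype=float)
    Z_full = _covariate_design(cohort, covariates)

    n = len(cohort)
    n_train = int(round((1 - cfg.holdout_fraction) * n))
    if n_train <= cfg.cv_folds:
        raise ValueError("too few participants for the requested CV folds")

    chosen = np.zeros(len(feats), dtype=int)
    for rep in range(cfg.n_reps):
        rng = np.random.default_rng(cfg.master_seed + rep)
        idx = rng.choice(n, size=n_train, replace=False)
        X = X_full[idx]
        y = y_full[idx]
        Z = Z_full[idx]
        # standardise features on the training subsample
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        # partial covariates out of outcome and features (exact, see docstring)
        coef_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
        coef_X, *_ = np.linalg.lstsq(Z, Xs, rcond=None)
        y_res = y - Z @ coef_y
        X_res = Xs - Z @ coef_X
        cv = KFold(cfg.cv_folds, shuffle=True, random_state=(cfg.master_seed + rep) % (2**32))
        path = ElasticNetCV(
            l1_ratio=cfg.enet_mixing,
            alphas=cfg.n_alphas,
            eps=cfg.alpha_eps,
            cv=cv,
            fit_intercept=False,
            max_iter=5000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            path.fit(X_res, y_res)
            # 1-SE rule: largest penalty within one standard error of the
            # CV-minimum mean squared error (alphas_ is descending)
            mean_mse = path.mse_path_.mean(axis=1)
            se = path.mse_path_.std(axis=1, ddof=1) / np.sqrt(path.mse_path_.shape[1])
            imin = int(mean_mse.argmin())
            i1se = int(np.nonzero(mean_mse <= mean_mse[imin] + se[imin])[0][0])
            model = ElasticNet(
                alpha=float(path.alphas_[i1se]),
                l1_ratio=cfg.enet_mixing,
                fit_intercept=False,
                max_iter=5000,
            )
            model.fit(X_res, y_res)
        chosen += model.coef_ != 0

    frequency = {f: c / cfg.n_reps for f, c in zip(feats, chosen)}
    selected = [f for f in feats if frequency[f] >= cfg.frequency_threshold]
    return SelectionResult(frequency=frequency, selected=selected, n_reps=cfg.n_reps)


# ---------------------------------------------------------------------------
# Robust regression
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RegressionResult:
    beta: float
    se: float
    p: float
    n: int
    stratum: str  # full | BA | nHW | interaction
    per_percent: float = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        self.per_percent = per_percent_effect(self.beta)


def huber_regression(
    cohort: pd.DataFrame,
    predictor: str,
    stratum: str = "full",
    with_interaction: bool = False,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    outcome: str = "moca",
) -> RegressionResult:
    """Huber M robust regression of MoCA on one (log-scale) predictor.

    ``stratum`` restricts to one racialized group ('BA': group==1,
    'nHW': group==0) and drops the group covariate; ``with_interaction``
    (full sample only) adds group x predictor and reports that term.
    Estimation is IRLS with Huber psi (c=1.345) and MAD scale re-estimated
    each iteration; p-values use the large-sample normal approximation on
    the robust SE.
    """
    covs = list(covariates)
    df = cohort
    if stratum == "BA":
        df = cohort[cohort["group"] == 1]
        covs = [c for c in covs if c != "group"]
    elif stratum == "nHW":
        df = cohort[cohort["group"] == 0]
        covs = [c for c in covs if c != "group"]
    elif stratum != "full":
        raise ValueError("stratum must be 'full', 'BA' or 'nHW'")
    if with_interaction and stratum != "full":
        raise ValueError("interaction models are full-sample only")

    n = len(df)
    if n < len(covs) + 3:
        raise ValueError(f"stratum {stratum!r} has too few participants (n={n})")

    x = df[predictor].to_numpy(dtype=float)
    cols = [x] + [df[c].to_numpy(dtype=float) for c in covs]
    names = [predictor] + covs
    if with_interaction:
        cols.append(df["group"].to_numpy(dtype=float) * x)
        names.append(f"group:{predictor}")
    X = sm.add_constant(np.column_stack(cols), prepend=True)
    y = df[outcome].to_numpy(dtype=float)

    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=HUBER_T))
    fit = model.fit(scale_est="mad", conv="coefs", tol=1e-8, maxiter=200)
    term = names.index(f"group:{predictor}") + 1 if with_interaction else 1
    return RegressionResult(
        beta=float(fit.params[term]),
        se=float(fit.bse[term]),
        p=float(fit.pvalues[term]),
        n=n,
        stratum="interaction" if with_interaction else stratum,
    )


# ---------------------------------------------------------------------------
# FDR and the conditional interaction rule
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FdrDecision:
    q: float
    rejected: set
    adjusted_p: dict

    def is_rejected(self, test_id) -> bool:
        return test_id in self.rejected


def bh_fdr(pvalues: Mapping, q: float = 0.05) -> FdrDecision:
    """Benjamini–Hochberg step-up over one family of tests.

    Sort ascending, find the largest k with p_(k) <= k q / m, reject the k
    smallest; adjusted p-values use the standard monotone formula.
    """
    ids = list(pvalues.keys())
    if not ids:
        return FdrDecision(q=q, rejected=set(), adjusted_p={})
    p = np.array([pvalues[i] for i in ids], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return FdrDecision(
        q=q,
        rejected={i for i, r in zip(ids, reject) if r},
        adjusted_p={i: float(a) for i, a in zip(ids, p_adj)},
    )


def conditional_interaction(
    full: pd.DataFrame,
    predictor: str,
    fdr_ba: FdrDecision,
    fdr_nhw: FdrDecision,
    test_id=None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> RegressionResult | None:
    """Fit group x predictor interaction iff exactly one stratum rejected.

    When the stratified FDR decisions agree (both significant or neither),
    no interaction test is warranted and None is returned (rendered '-' in
    reports).
    """
    tid = predictor if test_id is None else test_id
    if fdr_ba.is_rejected(tid) == fdr_nhw.is_rejected(tid):
        return None
    return huber_regression(
        full, predictor, stratum="full", with_interaction=True, covariates=covariates
    )


# ---------------------------------------------------------------------------
# Validation and descriptives
# ---------------------------------------------------------------------------


def spearman_validation(lobar_uwmc, lobar_wmh) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties) with two-sided p."""
    x = np.asarray(lobar_uwmc, dtype=float)
    y = np.asarray(lobar_wmh, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def median_split(values) -> np.ndarray:
    """High/low split at the median; values equal to the median go to high."""
    v = np.asarray(values, dtype=float)
    return v >= np.median(v)


def describe_groups(
    cohort: pd.DataFrame,
    split: str = "racialized_group",
    continuous: Sequence[str] = ("age", "education", "physical_activity", "moca"),
    categorical: Sequence[str] = (
        "sex",
        "diabetes",
        "hypertension",
        "high_cholesterol",
        "apoe4",
    ),
) -> pd.DataFrame:
    """Group descriptives with Mann–Whitney / chi-square / Fisher tests.

    ``split='racialized_group'`` compares group==1 vs group==0;
    ``split='global_uwmc_median'`` compares high (>= median) vs low global
    UWMC.  Continuous rows report median (Q1, Q3) per group and a
    Mann–Whitney U p; binary rows report n (%) and chi-square, switching to
    Fisher's exact test when any expected cell count is below 5.
    """
    if split == "racialized_group":
        grouping = cohort["group"].to_numpy() == 1
        labels = ("BA", "nHW")
    elif split == "global_uwmc_median":
        grouping = median_split(cohort["global_uwmc"])
        labels = ("high", "low")
    else:
        raise ValueError("split must be 'racialized_group' or 'global_uwmc_median'")
    g1 = cohort[grouping]
    g0 = cohort[~grouping]
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("one split group is empty")

    rows = []

    def fmt_cont(s: pd.Series) -> str:
        return f"{s.median():.1f} ({s.quantile(0.25):.1f}, {s.quantile(0.75):.1f})"

    for var in continuous:
        a, b = g1[var], g0[var]
        if a.nunique() == 1 and b.nunique() == 1 and a.iloc[0] == b.iloc[0]:
            p = 1.0
        else:
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append((var, "continuous", fmt_cont(a), fmt_cont(b), "mannwhitney", p))

    for var in categorical:
        a = g1[var].to_numpy(dtype=int)
        b = g0[var].to_numpy(dtype=int)
        table = np.array(
            [[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]], dtype=float
        )
        if table.sum(axis=1).min() == 0:
            raise ValueError(f"empty group for variable {var}")
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if (expected < 5).any():
            p = float(sps.fisher_exact(table)[1])
            test = "fisher"
        else:
            p = float(sps.chi2_contingency(table, correction=False)[1])
            test = "chisquare"
        rows.append(
            (
                var,
                "categorical",
                f"{a.sum()} ({100 * a.mean():.1f}%)",
                f"{b.sum()} ({100 * b.mean():.1f}%)",
                test,
                p,
            )
        )

    return pd.DataFrame(
        rows, columns=["variable", "kind", labels[0], labels[1], "test", "p"]
    )


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------


class CognitionAnalysis:
    """UWMC-and-cognition analysis for one candidate feature set.

    Parameters
    ----------
    cohort : DataFrame
        One row per participant with ``moca``, the covariate columns and
        raw (untransformed) feature columns on [0, 1].
    candidate_features : sequence of str
        Feature columns entering data reduction.
    selection : SelectionConfig
        Resampling elastic-net settings (seed lives here).
    fdr_q : float
        FDR level per analysis column.

    ``fit()`` log-transforms features (and physical activity), runs
    stability selection, fits full/BA/nHW robust regressions per selected
    feature, applies BH within each column, and applies the conditional
    interaction rule.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        candidate_features: Sequence[str],
        selection: SelectionConfig | None = None,
        fdr_q: float = 0.05,
        covariates: Sequence[str] = DEFAULT_COVARIATES,
    ) -> None:
        self.raw_cohort = cohort
        self.candidate_features = list(candidate_features)
        self.selection_config = selection or SelectionConfig()
        self.fdr_q = fdr_q
        self.covariates = list(covariates)
        # transformed working copy: natural log with 0 -> 0.05
        work = cohort.copy()
        for col in self.candidate_features:
            work[col] = log_transform(work[col].to_numpy())
        if "physical_activity" in work.columns:
            work["physical_activity"] = log_transform(
                work["physical_activity"].to_numpy()
            )
        self.cohort = work

    def fit(self) -> "AnalysisResults":
        sel = stability_select(
            self.cohort,
            self.candidate_features,
            self.selection_config,
            covariates=self.covariates,
        )
        fits: dict[str, dict[str, RegressionResult]] = {}
        for feat in sel.selected:
            fits[feat] = {
                "full": huber_regression(self.cohort, feat, "full", covariates=self.covariates),
                "BA": huber_regression(self.cohort, feat, "BA", covariates=self.covariates),
                "nHW": huber_regression(self.cohort, feat, "nHW", covariates=self.covariates),
            }
        fdr = {
            col: bh_fdr({f: fits[f][col].p for f in sel.selected}, q=self.fdr_q)
            for col in ("full", "BA", "nHW")
        }
        interactions: dict[str, RegressionResult | None] = {}
        for feat in sel.selected:
            interactions[feat] = conditional_interaction(
                self.cohort, feat, fdr["BA"], fdr["nHW"], covariates=self.covariates
            )
        return AnalysisResults(
            selection=sel, fits=fits, fdr=fdr, interactions=interactions, q=self.fdr_q
        )


@dataclasses.dataclass
class AnalysisResults:
    """Estimates, FDR decisions and interaction tests for selected features."""

    selection: SelectionResult
    fits: dict[str, dict[str, RegressionResult]]
    fdr: dict[str, FdrDecision]
    interactions: dict[str, "RegressionResult | None"]
    q: float

    @staticmethod
    def _fmt_p(p: float) -> str:
        return "< 0.0001" if p < 1e-4 else f"{p:.4g}"

    def summary(self) -> pd.DataFrame:
        """Association table: per feature, beta (p) per column + FDR flags."""
        rows = []
        for feat in self.selection.selected:
            row = {"feature": feat}
            for col in ("full", "BA", "nHW"):
                r = self.fits[feat][col]
                row[f"beta_{col}"] = round(r.beta, 2)
                row[f"p_{col}"] = self._fmt_p(r.p)
                row[f"fdr_{col}"] = self.fdr[col].is_rejected(feat)
                row[f"per_percent_{col}"] = round(r.per_percent, 3)
            inter = self.interactions[feat]
            row["interaction_p"] = self._fmt_p(inter.p) if inter is not None else "-"
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Published reference coefficients
# ---------------------------------------------------------------------------


def load_reference_associations(which: str) -> pd.DataFrame:
    """Published pairwise association estimates for the amyloid/tau analyses.

    Robust-regression coefficients (full sample and per racialized group,
    with uncorrected p-values) for the region pairs that survived data
    reduction in the original UWMC cohort study.  P-values printed as
    "< 0.0001" are encoded as 0.0001; columns missing in print (no model
    fitted) are NaN.
    """
    from importlib.resources import files

    if which not in ("abeta", "tau"):
        raise ValueError("which must be 'abeta' or 'tau'")
    path = files("uwmc.data").joinpath(f"reference_associations_{which}.csv")
    with path.open() as fh:
        return pd.read_csv(fh)
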