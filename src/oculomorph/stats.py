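"""Cohort statistics: Spearman matrices, two-factor ANOVA, bootstrapped ROC.

The analysis stage of the eye-shape study: rank correlations between
morphometric and demographic variables across all eyes, a glaucoma x myopia
two-factor ANOVA with interaction on each morphometric outcome (PPG eyes
excluded from the 2x2 design), Tukey and Dunnett post-hoc comparisons, and
split-half bootstrapped logistic ROC curves for diagnostic models.

The ROC procedure guards against overfitting the way the study did: for
each of ``n_splits`` (default 200) replicates, one eye per subject is kept
(chosen at random), subjects are split 50/50, a logistic model with
standardized predictors is fitted by maximum likelihood on one half and its
ROC evaluated on the other; the curves are averaged vertically (TPR at
fixed FPR) and the AUC is computed on the *mean* curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "CorrelationMatrix",
    "AnovaResult",
    "RocSummary",
    "spearman_matrix",
    "stratified_correlations",
    "two_factor_anova",
    "bootstrap_roc",
    "model_comparison",
]


@dataclass
class CorrelationMatrix:
    variables: list
    rho: pd.DataFrame
    p_values: pd.DataFrame
    n: pd.DataFrame                 # pairwise-complete sample sizes


@dataclass
class AnovaResult:
    """Two-factor ANOVA with interaction plus post-hoc tables."""
    anova_table: pd.DataFrame       # type-II F and p for glaucoma, myopia, interaction
    tukey: pd.DataFrame             # all 6 pairs of the 4 groups
    dunnett: pd.DataFrame           # each non-control group vs control
    outcome: str = ""

    @property
    def effects(self) -> dict:
        out = {}
        for key, row in self.anova_table.iterrows():
            out[key] = {"F": float(row["F"]), "p": float(row["PR(>F)"])}
        return out


@dataclass
class RocSummary:
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    tpr_sd: np.ndarray
    auc_of_mean_curve: float
    n_splits: int
    n_ridge_fallbacks: int = 0
    predictors: list = field(default_factory=list)

    def fpr_at_sensitivity(self, sens: float = 0.80) -> float:
        """Smallest grid FPR whose mean TPR reaches the given sensitivity."""
        ok = self.mean_tpr >= sens
        if not ok.any():
            return 1.0
        return float(self.fpr_grid[int(np.argmax(ok))])


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def spearman_matrix(table: pd.DataFrame, variables) -> CorrelationMatrix:
    """Pairwise-complete Spearman rho (average-rank ties) with asymptotic p.

    Constant variables have undefined rank correlation; their entries are
    reported missing (NaN) with a warning.
    """
    variables = list(variables)
    k = len(variables)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    nmat = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            x = pd.to_numeric(table[variables[i]], errors="coerce")
            y = pd.to_numeric(table[variables[j]], errors="coerce")
            ok = x.notna() & y.notna()
            nmat[i, j] = nmat[j, i] = int(ok.sum())
            if ok.sum() < 3:
                continue
            xs, ys = x[ok].to_numpy(), y[ok].to_numpy()
            if i == j:
                rho[i, i], pval[i, i] = 1.0, 0.0
                continue
            if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                warnings.warn(
                    f"constant variable in pair ({variables[i]}, {variables[j]}): "
                    "Spearman rho undefined", stacklevel=2)
                continue
            r, p = sps.spearmanr(xs, ys)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    idx = pd.Index(variables)
    return CorrelationMatrix(
        variables=variables,
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p_values=pd.DataFrame(pval, index=idx, columns=idx),
        n=pd.DataFrame(nmat, index=idx, columns=idx),
    )


def stratified_correlations(table: pd.DataFrame, subset, variables) -> CorrelationMatrix:
    """Spearman matrix on a stratum of the cohort.

    ``subset`` is a boolean Series/array aligned with the table, a pandas
    query string, or a callable ``table -> boolean mask``.
    """
    if callable(subset):
        mask = np.asarray(subset(table), dtype=bool)
        sub = table[mask]
    elif isinstance(subset, str):
        sub = table.query(subset)
    else:
        sub = table[np.asarray(subset, dtype=bool)]
    if len(sub) == 0:
        raise ValueError("empty stratum")
    return spearman_matrix(sub, variables)


# ---------------------------------------------------------------------------
# two-factor ANOVA with interaction, Tukey and Dunnett post-hocs
# ---------------------------------------------------------------------------

_FOUR_GROUPS = ("control", "myopia", "glaucoma", "glaucoma_myopia")


def two_factor_anova(table: pd.DataFrame, outcome: str,
                     posthoc: bool = True) -> AnovaResult:
    """Glaucoma x myopia ANOVA with interaction (type-II SS), PPG excluded.

    Type-II sums of squares suit the unbalanced 2x2 design.  Post-hoc:
    Tukey HSD over the four groups (all six pairs) and Dunnett's test of
    each non-control group against control; ``posthoc=False`` skips both
    (useful inside permutation/power simulations).
    """
    df = table[~table.get("ppg", False)].copy() if "ppg" in table.columns else table.copy()
    df = df[df["group"].isin(_FOUR_GROUPS)]
    df["_y"] = pd.to_numeric(df[outcome], errors="coerce")
    df = df.dropna(subset=["_y"])
    df["_glaucoma"] = df["group"].isin(["glaucoma", "glaucoma_myopia"])
    df["_myopia"] = df["group"].isin(["myopia", "glaucoma_myopia"])
    counts = df.groupby(["_glaucoma", "_myopia"]).size()
    if len(counts) < 4 or (counts == 0).any():
        raise ValueError("unbalanced design: empty cell")

    model = smf.ols("_y ~ C(_glaucoma) * C(_myopia)", data=df).fit()
    if model.ssr < 1e-12 * max(1.0, abs(df["_y"]).max() ** 2 * len(df)):
        # all-constant outcome: F is 0 by definition, statsmodels would emit
        # nan; post-hoc contrasts are equally degenerate, so skip them
        anova = pd.DataFrame(
            {"sum_sq": 0.0, "df": [1.0, 1.0, 1.0],
             "F": 0.0, "PR(>F)": 1.0},
            index=["glaucoma", "myopia", "glaucoma:myopia"])
        return AnovaResult(anova_table=anova, tukey=pd.DataFrame(),
                           dunnett=pd.DataFrame(), outcome=outcome)
    else:
        anova = sm.stats.anova_lm(model, typ=2)
        anova = anova.rename(index={
            "C(_glaucoma)": "glaucoma",
            "C(_myopia)": "myopia",
            "C(_glaucoma):C(_myopia)": "glaucoma:myopia",
        }).drop(index="Residual")

    if not posthoc:
        return AnovaResult(anova_table=anova, tukey=pd.DataFrame(),
                           dunnett=pd.DataFrame(), outcome=outcome)

    tk = pairwise_tukeyhsd(df["_y"].to_numpy(), df["group"].to_numpy())
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    tukey["p_adjusted"] = tk.pvalues   # full precision (summary rounds to 4 dp)
    tukey = tukey.drop(columns=["p-adj"])
    # unadjusted p from the same studentized statistic and error df, for audit
    df_resid = tk.df_total
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.abs(tukey["meandiff"].astype(float).to_numpy()) / tk.std_pairs
    tukey["p_unadjusted"] = 2 * sps.t.sf(tstat, df_resid)

    groups_present = [g for g in _FOUR_GROUPS if (df["group"] == g).any()]
    samples = [df.loc[df["group"] == g, "_y"].to_numpy()
               for g in groups_present if g != "control"]
    control = df.loc[df["group"] == "control", "_y"].to_numpy()
    dn = sps.dunnett(*samples, control=control)
    dunnett = pd.DataFrame({
        "group": [g for g in groups_present if g != "control"],
        "statistic": dn.statistic,
        "p_adjusted": dn.pvalue,
    })
    # marginal p of the same statistic (pooled-variance df), for audit
    df_dunnett = len(df) - len(groups_present)
    dunnett["p_unadjusted"] = 2 * sps.t.sf(np.abs(dn.statistic), df_dunnett)

    return AnovaResult(anova_table=anova, tukey=tukey, dunnett=dunnett,
                       outcome=outcome)


# ---------------------------------------------------------------------------
# bootstrapped split-half logistic ROC
# ---------------------------------------------------------------------------

def _fit_logistic(X, y):
    """ML logistic fit; ridge fallback (lambda = 1e-4) on non-convergence."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf = LogisticRegression(C=np.inf, max_iter=500)
            clf.fit(X, y)
            return clf, False
        except Exception:
            pass
    clf = LogisticRegression(C=1e4, max_iter=2000)
    clf.fit(X, y)
    return clf, True


def bootstrap_roc(table: pd.DataFrame, predictors, label: str,
                  n_splits: int = 200, seed: int = 0,
                  fpr_grid: np.ndarray | None = None) -> RocSummary:
    """Split-half bootstrapped logistic ROC, averaged vertically.

    Per replicate: keep one eye per subject (uniformly at random), split the
    *subjects* 50/50 at random, standardize predictors on the fit half, fit
    the logistic model there, score the held-out half, and interpolate its
    TPR onto a fixed FPR grid.  The summary curve is the pointwise mean over
    replicates; the AUC is the trapezoid integral of that mean curve; the
    displayed dispersion band is half the pointwise SD.
    """
    predictors = list(predictors)
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    df = table.dropna(subset=predictors + [label]).copy()
    y_all = df[label].astype(bool)
    subjects = df["subject_id"].unique()
    subj_label = df.groupby("subject_id")[label].first().astype(bool)
    n_pos = int(subj_label.sum())
    n_neg = len(subj_label) - n_pos
    if min(n_pos, n_neg) < 10:
        raise ValueError("need at least 10 subjects per class")

    rng = np.random.default_rng(int(seed) % (2**31))
    tprs = np.empty((n_splits, len(fpr_grid)))
    n_ridge = 0
    groups = {s: sub.index.to_numpy() for s, sub in df.groupby("subject_id")}
    for b in range(n_splits):
        # one eye per subject
        rows = np.array([g[rng.integers(len(g))] for g in groups.values()])
        sub = df.loc[rows]
        subj = sub["subject_id"].to_numpy()
        order = rng.permutation(len(subj))
        half = len(subj) // 2
        fit_idx, eval_idx = order[:half], order[half:]
        # degenerate single-class halves: reshuffle (rare at study sizes)
        for _ in range(20):
            if sub.iloc[fit_idx][label].nunique() == 2 and \
               sub.iloc[eval_idx][label].nunique() == 2:
                break
            order = rng.permutation(len(subj))
            fit_idx, eval_idx = order[:half], order[half:]

        Xf = sub.iloc[fit_idx][predictors].to_numpy(dtype=float)
        Xe = sub.iloc[eval_idx][predictors].to_numpy(dtype=float)
        mu, sdv = Xf.mean(axis=0), Xf.std(axis=0)
        sdv[sdv < 1e-12] = 1.0
        clf, used_ridge = _fit_logistic((Xf - mu) / sdv,
                                        sub.iloc[fit_idx][label].astype(int))
        n_ridge += int(used_ridge)
        scores = clf.decision_function((Xe - mu) / sdv)
        fpr, tpr, _ = roc_curve(sub.iloc[eval_idx][label].astype(int), scores)
        tprs[b] = np.interp(fpr_grid, fpr, tpr)

    mean_tpr = tprs.mean(axis=0)
    auc = float(np.trapezoid(mean_tpr, fpr_grid))
    return RocSummary(fpr_grid=fpr_grid, mean_tpr=mean_tpr,
                      tpr_sd=tprs.std(axis=0), auc_of_mean_curve=auc,
                      n_splits=n_splits, n_ridge_fallbacks=n_ridge,
                      predictors=predictors)


def model_comparison(table: pd.DataFrame, model_specs: dict, label: str,
                     n_splits: int = 200, seed: int = 0) -> pd.DataFrame:
    """Rank candidate predictor sets by bootstrapped mean-curve AUC.

    Every model is evaluated with the same seed (identical resampling
    streams), so differences reflect the predictors alone.  Reports the
    false-positive rate at 80 % sensitivity as the operating point.
    """
    rows = {}
    for name, predictors in model_specs.items():
        summ = bootstrap_roc(table, predictors, label,
                             n_splits=n_splits, seed=seed)
        rows[name] = {
            "predictors": "+".join(predictors),
            "auc": summ.auc_of_mean_curve,
            "fpr_at_80_sens": summ.fpr_at_sensitivity(0.80),
            "n_ridge_fallbacks": summ.n_ridge_fallbacks,
        }
    out = pd.DataFrame(rows).T.sort_values("auc", ascending=False)
    out.index.name = "model"
    return out
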