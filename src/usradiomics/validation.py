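"""Internal-validation statistics for a binary risk model.

Covers the standard reporting battery for a clinical prediction score:
cohort summary tables, univariable/multivariable logistic odds ratios
with Wald 95% CIs, Harrell's C-index (equal to AUROC for a binary
outcome), bootstrap optimism-corrected C, deciles-of-risk calibration
and the Hosmer-Lemeshow chi-square test.

Ordinary logistic fits are delegated to statsmodels; the concordance,
optimism-correction and calibration machinery is implemented here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)

_Z95 = 1.959963984540054  # Phi^{-1}(0.975)


class CollinearPredictorsError(ValueError):
    pass


# --------------------------------------------------------------------------
# cohort summary

def _fmt_pct(k: int, n: int) -> str:
    return f"{k} ({100.0 * k / n:.1f}%)"


def cohort_summary(cohort: pd.DataFrame, label_col: str = "braf_label",
                   continuous: Sequence[str] = ("age", "size_mm"),
                   categorical: Sequence[str] = ("sex", "age_class", "size_class"),
                   score_col: Optional[str] = "radiomics_score") -> pd.DataFrame:
    """Per-class demographic summary with two-sample comparisons.

    Means are compared by Welch's t-test, score medians by the Wilcoxon
    rank-sum test, and proportions by chi-square with Yates correction
    (Fisher's exact test when any expected cell count is below 5).
    """
    if cohort.empty:
        raise ValueError("nonempty cohort required")
    y = cohort[label_col].to_numpy()
    classes = np.unique(y)
    single = len(classes) < 2
    groups = {c: cohort[y == c] for c in classes}
    n = len(cohort)

    rows: List[dict] = []
    head = {"variable": "n (%)"}
    for c in classes:
        head[f"class_{c}"] = _fmt_pct(len(groups[c]), n)
    head["p"] = np.nan
    rows.append(head)

    for col in continuous:
        if col not in cohort:
            continue
        row = {"variable": f"mean {col}"}
        for c in classes:
            v = groups[c][col]
            row[f"class_{c}"] = f"{v.mean():.1f}±{v.std():.1f}"
        if single:
            row["p"] = np.nan
        else:
            row["p"] = stats.ttest_ind(groups[classes[0]][col],
                                       groups[classes[1]][col],
                                       equal_var=False).pvalue
        rows.append(row)

    for col in categorical:
        if col not in cohort:
            continue
        levels = sorted(cohort[col].unique())
        tab = np.array([[int((groups[c][col] == lv).sum()) for lv in levels]
                        for c in classes])
        if single or tab.shape != (2, 2):
            p = np.nan
        else:
            expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
            if (expected < 5).any():
                p = stats.fisher_exact(tab).pvalue
            else:
                p = stats.chi2_contingency(tab, correction=True).pvalue
        for k, lv in enumerate(levels):
            row = {"variable": f"{col}={lv}"}
            for ic, c in enumerate(classes):
                row[f"class_{c}"] = _fmt_pct(int(tab[ic, k]), len(groups[c]))
            row["p"] = p if k == 0 else np.nan
            rows.append(row)

    if score_col and score_col in cohort and cohort[score_col].notna().all():
        row = {"variable": f"median {score_col} (IQR)"}
        for c in classes:
            v = groups[c][score_col]
            q1, q2, q3 = v.quantile([0.25, 0.5, 0.75])
            row[f"class_{c}"] = f"{q2:.3f} ({q1:.3f}, {q3:.3f})"
        if single:
            row["p"] = np.nan
        else:
            row["p"] = stats.mannwhitneyu(groups[classes[0]][score_col],
                                          groups[classes[1]][score_col],
                                          alternative="two-sided").pvalue
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# logistic odds ratios

@dataclass
class OddsRatio:
    variable: str
    oddsratio: float
    ci_low: float
    ci_high: float
    p: float
    separation: bool = False

    def as_dict(self) -> dict:
        return {"variable": self.variable, "OR": self.oddsratio,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "p": self.p, "separation": self.separation}


def _profile_ci(x: np.ndarray, y: np.ndarray, beta_hat: float,
                level: float = 0.95) -> tuple:
    """Profile-likelihood CI for a single-predictor logistic slope.

    Used as the fallback under (quasi-)separation, where the Wald CI is
    meaningless.  The profile deviance is evaluated on a beta grid by
    refitting the intercept with the slope held fixed via an offset.
    """
    cut = stats.chi2.ppf(level, 1)

    def dev(beta):
        mod = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(),
                     offset=beta * x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mod.fit()
        return res.deviance

    b0 = np.clip(beta_hat, -20, 20)
    d0 = dev(b0)
    grid = np.linspace(b0 - 25, b0 + 25, 401)
    devs = np.array([dev(b) for b in grid])
    inside = grid[devs <= d0 + cut]
    if inside.size == 0:
        return (-np.inf, np.inf)
    lo = float(inside.min()) if inside.min() > grid.min() else -np.inf
    hi = float(inside.max()) if inside.max() < grid.max() else np.inf
    return lo, hi


def univariable_logistic(cohort: pd.DataFrame, variable: str,
                         label_col: str = "braf_label") -> OddsRatio:
    """Single-predictor logistic OR with Wald 95% CI.

    Perfect or quasi-perfect separation is flagged and the CI falls back
    to profile likelihood.
    """
    x = cohort[variable].to_numpy(dtype=float)
    y = cohort[label_col].to_numpy(dtype=int)
    if np.std(x) == 0:
        raise ValueError(f"variable {variable!r} is constant")
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta, se = res.params[1], res.bse[1]
            pval = res.pvalues[1]
            converged = res.mle_retvals.get("converged", True)
        except Exception:
            beta, se, pval, converged = np.inf, np.inf, np.nan, False
    separated = (not converged) or (not np.isfinite(se)) or abs(beta) > 15 or se > 50
    if separated:
        lo, hi = _profile_ci(x, y, beta if np.isfinite(beta) else 0.0)
        return OddsRatio(variable, float(np.exp(beta)) if np.isfinite(beta) else np.inf,
                         float(np.exp(lo)), float(np.exp(hi)),
                         float(pval) if np.isfinite(pval) else np.nan,
                         separation=True)
    return OddsRatio(variable, float(np.exp(beta)),
                     float(np.exp(beta - _Z95 * se)),
                     float(np.exp(beta + _Z95 * se)), float(pval))


def multivariable_logistic(cohort: pd.DataFrame, variables: Sequence[str],
                           label_col: str = "braf_label") -> List[OddsRatio]:
    """Joint ML logistic fit; adjusted ORs with Wald 95% CIs."""
    y = cohort[label_col].to_numpy(dtype=int)
    if len(y) < 10 * len(variables):
        warnings.warn("fewer than 10 events-per-variable rows; estimates unstable")
    Xr = cohort[list(variables)].to_numpy(dtype=float)
    keep = Xr.std(axis=0) > 0
    dropped = [v for v, k in zip(variables, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant predictors: {dropped}")
    variables = [v for v, k in zip(variables, keep) if k]
    Xr = Xr[:, keep]
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), Xr])) < Xr.shape[1] + 1:
        raise CollinearPredictorsError("collinear predictors")
    X = sm.add_constant(Xr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    out = []
    for j, v in enumerate(variables, start=1):
        beta, se = res.params[j], res.bse[j]
        out.append(OddsRatio(v, float(np.exp(beta)),
                             float(np.exp(beta - _Z95 * se)),
                             float(np.exp(beta + _Z95 * se)),
                             float(res.pvalues[j])))
    return out


# --------------------------------------------------------------------------
# discrimination

def c_index(scores, labels) -> float:
    """Harrell's C over all positive-negative pairs; ties count 0.5.

    For a binary outcome this equals the area under the ROC curve; it is
    computed from the rank-sum statistic, so ties are handled exactly.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class BootstrapResult:
    apparent_c: float
    corrected_c: float
    mean_optimism: float
    ci_low: float
    ci_high: float
    B: int
    n_redrawn: int = 0


def bootstrap_validate(cohort: pd.DataFrame, model_spec: Callable,
                       B: int = 1000, seed: int = 0,
                       label_col: str = "braf_label",
                       feature_cols: Optional[Sequence[str]] = None
                       ) -> BootstrapResult:
    """Harrell optimism-corrected C-index by bootstrap resampling.

    ``model_spec(X_train, y_train)`` must return a callable
    ``predict(X) -> scores``.  For each resample the model is refitted,
    its C on the resample and on the original data are compared, and the
    mean optimism is subtracted from the apparent C.  The CI is the
    percentile interval of the resample-C distribution.  Resamples
    missing a class are redrawn (logged).
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    y = cohort[label_col].to_numpy(dtype=int)
    if feature_cols is None:
        feature_cols = [c for c in cohort.columns if c != label_col]
    X = cohort[list(feature_cols)].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    predict = model_spec(X, y)
    apparent = c_index(predict(X), y)

    n = len(y)
    optimism = np.empty(B)
    c_boot = np.empty(B)
    redrawn = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if 0 < yb.sum() < n:
                break
            redrawn += 1
            log.info("bootstrap resample %d had a single class; redrawn", b)
        Xb = X[idx]
        pred_b = model_spec(Xb, yb)
        cb = c_index(pred_b(Xb), yb)
        co = c_index(pred_b(X), y)
        c_boot[b] = cb
        optimism[b] = cb - co
    mean_opt = float(optimism.mean())
    lo, hi = np.percentile(c_boot, [2.5, 97.5])
    return BootstrapResult(apparent_c=float(apparent),
                           corrected_c=float(apparent - mean_opt),
                           mean_optimism=mean_opt,
                           ci_low=float(lo), ci_high=float(hi),
                           B=B, n_redrawn=redrawn)


def identity_score_spec(X: np.ndarray, y: np.ndarray) -> Callable:
    """model_spec for a pre-computed score column (no refitting)."""
    return lambda Xnew: Xnew[:, 0]


def fixed_lambda_lasso_spec(lam: float) -> Callable:
    """model_spec refitting an L1-logistic model at a fixed lambda."""
    from .lasso import lasso_logistic_path

    def spec(X: np.ndarray, y: np.ndarray) -> Callable:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - mu) / sd
        coefs, bs, _ = lasso_logistic_path(Xs, y, np.array([lam]), tol=1e-7)
        beta, b0 = coefs[0], bs[0]
        return lambda Xnew: ((Xnew - mu) / sd) @ beta + b0

    return spec


# --------------------------------------------------------------------------
# calibration

def _risk_groups(pred: np.ndarray, groups: int) -> np.ndarray:
    """Equal-count grouping by predicted risk; ties stay in one group."""
    if np.unique(pred).size == 1:
        log.info("constant predictions: single calibration group")
        return np.zeros(len(pred), dtype=int)
    ranks = pd.Series(pred).rank(method="first")
    edges = pd.qcut(pred, q=groups, duplicates="drop", labels=False)
    if np.unique(edges).size < groups:
        log.info("tie-collapse reduced calibration groups to %d",
                 np.unique(edges).size)
        return np.asarray(edges)
    return np.asarray(pd.qcut(ranks, q=groups, labels=False))


def calibration_table(pred, obs, groups: int = 10) -> pd.DataFrame:
    """Per-risk-group mean predicted probability and observed event rate."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs).astype(int)
    g = _risk_groups(pred, groups)
    rows = []
    for k in sorted(np.unique(g)):
        sel = g == k
        rows.append({"group": int(k), "n": int(sel.sum()),
                     "mean_predicted": float(pred[sel].mean()),
                     "observed_rate": float(obs[sel].mean()),
                     "expected_events": float(pred[sel].sum()),
                     "observed_events": int(obs[sel].sum())})
    return pd.DataFrame(rows)


@dataclass
class HosmerLemeshowResult:
    statistic: float
    df: int
    p: float
    table: pd.DataFrame


def hosmer_lemeshow(pred, obs, groups: int = 10) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow deciles-of-risk goodness-of-calibration test.

    chi2 = sum (O - E)^2 / (E (1 - E/n_g)) over risk groups, df = g - 2.
    """
    tab = calibration_table(pred, obs, groups)
    g = len(tab)
    O = tab["observed_events"].to_numpy(dtype=float)
    E = tab["expected_events"].to_numpy(dtype=float)
    ng = tab["n"].to_numpy(dtype=float)
    denom = E * (1.0 - E / ng)
    ok = denom > 0
    statistic = float(np.sum((O[ok] - E[ok]) ** 2 / denom[ok]))
    df = max(g - 2, 1)
    return HosmerLemeshowResult(statistic=statistic, df=df,
                                p=float(stats.chi2.sf(statistic, df)), table=tab)


def plot_calibration(tab: pd.DataFrame, path=None, ax=None):
    """Observed-vs-predicted calibration curve (one point per risk group)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [0, 1], "--", color="gray", lw=1, label="ideal")
    ax.plot(tab["mean_predicted"], tab["observed_rate"], "o-", label="model")
    ax.set_xlabel("predicted risk")
    ax.set_ylabel("observed probability")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax


# --------------------------------------------------------------------------
# report

@dataclass
class ValidationReport:
    """Bundle of the full internal-validation battery for one cohort."""

    univariable: List[OddsRatio] = field(default_factory=list)
    multivariable: List[OddsRatio] = field(default_factory=list)
    apparent_c: Optional[float] = None
    bootstrap: Optional[BootstrapResult] = None
    hosmer_lemeshow: Optional[HosmerLemeshowResult] = None
    calibration: Optional[pd.DataFrame] = None

    def as_dict(self) -> dict:
        out: Dict = {
            "univariable": [o.as_dict() for o in self.univariable],
            "multivariable": [o.as_dict() for o in self.multivariable],
            "apparent_c": self.apparent_c,
        }
        if self.bootstrap is not None:
            b = self.bootstrap
            out["bootstrap"] = {"corrected_c": b.corrected_c,
                                "mean_optimism": b.mean_optimism,
                                "ci": [b.ci_low, b.ci_high], "B": b.B}
        if self.hosmer_lemeshow is not None:
            h = self.hosmer_lemeshow
            out["hosmer_lemeshow"] = {"statistic": h.statistic,
                                      "df": h.df, "p": h.p}
        if self.calibration is not None:
            out["calibration"] = self.calibration.to_dict(orient="records")
        return out

    def summary(self) -> str:
        lines = ["Internal validation report", "=" * 42]
        if self.univariable:
            lines.append("Univariable odds ratios:")
            for o in self.univariable:
                flag = "  [separation]" if o.separation else ""
                lines.append(f"  {o.variable:<18} OR {o.oddsratio:8.3f} "
                             f"({o.ci_low:.3f}-{o.ci_high:.3f})  p={o.p:.3g}{flag}")
        if self.multivariable:
            lines.append("Multivariable (adjusted) odds ratios:")
            for o in self.multivariable:
                lines.append(f"  {o.variable:<18} OR {o.oddsratio:8.3f} "
                             f"({o.ci_low:.3f}-{o.ci_high:.3f})  p={o.p:.3g}")
        if self.apparent_c is not None:
            lines.append(f"Apparent C-index: {self.apparent_c:.3f}")
        if self.bootstrap is not None:
            b = self.bootstrap
            lines.append(f"Optimism-corrected C: {b.corrected_c:.3f} "
                         f"(95% CI {b.ci_low:.3f}-{b.ci_high:.3f}, B={b.B})")
        if self.hosmer_lemeshow is not None:
            h = self.hosmer_lemeshow
            lines.append(f"Hosmer-Lemeshow: chi2={h.statistic:.3f}, "
                         f"df={h.df}, p={h.p:.3f}")
        return "\n".join(lines)
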