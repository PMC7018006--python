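"""Radiomics Score construction by L1-penalized (LASSO) logistic regression.

The model surface follows the statsmodels idiom: build a
:class:`RadiomicsSignature` from a feature table and binary labels, call
``fit()`` and receive a :class:`SignatureResults` carrying the selected
:class:`ScoreModel`, the full :class:`LassoPath` (coefficient profiles
plus cross-validated deviance), and a ``summary()`` table.

The penalty weight lambda is chosen by K-fold cross-validated binomial
deviance, either at the minimum ("min") or by the one-standard-error
rule ("1se", the default: the largest lambda whose mean deviance is
within one SE of the minimum — the sparser, more conservative choice).
Features are standardized internally; reported coefficients are
back-transformed to the original feature scale so a fitted model prints
in the same form as the published Radiomics Score formulas.

The Radiomics Score itself is the affine combination
``intercept + sum(coef * feature)`` — the linear predictor, no link
transformation.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lasso import default_lambda_grid, lasso_logistic_path

_ZERO_TOL = 1e-7  # standardized-scale threshold below which a coefficient is zero
_EPS_PROB = 1e-12


class IncompleteFeatureVectorError(KeyError):
    pass


@dataclass
class ScoreModel:
    """Intercept plus sparse named coefficients on the original feature scale."""

    intercept: float
    coefficients: Dict[str, float]
    lambda_min: Optional[float] = None
    lambda_1se: Optional[float] = None
    lambda_rule: str = "1se"
    standardization: Optional[Dict[str, Tuple[float, float]]] = None

    @property
    def n_nonzero(self) -> int:
        return sum(1 for v in self.coefficients.values() if v != 0)

    def score(self, fv) -> float:
        return compute_score(self, fv)

    def to_json(self, path=None) -> str:
        payload = {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "lambda_min": self.lambda_min,
            "lambda_1se": self.lambda_1se,
            "lambda_rule": self.lambda_rule,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ScoreModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            intercept=float(payload["intercept"]),
            coefficients={k: float(v) for k, v in payload["coefficients"].items()},
            lambda_min=payload.get("lambda_min"),
            lambda_1se=payload.get("lambda_1se"),
            lambda_rule=payload.get("lambda_rule", "1se"),
        )


def published_model(which: str) -> ScoreModel:
    """The two published Radiomics Score models, digits verbatim.

    ``which`` is "total" (527 thyroid cancers, 8 nonzero coefficients)
    or "cptc_lt20" (389 conventional PTC < 20 mm, 4 nonzero
    coefficients).
    """
    text = resources.files("usradiomics.data").joinpath(
        "published_models.json").read_text()
    models = json.loads(text)
    if which not in models:
        raise KeyError(f"no such model: {which!r}")
    m = models[which]
    return ScoreModel(
        intercept=m["intercept"],
        coefficients=dict(m["coefficients"]),
        lambda_min=m["lambda_min"],
        lambda_1se=m["lambda_1se"],
        lambda_rule=m["lambda_rule"],
    )


def compute_score(model: ScoreModel, fv) -> float:
    """Radiomics Score: intercept + sum of coefficient x feature value."""
    if hasattr(fv, "values") and not isinstance(fv, (pd.Series, Mapping)):
        fv = fv.values  # FeatureVector
    total = model.intercept
    for name, coef in model.coefficients.items():
        try:
            x = fv[name]
        except (KeyError, IndexError) as exc:
            raise IncompleteFeatureVectorError(
                f"incomplete feature vector: missing {name!r}") from exc
        total += coef * float(x)
    return float(total)


@dataclass
class LassoPath:
    """Lambda grid (descending), coefficient profiles and CV deviance."""

    lambdas: np.ndarray                 # (L,)
    coef_path: np.ndarray               # (L, p) standardized scale, full-data fits
    intercept_path: np.ndarray          # (L,)
    cv_mean_deviance: np.ndarray        # (L,)
    cv_se: np.ndarray                   # (L,)
    feature_names: Sequence[str] = field(default_factory=list)

    @property
    def n_nonzero(self) -> np.ndarray:
        return (np.abs(self.coef_path) > _ZERO_TOL).sum(axis=1)

    @property
    def lambda_min(self) -> float:
        return float(self.lambdas[int(np.argmin(self.cv_mean_deviance))])

    @property
    def lambda_1se(self) -> float:
        k = int(np.argmin(self.cv_mean_deviance))
        cut = self.cv_mean_deviance[k] + self.cv_se[k]
        ok = np.nonzero(self.cv_mean_deviance <= cut)[0]
        return float(self.lambdas[ok.min()])  # grid is descending: min index = largest


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Deterministic row order keyed on row content, not input position.

    Sorting rows by a content hash makes fold assignment — and hence the
    whole fit — invariant to permutations of the input rows.
    """
    keys = []
    for i in range(X.shape[0]):
        h = hashlib.blake2b(digest_size=8)
        h.update(X[i].tobytes())
        h.update(bytes([int(y[i])]))
        keys.append(int.from_bytes(h.digest(), "big"))
    return np.argsort(np.asarray(keys), kind="stable")


def _stratified_folds(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Seeded stratified fold labels over canonically ordered rows."""
    rng = np.random.default_rng(seed)
    assign = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        perm = rng.permutation(len(idx))
        assign[idx[perm]] = np.arange(len(idx)) % folds
    return assign


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS_PROB, 1 - _EPS_PROB)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _l1_path_fits(X: np.ndarray, y: np.ndarray, lambdas: np.ndarray,
                  thresh: float = 1e-9):
    """Fit the descending-lambda path; early-stopped tails are held at the
    last fitted solution so every grid point has predictions."""
    coefs, bs, n_used = lasso_logistic_path(X, y, lambdas, thresh=thresh)
    if n_used < len(lambdas):
        coefs[n_used:] = coefs[n_used - 1]
        bs[n_used:] = bs[n_used - 1]
    return coefs, bs, n_used


class RadiomicsSignature:
    """LASSO-logistic signature model over a lesion x feature table.

    Parameters
    ----------
    X : DataFrame or array, shape (n, p)
        Feature matrix (columns named; required to report a formula).
    y : array-like of 0/1
        Binary outcome (e.g. mutation present).
    """

    def __init__(self, X, y, feature_names: Optional[Sequence[str]] = None):
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be (n, p) with matching labels")
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(X.shape[1])]
        self.X = X
        self.y = y
        self.feature_names = list(feature_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str) -> "RadiomicsSignature":
        y = df[label_col]
        X = df.drop(columns=[label_col])
        return cls(X, y)

    def fit(self, folds: int = 10, rule: str = "1se", n_lambdas: int = 100,
            lambda_min_ratio: float = None, seed: int = 0) -> "SignatureResults":
        if rule not in ("min", "1se"):
            raise ValueError("rule must be 'min' or '1se'")
        y = self.y
        counts = np.bincount(y, minlength=2)
        if counts.min() < 2:
            raise ValueError("need at least 2 cases per class")
        if counts.min() < folds:
            raise ValueError("fold infeasible: a class has fewer members than folds")

        X = self.X
        names = np.asarray(self.feature_names)
        # relative threshold: a constant column's float std is ~1e-16, not 0
        keep = X.std(axis=0) > 1e-10 * np.maximum(1.0, np.abs(X.mean(axis=0)))
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} all-constant feature columns")
            X = X[:, keep]
            names = names[keep]

        order = _canonical_order(X, y)
        Xc, yc = X[order], y[order]
        center = Xc.mean(axis=0)
        scale = Xc.std(axis=0)
        Xs = (Xc - center) / scale

        lambdas = default_lambda_grid(Xs, yc, n_lambdas, lambda_min_ratio)

        # full-data path first: its early-stopping point truncates the grid
        # the folds are evaluated on (the glmnet convention)
        full_coefs, full_bs, n_used = _l1_path_fits(Xs, yc, lambdas)
        lambdas = lambdas[:n_used]
        full_coefs = full_coefs[:n_used]
        full_bs = full_bs[:n_used]
        n_lambdas = n_used

        fold_of = _stratified_folds(yc, folds, seed)
        fold_dev = np.empty((folds, n_lambdas))
        for f in range(folds):
            tr = fold_of != f
            te = ~tr
            # fold fits may run at a looser tolerance: the CV deviance used
            # to pick lambda is insensitive to 1e-5-level coefficient error
            coefs, bs, _ = _l1_path_fits(Xs[tr], yc[tr], lambdas, thresh=1e-7)
            eta = Xs[te] @ coefs.T + bs  # (n_te, L)
            p = 1.0 / (1.0 + np.exp(-eta))
            p = np.clip(p, _EPS_PROB, 1 - _EPS_PROB)
            yt = yc[te][:, None]
            fold_dev[f] = -2.0 * np.mean(
                yt * np.log(p) + (1 - yt) * np.log(1 - p), axis=0)
        cv_mean = fold_dev.mean(axis=0)
        cv_se = fold_dev.std(axis=0, ddof=1) / np.sqrt(folds)

        path = LassoPath(
            lambdas=lambdas, coef_path=full_coefs, intercept_path=full_bs,
            cv_mean_deviance=cv_mean, cv_se=cv_se, feature_names=list(names),
        )

        lam = path.lambda_1se if rule == "1se" else path.lambda_min
        k = int(np.argmin(np.abs(lambdas - lam)))
        beta_s = full_coefs[k].copy()
        beta_s[np.abs(beta_s) <= _ZERO_TOL] = 0.0
        b_s = full_bs[k]

        # back-transform to the original feature scale
        beta = beta_s / scale
        intercept = float(b_s - np.sum(beta_s * center / scale))
        nz = np.nonzero(beta_s)[0]
        model = ScoreModel(
            intercept=intercept,
            coefficients={names[j]: float(beta[j]) for j in nz},
            lambda_min=path.lambda_min,
            lambda_1se=path.lambda_1se,
            lambda_rule=rule,
            standardization={names[j]: (float(center[j]), float(scale[j]))
                             for j in nz},
        )
        return SignatureResults(signature=self, model=model, path=path,
                                folds=folds, rule=rule, seed=seed)


@dataclass
class SignatureResults:
    """Fitted signature: chosen ScoreModel plus the full lambda path."""

    signature: RadiomicsSignature
    model: ScoreModel
    path: LassoPath
    folds: int
    rule: str
    seed: int

    @property
    def lambda_(self) -> float:
        return self.path.lambda_1se if self.rule == "1se" else self.path.lambda_min

    def scores(self, X=None) -> np.ndarray:
        """Radiomics Score (linear predictor) per row."""
        if X is None:
            X = pd.DataFrame(self.signature.X, columns=self.signature.feature_names)
        elif not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             columns=self.signature.feature_names)
        out = np.full(len(X), self.model.intercept)
        for name, coef in self.model.coefficients.items():
            out += coef * X[name].to_numpy(dtype=float)
        return out

    def predict_proba(self, X=None) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.scores(X)))

    def summary(self) -> str:
        m = self.model
        lines = [
            "Radiomics Score — LASSO logistic signature",
            "=" * 46,
            f"n obs:            {len(self.signature.y)}",
            f"features offered: {len(self.signature.feature_names)}",
            f"CV folds:         {self.folds}   (seed {self.seed})",
            f"lambda rule:      {self.rule}",
            f"lambda(min):      {m.lambda_min:.6g}",
            f"lambda(1se):      {m.lambda_1se:.6g}",
            f"nonzero coefs:    {m.n_nonzero}",
            "-" * 46,
            f"{'feature':<22}{'coef (orig. scale)':>20}",
        ]
        for name, coef in sorted(m.coefficients.items(),
                                 key=lambda kv: -abs(kv[1])):
            lines.append(f"{name:<22}{coef:>20.7g}")
        lines.append(f"{'intercept':<22}{m.intercept:>20.7g}")
        return "\n".join(lines)


def fit_lasso_signature(table, labels, folds: int = 10, rule: str = "1se",
                        seed: int = 0, n_lambdas: int = 100
                        ) -> Tuple[ScoreModel, LassoPath]:
    """Functional wrapper: fit and return (ScoreModel, LassoPath)."""
    res = RadiomicsSignature(table, labels).fit(
        folds=folds, rule=rule, n_lambdas=n_lambdas, seed=seed)
    return res.model, res.path
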