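"""Binomial logistic habitat models: design coding, IRLS fitting, AIC subset
selection, and explained deviance.

The habitat model is an ordinary logistic GLM,

    logit P(y_i = 1) = b0 + x_i . b,

fitted by iteratively reweighted least squares (IRLS). Model parsimony
follows exhaustive best-subset search on AIC, with categorical predictors
entering or leaving as whole dummy blocks. Fit quality is summarised by the
explained deviance D^2 = (null - residual) / null x 100, the GLM analogue
of R^2.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.linalg import qr

from .coastio import PREDICTOR_COLUMNS

CONTINUOUS_TERMS = ("sst_avg", "wh_avg", "wh_min")
CATEGORICAL_TERMS = ("slope_class", "geology", "substrate")
DEFAULT_TERMS = tuple(PREDICTOR_COLUMNS)

_ETA_CLIP = 30.0
_MU_EPS = 1e-12
_PROB_CLIP = 1e-12


class DegenerateSampleError(ValueError):
    """Training response is all-absence or all-presence; no model is fittable.

    Mirrors the untrainable case of a rare habitat entirely missing from a
    sampled stretch of coast; callers report it as a scenario with
    status="degenerate" rather than a failure.
    """


@dataclass
class DesignMatrix:
    """Dummy-coded design with intercept, aligned to a row index set."""

    matrix: np.ndarray          # (n, p) incl. leading intercept column
    columns: tuple              # names; columns[0] == "intercept"
    terms: tuple                # model terms the columns derive from
    ref_levels: dict            # categorical term -> reference level

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def _dummy_name(term: str, level) -> str:
    return f"{term}[{level}]"


def build_design(
    df: pd.DataFrame,
    terms: Sequence[str] = DEFAULT_TERMS,
    ref_levels: Mapping[str, object] | None = None,
) -> DesignMatrix:
    """Build an intercept + main-effects design matrix.

    Continuous terms enter as single columns. Categorical terms are
    dummy-coded against a reference level — by default the most frequent
    level in `df` (stabilises fits when a rare level barely occurs in a
    training split); pass `ref_levels` to pin references explicitly.
    Levels absent from `df` simply produce no column. Aliased (linearly
    dependent) columns are dropped with a warning.
    """
    refs = dict(ref_levels or {})
    cols = [np.ones(len(df))]
    names = ["intercept"]
    used_refs: dict = {}
    for term in terms:
        if term in CONTINUOUS_TERMS:
            cols.append(df[term].to_numpy(float))
            names.append(term)
        elif term in CATEGORICAL_TERMS:
            values = df[term]
            counts = values.value_counts()
            if term in refs and refs[term] in counts.index:
                ref = refs[term]
            else:
                ref = counts.index[0]  # most frequent level
            used_refs[term] = ref
            levels = sorted((l for l in counts.index if l != ref), key=str)
            for lev in levels:
                cols.append((values == lev).to_numpy(float))
                names.append(_dummy_name(term, lev))
        else:
            raise KeyError(f"unknown model term {term!r}")
    X = np.column_stack(cols)
    X, names = _drop_aliased(X, names)
    return DesignMatrix(X, tuple(names), tuple(terms), used_refs)


def _drop_aliased(X: np.ndarray, names: list) -> tuple:
    """Drop linearly dependent columns (pivoted QR), keeping the intercept."""
    if X.shape[1] <= 1:
        return X, names
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        keep = np.sort(piv[:rank])
        if 0 not in keep:  # never drop the intercept
            keep = np.sort(np.concatenate([[0], keep[:-1]]))
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"dropping aliased design columns: {dropped}")
        X = X[:, keep]
        names = [names[j] for j in keep]
    return X, names


def design_for(fit: "FittedHDM", df: pd.DataFrame) -> np.ndarray:
    """Rebuild the design of a fitted model on new rows (e.g. the test coast).

    Columns are reproduced by name from the fit, so the coding is identical
    to training. A categorical level unseen at training maps to the
    reference (all its dummies zero) with a warning.
    """
    n = len(df)
    out = np.empty((n, len(fit.columns)))
    seen_levels: dict = {}
    for j, name in enumerate(fit.columns):
        if name == "intercept":
            out[:, j] = 1.0
        elif "[" in name:
            term, lev = name[:-1].split("[", 1)
            if term not in df.columns:
                raise KeyError(f"test data missing term column {term!r}")
            vals = df[term].astype(str)
            out[:, j] = (vals == lev).to_numpy(float)
            seen_levels.setdefault(term, set()).add(lev)
        else:
            if name not in df.columns:
                raise KeyError(f"test data missing term column {name!r}")
            out[:, j] = df[name].to_numpy(float)
    for term, levs in seen_levels.items():
        train_levels = levs | {str(fit.ref_levels.get(term))}
        unseen = set(df[term].astype(str).unique()) - train_levels
        if unseen:
            warnings.warn(
                f"{term}: levels {sorted(unseen)} unseen at training; mapped to reference"
            )
    return out


@dataclass
class FittedHDM:
    """A fitted logistic habitat model and its fit statistics."""

    habitat: str
    selected: tuple                 # model terms in the final model
    columns: tuple                  # design column names incl. intercept
    coef: np.ndarray                # logit-scale coefficients, aligned to columns
    se: np.ndarray                  # asymptotic standard errors
    ref_levels: dict
    null_deviance: float
    residual_deviance: float
    aic: float
    d2: float
    converged: bool
    separation_flag: bool
    n_train: int
    train_prevalence: float

    def coef_dict(self) -> dict:
        return dict(zip(self.columns, self.coef.tolist()))

    def to_json(self) -> str:
        d = {
            "habitat": self.habitat,
            "selected": list(self.selected),
            "columns": list(self.columns),
            "coef": self.coef.tolist(),
            "se": self.se.tolist(),
            "ref_levels": {k: str(v) for k, v in self.ref_levels.items()},
            "null_deviance": self.null_deviance,
            "residual_deviance": self.residual_deviance,
            "aic": self.aic,
            "d2": self.d2,
            "converged": self.converged,
            "separation_flag": self.separation_flag,
            "n_train": self.n_train,
            "train_prevalence": self.train_prevalence,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FittedHDM":
        d = json.loads(text)
        d["selected"] = tuple(d["selected"])
        d["columns"] = tuple(d["columns"])
        d["coef"] = np.asarray(d["coef"], float)
        d["se"] = np.asarray(d["se"], float)
        return cls(**d)


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def null_deviance(y: np.ndarray) -> float:
    """Deviance of the intercept-only model (fitted prevalence)."""
    return _binomial_deviance(y, np.full(len(y), y.mean()))


def fit_logistic(
    X: DesignMatrix | np.ndarray,
    y: np.ndarray,
    habitat: str = "",
    max_iter: int = 50,
    tol: float = 1e-8,
    ridge: float = 1e-8,
) -> FittedHDM:
    """Maximum-likelihood logistic fit by IRLS.

    Convergence: |change in deviance| < `tol`, up to `max_iter` sweeps. A
    tiny ridge (`ridge` on the normal-equation diagonal) keeps the solve
    well-posed under quasi-separation — common when a rare habitat is
    nearly noise-free in a small training stretch; such fits are flagged
    via `separation_flag` (any standardized |coefficient| > 15) rather
    than refused.
    """
    if isinstance(X, DesignMatrix):
        dm = X
    else:
        Xa = np.asarray(X, float)
        names = ["intercept"] + [f"x{j}" for j in range(1, Xa.shape[1])]
        dm = DesignMatrix(Xa, tuple(names), tuple(names[1:]), {})
    y = np.asarray(y, float)
    if dm.matrix.shape[0] != len(y):
        raise ValueError("X rows and y length differ")
    s = y.sum()
    if s == 0 or s == len(y):
        raise DegenerateSampleError(
            f"response is constant ({'all-presence' if s else 'all-absence'})"
        )

    Xm = dm.matrix
    n, p = Xm.shape
    beta = np.zeros(p)
    # start from the intercept-only optimum
    beta[0] = np.log(y.mean() / (1 - y.mean()))
    dev = np.inf
    converged = False
    for _ in range(max_iter):
        eta = np.clip(Xm @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        Xw = Xm * w[:, None]
        A = Xm.T @ Xw
        A[np.diag_indices_from(A)] += ridge
        beta = np.linalg.solve(A, Xw.T @ z)
        new_dev = _binomial_deviance(y, expit(np.clip(Xm @ beta, -_ETA_CLIP, _ETA_CLIP)))
        if abs(dev - new_dev) < tol:
            dev = new_dev
            converged = True
            break
        dev = new_dev

    eta = np.clip(Xm @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    A = Xm.T @ (Xm * w[:, None])
    A[np.diag_indices_from(A)] += ridge
    cov = np.linalg.inv(A)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))

    # separation check on an internally standardized scale
    scale = np.ones(p)
    for j, name in enumerate(dm.columns):
        if name in CONTINUOUS_TERMS:
            sd = Xm[:, j].std()
            scale[j] = sd if sd > 0 else 1.0
    separation = bool(np.any(np.abs(beta[1:] * scale[1:]) > 15.0))

    nd = null_deviance(y)
    d2 = 0.0 if nd == 0 else (nd - dev) / nd * 100.0
    return FittedHDM(
        habitat=habitat,
        selected=dm.terms,
        columns=dm.columns,
        coef=beta,
        se=se,
        ref_levels=dict(dm.ref_levels),
        null_deviance=nd,
        residual_deviance=dev,
        aic=dev + 2 * p,
        d2=float(np.clip(d2, 0.0, 100.0)),
        converged=converged,
        separation_flag=separation,
        n_train=n,
        train_prevalence=float(y.mean()),
    )


def select_model_aic(
    candidates: Sequence[str],
    df: pd.DataFrame,
    y: np.ndarray,
    habitat: str = "",
    ref_levels: Mapping[str, object] | None = None,
) -> FittedHDM:
    """Exhaustive best-subset search over candidate terms, minimising AIC.

    Every subset of `candidates` (categoricals as whole dummy blocks) is
    fitted; the minimum-AIC fit wins. Ties break toward fewer terms, then
    lexicographic term order. With at most 12 candidates the search is a
    few thousand IRLS fits.
    """
    candidates = tuple(candidates)
    if len(candidates) > 12:
        raise ValueError("more than 12 candidate terms; exhaustive search refused")
    best = None
    best_key = None
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            dm = build_design(df, subset, ref_levels)
            fit = fit_logistic(dm, y, habitat=habitat)
            key = (fit.aic, len(subset), subset)
            if best_key is None or key < best_key:
                best, best_key = fit, key
    assert best is not None
    best.selected = tuple(best_key[2])
    return best


def explained_deviance(fit: FittedHDM) -> float:
    """D^2 = (null deviance - residual deviance) / null deviance x 100."""
    if fit.null_deviance == 0:
        raise ValueError("null deviance is zero (constant response)")
    return (fit.null_deviance - fit.residual_deviance) / fit.null_deviance * 100.0


def predict_prob(fit: FittedHDM, df_test: pd.DataFrame) -> np.ndarray:
    """Predicted presence probabilities on new rows, clipped into (0, 1)."""
    X = design_for(fit, df_test)
    p = expit(X @ fit.coef)
    return np.clip(p, _PROB_CLIP, 1 - _PROB_CLIP)
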