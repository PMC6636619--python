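"""Pheno-climatic models: OLS with sequential variance partitioning.

Two multiple linear regressions of collection day of year (DOY) are the
workhorses:

* Model 1 (climate only):      DOY ~ winter_ppt_mm + spring_tmax_c
* Model 2 (climate + stage):   DOY ~ pi + winter_ppt_mm + spring_tmax_c

Each fit reports ordinary-least-squares coefficients with standard errors,
a sequential (Type I) analysis-of-variance table in which terms enter in
the ModelSpec's order, R², a small-sample corrected AIC, and the
proportions of total variance attributable to each term and to error.
Predictive power is assessed by seeded k-fold cross-validation.

Conventions
-----------
* Sequential F ratios use the full model's error mean square as
  denominator, so the table reproduces what fixed-model ANOVA software
  prints.
* AICc counts parameters as k = p + 2 for p slope terms: the intercept and
  the Gaussian error variance are estimated too.  AICc conventions differ
  by additive constants across software; this one includes the full
  Gaussian log-likelihood (constants and all).
* Per-fold cross-validated R² uses the held-out fold's own response mean as
  the baseline by default (``baseline="fold"``); ``baseline="train"`` uses
  the training mean instead.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import PhenoclimError


class ModelError(PhenoclimError):
    """Raised for unusable model specifications or data."""


class CollinearityError(ModelError):
    """Raised when the design matrix is rank deficient."""


@dataclass(frozen=True)
class ModelSpec:
    """An ordered linear-model specification.

    Term order matters: it fixes the order in which sequential sums of
    squares are attributed.
    """

    terms: tuple[str, ...]
    response: str = "doy"
    include_intercept: bool = True

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ModelError(f"duplicate terms in model spec: {self.terms}")


#: The two models of the framework, in their canonical term order.
MODEL1 = ModelSpec(terms=("winter_ppt_mm", "spring_tmax_c"))
MODEL2 = ModelSpec(terms=("pi", "winter_ppt_mm", "spring_tmax_c"))


@dataclass
class SeqAnovaRow:
    term: str
    df: int
    ss: float
    f_ratio: float
    p_value: float


@dataclass
class PCMFit:
    """A fitted pheno-climatic model with its ANOVA and information criteria."""

    spec: ModelSpec
    intercept: float
    intercept_se: float
    coefficients: dict[str, tuple[float, float]]  # term -> (estimate, SE)
    seq_anova: list[SeqAnovaRow]
    sse: float
    sst: float
    r2: float
    aicc: float
    aic: float
    loglik: float
    n: int
    df_error: int
    cov_params: np.ndarray = field(repr=False)  # order: [intercept?, *terms]
    term_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    term_means: dict[str, float] = field(default_factory=dict)
    response_mean: float = float("nan")

    @property
    def mse(self) -> float:
        return self.sse / self.df_error

    @property
    def design_columns(self) -> list[str]:
        cols = ["<intercept>"] if self.spec.include_intercept else []
        return cols + list(self.spec.terms)

    def params_vector(self) -> np.ndarray:
        vals = [self.intercept] if self.spec.include_intercept else []
        vals += [self.coefficients[t][0] for t in self.spec.terms]
        return np.asarray(vals)

    # -- serialisation (used by the CLI to save/reload fits) ---------------

    def to_dict(self) -> dict:
        return {
            "spec": {
                "terms": list(self.spec.terms),
                "response": self.spec.response,
                "include_intercept": self.spec.include_intercept,
            },
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "coefficients": {t: list(v) for t, v in self.coefficients.items()},
            "seq_anova": [asdict(r) for r in self.seq_anova],
            "sse": self.sse,
            "sst": self.sst,
            "r2": self.r2,
            "aicc": self.aicc,
            "aic": self.aic,
            "loglik": self.loglik,
            "n": self.n,
            "df_error": self.df_error,
            "cov_params": self.cov_params.tolist(),
            "term_ranges": {t: list(v) for t, v in self.term_ranges.items()},
            "term_means": self.term_means,
            "response_mean": self.response_mean,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PCMFit":
        return cls(
            spec=ModelSpec(
                terms=tuple(d["spec"]["terms"]),
                response=d["spec"]["response"],
                include_intercept=d["spec"]["include_intercept"],
            ),
            intercept=d["intercept"],
            intercept_se=d["intercept_se"],
            coefficients={t: tuple(v) for t, v in d["coefficients"].items()},
            seq_anova=[SeqAnovaRow(**r) for r in d["seq_anova"]],
            sse=d["sse"],
            sst=d["sst"],
            r2=d["r2"],
            aicc=d["aicc"],
            aic=d["aic"],
            loglik=d["loglik"],
            n=d["n"],
            df_error=d["df_error"],
            cov_params=np.asarray(d["cov_params"]),
            term_ranges={t: tuple(v) for t, v in d["term_ranges"].items()},
            term_means=d["term_means"],
            response_mean=d["response_mean"],
        )

    @classmethod
    def from_json(cls, path) -> "PCMFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class CVResult:
    """k-fold cross-validation summary."""

    k: int
    seed: int
    per_fold_r2: list[float]
    baseline: str = "fold"

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.per_fold_r2))


# ---------------------------------------------------------------------------
# Fitting


def _design(spec: ModelSpec, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in (spec.response, *spec.terms) if c not in data.columns]
    if missing:
        raise ModelError(f"data lacks required columns {missing}")
    used = data[[spec.response, *spec.terms]]
    if used.isna().any().any():
        raise ModelError("missing values in model columns; drop or impute upstream")
    y = used[spec.response].to_numpy(dtype=float)
    X = used[list(spec.terms)].to_numpy(dtype=float)
    if spec.include_intercept:
        X = np.column_stack([np.ones(len(y)), X])
    return y, X


def _check_rank(X: np.ndarray, columns: Sequence[str]) -> None:
    """Identify the first design column linearly dependent on its predecessors."""
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    for j in range(1, X.shape[1] + 1):
        if np.linalg.matrix_rank(X[:, :j]) < j:
            raise CollinearityError(
                f"design is rank deficient: column {columns[j - 1]!r} is linearly "
                f"dependent on the preceding columns"
            )


def fit(spec: ModelSpec, data: pd.DataFrame) -> PCMFit:
    """Ordinary least squares with sequential (Type I) sums of squares.

    Terms are added in ``spec.terms`` order; the SS attributed to each term
    is the drop in residual SS when it enters.  F ratios test each term's
    SS against the full model's error mean square.
    """
    y, X = _design(spec, data)
    n, ncols = X.shape
    if n <= ncols + 1:
        raise ModelError(f"need n > p + 1 observations (n={n}, p={ncols})")
    _check_rank(X, ["<intercept>"] * spec.include_intercept + list(spec.terms))

    res = sm.OLS(y, X).fit()
    sse = float(res.ssr)
    if spec.include_intercept:
        sst = float(np.sum((y - y.mean()) ** 2))
        base_sse = sst
    else:
        sst = float(np.sum(y**2))
        base_sse = sst
    df_error = n - ncols

    # sequential SS by nested refits: SS(term_i) = SSE(model with terms<i) - SSE(<=i)
    seq_rows: list[SeqAnovaRow] = []
    prev_sse = base_sse
    mse_full = sse / df_error
    for i, term in enumerate(spec.terms, start=1):
        cols = ([0] if spec.include_intercept else []) + list(
            range(int(spec.include_intercept), int(spec.include_intercept) + i)
        )
        sub = sm.OLS(y, X[:, cols]).fit()
        ss = prev_sse - float(sub.ssr)
        prev_sse = float(sub.ssr)
        f_ratio = (ss / 1.0) / mse_full
        p = float(stats.f.sf(f_ratio, 1, df_error)) if f_ratio >= 0 else float("nan")
        seq_rows.append(SeqAnovaRow(term=term, df=1, ss=ss, f_ratio=f_ratio, p_value=p))

    params = res.params
    bse = res.bse
    offset = int(spec.include_intercept)
    coefficients = {
        term: (float(params[offset + j]), float(bse[offset + j]))
        for j, term in enumerate(spec.terms)
    }
    r2 = 1.0 - sse / sst
    loglik = float(res.llf)
    k = ncols + 1  # + error variance
    aic = -2.0 * loglik + 2.0 * k
    if n - k - 1 <= 0:
        raise ModelError(f"AICc undefined: n={n} too small for k={k} parameters")
    aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)

    return PCMFit(
        spec=spec,
        intercept=float(params[0]) if spec.include_intercept else 0.0,
        intercept_se=float(bse[0]) if spec.include_intercept else 0.0,
        coefficients=coefficients,
        seq_anova=seq_rows,
        sse=sse,
        sst=sst,
        r2=r2,
        aicc=aicc,
        aic=aic,
        loglik=loglik,
        n=n,
        df_error=df_error,
        cov_params=np.asarray(res.cov_params()),
        term_ranges={
            t: (float(data[t].min()), float(data[t].max())) for t in spec.terms
        },
        term_means={t: float(data[t].mean()) for t in spec.terms},
        response_mean=float(np.mean(y)),
    )


def aicc(fit_result: PCMFit) -> float:
    """Small-sample corrected AIC of a fit (k counts intercept + error variance)."""
    return fit_result.aicc


def variance_partition(fit_result: PCMFit) -> list[tuple[str, float]]:
    """Proportion of total variance per sequential term, plus the error share.

    Proportions sum to one: SS(term)/SST for each term in entry order and
    SSE/SST for "error".
    """
    parts = [(row.term, row.ss / fit_result.sst) for row in fit_result.seq_anova]
    parts.append(("error", fit_result.sse / fit_result.sst))
    return parts


# ---------------------------------------------------------------------------
# Cross-validation


def kfold_cv(
    spec: ModelSpec,
    data: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    baseline: str = "fold",
) -> CVResult:
    """Seeded k-fold cross-validation of a model's predictive R².

    The rows are randomly permuted with ``seed`` and split into k near-equal
    folds (remainders spread one per fold).  Each fold is predicted from a
    fit on its complement; the per-fold R² is 1 - SS_resid/SS_baseline with
    the baseline mean taken from the held-out fold itself (default) or from
    the training rows (``baseline="train"``).
    """
    n = len(data)
    if k < 2:
        raise ModelError(f"k must be at least 2, got {k}")
    if n < 2 * k:
        raise ModelError(f"need n >= 2k rows for {k}-fold CV, got n={n}")
    if baseline not in ("fold", "train"):
        raise ModelError(f"baseline must be 'fold' or 'train', got {baseline!r}")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)

    data = data.reset_index(drop=True)
    per_fold: list[float] = []
    for fold_idx in folds:
        mask = np.zeros(n, dtype=bool)
        mask[fold_idx] = True
        train, test = data[~mask], data[mask]
        f = fit(spec, train)
        y_true = test[spec.response].to_numpy(dtype=float)
        y_hat = predict(f, test)
        base_mean = y_true.mean() if baseline == "fold" else train[spec.response].mean()
        ss_res = float(np.sum((y_true - y_hat) ** 2))
        ss_base = float(np.sum((y_true - base_mean) ** 2))
        per_fold.append(1.0 - ss_res / ss_base)
    return CVResult(k=k, seed=seed, per_fold_r2=per_fold, baseline=baseline)


def predict(fit_result: PCMFit, data: pd.DataFrame) -> np.ndarray:
    """Linear-predictor evaluation for each row of ``data``."""
    X = data[list(fit_result.spec.terms)].to_numpy(dtype=float)
    if fit_result.spec.include_intercept:
        X = np.column_stack([np.ones(len(X)), X])
    return X @ fit_result.params_vector()


# ---------------------------------------------------------------------------
# Model comparison


@dataclass
class ComparisonReport:
    """How much a second model improves on a first fitted to the same data."""

    r2_a: float
    r2_b: float
    delta_r2: float
    relative_r2_gain: float  # r2_b / r2_a - 1
    aicc_a: float
    aicc_b: float
    delta_aicc: float  # b - a; negative favours b
    relative_error_ratio: float  # sse_a / sse_b - 1

    def summary(self) -> str:
        return (
            f"R² {self.r2_a:.2f} -> {self.r2_b:.2f} "
            f"({100 * self.relative_r2_gain:.0f}% more variation explained); "
            f"AICc {self.aicc_a:.2f} -> {self.aicc_b:.2f} (Δ {self.delta_aicc:+.2f}); "
            f"error variance {100 * self.relative_error_ratio:.0f}% higher without "
            f"the second model's terms"
        )


def compare(fit_a: PCMFit, fit_b: PCMFit) -> ComparisonReport:
    """Compare two fits of the same response on the same data (a = baseline)."""
    if fit_a.n != fit_b.n:
        raise ModelError(f"fits use different n ({fit_a.n} vs {fit_b.n})")
    if fit_a.spec.response != fit_b.spec.response:
        raise ModelError("fits model different responses")
    return ComparisonReport(
        r2_a=fit_a.r2,
        r2_b=fit_b.r2,
        delta_r2=fit_b.r2 - fit_a.r2,
        relative_r2_gain=fit_b.r2 / fit_a.r2 - 1.0 if fit_a.r2 != 0 else math.inf,
        aicc_a=fit_a.aicc,
        aicc_b=fit_b.aicc,
        delta_aicc=fit_b.aicc - fit_a.aicc,
        relative_error_ratio=fit_a.sse / fit_b.sse - 1.0,
    )


# ---------------------------------------------------------------------------
# Reporting


def fit_report(fit_result: PCMFit) -> str:
    """Plain-text report mirroring a fixed-model ANOVA table layout."""
    lines = [
        f"Model: {fit_result.spec.response} ~ "
        + " + ".join(fit_result.spec.terms)
        + ("  (+ intercept)" if fit_result.spec.include_intercept else ""),
        f"n = {fit_result.n}",
        "",
        f"{'Source':<20}{'df':>4}{'Seq SS':>14}{'F ratio':>10}{'P value':>10}",
    ]
    for row in fit_result.seq_anova:
        p = f"{row.p_value:.3g}" if row.p_value >= 1e-4 else "<1e-4"
        lines.append(f"{row.term:<20}{row.df:>4}{row.ss:>14.1f}{row.f_ratio:>10.2f}{p:>10}")
    lines.append(f"{'Error':<20}{fit_result.df_error:>4}{fit_result.sse:>14.1f}")
    lines += [
        f"R²    {fit_result.r2:.4f}",
        f"AICc  {fit_result.aicc:.2f}",
        "",
        f"{'Term':<20}{'Estimate':>12}{'SE':>10}",
    ]
    if fit_result.spec.include_intercept:
        lines.append(f"{'Intercept':<20}{fit_result.intercept:>12.4f}{fit_result.intercept_se:>10.4f}")
    for term, (est, se) in fit_result.coefficients.items():
        lines.append(f"{term:<20}{est:>12.4f}{se:>10.4f}")
    lines.append("")
    lines.append("Variance partition:")
    for name, prop in variance_partition(fit_result):
        lines.append(f"  {name:<18}{100 * prop:>7.2f}%")
    return "\n".join(lines)
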