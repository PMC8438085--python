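"""Environmental drivers of inter-compartment link strength.

For each significant consensus link, the per-farm link strengths are regressed
on farm covariates through a fixed chain: redundancy filtering of collinear
covariates, shadow-feature random-forest selection, bidirectional stepwise OLS
minimizing AIC over linear, quadratic and interaction terms, followed by
standardized coefficients, a sequential variance decomposition and quadratic
optima x* = -b1/(2 b2) for concave retained pairs (x, x^2).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestRegressor

#: covariate pool used when a covariate table carries the standard column names
DEFAULT_CANDIDATE_POOL = [
    "Elevation",
    "Cattle_spring",
    "Cattle_summer",
    "Total_manure",
    "C_org",
    "pH",
    "Clay",
    "Grass",
    "SpRichness",
    "Dairy_cows",
    "Milking_preparation",
    "Cow-teat_care",
]


# ---------------------------------------------------------------------------
# covariate screening


def redundancy_filter(X: pd.DataFrame, threshold: float = 0.6) -> list[str]:
    """Drop strongly redundant quantitative covariates.

    Iteratively removes the variable with the largest mean absolute correlation
    among pairs violating |r| >= threshold, until every retained quantitative
    pair satisfies |r| < threshold. Categorical (non-numeric) columns are
    always retained.
    """
    quant = [c for c in X.columns if np.issubdtype(X[c].dtype, np.number)]
    cat = [c for c in X.columns if c not in quant]
    keep = list(quant)
    while len(keep) > 1:
        corr = X[keep].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        violating = corr >= threshold
        if not violating.any():
            break
        viol_counts = violating.sum(axis=1)
        viol_sums = np.where(violating, corr, 0.0).sum(axis=1)
        scores = np.where(
            viol_counts > 0, viol_sums / np.maximum(viol_counts, 1), -np.inf
        )
        # ties resolved toward dropping the later column
        drop = int(np.flatnonzero(scores == scores.max())[-1])
        keep.pop(drop)
    return [c for c in X.columns if c in keep or c in cat]


def dummy_code(X: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code categorical columns (reference level = first alphabetically)."""
    out = {}
    for col in X.columns:
        if np.issubdtype(X[col].dtype, np.number):
            out[col] = X[col].astype(float)
        else:
            levels = sorted(X[col].astype(str).unique())
            for level in levels[1:]:
                out[f"{col}[{level}]"] = (X[col].astype(str) == level).astype(float)
    return pd.DataFrame(out, index=X.index)


@dataclass
class ShadowSelection:
    confirmed: list[str]
    tentative: list[str]
    rejected: list[str]
    hits: dict[str, int]
    n_iter: int

    @property
    def retained(self) -> list[str]:
        """Confirmed plus tentative variables (tentative kept, conservatively)."""
        return self.confirmed + self.tentative


def shadow_select(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    n_iter: int = 100,
    n_trees: int = 500,
    seed: int | None = 0,
    alpha: float = 0.05,
    n_shadow_copies: int = 3,
) -> ShadowSelection:
    """Shadow-attribute random-forest variable selection.

    Each iteration appends ``n_shadow_copies`` independently permuted copies
    (shadows) of every column, fits a random-forest regressor, and scores a
    hit for every real variable whose importance exceeds the maximum shadow
    importance. Variables are confirmed or rejected by a two-sided binomial
    test (p = 0.5) on the hit count at a Bonferroni-adjusted level
    ``alpha / n_variables``; variables left undecided after ``n_iter``
    iterations are tentative. The enlarged shadow ensemble raises the
    maximum-shadow bar, which keeps sample-specific chance associations from
    being confirmed at small n while leaving genuine signal (which dominates
    every shadow) untouched.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 15:
        raise ValueError("shadow selection needs at least 15 rows")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    rng = np.random.default_rng(seed)
    hits = np.zeros(p, dtype=int)
    for _ in range(n_iter):
        shadows = []
        for _copy in range(n_shadow_copies):
            shadow = Xv.copy()
            for j in range(p):
                rng.shuffle(shadow[:, j])
            shadows.append(shadow)
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(np.hstack([Xv] + shadows), y)
        imp = rf.feature_importances_
        hits += imp[:p] > imp[p:].max()

    adj_alpha = alpha / p
    confirmed, tentative, rejected = [], [], []
    for j, col in enumerate(X.columns):
        pv = binomtest(int(hits[j]), n_iter, 0.5).pvalue
        if pv < adj_alpha and hits[j] > n_iter / 2:
            confirmed.append(col)
        elif pv < adj_alpha and hits[j] < n_iter / 2:
            rejected.append(col)
        else:
            tentative.append(col)
    return ShadowSelection(
        confirmed=confirmed,
        tentative=tentative,
        rejected=rejected,
        hits={c: int(h) for c, h in zip(X.columns, hits)},
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# design matrix


def build_candidates(
    X: pd.DataFrame, variables: Sequence[str]
) -> pd.DataFrame:
    """Candidate term columns for stepwise selection.

    Quantitative variables contribute a linear and a squared term; dummy
    columns (named ``var[level]``) contribute their indicator only. Every
    unordered pair of distinct quantitative variables contributes the four
    interaction products of their linear/squared columns (including
    squared x squared). Zero-variance columns are dropped.
    """
    cols: dict[str, np.ndarray] = {}
    quant = [v for v in variables if "[" not in v]
    for v in variables:
        cols[v] = X[v].to_numpy(dtype=float)
    for v in quant:
        cols[f"{v}^2"] = X[v].to_numpy(dtype=float) ** 2
    for v1, v2 in itertools.combinations(quant, 2):
        for t1 in (v1, f"{v1}^2"):
            for t2 in (v2, f"{v2}^2"):
                cols[f"{t1}:{t2}"] = cols[t1] * cols[t2]
    out = pd.DataFrame(cols, index=X.index)
    keep = [c for c in out.columns if np.ptp(out[c].to_numpy()) > 0]
    return out[keep]


# ---------------------------------------------------------------------------
# stepwise OLS


def _aic(y: np.ndarray, design: np.ndarray) -> float:
    """AIC = n ln(RSS/n) + 2(k+1), for an OLS fit with intercept and k terms."""
    n = len(y)
    X = np.column_stack([np.ones(n), design]) if design.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * X.shape[1]


@dataclass
class StepwiseResult:
    terms: list[str]  # in entry order
    aic: float
    aic_path: list[float]
    intercept_only: bool


def stepwise_aic(
    y: pd.Series | np.ndarray,
    candidates: pd.DataFrame,
    direction: str = "both",
    tol: float = 1e-8,
) -> StepwiseResult:
    """Bidirectional stepwise OLS term selection minimizing AIC.

    Starts from the intercept-only model; at each step the single addition or
    removal with the lowest AIC is taken if it improves on the current AIC,
    ties broken toward the smaller model. No marginality constraint is
    imposed: squared or interaction terms may enter without their parents.
    """
    if direction not in ("both", "forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    yv = np.asarray(y, dtype=float)
    if len(yv) < 10:
        raise ValueError("stepwise selection needs at least 10 rows")
    arr = {c: candidates[c].to_numpy(dtype=float) for c in candidates.columns}
    current: list[str] = [] if direction != "backward" else list(candidates.columns)
    cur_aic = _aic(yv, np.column_stack([arr[t] for t in current]) if current else np.empty((len(yv), 0)))
    path = [cur_aic]
    while True:
        moves: list[tuple[float, int, tuple[str, str]]] = []
        if direction in ("both", "forward"):
            for cand in candidates.columns:
                if cand in current:
                    continue
                trial = current + [cand]
                moves.append(
                    (_aic(yv, np.column_stack([arr[t] for t in trial])), len(trial), ("add", cand))
                )
        if direction in ("both", "backward"):
            for term in current:
                trial = [t for t in current if t != term]
                design = (
                    np.column_stack([arr[t] for t in trial])
                    if trial
                    else np.empty((len(yv), 0))
                )
                moves.append((_aic(yv, design), len(trial), ("drop", term)))
        if not moves:
            break
        # smallest AIC; ties toward the smaller model
        moves.sort(key=lambda m: (round(m[0] / tol) * tol, m[1]))
        best_aic, _, (kind, term) = moves[0]
        if best_aic < cur_aic - tol:
            if kind == "add":
                current.append(term)
            else:
                current.remove(term)
            cur_aic = best_aic
            path.append(cur_aic)
        else:
            break
    return StepwiseResult(
        terms=current, aic=cur_aic, aic_path=path, intercept_only=not current
    )


# ---------------------------------------------------------------------------
# post-fit summaries


@dataclass
class FittedModel:
    """OLS fit of the stepwise-selected terms on the raw covariate scale."""

    terms: list[str]
    design: pd.DataFrame  # columns in entry order
    y: pd.Series
    coefs: dict[str, float]
    intercept: float
    r_squared: float
    r_squared_adj: float
    model_p_value: float
    intercept_only: bool


def fit_selected(y: pd.Series, candidates: pd.DataFrame, selection: StepwiseResult) -> FittedModel:
    design = candidates[selection.terms]
    X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    coefs = {t: float(b) for t, b in zip(selection.terms, res.params[1:])}
    p = float(res.f_pvalue) if selection.terms and not math.isnan(res.f_pvalue) else 1.0
    return FittedModel(
        terms=list(selection.terms),
        design=design,
        y=pd.Series(np.asarray(y, dtype=float), index=candidates.index),
        coefs=coefs,
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared) if selection.terms else 0.0,
        r_squared_adj=float(res.rsquared_adj) if selection.terms else 0.0,
        model_p_value=p,
        intercept_only=selection.intercept_only,
    )


def standardize_coefficients(model: FittedModel) -> dict[str, float]:
    """beta_std = beta * sd(term) / sd(y); squared and interaction columns are
    standardized as whole columns."""
    sdy = float(np.std(model.y, ddof=1))
    if sdy == 0:
        raise ValueError("response has zero variance")
    return {
        t: model.coefs[t] * float(np.std(model.design[t], ddof=1)) / sdy
        for t in model.terms
    }


def variance_decomposition(
    model: FittedModel, method: str = "sequential", n_orderings: int = 100, seed: int = 0
) -> tuple[dict[str, float], float]:
    """Per-term variance percentages plus the residual percentage.

    ``sequential`` uses Type-I sums of squares in stepwise entry order;
    ``averaged`` averages the sequential shares over term orderings (all
    orderings up to 7 terms, a seeded sample beyond).
    """
    yv = model.y.to_numpy(dtype=float)
    tss = float(np.sum((yv - yv.mean()) ** 2))
    if tss == 0:
        raise ValueError("response has zero variance")
    if not model.terms:
        return {}, 100.0

    def seq_shares(order: Sequence[str]) -> dict[str, float]:
        shares = {}
        prev_rss = tss
        cols: list[np.ndarray] = []
        for t in order:
            cols.append(model.design[t].to_numpy(dtype=float))
            X = np.column_stack([np.ones(len(yv))] + cols)
            beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
            rss = float(np.sum((yv - X @ beta) ** 2))
            shares[t] = 100.0 * (prev_rss - rss) / tss
            prev_rss = rss
        return shares

    if method == "sequential":
        shares = seq_shares(model.terms)
    elif method == "averaged":
        k = len(model.terms)
        if k <= 7:
            orderings = list(itertools.permutations(model.terms))
        else:
            rng = np.random.default_rng(seed)
            orderings = [
                list(rng.permutation(model.terms)) for _ in range(n_orderings)
            ]
        acc = {t: 0.0 for t in model.terms}
        for order in orderings:
            for t, s in seq_shares(order).items():
                acc[t] += s
        shares = {t: v / len(orderings) for t, v in acc.items()}
    else:
        raise ValueError(f"unknown variance method {method!r}")
    residual = 100.0 - sum(shares.values())
    return shares, residual


@dataclass
class QuadraticOptimum:
    variable: str
    x_star: float | None
    kind: str  # "maximum" | "minimum" | "none"
    interior_maximum: bool


def quadratic_optimum(
    b_lin: float, b_sq: float, observed_range: tuple[float, float] | None = None
) -> QuadraticOptimum:
    """Vertex x* = -b_lin / (2 b_sq) of a fitted quadratic response.

    Reported as an interior maximum only when the curvature is negative and,
    if an observed range is given, the vertex lies inside it.
    """
    if b_sq == 0:
        return QuadraticOptimum("", None, "none", False)
    x_star = -b_lin / (2.0 * b_sq)
    if b_sq > 0:
        return QuadraticOptimum("", x_star, "minimum", False)
    interior = observed_range is None or (
        observed_range[0] <= x_star <= observed_range[1]
    )
    return QuadraticOptimum("", x_star, "maximum", interior)


def _partial_coefficients(
    model: FittedModel, candidates: pd.DataFrame, var: str
) -> tuple[float, float]:
    """Effective linear/quadratic coefficients of ``var`` by partial derivation.

    Interaction terms retained in the model contribute to the derivative with
    their partner factor fixed at its sample mean, so the reported optimum
    refers to an otherwise-average farm rather than one with partners at zero.
    """
    lin, sq = var, f"{var}^2"
    b1, b2 = model.coefs[lin], model.coefs[sq]
    for term, coef in model.coefs.items():
        if ":" not in term:
            continue
        a, b = term.split(":", 1)
        for factor, partner in ((a, b), (b, a)):
            partner_mean = float(candidates[partner].mean())
            if factor == lin:
                b1 += coef * partner_mean
            elif factor == sq:
                b2 += coef * partner_mean
    return b1, b2


# ---------------------------------------------------------------------------
# full chain


def link_driver_analysis(
    link_strengths: pd.Series,
    covariates: pd.DataFrame,
    link_name: str = "",
    redundancy_threshold: float = 0.6,
    shadow_iters: int = 100,
    rf_trees: int = 500,
    variance_method: str = "sequential",
    aic_direction: str = "both",
    seed: int | None = 0,
    tentative_policy: str = "drop",
) -> dict:
    """Full driver analysis for one consensus link.

    ``link_strengths`` is the per-farm link weight (index = farm id);
    ``covariates`` the farm covariate table (index = farm id). Farms with an
    undefined link strength are dropped; at least 15 must remain. When the
    covariate table carries the standard column names, the analysis restricts
    to the default candidate pool up front.

    ``tentative_policy`` controls what enters the regression stage: only
    shadow-confirmed variables (``"drop"``, the default — keeps the chain's
    null false-positive rate low at small n) or confirmed plus tentative
    (``"keep"``).
    """
    y = link_strengths.dropna()
    if len(y) < 15:
        raise ValueError(f"only {len(y)} farms with a defined link strength (< 15)")
    X = covariates.loc[y.index]
    if all(c in X.columns for c in DEFAULT_CANDIDATE_POOL):
        X = X[DEFAULT_CANDIDATE_POOL]

    retained = redundancy_filter(X, threshold=redundancy_threshold)
    Xr = dummy_code(X[retained])
    Xr = Xr[[c for c in Xr.columns if np.ptp(Xr[c].to_numpy()) > 0]]

    if tentative_policy not in ("drop", "keep"):
        raise ValueError(f"unknown tentative policy {tentative_policy!r}")
    sel = shadow_select(
        Xr, y, n_iter=shadow_iters, n_trees=rf_trees, seed=seed
    )
    selected = sel.confirmed if tentative_policy == "drop" else sel.retained
    report: dict = {
        "link": link_name,
        "n_farms": int(len(y)),
        "redundancy_retained": retained,
        "shadow_confirmed": sel.confirmed,
        "shadow_tentative": sel.tentative,
    }
    if not selected:
        report.update(
            terms=[], residual_pct=100.0, r_squared=0.0, r_squared_adj=0.0,
            model_p_value=1.0, optima=[], intercept=float(np.mean(y)),
            intercept_only=True,
        )
        return report

    candidates = build_candidates(Xr, selected)
    selection = stepwise_aic(y, candidates, direction=aic_direction)
    model = fit_selected(y, candidates, selection)
    beta_std = standardize_coefficients(model) if model.terms else {}
    shares, residual = variance_decomposition(
        model, method=variance_method, seed=seed or 0
    )

    optima = []
    for var in selected:
        if "[" in var:
            continue
        lin, sq = var, f"{var}^2"
        if lin in model.coefs and sq in model.coefs:
            b1, b2 = _partial_coefficients(model, candidates, var)
            rng_obs = (float(Xr[var].min()), float(Xr[var].max()))
            opt = quadratic_optimum(b1, b2, rng_obs)
            if opt.kind == "maximum":
                optima.append(
                    {
                        "variable": var,
                        "x_star": opt.x_star,
                        "interior_maximum": opt.interior_maximum,
                    }
                )

    report.update(
        terms=[
            {
                "name": t,
                "coef": model.coefs[t],
                "coef_std": beta_std[t],
                "variance_pct": shares[t],
            }
            for t in model.terms
        ],
        residual_pct=residual,
        r_squared=model.r_squared,
        r_squared_adj=model.r_squared_adj,
        model_p_value=model.model_p_value,
        optima=optima,
        intercept=model.intercept,
        intercept_only=model.intercept_only,
    )
    return report
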