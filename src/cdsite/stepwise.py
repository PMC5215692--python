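"""Forward-stepwise logistic regression with interaction screening.

The fitting engine is plain maximum likelihood by iteratively reweighted
least squares (IRLS).  Model search is classic forward selection with
backward pruning: at each step the candidate whose addition gives the
smallest likelihood-ratio-test p-value below ``p_enter`` joins the model,
then any included term whose removal LRT p-value exceeds ``p_remove`` is
dropped; the procedure stops when neither move applies.  Ties are broken
by candidate order, then lexicographic term name, so the path is
deterministic.

Markers can be coded as dosage {0,1,2} (dose-response) or carrier {0,1};
the coding is the caller's choice and travels with the design columns.
Complete separation is detected and flagged rather than left to blow up
the coefficients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MAX_ITER = 50
TOL = 1e-8
SEPARATION_COEF = 15.0  # |beta| beyond this on a 0/1/2 scale means separation

Z95 = 1.959963984540054


class DesignError(ValueError):
    """Unusable design matrix (rank deficiency, constant column...)."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit."""

    terms: tuple[str, ...]  # including "intercept" first
    coef: np.ndarray
    bse: np.ndarray
    loglik: float
    n_used: int
    converged: bool
    separation: bool = False

    def coef_for(self, term: str) -> float:
        return float(self.coef[self.terms.index(term)])

    def odds_ratios(self) -> pd.DataFrame:
        """Per-term OR = exp(coef) with Wald 95% CI."""
        rows = []
        for i, t in enumerate(self.terms):
            if t == "intercept":
                continue
            rows.append(
                (
                    t,
                    float(self.coef[i]),
                    math.exp(self.coef[i]),
                    math.exp(self.coef[i] - Z95 * self.bse[i]),
                    math.exp(self.coef[i] + Z95 * self.bse[i]),
                )
            )
        return pd.DataFrame(rows, columns=["term", "coef", "odds_ratio", "ci_low", "ci_high"])


def _check_design(X: np.ndarray, names: list[str]) -> None:
    n, k = X.shape
    if n <= k:
        raise DesignError(f"{n} subjects for {k} terms: underdetermined")
    for j, name in enumerate(names):
        if name != "intercept" and np.ptp(X[:, j]) == 0:
            raise DesignError(f"term {name!r} is constant")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        # name the collinear columns via QR pivoting on the correlation structure
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(k) if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise DesignError(f"design is rank-deficient; collinear term(s): {bad or names}")


def fit_logistic(
    design: pd.DataFrame | np.ndarray,
    outcome: np.ndarray,
    add_intercept: bool = True,
) -> LogisticFit:
    """Fit P(y=1) = logistic(X beta) by IRLS.

    ``design`` holds the non-intercept terms; an intercept column is
    prepended unless ``add_intercept`` is False.  Convergence is declared
    when the largest coefficient change drops below 1e-8, within 50
    iterations.  Complete or quasi-complete separation is flagged and the
    coefficients of the last numerically stable iteration are returned.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(outcome, dtype=float)
    keep = ~(np.isnan(X).any(axis=1) | np.isnan(y))
    X, y = X[keep], y[keep]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept", *names]
    _check_design(X, names)

    n, k = X.shape
    beta = np.zeros(k)
    last_stable = beta.copy()
    separation = False
    converged = False
    for _ in range(MAX_ITER):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if np.max(np.abs(beta)) > SEPARATION_COEF or w.min() < 1e-12:
            separation = True
            beta = last_stable
            break
        last_stable = beta.copy()
        # weighted least squares step on the working response
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        except np.linalg.LinAlgError:
            separation = True
            beta = last_stable
            break
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < TOL:
            converged = True
            break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    loglik = float(np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    try:
        cov = np.linalg.inv(X.T @ (X * w[:, None]))
        bse = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        bse = np.full(k, np.nan)
    if separation:
        logger.warning("separation detected; coefficients from last stable iteration")
    return LogisticFit(
        terms=tuple(names),
        coef=beta,
        bse=bse,
        loglik=loglik,
        n_used=n,
        converged=converged,
        separation=separation,
    )


def likelihood_ratio_test(fit_small: LogisticFit, fit_big: LogisticFit) -> tuple[float, int, float]:
    """LRT of nested fits: 2*delta-loglik ~ chi2 with df = extra terms."""
    small = set(fit_small.terms)
    big = set(fit_big.terms)
    if not small <= big:
        raise ValueError("models are not nested (small terms not a subset of big)")
    if fit_small.n_used != fit_big.n_used:
        raise ValueError("fits use different subject sets")
    df = len(big) - len(small)
    stat = max(0.0, 2.0 * (fit_big.loglik - fit_small.loglik))
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


@dataclass
class StepwisePath:
    """Audit log of a forward-stepwise run."""

    steps: list[dict] = field(default_factory=list)
    final_terms: tuple[str, ...] = ()
    final_fit: LogisticFit | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "action", "term", "lrt_p"])


def forward_stepwise(
    candidates: pd.DataFrame,
    outcome: np.ndarray,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwisePath:
    """Forward selection with backward pruning over coded marker columns.

    Candidates are expected to be pre-filtered (e.g. the markers surviving
    Bonferroni correction, with a composite indicator replacing its member
    SNPs).  Missing values are dropped complete-case over the whole
    candidate set so every nested fit shares one subject set.
    """
    path = StepwisePath()
    if candidates.shape[1] == 0:
        return path
    y = np.asarray(outcome, dtype=float)
    keep = ~(candidates.isna().any(axis=1).to_numpy() | np.isnan(y))
    candidates = candidates.loc[keep]
    y = y[keep]
    order = list(candidates.columns)

    included: list[str] = []
    step = 0
    current_fit = fit_logistic(candidates[included], y) if included else fit_logistic(
        pd.DataFrame(index=candidates.index), y
    )
    while True:
        changed = False
        # best addition
        best: tuple[float, int, str] | None = None
        for idx, term in enumerate(order):
            if term in included:
                continue
            try:
                trial = fit_logistic(candidates[included + [term]], y)
            except DesignError:
                continue
            _, _, p = likelihood_ratio_test(current_fit, trial)
            key = (p, idx, term)
            if p < p_enter and (best is None or key < best):
                best = key
        if best is not None:
            p, _, term = best
            included.append(term)
            current_fit = fit_logistic(candidates[included], y)
            step += 1
            path.steps.append({"step": step, "action": "add", "term": term, "lrt_p": p})
            changed = True
        # prune: remove the worst offender above p_remove, if any
        while len(included) > 0:
            worst: tuple[float, int, str] | None = None
            for term in included:
                reduced = [t for t in included if t != term]
                red_fit = fit_logistic(candidates[reduced], y)
                _, _, p = likelihood_ratio_test(red_fit, current_fit)
                key = (-p, order.index(term), term)
                if p > p_remove and (worst is None or key < worst):
                    worst = key
            if worst is None:
                break
            p_neg, _, term = worst
            included.remove(term)
            current_fit = fit_logistic(candidates[included], y) if included else fit_logistic(
                pd.DataFrame(index=candidates.index), y
            )
            step += 1
            path.steps.append({"step": step, "action": "remove", "term": term, "lrt_p": -p_neg})
            changed = True
        if not changed:
            break
    path.final_terms = tuple(included)
    path.final_fit = current_fit if included else None
    return path


def interaction_screen(
    design: pd.DataFrame, outcome: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise gene-gene interaction LRTs among selected terms.

    For each unordered pair the model with the product term is compared
    against the main-effects model by LRT.  Returns a table of pairs with
    p-values and a flag for p < alpha; fewer than two terms give an empty
    table.
    """
    terms = list(design.columns)
    rows = []
    if len(terms) >= 2:
        y = np.asarray(outcome, dtype=float)
        keep = ~(design.isna().any(axis=1).to_numpy() | np.isnan(y))
        design = design.loc[keep]
        y = y[keep]
        base = fit_logistic(design, y)
        for i in range(len(terms)):
            for j in range(i + 1, len(terms)):
                a, b = terms[i], terms[j]
                aug = design.copy()
                aug[f"{a}:{b}"] = design[a] * design[b]
                try:
                    big = fit_logistic(aug, y)
                    _, _, p = likelihood_ratio_test(base, big)
                except DesignError:
                    p = float("nan")
                rows.append((a, b, p, bool(p < alpha) if p == p else False))
    return pd.DataFrame(rows, columns=["term_a", "term_b", "p_value", "flagged"])
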