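"""Stepwise multiple linear regression QSAR engine.

Fits pEC50 against named interface descriptors by ordinary least squares
and carries the full validation ladder used for small structure-based
QSAR models: adjusted R², overall F-test, per-term t-tests, variance
inflation factors, AIC/AICc, leave-one-out Q², Y-randomization with the
cRp² statistic, and two model-selection protocols (a bounded-R²_adj
multi-criterion protocol and an AICc ranking gated by physical
interpretability).

Conventions (declared in every report):

* AIC = n·ln(RSS/n) + 2k with k counting the intercept and slopes,
  AICc = AIC + 2k(k+1)/(n−k−1).
* Q² = 1 − PRESS/TSS with TSS about the full-sample mean; PRESS is
  computed with the hat-matrix shortcut (identical to n explicit refits).
* Stepwise selection: forward inclusion of the smallest partial-F
  p-value ≤ α followed by backward elimination of any included term with
  p > α; ties break on canonical descriptor-name order.
* cRp² = sqrt(R²) · sqrt(R² − mean R²_random), clipped at 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .energetics import DESCRIPTOR_NAMES

__all__ = [
    "DESCRIPTOR_SETS",
    "LinearModelReport",
    "YRandomizationReport",
    "SelectionBounds",
    "ModelVerdict",
    "fit_ols",
    "stepwise_select",
    "loocv_q2",
    "vif",
    "aic_aicc",
    "y_randomize",
    "reference_binding_model",
    "select_model_bounded",
    "select_model_aic",
]

#: Descriptor groupings used to build the candidate sets of the four models.
DESCRIPTOR_SETS = {
    "contacts": list(DESCRIPTOR_NAMES[:12]),
    "packing": list(DESCRIPTOR_NAMES[12:18]),
    "nova": list(DESCRIPTOR_NAMES[18:26]),
    "mixed": list(DESCRIPTOR_NAMES),
}

_CANONICAL_RANK = {name: i for i, name in enumerate(DESCRIPTOR_NAMES)}


def _term_sort_key(name: str):
    return (_CANONICAL_RANK.get(name, len(_CANONICAL_RANK)), name)


def _design(table: pd.DataFrame, terms: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    y = table["pec50"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(table))] + [table[t].to_numpy(dtype=float) for t in terms]
    )
    return X, y


def _check_table(table: pd.DataFrame) -> None:
    if "pec50" not in table.columns:
        raise ValueError("descriptor table must have a 'pec50' column")
    if len(table) < 5:
        raise ValueError("need at least 5 rows")
    cols = [c for c in table.columns if c not in ("id",)]
    if table[cols].isna().any().any():
        raise ValueError("descriptor table contains missing values")
    if np.ptp(table["pec50"].to_numpy(dtype=float)) == 0:
        raise ValueError("response has zero variance")


@dataclass(frozen=True)
class LinearModelReport:
    """A fitted linear model together with its validation statistics."""

    terms: tuple[str, ...]
    weights: dict[str, float]
    std_errors: dict[str, float]
    intercept: float
    intercept_se: float
    n: int
    r2: float
    r2_adj: float
    p_f: float
    p_t: dict[str, float]
    vif: dict[str, float]
    aic: float
    aicc: float
    q2: float
    rss: float
    is_reference: bool = False
    conventions: dict = field(default_factory=lambda: {
        "aic": "n*ln(RSS/n) + 2k, k = intercept + slopes",
        "q2": "1 - PRESS/TSS, TSS about the full-sample mean",
    })

    @property
    def k(self) -> int:
        """Number of fitted parameters including the intercept."""
        return len(self.terms) + 1

    @property
    def equation_text(self) -> str:
        parts = []
        for i, t in enumerate(self.terms):
            w = self.weights[t]
            sign = "-" if w < 0 else ("+" if i else "")
            parts.append(f"{sign} {abs(w):.4g}{t}" if i else
                         f"{sign}{abs(w):.4g}{t}")
        c = self.intercept
        parts.append(f"{'-' if c < 0 else '+'} {abs(c):.4g}")
        rhs = " ".join(parts) if self.terms else f"{c:.4g}"
        return f"pEC50 = {rhs}"

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "weights": self.weights,
            "std_errors": self.std_errors,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "n": self.n,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "p_f": self.p_f,
            "p_t": self.p_t,
            "vif": self.vif,
            "aic": self.aic,
            "aicc": self.aicc,
            "q2": self.q2,
            "equation": self.equation_text,
            "is_reference": self.is_reference,
            "conventions": self.conventions,
        }

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        out = np.full(len(table), self.intercept)
        for t in self.terms:
            out += self.weights[t] * table[t].to_numpy(dtype=float)
        return out


def _ols_core(X: np.ndarray, y: np.ndarray, term_names: Sequence[str]):
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > {p} rows to fit {p - 1} terms plus intercept")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify offending columns by incremental rank
        bad = []
        base = X[:, :1]
        for j in range(1, p):
            cand = np.column_stack([base, X[:, j]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                bad.append(term_names[j - 1])
            else:
                base = cand
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    dof = n - p
    sigma2 = rss / dof if dof > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    return beta, se, rss, tss, dof, xtx_inv


def aic_aicc(n: int, k: int, rss: float) -> tuple[float, float]:
    """Gaussian AIC and AICc (k counts the intercept and the slopes)."""
    if rss <= 0:
        raise ValueError("AIC undefined for a zero-residual fit")
    aic = n * math.log(rss / n) + 2 * k
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    aicc = aic + 2 * k * (k + 1) / (n - k - 1)
    return aic, aicc


def loocv_q2(
    table: pd.DataFrame, terms: Sequence[str], method: str = "hat"
) -> float:
    """Leave-one-out cross-validated R² (Q² = 1 − PRESS/TSS).

    ``method="hat"`` uses the algebraic shortcut PRESS = Σ(e_i/(1−h_ii))²;
    ``method="refit"`` performs the n explicit refits. Both agree to
    rounding error. Unlike table-level fits this accepts any n >= 3.
    """
    terms = list(terms)
    X, y = _design(table, terms)
    n, p = X.shape
    if n < 3:
        raise ValueError("need n >= 3 for leave-one-out")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    tss = float(np.sum((y - y.mean()) ** 2))
    if method == "hat":
        beta, _, _, _, _, xtx_inv = _ols_core(X, y, terms)
        h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
        if np.any(h >= 1.0 - 1e-12):
            raise ValueError("a leave-one-out design is rank deficient")
        resid = y - X @ beta
        press = float(np.sum((resid / (1.0 - h)) ** 2))
    elif method == "refit":
        press = 0.0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            Xi, yi = X[mask], y[mask]
            if np.linalg.matrix_rank(Xi) < Xi.shape[1]:
                raise ValueError("a leave-one-out design is rank deficient")
            bi, _, _, _ = np.linalg.lstsq(Xi, yi, rcond=None)
            press += float((y[i] - X[i] @ bi) ** 2)
    else:
        raise ValueError(f"unknown method {method!r}")
    return 1.0 - press / tss


def vif(table: pd.DataFrame, terms: Sequence[str]) -> dict[str, float]:
    """Variance inflation factors VIF_j = 1/(1 − R_j²)."""
    terms = list(terms)
    if len(terms) < 2:
        raise ValueError("VIF needs at least two terms")
    out = {}
    for t in terms:
        others = [u for u in terms if u != t]
        X = np.column_stack(
            [np.ones(len(table))]
            + [table[u].to_numpy(dtype=float) for u in others]
        )
        y = table[t].to_numpy(dtype=float)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss == 0:
            raise ValueError(f"term {t!r} has zero variance")
        r2_j = 1.0 - float(resid @ resid) / tss
        if r2_j >= 1.0 - 1e-12:
            raise ValueError(f"term {t!r} is perfectly collinear with the others")
        out[t] = 1.0 / (1.0 - r2_j)
    return out


def fit_ols(
    table: pd.DataFrame,
    terms: Sequence[str],
    is_reference: bool = False,
) -> LinearModelReport:
    """Ordinary least squares of pEC50 on the named descriptor subset."""
    _check_table(table)
    terms = list(terms)
    X, y = _design(table, terms)
    beta, se, rss, tss, dof, _ = _ols_core(X, y, terms)
    n, p = X.shape
    k = p  # parameters including intercept
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    if terms:
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof
        f_stat = ((tss - rss) / len(terms)) / (rss / dof) if rss > 0 else np.inf
        p_f = float(stats.f.sf(f_stat, len(terms), dof))
        tvals = beta / se
        p_t = {
            t: float(2.0 * stats.t.sf(abs(tvals[i + 1]), dof))
            for i, t in enumerate(terms)
        }
        vifs = vif(table, terms) if len(terms) >= 2 else {terms[0]: 1.0}
    else:
        r2, r2_adj, p_f, p_t, vifs = 0.0, 0.0, 1.0, {}, {}
    if rss > 0 and n > k + 1:
        aic, aicc = aic_aicc(n, k, rss)
    else:
        aic = aicc = float("nan")
    q2 = loocv_q2(table, terms) if n >= 3 else float("nan")
    return LinearModelReport(
        terms=tuple(terms),
        weights={t: float(beta[i + 1]) for i, t in enumerate(terms)},
        std_errors={t: float(se[i + 1]) for i, t in enumerate(terms)},
        intercept=float(beta[0]),
        intercept_se=float(se[0]),
        n=n,
        r2=float(r2),
        r2_adj=float(r2_adj),
        p_f=p_f,
        p_t=p_t,
        vif=vifs,
        aic=float(aic),
        aicc=float(aicc),
        q2=float(q2),
        rss=rss,
        is_reference=is_reference,
    )


def stepwise_select(
    table: pd.DataFrame,
    candidate_terms: Sequence[str],
    alpha: float = 0.05,
    max_steps: int = 100,
) -> LinearModelReport:
    """Forward selection with backward elimination at significance ``alpha``.

    At each step the candidate with the smallest partial-F p-value enters
    if that p-value is ≤ α; any included term whose p-value rises above α
    is then dropped (worst first). Ties break on canonical
    descriptor-name order, making the result independent of the candidate
    list order. May return the intercept-only model.
    """
    _check_table(table)
    candidates = sorted(set(candidate_terms), key=_term_sort_key)
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    included: list[str] = []
    y = table["pec50"].to_numpy(dtype=float)
    n = len(y)

    def partial_p(term: str) -> float:
        terms = included + [term]
        X, _ = _design(table, terms)
        if np.linalg.matrix_rank(X) < X.shape[1] or n <= X.shape[1]:
            return 1.0
        beta, se, _, _, dof, _ = _ols_core(X, y, terms)
        tval = beta[-1] / se[-1] if se[-1] > 0 else np.inf
        return float(2.0 * stats.t.sf(abs(tval), dof))

    for _ in range(max_steps):
        changed = False
        # forward step
        remaining = [c for c in candidates if c not in included]
        if remaining:
            pvals = [(partial_p(c), _term_sort_key(c), c) for c in remaining]
            best_p, _, best = min(pvals)
            if best_p <= alpha:
                included.append(best)
                included.sort(key=_term_sort_key)
                changed = True
        # backward step(s)
        while included:
            X, _ = _design(table, included)
            beta, se, _, _, dof, _ = _ols_core(X, y, included)
            p_t = {
                t: float(2.0 * stats.t.sf(abs(beta[i + 1] / se[i + 1]), dof))
                for i, t in enumerate(included)
            }
            worst = max(included, key=lambda t: (p_t[t], _term_sort_key(t)))
            if p_t[worst] > alpha:
                included.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    return fit_ols(table, included)


@dataclass(frozen=True)
class YRandomizationReport:
    n_trials: int
    r2_trials: tuple[float, ...]
    q2_trials: tuple[float, ...]
    model_r2: float
    crp2: float

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2_trials))

    @property
    def mean_q2(self) -> float:
        return float(np.mean(self.q2_trials))


def crp2_statistic(r2: float, mean_r2_random: float) -> float:
    """cRp² = sqrt(R²)·sqrt(R² − mean R²_random), clipped at 0."""
    radicand = r2 * (r2 - mean_r2_random)
    return math.sqrt(radicand) if radicand > 0 else 0.0


def y_randomize(
    table: pd.DataFrame,
    terms: Sequence[str],
    n_trials: int = 50,
    seed: int = 0,
) -> YRandomizationReport:
    """Response permutation test on a fixed term set.

    The response is permuted ``n_trials`` times (seeded) while the
    descriptor matrix is held fixed; the same term set is refit each
    trial. Re-running stepwise selection per trial is deliberately not
    done here (a fresh selection answers a different question); use
    :func:`stepwise_select` on permuted tables for that variant.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(seed)
    base = fit_ols(table, terms)
    r2s, q2s = [], []
    shuffled = table.copy()
    for _ in range(n_trials):
        shuffled["pec50"] = rng.permutation(table["pec50"].to_numpy())
        fit = fit_ols(shuffled, terms)
        r2s.append(fit.r2)
        q2s.append(fit.q2)
    crp2 = crp2_statistic(base.r2, float(np.mean(r2s)))
    return YRandomizationReport(
        n_trials=n_trials,
        r2_trials=tuple(r2s),
        q2_trials=tuple(q2s),
        model_r2=base.r2,
        crp2=crp2,
    )


def reference_binding_model(table: pd.DataFrame) -> LinearModelReport:
    """Single-term binding-energy benchmark model (pEC50 ~ BE)."""
    if "BE" not in table.columns:
        raise ValueError("table has no BE column")
    return fit_ols(table, ["BE"], is_reference=True)


@dataclass(frozen=True)
class SelectionBounds:
    """Acceptable R²_adj window for a promising model.

    The lower bound is the fit of the single-term binding-energy
    reference model; the upper bound is the agreement between two
    independent experimental assays on the same system - a computational
    model should not outperform experiment against experiment.
    """

    lower_r2adj: float = 0.37
    upper_r2adj: float = 0.62
    reference_q2: float = 0.24

    def __post_init__(self) -> None:
        if not self.lower_r2adj < self.upper_r2adj:
            raise ValueError("lower bound must be below upper bound")


@dataclass(frozen=True)
class ModelVerdict:
    model: LinearModelReport
    label: str  # "pass" | "underfit" | "overfit"
    significant_f: bool
    significant_t: bool
    low_collinearity: bool
    q2_above_reference: bool
    rank: int | None = None  # 1-based among passing candidates


def select_model_bounded(
    candidates: Sequence[LinearModelReport],
    bounds: SelectionBounds,
    alpha: float = 0.05,
    vif_limit: float = 5.0,
) -> list[ModelVerdict]:
    """Label candidates against the R²_adj window and statistical gates."""
    verdicts = []
    for m in candidates:
        if m.r2_adj <= bounds.lower_r2adj:
            label = "underfit"
        elif m.r2_adj > bounds.upper_r2adj:
            label = "overfit"
        else:
            label = "pass"
        verdicts.append(
            ModelVerdict(
                model=m,
                label=label,
                significant_f=m.p_f <= alpha,
                significant_t=all(p <= alpha for p in m.p_t.values()),
                low_collinearity=all(v < vif_limit for v in m.vif.values()),
                q2_above_reference=m.q2 > bounds.reference_q2,
            )
        )
    passing = sorted(
        [v for v in verdicts if v.label == "pass"],
        key=lambda v: -v.model.r2_adj,
    )
    ranked = {id(v): i + 1 for i, v in enumerate(passing)}
    return [
        ModelVerdict(v.model, v.label, v.significant_f, v.significant_t,
                     v.low_collinearity, v.q2_above_reference,
                     ranked.get(id(v)))
        for v in verdicts
    ]


def select_model_aic(
    candidates: Sequence[LinearModelReport],
    interpretability_flags: Sequence[bool],
) -> LinearModelReport | None:
    """Best-AICc candidate that also passes physical interpretability.

    Candidates are visited in ascending AICc; the first whose flag is
    true is returned, else ``None``.
    """
    if len(candidates) != len(interpretability_flags):
        raise ValueError("one flag per candidate is required")
    order = np.argsort([m.aicc for m in candidates], kind="stable")
    for i in order:
        if interpretability_flags[i]:
            return candidates[i]
    return None
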