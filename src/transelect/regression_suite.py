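"""Cross-species statistical layer: OLS with dummy/interaction terms,
midrank transforms and rank regressions, and floor-exponential fits.

Species-level features (AUG%, UAA%, MeanMFE) are regressed on ranked
generation time (RankGT), genomic GC%, and expression class (GE, encoded
HEG = 0 / REST = 1), optionally with a GC% x GE interaction.  Machinery
counts follow floor-exponential decay, N = floor + a*exp(-b*RankGT),
where the floor is either fixed (one rrn operon is the biological minimum)
or estimated (the minimal tRNA set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

#: deterministic multi-start grid for the decay-rate parameter
B_START_GRID: tuple[float, ...] = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0)

GE_ENCODING = {"HEG": 0, "REST": 1}


@dataclass
class RegressionResult:
    """OLS summary: one row of (coef, SE, t, two-tailed p) per term."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r_squared: float
    n: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Coefficient": self.coef, "Standard Error": self.se,
             "t Stat": self.t, "p-Value": self.p},
            index=pd.Index(self.terms, name="term"),
        )

    def __getitem__(self, term: str) -> float:
        return float(self.coef[self.terms.index(term)])

    def one_tailed_p(self, term: str) -> float:
        """Halved p for a declared directional hypothesis on one term."""
        return float(self.p[self.terms.index(term)]) / 2.0


@dataclass
class NonlinearFitResult:
    """Floor-exponential fit y = c + a*exp(-b*x)."""

    a: float
    b: float
    c: float
    floor_fixed: bool
    rss: float
    converged: bool
    starts_tried: int
    degenerate: bool = False


def _encode_ge(values) -> np.ndarray:
    out = []
    for v in values:
        if isinstance(v, str):
            out.append(GE_ENCODING[v])
        else:
            out.append(float(v))
    return np.asarray(out, dtype=float)


def ols_fit(data: pd.DataFrame, response: str, predictors: list[str],
            interactions: list[tuple[str, str]] | None = None) -> RegressionResult:
    """Least-squares fit with optional pairwise interaction columns.

    String-valued GE columns are encoded HEG = 0, REST = 1.  Standard
    errors use the unbiased residual variance; p values are two-tailed
    from the t distribution with n - k df.
    """
    y = np.asarray(data[response], dtype=float)
    cols, names = [], []
    encoded: dict[str, np.ndarray] = {}
    for pred in predictors:
        col = (_encode_ge(data[pred]) if data[pred].dtype == object
               else np.asarray(data[pred], dtype=float))
        encoded[pred] = col
        cols.append(col)
        names.append(pred)
    for a, b in interactions or []:
        ca = encoded.get(a, _encode_ge(data[a]) if data[a].dtype == object
                         else np.asarray(data[a], dtype=float))
        cb = encoded.get(b, _encode_ge(data[b]) if data[b].dtype == object
                         else np.asarray(data[b], dtype=float))
        cols.append(ca * cb)
        names.append(f"{a}*{b}")
    X = np.column_stack(cols)
    n, k = X.shape[0], X.shape[1] + 1
    if n <= k:
        raise ValueError(f"n = {n} observations cannot identify {k} terms")
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc)
    if rank < k:
        raise ValueError(f"singular design matrix over terms {names}")
    fit = sm.OLS(y, Xc).fit()
    return RegressionResult(terms=["Intercept"] + names,
                            coef=np.asarray(fit.params),
                            se=np.asarray(fit.bse),
                            t=np.asarray(fit.tvalues),
                            p=np.asarray(fit.pvalues),
                            r_squared=float(fit.rsquared), n=n)


def derive_class_equations(result: RegressionResult, ge_term: str = "GE"
                           ) -> dict[str, dict[str, float]]:
    """Per-class linear equations by substituting GE = 0 (HEG) / 1 (REST).

    An interaction term ``X*GE`` folds into the class-specific slope of X.
    """
    if ge_term not in result.terms:
        raise ValueError(f"model has no {ge_term} term")
    equations: dict[str, dict[str, float]] = {}
    for cls, ge_value in GE_ENCODING.items():
        eq: dict[str, float] = {}
        for term, coef in zip(result.terms, result.coef):
            coef = float(coef)
            if term == "Intercept":
                eq["Intercept"] = eq.get("Intercept", 0.0) + coef
            elif term == ge_term:
                eq["Intercept"] = eq.get("Intercept", 0.0) + coef * ge_value
            elif "*" in term:
                a, b = term.split("*")
                if ge_term in (a, b):
                    other = b if a == ge_term else a
                    eq[other] = eq.get(other, 0.0) + coef * ge_value
                else:
                    eq[term] = eq.get(term, 0.0) + coef
            else:
                eq[term] = eq.get(term, 0.0) + coef
        equations[cls] = eq
    return equations


def rank_transform(values) -> np.ndarray:
    """Midranks (ties get average rank, e.g. 6.5)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty vector")
    return stats.rankdata(values, method="average")


def rank_regression(rank_y, rank_x) -> RegressionResult:
    """Simple OLS of one ranked variable on another."""
    df = pd.DataFrame({"y": np.asarray(rank_y, dtype=float),
                       "x": np.asarray(rank_x, dtype=float)})
    if len(df) < 3:
        raise ValueError("rank regression needs at least 3 points")
    return ols_fit(df, "y", ["x"])


def fit_floor_exponential(x, y, floor: float | None = None) -> NonlinearFitResult:
    """Least-squares fit of y = c + a*exp(-b*x).

    ``floor``: a fixed value for c (e.g. 1 for rrn operons) or None to
    estimate it.  Deterministic multi-start local optimisation over the
    B_START_GRID decay rates, keeping the best residual sum of squares;
    at each start a and c are initialised from the data range.  Fits are
    unweighted and c is unconstrained (a negative estimate is reported,
    not clipped).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    min_n = 3 if floor is not None else 4
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points")
    if np.any(x <= 0):
        raise ValueError("x must be strictly positive (rank scale)")
    degenerate = bool(np.allclose(y, y[0]))

    best: optimize.OptimizeResult | None = None
    tried = 0
    for b0 in B_START_GRID:
        if floor is None:
            p0 = [float(y.min()), float(y.max() - y.min()) or 1.0, b0]

            def resid(p):
                c, a, b = p
                return c + a * np.exp(-b * x) - y
        else:
            p0 = [float(y.max() - floor) or 1.0, b0]

            def resid(p):
                a, b = p
                return floor + a * np.exp(-b * x) - y

        res = optimize.least_squares(resid, p0, max_nfev=10000)
        tried += 1
        if best is None or res.cost < best.cost:
            best = res
    assert best is not None
    if floor is None:
        c, a, b = (float(v) for v in best.x)
        fixed = False
    else:
        a, b = (float(v) for v in best.x)
        c, fixed = float(floor), True
    return NonlinearFitResult(a=a, b=b, c=c, floor_fixed=fixed,
                              rss=float(2.0 * best.cost), converged=bool(best.success),
                              starts_tried=tried, degenerate=degenerate)
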