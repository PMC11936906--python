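"""Count and rate statistics for condition comparisons.

Three complementary routes, all operating on the tidy count table
(columns ``subject, session, condition, window, count, exposure_s``):

* an exact conditional test for two Poisson rates (conditioning on the
  total count turns the comparison into a binomial test on the exposure
  split),
* a within-subject permutation test of condition labels, assumption-free
  and exact by enumeration when the design is small, and
* fixed-effects Poisson regression with a log link and log-exposure
  offsets, fitted by iteratively reweighted least squares (IRLS), with
  likelihood-ratio tests for named terms.

Bird heterogeneity is handled by bird indicator columns (fixed effects)
and by stratifying permutations within bird; random-intercept mixed models
are deliberately out of scope.  Pairwise condition contrasts are reported
with Holm-adjusted p-values by default, raw p-values always retained.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RateComparison",
    "GlmFit",
    "poisson_rate_ratio_test",
    "permutation_condition_test",
    "fit_poisson_glm_irls",
    "condition_design",
    "habituation_trend",
    "holm_adjust",
    "pairwise_condition_tests",
]

_PMF_SLACK = 1.0 + 1e-9  # ties in pmf comparison at double precision


@dataclass(frozen=True)
class RateComparison:
    """Result of a two-sample rate comparison."""

    x1: int
    x2: int
    T1: float
    T2: float
    rate_ratio: float
    p_value: float
    method: str


@dataclass(frozen=True)
class GlmFit:
    """A fitted Poisson log-link regression.

    ``lr_stat``/``lr_df``/``lr_p`` test the named ``term`` by deviance
    difference against the nested fit without it.  ``boundary`` flags a
    maximum on the boundary of the parameter space (some stratum with all
    zero counts drives its log-rate to minus infinity); coefficients are
    then reported at a large negative value rather than raising.
    """

    names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    deviance: float
    converged: bool
    boundary: bool = False
    term: str | None = None
    lr_stat: float | None = None
    lr_df: int | None = None
    lr_p: float | None = None

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.standard_errors[self.names.index(name)])


def poisson_rate_ratio_test(x1: int, T1: float, x2: int, T2: float) -> RateComparison:
    """Exact conditional test that two Poisson rates are equal.

    Conditional on ``n = x1 + x2``, ``x1 ~ Binomial(n, T1/(T1+T2))`` under
    the null.  The two-sided p-value follows the minimum-likelihood
    convention: the sum of probabilities of all outcomes no more probable
    than the observed one.  The rate ratio is ``(x1/T1)/(x2/T2)`` —
    infinite when ``x2 = 0 < x1``, undefined (NaN) when both counts are 0.
    """
    if x1 < 0 or x2 < 0:
        raise ValueError("counts must be non-negative")
    if T1 <= 0 or T2 <= 0:
        raise ValueError("exposures must be positive")
    n = x1 + x2
    if n == 0:
        return RateComparison(x1, x2, T1, T2, np.nan, 1.0, "exact-conditional")
    p1 = T1 / (T1 + T2)
    pmf = sps.binom.pmf(np.arange(n + 1), n, p1)
    p = float(np.sum(pmf[pmf <= pmf[x1] * _PMF_SLACK]))
    p = min(p, 1.0)
    if x2 == 0:
        ratio = np.inf
    else:
        ratio = (x1 / T1) / (x2 / T2)
    return RateComparison(x1, x2, T1, T2, ratio, p, "exact-conditional")


def _paired_rates(
    table: pd.DataFrame, conditions: tuple[str, str], window: str | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-bird (x1, T1, x2, T2) aggregated over sessions (and windows)."""
    sub = table
    if window is not None:
        sub = sub[sub["window"] == window]
    sub = sub[sub["condition"].isin(conditions)]
    agg = sub.groupby(["subject", "condition"])[["count", "exposure_s"]].sum()
    birds = sorted(sub["subject"].unique())
    x1, t1, x2, t2 = [], [], [], []
    for b in birds:
        try:
            r1 = agg.loc[(b, conditions[0])]
            r2 = agg.loc[(b, conditions[1])]
        except KeyError as err:
            raise ValueError(
                f"subject {b!r} lacks condition {err.args[0]}: the permutation "
                "test needs every bird observed under each condition"
            ) from None
        x1.append(r1["count"])
        t1.append(r1["exposure_s"])
        x2.append(r2["count"])
        t2.append(r2["exposure_s"])
    return (np.array(x1), np.array(t1), np.array(x2), np.array(t2))


def _statistic(
    x1: np.ndarray, t1: np.ndarray, x2: np.ndarray, t2: np.ndarray, kind: str
) -> float | np.ndarray:
    if kind == "rate_difference":
        return np.mean(x1 / t1 - x2 / t2, axis=-1)
    if kind == "log_rate_ratio":
        eps = 0.5  # continuity guard for zero totals
        r1 = (np.sum(x1, axis=-1) + eps) / np.sum(t1, axis=-1)
        r2 = (np.sum(x2, axis=-1) + eps) / np.sum(t2, axis=-1)
        return np.log(r1) - np.log(r2)
    raise ValueError(f"unknown statistic {kind!r}")


def permutation_condition_test(
    table: pd.DataFrame,
    conditions: tuple[str, str],
    *,
    statistic: str = "rate_difference",
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
    window: str | None = "within_song",
) -> float:
    """Within-bird permutation test of two condition labels.

    Counts and exposures are aggregated per (bird, condition); the condition
    labels are then permuted *within* bird (each bird's pair of cells may be
    swapped), which under the null of no condition effect leaves the joint
    distribution unchanged.  When the number of distinct label assignments
    ``2**n_birds`` is at most ``n_perm`` the test enumerates them all and
    the p-value is exact: ``#{|T*| >= |T_obs|} / 2**n_birds``.  Otherwise
    ``n_perm`` random assignments are drawn and
    ``p = (1 + #{|T*| >= |T_obs|}) / (1 + n_perm)``.
    """
    x1, t1, x2, t2 = _paired_rates(table, conditions, window)
    n_birds = len(x1)
    if n_birds == 0:
        raise ValueError("no subjects with both conditions")
    t_obs = float(_statistic(x1, t1, x2, t2, statistic))
    if 2**n_birds <= n_perm:
        flips = np.array(
            list(itertools.product([False, True], repeat=n_birds)), dtype=bool
        )
        exhaustive = True
    else:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        flips = rng.random((n_perm, n_birds)) < 0.5
        exhaustive = False
    x1s = np.where(flips, x2, x1)
    t1s = np.where(flips, t2, t1)
    x2s = np.where(flips, x1, x2)
    t2s = np.where(flips, t1, t2)
    t_star = _statistic(x1s, t1s, x2s, t2s, statistic)
    hits = np.abs(t_star) >= abs(t_obs) - 1e-12
    if exhaustive:
        return float(np.mean(hits))
    return float((1 + np.sum(hits)) / (1 + len(flips)))


_BOUNDARY_COEF = -30.0  # log-rate floor ~ 1e-13 calls/s: numerically zero


def fit_poisson_glm_irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    *,
    names: list[str] | None = None,
    term: str | None = None,
    term_columns: list[int] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> GlmFit:
    """Poisson log-link maximum likelihood via IRLS.

    ``offset`` holds log exposures.  Convergence when the largest
    coefficient update falls below ``tol`` (default 1e-8) or after
    ``max_iter`` iterations.  If ``term_columns`` names a set of columns,
    the nested model without them is refitted and the likelihood-ratio
    statistic (deviance difference) reported for that term.

    Rank-deficient designs are rejected naming the collinear columns.  A
    response stratum with no events pushes its log-rate to minus infinity;
    the fit then reports the coefficient at a large negative boundary value
    with ``boundary=True`` instead of raising.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("design matrix and response disagree")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("responses must be non-negative counts")
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the culprits: columns whose removal restores full rank
        collinear = [
            names[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, dtype=float)

    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(offset + X @ beta, -300, 300)
        mu = np.exp(eta)
        w = np.maximum(mu, 1e-300)
        z = (eta - offset) + (y - mu) / w
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            break
        step = beta_new - beta
        beta = beta_new
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    boundary = bool(np.any(beta < _BOUNDARY_COEF))
    beta = np.maximum(beta, _BOUNDARY_COEF)
    eta = np.clip(offset + X @ beta, -300, 300)
    mu = np.exp(eta)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_terms = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
    deviance = float(2.0 * np.sum(dev_terms))
    w = np.maximum(mu, 1e-300)
    cov = np.linalg.pinv((X.T * w) @ X)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    lr_stat = lr_df = lr_p = None
    if term_columns:
        keep = [j for j in range(p) if j not in set(term_columns)]
        reduced = fit_poisson_glm_irls(
            y,
            X[:, keep] if keep else np.ones((n, 1)),
            offset,
            names=[names[j] for j in keep] if keep else ["intercept"],
            tol=tol,
            max_iter=max_iter,
        )
        lr_stat = max(0.0, reduced.deviance - deviance)
        lr_df = len(set(term_columns))
        lr_p = float(sps.chi2.sf(lr_stat, lr_df))
    return GlmFit(
        names=tuple(names),
        coefficients=beta,
        standard_errors=se,
        deviance=deviance,
        converged=converged or boundary,
        boundary=boundary,
        term=term,
        lr_stat=lr_stat,
        lr_df=lr_df,
        lr_p=lr_p,
    )


def condition_design(
    table: pd.DataFrame,
    *,
    window: str | None = "within_song",
    reference: str | None = None,
    include_bird: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[int]]:
    """Build (y, X, offset, names, condition_columns) from a count table.

    One row per table cell: bird indicator columns (fixed intercepts, one
    per bird — no global intercept) plus condition indicators relative to
    ``reference`` (default: first condition in sorted order).  Offset is
    log exposure.
    """
    sub = table if window is None else table[table["window"] == window]
    sub = sub[sub["exposure_s"] > 0]
    conds = sorted(sub["condition"].unique())
    if reference is None:
        reference = conds[0]
    if reference not in conds:
        raise ValueError(f"reference condition {reference!r} not in table")
    birds = sorted(sub["subject"].unique())
    cols: list[np.ndarray] = []
    names: list[str] = []
    if include_bird:
        for b in birds:
            cols.append((sub["subject"] == b).to_numpy(float))
            names.append(f"bird[{b}]")
    else:
        cols.append(np.ones(len(sub)))
        names.append("intercept")
    cond_cols: list[int] = []
    for c in conds:
        if c == reference:
            continue
        cond_cols.append(len(names))
        cols.append((sub["condition"] == c).to_numpy(float))
        names.append(f"condition[{c}]")
    y = sub["count"].to_numpy(float)
    X = np.column_stack(cols)
    offset = np.log(sub["exposure_s"].to_numpy(float))
    return y, X, offset, names, cond_cols


def habituation_trend(
    table: pd.DataFrame, *, window: str | None = "within_song"
) -> GlmFit:
    """Log-linear session trend in calling.

    Poisson regression of per-(bird, session) counts on the session index
    with bird fixed intercepts and log-exposure offset.  The ``session``
    coefficient is the log rate change per session (geometric habituation
    appears as a constant negative slope); its likelihood-ratio test asks
    whether calling changes across sessions at all.
    """
    sub = table if window is None else table[table["window"] == window]
    sub = sub[sub["exposure_s"] > 0]
    agg = (
        sub.groupby(["subject", "session"])[["count", "exposure_s"]]
        .sum()
        .reset_index()
    )
    if agg["session"].nunique() < 2:
        raise ValueError("habituation trend needs at least two sessions")
    birds = sorted(agg["subject"].unique())
    cols = [(agg["subject"] == b).to_numpy(float) for b in birds]
    names = [f"bird[{b}]" for b in birds]
    session_col = len(names)
    cols.append(agg["session"].to_numpy(float) - 1.0)
    names.append("session")
    return fit_poisson_glm_irls(
        agg["count"].to_numpy(float),
        np.column_stack(cols),
        np.log(agg["exposure_s"].to_numpy(float)),
        names=names,
        term="session",
        term_columns=[session_col],
    )


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def pairwise_condition_tests(
    table: pd.DataFrame,
    *,
    window: str | None = "within_song",
    method: str = "exact",
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """All pairwise condition contrasts with Holm-adjusted p-values.

    ``method='exact'`` pools counts and exposures over birds and sessions
    and applies the exact conditional rate test; ``method='permutation'``
    runs the within-bird permutation test per pair.  Raw p-values are
    retained alongside the adjusted ones.
    """
    sub = table if window is None else table[table["window"] == window]
    conds = sorted(c for c in sub["condition"].unique())
    rows = []
    for c1, c2 in itertools.combinations(conds, 2):
        if method == "exact":
            g = sub[sub["condition"].isin([c1, c2])].groupby("condition")[
                ["count", "exposure_s"]
            ].sum()
            res = poisson_rate_ratio_test(
                int(g.loc[c1, "count"]),
                float(g.loc[c1, "exposure_s"]),
                int(g.loc[c2, "count"]),
                float(g.loc[c2, "exposure_s"]),
            )
            rows.append(
                {
                    "condition_1": c1,
                    "condition_2": c2,
                    "rate_ratio": res.rate_ratio,
                    "p_raw": res.p_value,
                }
            )
        elif method == "permutation":
            p = permutation_condition_test(
                table, (c1, c2), n_perm=n_perm, rng=rng, window=window
            )
            rows.append(
                {"condition_1": c1, "condition_2": c2, "rate_ratio": np.nan, "p_raw": p}
            )
        else:
            raise ValueError(f"unknown method {method!r}")
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out
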