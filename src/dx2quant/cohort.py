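"""Cohort statistics for splice-ratio stratified survival analyses.

Implements the statistical toolkit used to relate exon-skipping isoform
ratios (or RT-PCR positivity) to clinical outcome in a patient cohort:

* quartile-cutoff stratification of continuous ratios,
* Kaplan-Meier product-limit estimation with median survival and
  Brookmeyer-Crowley style (log-log) confidence limits,
* the k-group log-rank test,
* Cox proportional-hazards regression (Newton-Raphson on the partial
  likelihood; Breslow or Efron tie handling) with Wald intervals and the
  score test at beta = 0,
* an exact R x C Fisher test by depth-first enumeration of all tables with
  the observed margins, and
* the Mann-Whitney U test (exact by enumeration for small samples,
  otherwise normal approximation with tie and continuity corrections).

Times are in months; an event flag of True means death (OS) or
progression-or-death (PFS); False means right-censoring at last contact.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "QuantileSplit",
    "SurvivalCurve",
    "CoxResult",
    "ConvergenceError",
    "EnumerationBudgetError",
    "quantile_cutoff",
    "km_estimate",
    "logrank_test",
    "cox_ph",
    "fisher_exact_rxc",
    "mann_whitney_u",
]


class ConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization diverged (e.g. monotone likelihood)."""


class EnumerationBudgetError(RuntimeError):
    """Exact enumeration would exceed the configured table budget."""


# ---------------------------------------------------------------------------
# stratification


@dataclass(frozen=True)
class QuantileSplit:
    """A quantile cutoff and the resulting high (>= cutoff) / low labels."""

    cutoff: float
    labels: np.ndarray  # array of "high"/"low" aligned with the input
    q: float


def quantile_cutoff(
    ratios: Sequence[float], q: float = 0.25, method: str = "linear"
) -> QuantileSplit:
    """Dichotomize ratios at their q-quantile (default: first quartile).

    The default estimator is linear interpolation (R type-7), the common
    software default; it is configurable because a quartile cutoff value
    depends on the estimator. Samples >= cutoff are labeled "high".
    """
    values = np.asarray(ratios, dtype=float)
    if values.size == 0:
        raise ValueError("ratios must be non-empty")
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    cutoff = float(np.quantile(values, q, method=method))
    labels = np.where(values >= cutoff, "high", "low")
    if np.all(labels == "high") or np.all(labels == "low"):
        warnings.warn(
            "quantile cutoff produced a single group (degenerate ratio "
            "distribution)",
            stacklevel=2,
        )
    return QuantileSplit(cutoff=cutoff, labels=labels, q=q)


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate over the distinct event times.

    ``median`` is the smallest event time with S(t) <= 0.5, or None when not
    reached. ``median_ci`` gives log-log (Greenwood) 95% limits on the
    median; either bound may be None (not reached).
    """

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    median: float | None
    median_ci: tuple[float | None, float | None]

    def survival_at(self, t: float) -> float:
        """Stepwise S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.shape != e.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("times and events must be equal-length non-empty 1D arrays")
    if np.any(t < 0):
        raise ValueError("negative survival times")

    event_times = np.unique(t[e])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    var_term = 0.0  # Greenwood cumulative sum
    lower_env, upper_env = [], []
    for et in event_times:
        n = int(np.sum(t >= et))
        d = int(np.sum((t == et) & e))
        s *= 1.0 - d / n
        if n - d > 0:
            var_term += d / (n * (n - d))
        at_risk.append(n)
        n_ev.append(d)
        surv.append(s)
        lo, hi = _loglog_ci(s, var_term)
        lower_env.append(lo)
        upper_env.append(hi)

    surv_arr = np.asarray(surv)
    median = _first_time_below(event_times, surv_arr, 0.5)
    # Brookmeyer-Crowley style: median CI from the times where the pointwise
    # CI envelope crosses 0.5
    ci_lo = _first_time_below(event_times, np.asarray(upper_env), 0.5)
    ci_hi = _first_time_below(event_times, np.asarray(lower_env), 0.5)
    return SurvivalCurve(
        times=event_times,
        survival=surv_arr,
        n_at_risk=np.asarray(at_risk),
        n_events=np.asarray(n_ev),
        median=median,
        median_ci=(ci_lo, ci_hi),
    )


def _loglog_ci(s: float, greenwood_sum: float, z: float = 1.959963984540054):
    if s <= 0.0:
        return 0.0, 0.0
    if s >= 1.0 or greenwood_sum == 0.0:
        return s, s
    se_log = math.sqrt(greenwood_sum) / abs(math.log(s))
    theta = math.exp(z * se_log)
    return s ** theta, s ** (1.0 / theta)


def _first_time_below(times: np.ndarray, surv: np.ndarray, level: float):
    hit = np.nonzero(surv <= level + 1e-12)[0]
    return float(times[hit[0]]) if hit.size else None


# ---------------------------------------------------------------------------
# log-rank


def logrank_test(
    groups: Sequence[tuple[Sequence[float], Sequence[bool]]],
) -> tuple[float, float]:
    """k-group log-rank test: (chi2, p) with k-1 degrees of freedom.

    Uses the observed-minus-expected statistic with the hypergeometric
    variance-covariance accumulated over the pooled distinct event times.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ts, es = [], []
    for gt, ge in groups:
        gt = np.asarray(gt, dtype=float)
        ge = np.asarray(ge, dtype=bool)
        if gt.size == 0:
            raise ValueError("every group must be non-empty")
        ts.append(gt)
        es.append(ge)
    k = len(groups)
    pooled_events = np.unique(np.concatenate([t[e] for t, e in zip(ts, es)]))

    obs = np.zeros(k)
    exp = np.zeros(k)
    cov = np.zeros((k - 1, k - 1))
    for et in pooled_events:
        n_g = np.array([np.sum(t >= et) for t in ts], dtype=float)
        d_g = np.array(
            [np.sum((t == et) & e) for t, e in zip(ts, es)], dtype=float
        )
        n_tot = n_g.sum()
        d_tot = d_g.sum()
        if n_tot == 0 or d_tot == 0:
            continue
        obs += d_g
        exp += d_tot * n_g / n_tot
        if n_tot > 1:
            # multivariate hypergeometric covariance of the group death counts
            factor = d_tot * (n_tot - d_tot) / (n_tot - 1)
            p_g = n_g / n_tot
            for i in range(k - 1):
                for j in range(k - 1):
                    delta = 1.0 if i == j else 0.0
                    cov[i, j] += factor * p_g[i] * (delta - p_g[j])
    diff = (obs - exp)[: k - 1]
    if not np.any(cov):
        return 0.0, 1.0
    chi2 = float(diff @ np.linalg.solve(cov, diff))
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, p


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass(frozen=True)
class CoxResult:
    """Fitted Cox model: per-covariate coefficients, HRs, Wald CIs and p.

    ``score_chi2`` is the score test of the global null beta = 0; for a
    single binary covariate it coincides with the log-rank chi-square.
    """

    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci95: np.ndarray  # (p, 2)
    p: np.ndarray
    score_chi2: float
    loglik: float
    n_iter: int

    def single(self) -> dict:
        """Scalars for the one-covariate case."""
        return {
            "coef": float(self.coef[0]),
            "hr": float(self.hr[0]),
            "ci95": (float(self.ci95[0, 0]), float(self.ci95[0, 1])),
            "p": float(self.p[0]),
        }


def _cox_derivatives(beta, X, times, events, ties):
    """(loglik, gradient, information) of the partial likelihood."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for et in np.unique(times[events]):
        at_risk = times >= et
        dead = (times == et) & events
        d = int(dead.sum())
        s0 = w[at_risk].sum()
        s1 = X[at_risk].T @ w[at_risk]
        s2 = (X[at_risk].T * w[at_risk]) @ X[at_risk]
        sum_x = X[dead].sum(axis=0)
        loglik += eta[dead].sum()
        if ties == "breslow" or d == 1:
            loglik -= d * math.log(s0)
            grad += sum_x - d * s1 / s0
            info += d * (s2 / s0 - np.outer(s1, s1) / s0**2)
        elif ties == "efron":
            wd = w[dead].sum()
            s1d = X[dead].T @ w[dead]
            s2d = (X[dead].T * w[dead]) @ X[dead]
            grad += sum_x
            for r in range(d):
                f = r / d
                s0r = s0 - f * wd
                s1r = s1 - f * s1d
                s2r = s2 - f * s2d
                loglik -= math.log(s0r)
                grad -= s1r / s0r
                info += s2r / s0r - np.outer(s1r, s1r) / s0r**2
        else:
            raise ValueError(f"unknown tie handling: {ties!r}")
    return loglik, grad, info


def cox_ph(
    times: Sequence[float],
    events: Sequence[bool],
    covariates,
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Maximizes the partial likelihood (Breslow tie handling by default,
    Efron by flag) to gradient norm < ``tol``. ``covariates`` is an (n,) or
    (n, p) array. Wald CI: exp(coef +/- 1.96 * SE). Raises on datasets with
    no events, constant covariates, or monotone likelihood (divergence).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if t.size != e.size or X.shape[0] != t.size:
        raise ValueError("times, events and covariates must align")
    if not np.any(e):
        raise ValueError("no events: the partial likelihood is not identifiable")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant covariate: coefficient not identifiable")
    X = X - X.mean(axis=0)  # centering for numerical stability
    p = X.shape[1]

    beta = np.zeros(p)
    ll0, g0, i0 = _cox_derivatives(beta, X, t, e, ties)
    score_chi2 = float(g0 @ np.linalg.solve(i0, g0))

    loglik, grad, info = ll0, g0, i0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.linalg.norm(grad) < tol:
            break
        step = np.linalg.solve(info, grad)
        # step halving to keep the likelihood increasing
        scale = 1.0
        for _ in range(30):
            new_beta = beta + scale * step
            new_ll, new_grad, new_info = _cox_derivatives(new_beta, X, t, e, ties)
            if new_ll >= loglik - 1e-12:
                break
            scale /= 2.0
        beta, loglik, grad, info = new_beta, new_ll, new_grad, new_info
        if np.any(np.abs(beta) > 30):
            raise ConvergenceError(
                "coefficient diverging (|beta| > 50): likely monotone partial "
                "likelihood / complete separation of the risk sets"
            )
    else:
        if np.linalg.norm(grad) >= tol:
            raise ConvergenceError(
                f"Newton iteration did not reach gradient norm < {tol} in "
                f"{max_iter} iterations"
            )

    se = np.sqrt(np.diag(np.linalg.inv(info)))
    if not np.all(np.isfinite(se)) or np.any(se > 1e3):
        # information collapsed: the likelihood is (near-)monotone in beta
        raise ConvergenceError(
            "partial-likelihood information is degenerate (SE > 1000): "
            "monotone likelihood / complete separation of the risk sets"
        )
    z = 1.959963984540054
    with np.errstate(over="ignore"):
        ci = np.exp(np.column_stack([beta - z * se, beta + z * se]))
    pvals = 2.0 * stats.norm.sf(np.abs(beta / se))
    return CoxResult(
        coef=beta,
        se=se,
        hr=np.exp(beta),
        ci95=ci,
        p=pvals,
        score_chi2=score_chi2,
        loglik=loglik,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# exact R x C Fisher test


def fisher_exact_rxc(
    table, budget: int = 5_000_000, rel_tol: float = 1e-7
) -> float:
    """Two-sided Fisher exact p for an R x C contingency table.

    Enumerates (depth-first, margin-constrained) every table sharing the
    observed row and column sums; p is the total hypergeometric probability
    of tables no more probable than the observed one (probability-mass
    ordering, with relative tolerance on the comparison since table
    probabilities are floats). Raises :class:`EnumerationBudgetError` when
    more than ``budget`` tables would be visited; a Monte-Carlo permutation
    test is the standard fallback for such tables.
    """
    T = np.asarray(table)
    if T.ndim != 2:
        raise ValueError("table must be 2D")
    if not np.issubdtype(T.dtype, np.integer):
        Tf = np.asarray(table, dtype=float)
        if np.any(Tf != np.round(Tf)):
            raise ValueError("table entries must be integers")
        T = Tf.astype(int)
    if np.any(T < 0):
        raise ValueError("table entries must be non-negative")
    T = T[T.sum(axis=1) > 0][:, T.sum(axis=0) > 0]
    if T.size == 0 or T.shape[0] < 2 or T.shape[1] < 2:
        return 1.0

    rows = T.sum(axis=1)
    cols = T.sum(axis=0)
    n = int(T.sum())
    const = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    logp_obs = const - gammaln(T + 1).sum()

    R, C = T.shape
    # suffix sums of remaining row totals, for composition feasibility bounds
    remaining_rows = np.concatenate([np.cumsum(rows[::-1])[::-1], [0]])

    threshold = logp_obs + rel_tol  # log(1 + rel_tol) ~ rel_tol
    visited = 0
    p_sum = 0.0
    total = 0.0

    col_rem = cols.astype(int).copy()

    def recurse(r: int, acc: float) -> None:
        nonlocal visited, p_sum, total
        if r == R - 1:
            # last row forced by the column margins
            visited += 1
            if visited > budget:
                raise EnumerationBudgetError(
                    f"exact enumeration exceeded the budget of {budget} tables; "
                    "use a Monte-Carlo permutation test for this table"
                )
            logp = acc - gammaln(col_rem + 1).sum()
            prob = math.exp(logp)
            total += prob
            if logp <= threshold:
                p_sum += prob
            return
        row_total = int(rows[r])
        later = int(remaining_rows[r + 1])
        # enumerate compositions of row_total over C cells bounded by col_rem
        def fill(c: int, left: int, acc2: float) -> None:
            if c == C - 1:
                if left <= col_rem[c] and (col_rem[c] - left) <= later:
                    col_rem[c] -= left
                    recurse(r + 1, acc2 - gammaln(left + 1))
                    col_rem[c] += left
                return
            hi = min(left, int(col_rem[c]))
            # leave enough for the later rows in this column
            lo = max(0, left - int(col_rem[c + 1:].sum()))
            for x in range(lo, hi + 1):
                col_rem[c] -= x
                fill(c + 1, left - x, acc2 - gammaln(x + 1))
                col_rem[c] += x

        fill(0, row_total, acc)

    recurse(0, const)
    if abs(total - 1.0) > 1e-6:
        warnings.warn(
            f"enumerated table probabilities sum to {total:.9f}, not 1",
            stacklevel=2,
        )
    return min(1.0, p_sum)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 12
) -> tuple[float, float]:
    """Mann-Whitney U with a two-sided p-value.

    Exact by full enumeration of group assignments (midrank ties honoured)
    when n_x + n_y <= ``exact_max_n``; otherwise the normal approximation
    with tie and continuity corrections. Returns (U of x, p).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    ranks = stats.rankdata(pooled)  # midranks
    u_x = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if n1 + n2 <= exact_max_n:
        mu = n1 * n2 / 2.0
        obs_dev = abs(u_x - mu)
        count = 0
        n_total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
            n_total += 1
            if abs(u - mu) >= obs_dev - 1e-9:
                count += 1
        return u_x, count / n_total

    res = stats.mannwhitneyu(
        xa, ya, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return u_x, float(res.pvalue)
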