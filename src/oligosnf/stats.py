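"""Survival and categorical statistics for the subtyping pipeline.

Kaplan–Meier product-limit curves, the k-group log-rank test, Cox
proportional-hazards regression (Newton–Raphson on the partial likelihood,
Breslow or Efron tie handling), Fisher's exact test, the Pearson chi-square
test and Benjamini–Hochberg adjustment. All p-values are two-sided.

KM, log-rank and Cox are implemented here directly — they are the
quantities the permutation test and the risk stratification are built on,
and the tests cross-check them against independent references. Fisher,
chi-square and BH delegate to scipy / statsmodels.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclasses.dataclass
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    effect: dict | None = None  # e.g. {"hazard_ratio": ...} or {"odds_ratio": ...}
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclasses.dataclass
class SurvivalCurve:
    """Right-censored product-limit estimate of a survival function."""

    event_times: np.ndarray   # sorted distinct times with >= 1 event
    survival: np.ndarray      # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray
    median: float | None

    def survival_at(self, t: float) -> float:
        """Step-function query S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event indicators must be 0/1")
    return times, events


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimator with right censoring."""
    times, events = _check_surv(times, events)
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    distinct = np.unique(t[e == 1])
    at_risk = np.array([(t >= ti).sum() for ti in distinct], dtype=int)
    d = np.array([((t == ti) & (e == 1)).sum() for ti in distinct], dtype=int)
    surv = np.cumprod(1.0 - d / at_risk) if len(distinct) else np.array([])
    below = np.nonzero(surv <= 0.5)[0] if len(distinct) else []
    median = float(distinct[below[0]]) if len(below) else None
    return SurvivalCurve(distinct, surv, at_risk, d, median)


def logrank_test(times, events, groups) -> TestResult:
    """k-group log-rank test.

    At every event time the observed minus expected event count per group
    is accumulated; the quadratic form with the hypergeometric covariance
    is referred to chi-square with k-1 degrees of freedom.
    """
    times, events = _check_surv(times, events)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank needs >= 2 non-empty groups")
    G = np.array([groups == g for g in labels])  # k x n boolean
    event_times = np.unique(times[events == 1])
    OmE = np.zeros(k)
    V = np.zeros((k, k))
    for ti in event_times:
        at_risk = times >= ti
        n = at_risk.sum()
        d = int(((times == ti) & (events == 1)).sum())
        ng = G[:, at_risk].sum(axis=1).astype(float)
        dg = (G[:, (times == ti) & (events == 1)]).sum(axis=1)
        OmE += dg - d * ng / n
        if n > 1:
            frac = ng / n
            hyper = d * (n - d) / (n - 1)
            V += hyper * (np.diag(frac) - np.outer(frac, frac))
    z = OmE[:-1]
    Vsub = V[:-1, :-1]
    stat = float(z @ np.linalg.pinv(Vsub) @ z) if Vsub.size else 0.0
    stat = max(stat, 0.0)
    p = float(sps.chi2.sf(stat, k - 1)) if stat > 0 else 1.0
    return TestResult(stat, k - 1, p, method="logrank")


# ---------------------------------------------------------------------------
# Cox proportional hazards

class ConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed (possibly monotone likelihood)."""


@dataclasses.dataclass
class CoxResult:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    ties: str
    n: int
    n_events: int

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def per_covariate(self) -> list[TestResult]:
        out = []
        for j, name in enumerate(self.names):
            z = self.coef[j] / self.se[j]
            out.append(
                TestResult(
                    statistic=float(z),
                    df=1,
                    p_value=float(2 * sps.norm.sf(abs(z))),
                    effect={"hazard_ratio": float(np.exp(self.coef[j])),
                            "log_hazard_ratio": float(self.coef[j]),
                            "se": float(self.se[j])},
                    method=f"cox_wald[{name}]",
                )
            )
        return out


def _cox_derivatives(beta, X, times, events, ties):
    """Partial log-likelihood, gradient and Hessian (Breslow or Efron ties)."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    order = np.argsort(-times, kind="stable")  # descending: accumulate risk sets
    Xo, to, eo, wo = X[order], times[order], events[order], w[order]

    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        ti = to[i]
        j = i
        while j < n and to[j] == ti:
            s0 += wo[j]
            s1 += wo[j] * Xo[j]
            s2 += wo[j] * np.outer(Xo[j], Xo[j])
            j += 1
        ev = [m for m in range(i, j) if eo[m] == 1]
        d = len(ev)
        if d:
            xs = Xo[ev].sum(axis=0)
            loglik += float(eta[order][ev].sum())
            if ties == "breslow":
                for _ in range(d):
                    mu = s1 / s0
                    loglik -= np.log(s0)
                    grad_term = mu
                    hess_term = s2 / s0 - np.outer(mu, mu)
                    grad -= grad_term
                    hess -= hess_term
            else:  # efron
                d0 = wo[ev].sum()
                d1 = (wo[ev, None] * Xo[ev]).sum(axis=0)
                d2 = sum(wo[m] * np.outer(Xo[m], Xo[m]) for m in ev)
                for ell in range(d):
                    c = ell / d
                    z0 = s0 - c * d0
                    z1 = s1 - c * d1
                    z2 = s2 - c * d2
                    mu = z1 / z0
                    loglik -= np.log(z0)
                    grad -= mu
                    hess -= z2 / z0 - np.outer(mu, mu)
            grad += xs
        i = j
    return loglik, grad, hess


def cox_ph(
    covariates,
    times,
    events,
    names: list[str] | None = None,
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton–Raphson.

    ``covariates`` is (n, p) (a 1-D array is treated as a single covariate).
    Requires no constant covariate and at least p observed events. Raises
    :class:`ConvergenceError` on non-convergence or monotone likelihood
    (perfect separation), advising a penalized fit.
    """
    X = np.asarray(covariates, float)
    if X.ndim == 1:
        X = X[:, None]
    times, events = _check_surv(times, events)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if X.std(axis=0).min() == 0:
        j = int(np.argmin(X.std(axis=0)))
        raise ValueError(f"covariate {names[j]!r} is constant")
    if events.sum() < p:
        raise ValueError("fewer events than covariates")
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")

    # center for numerical stability; beta is translation-invariant
    Xc = X - X.mean(axis=0)
    beta = np.zeros(p)
    loglik, grad, hess = _cox_derivatives(beta, Xc, times, events, ties)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                "singular information matrix; consider a penalized fit"
            ) from exc
        new_beta = beta - step
        new_ll, new_grad, new_hess = _cox_derivatives(new_beta, Xc, times, events, ties)
        halvings = 0
        while new_ll < loglik - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta - step
            new_ll, new_grad, new_hess = _cox_derivatives(new_beta, Xc, times, events, ties)
            halvings += 1
        rel = np.max(np.abs(new_beta - beta)) / max(1.0, np.max(np.abs(new_beta)))
        beta, loglik, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(beta)) > 50:
            raise ConvergenceError(
                "monotone partial likelihood (perfect separation); "
                "consider a penalized (ridge) Cox fit"
            )
        if rel < tol:
            break
    else:
        raise ConvergenceError(f"Newton–Raphson did not converge in {max_iter} iterations")

    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    return CoxResult(names=list(names), coef=beta, se=se, loglik=float(loglik),
                     ties=ties, n=n, n_events=int(events.sum()))


def cox_score_test(covariates, times, events, ties: str = "breslow") -> TestResult:
    """Score (Rao) test of beta = 0: U(0)' I(0)^{-1} U(0) ~ chi-square(p).

    For a single binary covariate with no tied event times this equals the
    two-group log-rank statistic.
    """
    X = np.asarray(covariates, float)
    if X.ndim == 1:
        X = X[:, None]
    times, events = _check_surv(times, events)
    Xc = X - X.mean(axis=0)
    _, grad, hess = _cox_derivatives(np.zeros(X.shape[1]), Xc, times, events, ties)
    info = -hess
    stat = float(grad @ np.linalg.solve(info, grad))
    p = X.shape[1]
    return TestResult(stat, p, float(sps.chi2.sf(stat, p)), method="cox_score")


# ---------------------------------------------------------------------------
# categorical tests and multiplicity

def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 count table, with odds ratio.

    A table with a zero margin carries no evidence of association: p = 1.
    """
    tab = np.asarray(table)
    if tab.shape != (2, 2) or (tab < 0).any() or not np.issubdtype(tab.dtype, np.integer):
        tab = np.asarray(table, float)
        if tab.shape != (2, 2) or (tab < 0).any() or (tab != np.round(tab)).any():
            raise ValueError("fisher_exact needs a 2x2 table of nonnegative integers")
        tab = tab.astype(int)
    odds, p = sps.fisher_exact(tab, alternative="two-sided")
    return TestResult(float(odds) if np.isfinite(odds) else np.inf, None, float(p),
                      effect={"odds_ratio": float(odds)}, method="fisher_exact")


def chisq_test(table) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table."""
    tab = np.asarray(table, float)
    if tab.ndim != 2 or (tab < 0).any():
        raise ValueError("chisq_test needs a nonnegative r x c table")
    total = tab.sum()
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / total if total else tab
    if (expected <= 0).any():
        raise ValueError("zero expected count; use an exact test instead")
    stat, p, df, _ = sps.chi2_contingency(tab, correction=False)
    return TestResult(float(stat), int(df), float(p), method="chi_square")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p.ravel(), method="fdr_bh")
    return adj.reshape(p.shape)
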