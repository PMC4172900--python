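"""Time-to-event primitives.

Endpoint construction from dates, person-years incidence rates, Cox
proportional-hazards fitting (Breslow tie handling, Newton-Raphson with
step-halving), and per-class survivor functions from the Breslow baseline
cumulative hazard.

The module also exposes a batched single-indicator Cox solver
(:func:`binary_cox_batch`) used by the recursive-partitioning split search,
where millions of one-parameter fits are needed inside permutation loops.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalRecord",
    "CoxFit",
    "IncidenceRate",
    "build_endpoint",
    "incidence_rate",
    "incidence_rate_from_counts",
    "event_proportion",
    "fit_cox",
    "breslow_baseline",
    "class_survival_curves",
    "risk_set_starts",
    "binary_cox_batch",
]

DAYS_PER_YEAR = 365.25

Z_95 = 1.959963984540054  # Phi^-1(0.975)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's follow-up for one endpoint.

    time is in years (days / 365.25); event is 1 if the endpoint event was
    observed, 0 if the subject was censored at last follow-up.
    """

    patient_id: str
    time: float
    event: int
    endpoint: str  # "OS" or "PFS"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"time must be >= 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model.

    Hazard ratios are exp(coefficients); 95% CIs are Wald intervals on the
    log-hazard scale, exp(beta +/- 1.96*SE).
    """

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    log_partial_likelihood: float
    log_partial_likelihood_null: float
    n: int
    n_events: int
    n_iter: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def lr_statistic(self) -> float:
        """Likelihood-ratio chi-square vs the null (beta = 0) model."""
        return 2.0 * (self.log_partial_likelihood - self.log_partial_likelihood_null)


@dataclass(frozen=True)
class IncidenceRate:
    """Events per 100 person-years, exact and as the truncated display integer."""

    n_events: int
    person_years: float
    rate_per_100py: float
    display_rate: int

    def __post_init__(self) -> None:
        if self.person_years <= 0:
            raise ValueError("person_years must be > 0")


# ---------------------------------------------------------------------------
# Endpoints and rates
# ---------------------------------------------------------------------------


def _as_date(d) -> _dt.date:
    if isinstance(d, _dt.datetime):
        return d.date()
    if isinstance(d, _dt.date):
        return d
    return _dt.date.fromisoformat(str(d))


def build_endpoint(
    baseline_date,
    event_date,
    last_followup_date,
    endpoint: str,
    patient_id: str = "",
) -> SurvivalRecord:
    """Turn visit dates into a (time, event) record.

    If ``event_date`` is given the record is an event at
    (event_date - baseline)/365.25 years; otherwise the subject is censored at
    last follow-up. Dates may be datetime.date or ISO strings.
    """
    baseline = _as_date(baseline_date)
    if event_date is not None:
        ev = _as_date(event_date)
        if ev < baseline:
            raise ValueError(f"event date {ev} precedes baseline {baseline}")
        return SurvivalRecord(patient_id, (ev - baseline).days / DAYS_PER_YEAR, 1, endpoint)
    fu = _as_date(last_followup_date)
    if fu < baseline:
        raise ValueError(f"follow-up date {fu} precedes baseline {baseline}")
    return SurvivalRecord(patient_id, (fu - baseline).days / DAYS_PER_YEAR, 0, endpoint)


def incidence_rate_from_counts(n_events: int, person_years: float) -> IncidenceRate:
    """Rate = 100 * events / person-years; display value truncated toward zero.

    Truncation (not rounding) matches the convention of reporting 17 events
    over 29 person-years as 58 per 100 person-years (17/29*100 = 58.62).
    """
    if person_years <= 0:
        raise ValueError("total person-years must be > 0")
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    rate = 100.0 * n_events / person_years
    return IncidenceRate(int(n_events), float(person_years), rate, int(rate))


def incidence_rate(times, events) -> IncidenceRate:
    """Crude incidence rate from per-subject follow-up times and event flags."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise ValueError("no records")
    return incidence_rate_from_counts(int(e.sum()), float(t.sum()))


def event_proportion(n_events: int, n: int) -> float:
    """Crude event percentage, e.g. 16 of 26 -> 61.5."""
    if n <= 0:
        raise ValueError("n must be > 0")
    return 100.0 * n_events / n


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties)
# ---------------------------------------------------------------------------


def risk_set_starts(time_sorted: np.ndarray) -> np.ndarray:
    """For each position i in an ascending-sorted time vector, the first index
    of the risk set {k : t_k >= t_i} (i.e. the first position tied with t_i)."""
    return np.searchsorted(time_sorted, time_sorted, side="left")


def _suffix_sum(a: np.ndarray) -> np.ndarray:
    """S[j] = sum over rows k >= j of a[k]; shape (n+1, ...) with S[n] = 0."""
    out = np.zeros((a.shape[0] + 1,) + a.shape[1:], dtype=float)
    out[:-1] = np.cumsum(a[::-1], axis=0)[::-1]
    return out


BETA_CAP = 15.0  # |beta| beyond this is treated as monotone likelihood


def fit_cox(
    times,
    events,
    covariates,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> CoxFit:
    """Maximize the Breslow partial likelihood by Newton-Raphson.

    Parameters
    ----------
    times, events : array-like, shape (n,)
        Follow-up times (years) and 0/1 event indicators.
    covariates : array-like, shape (n, p)
        Covariate matrix; p = 0 is allowed (null model, used for baseline
        hazard estimation only).

    Step-halving is applied whenever a Newton step would decrease the log
    partial likelihood; convergence when |delta logPL| < tol. Perfect
    separation of risk (monotone likelihood) is flagged via ``converged=False``
    with diagnostics, never reported as a silently huge hazard ratio.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if t.shape[0] != n or e.shape[0] != n:
        raise ValueError("times, events and covariates must have equal length")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    n_events = int(e.sum())
    if n_events < 1:
        raise ValueError("at least one event is required")
    if names is None:
        names = [f"x{j}" for j in range(p)]

    order = np.argsort(t, kind="stable")
    ts, es, Xs = t[order], e[order], X[order]
    starts = risk_set_starts(ts)
    ev = es == 1
    starts_e = starts[ev]

    # centering stabilises exp(eta); beta is location-invariant
    mu = Xs.mean(axis=0) if p else np.zeros(0)
    Xc = Xs - mu

    def loglik_grad_hess(beta):
        eta = Xc @ beta
        w = np.exp(eta)
        W = _suffix_sum(w)[starts_e]  # (E,)
        ll = float(eta[ev].sum() - np.log(W).sum())
        Sx = _suffix_sum(w[:, None] * Xc)[starts_e]  # (E, p)
        xbar = Sx / W[:, None]
        grad = Xc[ev].sum(axis=0) - xbar.sum(axis=0)
        Sxx = _suffix_sum(w[:, None, None] * Xc[:, :, None] * Xc[:, None, :])[starts_e]
        hess = (Sxx / W[:, None, None]).sum(axis=0) - np.einsum("ip,iq->pq", xbar, xbar)
        return ll, grad, hess

    beta = np.zeros(p)
    ll_null, _, _ = loglik_grad_hess(beta)
    if p == 0:
        return CoxFit(
            names=[], coef=np.zeros(0), se=np.zeros(0), hr=np.ones(0),
            ci95_low=np.ones(0), ci95_high=np.ones(0),
            log_partial_likelihood=ll_null, log_partial_likelihood_null=ll_null,
            n=n, n_events=n_events, n_iter=0, converged=True,
        )

    ll, grad, hess = loglik_grad_hess(beta)
    converged = False
    diagnostics: dict = {}
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            diagnostics["reason"] = "singular information matrix"
            break
        new_beta = beta + step
        new_ll, new_grad, new_hess = loglik_grad_hess(new_beta)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_grad, new_hess = loglik_grad_hess(new_beta)
            halvings += 1
        delta = new_ll - ll
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(beta)) > BETA_CAP:
            diagnostics["reason"] = "monotone likelihood (risk separation)"
            diagnostics["beta_at_stop"] = beta.copy()
            break
        if abs(delta) < tol:
            converged = True
            break

    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(hess)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    with np.errstate(over="ignore"):
        hr = np.exp(beta)
        ci_low = np.exp(beta - Z_95 * se)
        ci_high = np.exp(beta + Z_95 * se)
    return CoxFit(
        names=list(names),
        coef=beta,
        se=se,
        hr=hr,
        ci95_low=ci_low,
        ci95_high=ci_high,
        log_partial_likelihood=ll,
        log_partial_likelihood_null=ll_null,
        n=n,
        n_events=n_events,
        n_iter=it,
        converged=converged,
        diagnostics=diagnostics,
    )


def breslow_baseline(times, events, covariates=None, fit: CoxFit | None = None):
    """Breslow estimate of the baseline cumulative hazard.

    Returns (event_times, H0) where H0[k] = sum over event times t_i <= t_k of
    d_i / sum_{j at risk} exp(x_j' beta). With no covariates this reduces to
    the Nelson-Aalen estimator.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    if covariates is None or fit is None or len(fit.coef) == 0:
        w = np.ones_like(ts)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        w = np.exp(X[order] @ fit.coef)
    starts = risk_set_starts(ts)
    W = _suffix_sum(w)
    ev = es == 1
    # one increment 1/D per individual event; ties share the same denominator
    incr = 1.0 / W[starts[ev]]
    ut, inv = np.unique(ts[ev], return_inverse=True)
    dH = np.zeros(ut.shape[0])
    np.add.at(dH, inv, incr)
    return ut, np.cumsum(dH)


def class_survival_curves(
    times,
    events,
    class_labels,
    reference_class=None,
) -> tuple[pd.DataFrame, CoxFit]:
    """Per-class survivor functions from a Cox model on class indicators.

    Fits one Cox model with (k-1) indicator covariates (the reference class is
    the baseline), computes the Breslow baseline cumulative hazard H0, and
    returns step functions S_k(t) = exp(-H0(t))^{HR_k}, each starting at
    S(0) = 1. If ``reference_class`` is None the class with the lowest crude
    event rate (events per person-year) is used.

    Returns a tidy frame (time, class, survival) and the underlying CoxFit.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    labels = np.asarray(class_labels)
    classes = list(pd.unique(labels))
    counts = {c: int((labels == c).sum()) for c in classes}
    for c, cnt in counts.items():
        if cnt == 0:
            raise ValueError(f"class {c!r} has zero subjects")
    if reference_class is None:
        rates = {
            c: e[labels == c].sum() / max(t[labels == c].sum(), 1e-300) for c in classes
        }
        reference_class = min(sorted(classes, key=str), key=lambda c: rates[c])
    elif reference_class not in classes:
        raise ValueError(f"class {reference_class!r} has zero subjects")
    others = [c for c in sorted(classes, key=str) if c != reference_class]
    X = np.column_stack([(labels == c).astype(float) for c in others]) if others else np.zeros((t.size, 0))
    fit = fit_cox(t, e, X, names=[str(c) for c in others])
    ut, H0 = breslow_baseline(t, e, X, fit)
    S0 = np.exp(-H0)
    hr_map = {reference_class: 1.0}
    hr_map.update({c: float(h) for c, h in zip(others, fit.hr)})
    rows = []
    for c in [reference_class] + others:
        rows.append(pd.DataFrame({"time": 0.0, "class": [c], "survival": 1.0}))
        rows.append(
            pd.DataFrame({"time": ut, "class": c, "survival": S0 ** hr_map[c]})
        )
    curves = pd.concat(rows, ignore_index=True)
    return curves, fit


# ---------------------------------------------------------------------------
# Batched single-indicator Cox (the split-search workhorse)
# ---------------------------------------------------------------------------


def binary_cox_batch(
    n1_risk: np.ndarray,
    n0_risk: np.ndarray,
    s1: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """Fit many single binary-indicator Cox models at once.

    For a 0/1 covariate the Breslow log partial likelihood depends on the data
    only through, per individual event i, the at-risk counts in each group:

        logPL(beta) = beta*s1 - sum_i log(n0_i + n1_i * exp(beta))

    where s1 is the number of events in group 1. This lets the split search
    evaluate every candidate threshold and every covariate permutation as one
    vectorised 1-D Newton iteration.

    Parameters
    ----------
    n1_risk, n0_risk : (E, C) arrays
        Group-1 / group-0 at-risk counts at each of the E individual events,
        for each of the C candidate indicator columns.
    s1 : (C,) array
        Events in group 1 per candidate.

    Returns
    -------
    beta, lr, se, converged : arrays of shape (C,)
        MLE of the log hazard ratio, likelihood-ratio chi-square vs beta=0,
        Wald standard error, and a convergence flag (False signals monotone
        likelihood / separation; such candidates should be discarded).
    """
    n1 = np.asarray(n1_risk)
    if n1.dtype not in (np.float32, np.float64):
        n1 = n1.astype(np.float64)
    dt = n1.dtype
    n0 = np.asarray(n0_risk, dtype=dt)
    s1 = np.asarray(s1, dtype=dt)
    if dt == np.float32:
        # float32 cannot resolve 1e-8 steps; the cheap path is meant for
        # permutation nulls where 1e-4 beta precision is ample
        tol = max(tol, 1e-4)
    C = s1.shape[0]
    n_events = n1.shape[0]
    beta_out = np.zeros(C, dtype=dt)
    conv_out = np.zeros(C, dtype=bool)
    # start from the log observed/expected ratio (the log-rank-style
    # one-step estimate); it is usually within ~0.1 of the MLE, so Newton
    # needs only a handful of iterations
    denom0 = n0 + n1
    e1 = (n1 / denom0).sum(axis=0)
    e0 = n_events - e1
    s0 = n_events - s1
    with np.errstate(divide="ignore", invalid="ignore"):
        init = np.log((s1 + 0.5) / (e1 + 0.5)) - np.log((s0 + 0.5) / (e0 + 0.5))
    init = np.clip(np.nan_to_num(init), -4.0, 4.0)
    # columns leave the iteration as they converge (or pin at the cap), so a
    # few slow near-separated candidates do not keep the whole batch running
    idx = np.arange(C)
    n1a, n0a, s1a = n1, n0, s1
    beta = init
    for _ in range(max_iter):
        if idx.size == 0:
            break
        eb = np.exp(beta)
        denom = n0a + n1a * eb
        p1 = n1a * eb / denom
        U = s1a - p1.sum(axis=0)
        info = (p1 * (1.0 - p1)).sum(axis=0)
        step = np.clip(U / np.maximum(info, 1e-12), -2.0, 2.0)
        capped = np.abs(beta) >= BETA_CAP
        step[capped] = 0.0
        beta = np.clip(beta + step, -BETA_CAP, BETA_CAP)
        done = (np.abs(step) < tol) | capped
        if done.any():
            beta_out[idx[done]] = beta[done]
            conv_out[idx[done]] = ~capped[done]
            keep = ~done
            idx, beta, s1a = idx[keep], beta[keep], s1a[keep]
            n1a, n0a = n1a[:, keep], n0a[:, keep]
    if idx.size:  # hit max_iter without settling
        beta_out[idx] = beta
        conv_out[idx] = False
    eb = np.exp(beta_out)
    denom = n0 + n1 * eb
    p1 = n1 * eb / denom
    info = (p1 * (1.0 - p1)).sum(axis=0)
    ll = beta_out * s1 - np.log(denom).sum(axis=0)
    ll0 = -np.log(denom0).sum(axis=0)
    lr = np.maximum(2.0 * (ll - ll0), 0.0)
    with np.errstate(divide="ignore"):
        se = 1.0 / np.sqrt(np.maximum(info, 1e-300))
    return beta_out, lr, se, conv_out
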