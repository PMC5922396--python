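"""Survival analysis: Kaplan-Meier, log-rank, Cox proportional hazards with a
gamma shared frailty, covariate transforms, forward stepwise selection, and
Uno's inverse-probability-of-censoring-weighted C-index with bootstrap model
comparison.

Model
-----
For patient *i* in dataset (frailty group) *g* the hazard is

    h_i(t) = z_g * lambda0(t) * exp(x_i' beta),   z_g ~ Gamma(1/theta, theta)

with E[z] = 1 and Var[z] = theta.  ``theta = 0`` collapses to the ordinary
Cox model.  beta is estimated by Newton-Raphson on the Efron-approximation
partial likelihood with step-halving; the frailty model is fitted by an EM
algorithm (closed-form E-step for gamma frailty) nested inside a 1-D profile
maximization of the integrated (marginal) log-likelihood over theta.  When
the profile optimum is at theta ~ 0 the model is reported as collapsed to
the plain fit.

Kaplan-Meier curves and the log-rank test delegate to lifelines; Uno's
C-index delegates to scikit-survival (both standard estimators).  The Cox
machinery is implemented here because no installed package fits the gamma
shared-frailty model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sksurv.metrics import concordance_index_ipcw
from sksurv.util import Surv


class SurvivalError(ValueError):
    """Invalid input to a survival routine."""


class SingularDesignError(SurvivalError):
    """Design matrix is singular (e.g. a zero-variance covariate)."""


class ConvergenceError(RuntimeError):
    """Newton iterations failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# covariate transforms
# ---------------------------------------------------------------------------

def count_log_transform(x):
    """Shifted log for per-7.5 mL counts: ln(0.0001 + count/1000)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise SurvivalError("counts must be non-negative")
    return np.log(1e-4 + x / 1000.0)


def enzyme_log_transform(x):
    """Shifted log for enzyme activities: ln(0.001 + U/L / 100)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise SurvivalError("enzyme activities must be non-negative")
    return np.log(1e-3 + x / 100.0)


#: covariate name -> transform applied before Cox modelling
TRANSFORMS = {
    "ctc": count_log_transform,
    "tdev": count_log_transform,
    "ldh": enzyme_log_transform,
    "alp": enzyme_log_transform,
}


def transform_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``table`` with the count/enzyme covariates replaced by
    their shifted-log transforms (see :data:`TRANSFORMS`); other columns are
    untouched.  The transforms applied are recorded in
    ``result.attrs["transforms"]``.
    """
    out = table.copy()
    applied = {}
    for name, fn in TRANSFORMS.items():
        if name in out.columns:
            out[name] = fn(out[name].to_numpy())
            applied[name] = fn.__name__
    out.attrs["transforms"] = applied
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

@dataclass
class KmCurve:
    """Product-limit survival curve.

    ``median`` is the smallest time with S(t) <= 0.5, or ``inf`` when the
    curve never reaches 0.5 ("median not reached" is a value, not an error).
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float
    n: int
    n_events: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_fit(time, event=None) -> KmCurve:
    """Kaplan-Meier estimate; ``event`` defaults to all-events."""
    time = np.asarray(time, dtype=float)
    if time.size == 0:
        raise SurvivalError("empty sample")
    if np.any(time <= 0):
        raise SurvivalError("survival times must be positive")
    if event is None:
        event = np.ones_like(time)
    event = np.asarray(event, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    return KmCurve(
        times=times,
        survival=surv,
        at_risk=at_risk,
        median=median,
        n=int(time.size),
        n_events=int(event.sum()),
    )


def logrank(*groups) -> tuple[float, float]:
    """Log-rank test over >= 2 groups, each a ``(time, event)`` pair.

    Returns ``(chi_squared, p)`` with ``groups - 1`` degrees of freedom.
    """
    if len(groups) < 2:
        raise SurvivalError("log-rank needs at least two groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        if t.size == 0:
            raise SurvivalError("log-rank group with zero subjects")
        e = np.ones_like(t) if e is None else np.asarray(e, dtype=int)
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, i))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox partial likelihood (Efron ties)
# ---------------------------------------------------------------------------

class _CoxData:
    """Pre-sorted design for repeated partial-likelihood evaluations."""

    def __init__(self, time, event, X, groups=None):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if np.any(time <= 0):
            raise SurvivalError("survival times must be positive")
        if not np.isin(event, (0, 1)).all():
            raise SurvivalError("event flags must be 0/1")
        order = np.argsort(time, kind="stable")
        self.time = time[order]
        self.event = event[order]
        self.X = X[order]
        self.order = order
        self.groups = None if groups is None else np.asarray(groups)[order]
        self.n, self.p = self.X.shape
        # tie groups over *event* times: (risk_start, event_row_indices)
        self.tie_groups = []
        i = 0
        while i < self.n:
            j = i
            while j < self.n and self.time[j] == self.time[i]:
                j += 1
            d_idx = np.arange(i, j)[self.event[i:j] == 1]
            if d_idx.size:
                self.tie_groups.append((i, d_idx))
            i = j
        # split into the vectorizable untied case and the Efron-tie loop
        self.single_starts = np.array(
            [s for s, d in self.tie_groups if d.size == 1], dtype=int
        )
        self.single_events = np.array(
            [d[0] for s, d in self.tie_groups if d.size == 1], dtype=int
        )
        self.multi_groups = [(s, d) for s, d in self.tie_groups if d.size > 1]
        self.event_rows = np.flatnonzero(self.event == 1)

    def loglik(self, beta, offset=None):
        """Efron partial log-likelihood with gradient and Hessian."""
        eta = self.X @ beta if self.p else np.zeros(self.n)
        if offset is not None:
            eta = eta + offset
        eta = eta - eta.max()  # guard overflow; PL is shift-invariant
        w = np.exp(eta)
        wx = w[:, None] * self.X
        wxx = wx[:, :, None] * self.X[:, None, :]
        # suffix sums over the risk sets
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum(wx[::-1], axis=0)[::-1]
        S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

        ll = float(eta[self.event_rows].sum())
        grad = self.X[self.event_rows].sum(axis=0)
        hess = np.zeros((self.p, self.p))
        if self.single_starts.size:
            s0 = S0[self.single_starts]
            ll -= float(np.log(s0).sum())
            m1 = S1[self.single_starts] / s0[:, None]
            grad -= m1.sum(axis=0)
            hess -= (
                (S2[self.single_starts] / s0[:, None, None]).sum(axis=0)
                - m1.T @ m1
            )
        for start, d_idx in self.multi_groups:
            d = d_idx.size
            sd0 = w[d_idx].sum()
            sd1 = wx[d_idx].sum(axis=0)
            sd2 = wxx[d_idx].sum(axis=0)
            for l in range(d):
                f = l / d
                phi0 = S0[start] - f * sd0
                phi1 = S1[start] - f * sd1
                phi2 = S2[start] - f * sd2
                ll -= math.log(phi0)
                m1 = phi1 / phi0
                grad -= m1
                hess -= phi2 / phi0 - np.outer(m1, m1)
        return ll, grad, hess

    def newton(self, offset=None, beta0=None, tol=1e-9, max_iter=60):
        """Maximize the partial likelihood; step-halving keeps the likelihood
        non-decreasing across iterations."""
        beta = np.zeros(self.p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
        ll, grad, hess = self.loglik(beta, offset)
        trace = [ll]
        if self.p == 0:
            return beta, ll, hess, trace
        for _ in range(max_iter):
            try:
                delta = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError as exc:
                raise SingularDesignError(f"singular information matrix: {exc}") from exc
            step = 1.0
            for _half in range(40):
                cand = beta + step * delta
                ll_new, grad_new, hess_new = self.loglik(cand, offset)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                step /= 2.0
            else:
                raise ConvergenceError("step-halving failed", trace)
            improved = ll_new - ll
            beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
            trace.append(ll)
            if abs(improved) < tol and np.max(np.abs(grad)) < 1e-6:
                return beta, ll, hess, trace
        raise ConvergenceError(
            f"Newton did not converge in {max_iter} iterations", trace
        )

    def breslow_cumhaz(self, beta, offset=None):
        """Breslow cumulative baseline hazard Lambda0 evaluated at each
        subject's own time (sorted order), plus the per-event-time increments.
        """
        eta = self.X @ beta if self.p else np.zeros(self.n)
        if offset is not None:
            eta = eta + offset
        w = np.exp(eta)
        S0 = np.cumsum(w[::-1])[::-1]
        increments = []  # (time_index_start, lambda0_k, d)
        cum = np.zeros(self.n)
        running = 0.0
        k = 0
        tie_iter = iter(self.tie_groups)
        current = next(tie_iter, None)
        i = 0
        while i < self.n:
            j = i
            while j < self.n and self.time[j] == self.time[i]:
                j += 1
            if current is not None and current[0] == i:
                d = current[1].size
                lam = d / S0[i]
                running += lam
                increments.append((i, lam, d))
                current = next(tie_iter, None)
            cum[i:j] = running
            i = j
        return cum, increments


def _design(df, covariates, duration_col, event_col):
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise SurvivalError(f"unknown covariates: {missing}")
    X = df[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((len(df), 0))
    if covariates:
        variances = X.var(axis=0)
        dead = [c for c, v in zip(covariates, variances) if v == 0]
        if dead:
            raise SingularDesignError(f"zero-variance covariates: {dead}")
    return df[duration_col].to_numpy(dtype=float), df[event_col].to_numpy(dtype=int), X


@dataclass
class CoxResult:
    """Fitted (frailty) Cox model.

    ``summary`` has one row per covariate: ``coef``, ``hr``, ``se``,
    ``ci_lower``, ``ci_upper``, ``p`` (Wald, 95%).  ``log_likelihood`` is the
    Efron partial log-likelihood for plain fits and the integrated (marginal)
    log-likelihood for frailty fits — comparable across nested models fitted
    with the same frailty setting.
    """

    summary: pd.DataFrame
    covariates: list
    beta: np.ndarray
    log_likelihood: float
    frailty_variance: float = 0.0
    frailty: dict | None = None
    n: int = 0
    n_events: int = 0
    n_iter: int = 0
    converged: bool = True
    frailty_collapsed: bool = False
    iteration_trace: list = field(default_factory=list, repr=False)

    def predict_risk(self, df: pd.DataFrame) -> np.ndarray:
        """Linear predictor x' beta (frailty term excluded)."""
        if not self.covariates:
            return np.zeros(len(df))
        X = df[list(self.covariates)].to_numpy(dtype=float)
        return X @ self.beta

    def to_json_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "summary": self.summary.reset_index().to_dict(orient="records"),
            "log_likelihood": self.log_likelihood,
            "frailty_variance": self.frailty_variance,
            "frailty": self.frailty,
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
        }


def _wald_summary(covariates, beta, hess):
    if not covariates:
        return pd.DataFrame(
            columns=["coef", "hr", "se", "ci_lower", "ci_upper", "p"]
        )
    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(f"singular information matrix: {exc}") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    halfwidth = 1.959963984540054 * se
    return pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "se": se,
            "ci_lower": np.exp(beta - halfwidth),
            "ci_upper": np.exp(beta + halfwidth),
            "p": p,
        },
        index=list(covariates),
    )


def _frailty_em(data: _CoxData, theta: float, beta0=None, z0=None, max_iter=60, tol=1e-9):
    """Fit the gamma-frailty model for fixed frailty variance theta.

    Maximizes the penalized partial likelihood

        PPL(beta, omega) = PL(beta, omega) + (1/theta) * sum_g (omega_g - e^omega_g)

    jointly over beta and the per-group log-frailties omega by Newton with
    step-halving; the stationary point satisfies the closed-form gamma E-step
    z_g = (1/theta + d_g) / (1/theta + A_g), so this is the same fit as the
    EM algorithm but with quadratic convergence.  Returns (beta, z, hessian,
    integrated log-likelihood, iterations).
    """
    groups = data.groups
    labels = list(pd.unique(groups))
    g_index = {lab: np.flatnonzero(groups == lab) for lab in labels}
    d_g = {lab: int(data.event[idx].sum()) for lab, idx in g_index.items()}
    G = (np.asarray(groups)[:, None] == np.asarray(labels, dtype=object)[None, :]).astype(float)
    ext = _CoxData(data.time, data.event, np.hstack([data.X, G]) if data.p else G)
    p, g = data.p, len(labels)
    inv_theta = 1.0 / theta

    b = np.zeros(p + g)
    if beta0 is not None:
        b[:p] = beta0
    if z0 is not None:
        b[p:] = np.log(np.clip([z0[lab] for lab in labels], 1e-12, None))

    def penalized(bvec):
        ll, grad, hess = ext.loglik(bvec)
        om = np.clip(bvec[p:], -30.0, 30.0)
        zexp = np.exp(om)
        ll += inv_theta * float((om - zexp).sum())
        grad = grad.copy()
        grad[p:] += inv_theta * (1.0 - zexp)
        hess = hess.copy()
        hess[np.arange(p, p + g), np.arange(p, p + g)] -= inv_theta * zexp
        return ll, grad, hess

    ll, grad, hess = penalized(b)
    it = 0
    for it in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError(f"singular penalized information: {exc}") from exc
        step = 1.0
        for _half in range(40):
            cand = b + step * delta
            ll_new, grad_new, hess_new = penalized(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step /= 2.0
        else:
            raise ConvergenceError("frailty step-halving failed")
        improved = ll_new - ll
        b, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if abs(improved) < tol and np.max(np.abs(grad)) < 1e-7:
            break

    beta = b[:p]
    om = b[p:]
    z = {lab: float(np.exp(om[i])) for i, lab in enumerate(labels)}
    # accumulated group hazards and baseline under the fitted frailties
    offset = G @ om
    cum, increments = data.breslow_cumhaz(beta, offset=offset)
    eta = data.X @ beta if data.p else np.zeros(data.n)
    risk = np.exp(eta)
    A = {lab: float((cum[idx] * risk[idx]).sum()) for lab, idx in g_index.items()}
    # integrated log-likelihood (gamma frailty integrated out analytically)
    marg = 0.0
    for lab in labels:
        marg += (
            gammaln(inv_theta + d_g[lab])
            - gammaln(inv_theta)
            + d_g[lab] * math.log(theta)
            - (inv_theta + d_g[lab]) * math.log1p(theta * A[lab])
        )
    for start, d_idx in data.tie_groups:
        marg += eta[d_idx].sum()
    for _, lam, d in increments:
        marg += d * math.log(lam)
    # beta covariance from the (beta, beta) block of the penalized information
    hess_beta = np.linalg.inv(np.linalg.inv(-hess)[:p, :p]) * -1.0 if p else hess[:0, :0]
    return beta, z, hess_beta, marg, it


def _plain_full_loglik(data: _CoxData, beta):
    """theta -> 0 limit of the integrated likelihood (plain Cox with its
    Breslow baseline plugged in); used to decide frailty collapse."""
    cum, increments = data.breslow_cumhaz(beta)
    eta = data.X @ beta if data.p else np.zeros(data.n)
    risk = np.exp(eta)
    ll = -float((cum * risk).sum())
    for start, d_idx in data.tie_groups:
        ll += eta[d_idx].sum()
    for _, lam, d in increments:
        ll += d * math.log(lam)
    return ll


def cox_fit(
    df: pd.DataFrame,
    covariates,
    duration_col: str = "os_months",
    event_col: str = "event",
    frailty_col: str | None = None,
    theta_max: float = 5.0,
) -> CoxResult:
    """Fit a Cox proportional-hazards model, optionally with a gamma shared
    frailty per level of ``frailty_col``.

    The number of events must exceed the number of covariates.  Raises
    :class:`SingularDesignError` for zero-variance or collinear designs and
    :class:`ConvergenceError` (with an iteration trace) on failure.
    """
    covariates = list(covariates)
    time, event, X = _design(df, covariates, duration_col, event_col)
    if event.sum() < len(covariates) + 1:
        raise SurvivalError("too few events for the requested covariates")
    groups = df[frailty_col].to_numpy() if frailty_col else None
    data = _CoxData(time, event, X, groups=groups)

    if frailty_col is None:
        beta, ll, hess, trace = data.newton()
        return CoxResult(
            summary=_wald_summary(covariates, beta, hess),
            covariates=covariates,
            beta=beta,
            log_likelihood=ll,
            n=data.n,
            n_events=int(event.sum()),
            n_iter=len(trace) - 1,
            iteration_trace=trace,
        )

    # plain fit doubles as the theta = 0 reference
    beta0, ll_partial, hess0, trace0 = data.newton()
    ll_theta0 = _plain_full_loglik(data, beta0)

    cache = {}
    warm = {"beta": beta0, "z": None}

    def neg_marg(log_theta):
        theta = math.exp(float(log_theta))
        if theta not in cache:
            beta, z, hess, marg, iters = _frailty_em(
                data, theta, beta0=warm["beta"], z0=warm["z"]
            )
            warm["beta"], warm["z"] = beta, z
            cache[theta] = (beta, z, hess, marg, iters)
        return -cache[theta][3]

    # coarse profile of the marginal likelihood, then local refinement; the
    # grid screen makes the common boundary case (theta ~ 0) cheap
    grid = np.linspace(math.log(1e-3), math.log(theta_max), 7)
    profile = np.array([neg_marg(lt) for lt in grid])
    i_best = int(np.argmin(profile))
    if i_best == 0 and -profile[0] <= ll_theta0 + 1e-6:
        theta_hat = math.exp(grid[0])
    else:
        lo = grid[max(i_best - 1, 0)]
        hi = grid[min(i_best + 1, len(grid) - 1)]
        res = minimize_scalar(
            neg_marg,
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 5e-3, "maxiter": 25},
        )
        theta_hat = math.exp(float(res.x))
        if neg_marg(math.log(theta_hat)) > profile[i_best]:
            theta_hat = math.exp(grid[i_best])
    beta, z, hess, marg, iters = cache[theta_hat]

    if marg <= ll_theta0 + 1e-6 or theta_hat <= 2e-3:
        # frailty variance estimate at (or numerically on) the boundary:
        # model collapses to the plain Cox fit
        return CoxResult(
            summary=_wald_summary(covariates, beta0, hess0),
            covariates=covariates,
            beta=beta0,
            log_likelihood=ll_theta0,
            frailty_variance=0.0,
            frailty={lab: 1.0 for lab in pd.unique(groups)},
            n=data.n,
            n_events=int(event.sum()),
            n_iter=len(trace0) - 1,
            frailty_collapsed=True,
            iteration_trace=trace0,
        )
    return CoxResult(
        summary=_wald_summary(covariates, beta, hess),
        covariates=covariates,
        beta=beta,
        log_likelihood=marg,
        frailty_variance=theta_hat,
        frailty={lab: float(v) for lab, v in z.items()},
        n=data.n,
        n_events=int(event.sum()),
        n_iter=iters,
        iteration_trace=[],
    )


def cox_score_test(df, covariate, duration_col="os_months", event_col="event"):
    """Score (Rao) test of beta = 0 for a single covariate.

    For a binary covariate without tied event times this equals the log-rank
    chi-squared statistic (the classical equivalence).
    """
    time, event, X = _design(df, [covariate], duration_col, event_col)
    data = _CoxData(time, event, X)
    _, grad, hess = data.loglik(np.zeros(1))
    info = -hess
    chi2 = float(grad @ np.linalg.solve(info, grad))
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# forward stepwise selection
# ---------------------------------------------------------------------------

def forward_stepwise(
    df: pd.DataFrame,
    candidates,
    duration_col: str = "os_months",
    event_col: str = "event",
    p_in: float = 0.05,
    p_out: float = 0.10,
    frailty_col: str | None = None,
    max_steps: int = 50,
):
    """Forward stepwise Cox selection with backward elimination.

    At each step the candidate with the smallest likelihood-ratio entry
    p-value below ``p_in`` is added, then any included covariate whose LR
    removal p-value exceeds ``p_out`` is dropped; iteration stops when the
    model no longer changes.  An empty final model is a valid outcome.

    Returns ``(final CoxResult, trace)``; the trace records every add/drop
    with its p-value.
    """
    candidates = list(candidates)
    included: list = []
    trace = []

    def fit(covs):
        return cox_fit(
            df,
            covs,
            duration_col=duration_col,
            event_col=event_col,
            frailty_col=frailty_col,
        )

    current = fit(included)
    for step in range(max_steps):
        changed = False
        # forward
        best = None
        for cand in candidates:
            if cand in included:
                continue
            try:
                mod = fit(included + [cand])
            except (SurvivalError, ConvergenceError):
                continue
            lr = 2.0 * (mod.log_likelihood - current.log_likelihood)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            if best is None or p < best[1]:
                best = (cand, p, mod)
        if best is not None and best[1] < p_in:
            included.append(best[0])
            current = best[2]
            trace.append({"step": step, "action": "add", "covariate": best[0], "p": best[1]})
            changed = True
        # backward
        removed = True
        while removed and included:
            removed = False
            worst = None
            for cov in included:
                reduced = fit([c for c in included if c != cov])
                lr = 2.0 * (current.log_likelihood - reduced.log_likelihood)
                p = float(stats.chi2.sf(max(lr, 0.0), df=1))
                if worst is None or p > worst[1]:
                    worst = (cov, p, reduced)
            if worst is not None and worst[1] > p_out:
                included.remove(worst[0])
                current = worst[2]
                trace.append(
                    {"step": step, "action": "drop", "covariate": worst[0], "p": worst[1]}
                )
                removed = True
                changed = True
        if not changed:
            break
    return current, trace


# ---------------------------------------------------------------------------
# Uno's C-index and bootstrap model comparison
# ---------------------------------------------------------------------------

def uno_c(time, event, risk, tau: float = 24.0) -> float:
    """Uno's IPCW concordance index truncated at ``tau`` months.

    Pairs are weighted by the inverse squared Kaplan-Meier estimate of the
    censoring distribution; only pairs whose earlier (event) time precedes
    ``tau`` contribute.  Delegates to scikit-survival's estimator.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    risk = np.asarray(risk, dtype=float)
    y = Surv.from_arrays(event=event, time=time)
    try:
        c, *_ = concordance_index_ipcw(y, y, risk, tau=tau)
    except ValueError as exc:
        raise SurvivalError(f"no usable pairs before tau={tau}: {exc}") from exc
    return float(c)


@dataclass
class CIndexReport:
    """Bootstrap comparison of two models' truncated C-indices."""

    tau: float
    c_a: float
    c_b: float
    delta: float
    ci_lower: float
    ci_upper: float
    p_value: float
    reps_requested: int
    reps_used: int
    deltas: np.ndarray = field(repr=False, default=None)

    def to_json_dict(self) -> dict:
        return {
            "tau": self.tau,
            "c_index_a": self.c_a,
            "c_index_b": self.c_b,
            "delta": self.delta,
            "ci_95": [self.ci_lower, self.ci_upper],
            "p_value": self.p_value,
            "bootstrap_reps": self.reps_used,
        }


def bootstrap_c_delta(
    df: pd.DataFrame,
    covariates_a,
    covariates_b,
    duration_col: str = "os_months",
    event_col: str = "event",
    tau: float = 24.0,
    reps: int = 1000,
    seed: int = 0,
    frailty_col: str | None = None,
    bootstrap_frailty: bool = False,
) -> CIndexReport:
    """Compare two Cox models by Uno's C at ``tau`` with patient bootstrap.

    Point estimates come from fits on the full sample (with frailty if
    ``frailty_col`` is given); each of ``reps`` replicates resamples patients
    with replacement, refits both models (plain Cox unless
    ``bootstrap_frailty``) and recomputes both C-indices.  Reports
    ``delta = C_a - C_b``, the percentile 95% CI and a two-sided normal
    p-value from delta / bootstrap SE.  Replicates that fail to fit are
    skipped and counted.  Deterministic for a fixed seed.
    """
    if reps < 1:
        raise SurvivalError("reps must be >= 1")

    def fit_pair(sample, use_frailty):
        fcol = frailty_col if use_frailty else None
        mod_a = cox_fit(sample, covariates_a, duration_col, event_col, frailty_col=fcol)
        mod_b = cox_fit(sample, covariates_b, duration_col, event_col, frailty_col=fcol)
        t = sample[duration_col].to_numpy(dtype=float)
        e = sample[event_col].to_numpy(dtype=int)
        ca = uno_c(t, e, mod_a.predict_risk(sample), tau=tau)
        cb = uno_c(t, e, mod_b.predict_risk(sample), tau=tau)
        return ca, cb

    c_a, c_b = fit_pair(df, use_frailty=frailty_col is not None)
    delta = c_a - c_b

    rng = np.random.default_rng(seed)
    deltas = []
    failures = 0
    n = len(df)
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        sample = df.iloc[idx].reset_index(drop=True)
        try:
            ca, cb = fit_pair(sample, use_frailty=bootstrap_frailty and frailty_col is not None)
        except (SurvivalError, ConvergenceError, np.linalg.LinAlgError):
            failures += 1
            continue
        deltas.append(ca - cb)
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise SurvivalError("all bootstrap replicates failed to fit")
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    sd = float(deltas.std(ddof=1)) if deltas.size > 1 else 0.0
    if sd > 0:
        p = float(2 * stats.norm.sf(abs(delta) / sd))
    else:
        p = 1.0
    return CIndexReport(
        tau=tau,
        c_a=c_a,
        c_b=c_b,
        delta=delta,
        ci_lower=float(lo),
        ci_upper=float(hi),
        p_value=min(p, 1.0),
        reps_requested=reps,
        reps_used=int(deltas.size),
        deltas=deltas,
    )
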