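"""Synthetic patient cohorts with the statistical structure the survival
analysis assumes.

Each patient carries: overdispersed (negative binomial) CTC and tdEV counts
per 7.5 mL with a configurable Gaussian-copula correlation between them on
the latent scale; lognormal plasma/serum markers (CK18, ccCK18, PSA, LDH,
ALP); normal albumin, hemoglobin and age; a dataset label; and an overall
survival time in months drawn from a proportional-hazards model

    h_i(t) = z_g * lambda0 * exp(x_i' beta)

with a gamma(mean 1, variance theta) shared frailty z_g per dataset label, an
exponential baseline, and independent exponential right-censoring whose rate
is solved numerically so the realized censoring fraction matches the
configured rate in expectation.  Hazard covariates x_i are the log-transformed
counts/enzymes (same shifted-log transforms the Cox module applies), centered
at their sample means so ``lambda0`` keeps its interpretation for a median
patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ctcev.survival import transform_covariates


class CohortSimError(ValueError):
    """Invalid cohort simulation parameters."""


#: lognormal (mu, sigma) of plasma/serum markers; medians roughly at the
#: scale reported for castration-resistant prostate cancer cohorts
DEFAULT_LOGNORMAL = {
    "ck18": (6.0, 0.7),    # median ~400 U/L
    "cck18": (5.3, 0.7),   # median ~200 U/L
    "psa": (4.6, 1.2),     # median ~100 ng/mL
    "ldh": (5.5, 0.4),     # median ~245 U/L
    "alp": (4.8, 0.6),     # median ~120 U/L
}

#: normal (mean, sd) covariates
DEFAULT_NORMAL = {
    "albumin": (4.0, 0.45),     # g/dL
    "hemoglobin": (12.5, 1.6),  # g/dL
    "age": (69.0, 8.0),         # years
}


@dataclass
class CohortSimParams:
    """Cohort generator parameters.

    Default sample sizes mirror a retrospective set of 84 and a prospective
    set of 45 patients.  The tdEV count mean defaults to 20x the CTC mean,
    the frequency ratio at which these vesicles outnumber intact tumor cells
    in the same image archives.  ``coefficients`` are log-hazard slopes on
    the *transformed* covariates (see :data:`ctcev.survival.TRANSFORMS`);
    unlisted covariates get slope 0.
    """

    n_patients: dict = field(default_factory=lambda: {"retrospective": 84, "prospective": 45})
    ctc_mean: float = 10.0
    ctc_dispersion: float = 0.8
    tdev_mean: float = 200.0
    tdev_dispersion: float = 1.0
    ctc_tdev_corr: float = 0.8
    lognormal: dict = field(default_factory=lambda: dict(DEFAULT_LOGNORMAL))
    normal: dict = field(default_factory=lambda: dict(DEFAULT_NORMAL))
    baseline_rate: float = 0.05   # events per month; median ~14 months at x = x_bar
    coefficients: dict = field(default_factory=dict)
    frailty_variance: float = 0.0
    censoring_rate: float = 0.2
    seed: int = 0
    require_signal: bool = False

    def validate(self) -> None:
        if not self.n_patients:
            raise CohortSimError("need at least one dataset label")
        for label, n in self.n_patients.items():
            if n < 2:
                raise CohortSimError(f"n_patients[{label!r}] must be >= 2")
        for name, v in [
            ("ctc_mean", self.ctc_mean),
            ("tdev_mean", self.tdev_mean),
            ("ctc_dispersion", self.ctc_dispersion),
            ("tdev_dispersion", self.tdev_dispersion),
            ("baseline_rate", self.baseline_rate),
        ]:
            if v <= 0:
                raise CohortSimError(f"{name} must be > 0")
        if self.frailty_variance < 0:
            raise CohortSimError("frailty_variance must be >= 0")
        if not (0 <= self.censoring_rate < 1):
            raise CohortSimError("censoring_rate must be in [0, 1)")
        if not (-1 < self.ctc_tdev_corr < 1):
            raise CohortSimError("ctc_tdev_corr must be in (-1, 1)")
        if self.require_signal and not any(v != 0 for v in self.coefficients.values()):
            raise CohortSimError(
                "parameter recovery requested but all log-hazard coefficients are zero"
            )

    def to_json_dict(self) -> dict:
        return asdict(self)


def _nb_n_p(mean: float, dispersion: float):
    """Negative binomial (n, p) from mean and dispersion r (var = mu + mu^2/r)."""
    n = dispersion
    p = n / (n + mean)
    return n, p


def _correlated_counts(rng, n, ctc_mean, ctc_disp, tdev_mean, tdev_disp, rho):
    """NB count pair via a Gaussian copula with latent correlation rho."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
    u = stats.norm.cdf(z)
    # clip away u == 1 which would map to inf under ppf
    u = np.clip(u, 1e-12, 1 - 1e-12)
    n1, p1 = _nb_n_p(ctc_mean, ctc_disp)
    n2, p2 = _nb_n_p(tdev_mean, tdev_disp)
    ctc = stats.nbinom.ppf(u[:, 0], n1, p1).astype(int)
    tdev = stats.nbinom.ppf(u[:, 1], n2, p2).astype(int)
    return ctc, tdev


def _censoring_rate_solver(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_i c/(c + h_i) = target."""
    def frac(c):
        return np.mean(c / (c + hazards)) - target

    lo, hi = 1e-10, 1e6
    return float(optimize.brentq(frac, lo, hi, xtol=1e-12, rtol=1e-10))


def generate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Generate one cohort table.

    Returns a DataFrame with one row per patient and columns ``dataset``,
    ``ctc``, ``tdev``, ``ck18``, ``cck18``, ``psa``, ``ldh``, ``alp``,
    ``albumin``, ``hemoglobin``, ``age``, ``os_months``, ``event`` plus the
    true per-dataset frailty in ``df.attrs["frailty"]`` and the true linear
    predictor in column ``true_log_hazard_ratio`` (for recovery tests).
    Identical ``params`` (including seed) give an identical table.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(3)]
    rng_cov, rng_frail, rng_surv = rngs

    pieces = []
    for label, n in params.n_patients.items():
        ctc, tdev = _correlated_counts(
            rng_cov,
            n,
            params.ctc_mean,
            params.ctc_dispersion,
            params.tdev_mean,
            params.tdev_dispersion,
            params.ctc_tdev_corr,
        )
        block = {"dataset": [label] * n, "ctc": ctc, "tdev": tdev}
        for name, (mu, sigma) in params.lognormal.items():
            block[name] = np.exp(rng_cov.normal(mu, sigma, size=n))
        for name, (mu, sd) in params.normal.items():
            block[name] = rng_cov.normal(mu, sd, size=n)
        pieces.append(pd.DataFrame(block))
    df = pd.concat(pieces, ignore_index=True)

    # linear predictor on transformed, sample-mean-centered covariates
    transformed = transform_covariates(df.drop(columns=["dataset"]))
    eta = np.zeros(len(df))
    for name, beta in params.coefficients.items():
        if beta == 0:
            continue
        if name not in transformed.columns:
            raise CohortSimError(f"coefficient on unknown covariate {name!r}")
        x = transformed[name].to_numpy(dtype=float)
        eta += beta * (x - x.mean())
    df["true_log_hazard_ratio"] = eta

    # per-dataset gamma frailty with mean 1, variance theta
    theta = params.frailty_variance
    labels = list(params.n_patients)
    if theta > 0:
        frailty = {
            lab: float(rng_frail.gamma(1.0 / theta, theta)) for lab in labels
        }
    else:
        frailty = {lab: 1.0 for lab in labels}
    z = df["dataset"].map(frailty).to_numpy(dtype=float)

    hazards = z * params.baseline_rate * np.exp(eta)
    event_time = rng_surv.exponential(1.0 / hazards)
    if params.censoring_rate > 0:
        c_rate = _censoring_rate_solver(hazards, params.censoring_rate)
        cens_time = rng_surv.exponential(1.0 / c_rate, size=len(df))
        observed = np.minimum(event_time, cens_time)
        event = (event_time <= cens_time).astype(int)
    else:
        observed = event_time
        event = np.ones(len(df), dtype=int)
    df["os_months"] = observed
    df["event"] = event
    df.attrs["frailty"] = frailty
    df.attrs["params"] = params.to_json_dict()
    return df
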