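"""Descriptive statistics, group comparisons, correlations, ELISA
quantification and ROC-based biomarker cut-off determination.

The cut-off procedure dichotomizes patients into favorable / unfavorable
groups at the biomarker value whose binary short-vs-long-survivor prediction
has minimum |sensitivity - specificity|, where the survival classes come from
the cohort's Kaplan-Meier median overall survival.  High biomarker values are
the unfavorable (positive) class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ctcev.survival import km_fit


class BiomarkerError(ValueError):
    """Invalid input to a biomarker statistic."""


class ElisaQcError(RuntimeError):
    """A quality-control well fell outside its declared concentration range."""


# ---------------------------------------------------------------------------
# descriptive statistics and group tests
# ---------------------------------------------------------------------------

@dataclass
class DescriptiveSummary:
    median: float
    min: float
    max: float
    p25: float
    p75: float
    iqr: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def describe(values) -> DescriptiveSummary:
    """Median, min, max, 25th/75th percentiles and IQR.

    Quantiles use linear interpolation between order statistics.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise BiomarkerError("empty series")
    if np.isnan(v).any():
        raise BiomarkerError("series contains NaN")
    p25, med, p75 = np.quantile(v, [0.25, 0.5, 0.75])
    return DescriptiveSummary(
        median=float(med),
        min=float(v.min()),
        max=float(v.max()),
        p25=float(p25),
        p75=float(p75),
        iqr=float(p75 - p25),
    )


#: largest per-group size at which the exact Mann-Whitney null distribution
#: is enumerated (ties force the tie-corrected normal approximation)
MANN_WHITNEY_EXACT_MAX = 25


def mann_whitney(x, y):
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where ``U`` counts pairs with ``x_i < y_j`` plus half
    the ties.  The exact null distribution is used when both groups have at
    most :data:`MANN_WHITNEY_EXACT_MAX` observations and there are no ties;
    otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise BiomarkerError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    small = max(x.size, y.size) <= MANN_WHITNEY_EXACT_MAX
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(y, x, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def correlate(x, y, method: str = "spearman"):
    """Spearman or Pearson correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise BiomarkerError("need equal-length series with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise BiomarkerError("zero-variance input")
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise BiomarkerError(f"unknown method {method!r}")
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# ROC cut-off determination
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """Empirical ROC over the observed biomarker values.

    ``cutoff`` minimizes |sensitivity - specificity|; ties are broken by
    maximal sensitivity + specificity, then by the smallest threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    cutoff: float
    min_abs_diff: float
    n_short: int
    n_long: int
    n_excluded: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "auc": self.auc,
            "min_abs_sens_minus_spec": self.min_abs_diff,
            "n_short": self.n_short,
            "n_long": self.n_long,
            "n_excluded_censored_before_median": self.n_excluded,
        }


def roc_cutoff(values, times, events) -> RocResult:
    """Determine the biomarker cut-off against dichotomized survival.

    The reference classes come from the Kaplan-Meier median overall survival
    of the input sample: patients with follow-up >= median are "long"
    survivors (regardless of event status), patients who died before the
    median are "short" (the positive class), and patients censored before
    the median are excluded (their class is unknowable).  Candidate
    thresholds are the distinct observed biomarker values; a patient is
    called positive when value >= threshold.  AUC is the trapezoid area
    under the empirical ROC.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not (values.size == times.size == events.size):
        raise BiomarkerError("values, times and events must be equal length")
    if values.size < 10:
        raise BiomarkerError("need n >= 10")
    median = km_fit(times, events).median
    if not np.isfinite(median):
        raise BiomarkerError("median survival not reached; cannot label classes")
    keep = (times >= median) | (events == 1)
    short = (times < median) & (events == 1)
    labels = short[keep]
    v = values[keep]
    n_short = int(labels.sum())
    n_long = int((~labels).sum())
    if n_short == 0 or n_long == 0:
        raise BiomarkerError("one survival class is empty; no cut-off exists")

    thresholds = np.unique(v)
    pos = v[:, None] >= thresholds[None, :]
    sens = pos[labels].mean(axis=0)
    spec = (~pos[~labels]).mean(axis=0)

    # trapezoid AUC over the empirical ROC, closed at (0,0) and (1,1)
    pts = sorted(zip(1.0 - spec, sens))
    xs = np.concatenate([[0.0], [p[0] for p in pts], [1.0]])
    ys = np.concatenate([[0.0], [p[1] for p in pts], [1.0]])
    auc = float(np.trapezoid(ys, xs))

    diff = np.abs(sens - spec)
    best = diff.min()
    tied = np.flatnonzero(np.isclose(diff, best, rtol=0, atol=1e-12))
    # tie-break: max sens + spec, then smallest threshold
    youden = (sens + spec)[tied]
    tied = tied[np.isclose(youden, youden.max(), rtol=0, atol=1e-12)]
    choice = tied[np.argmin(thresholds[tied])]
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        cutoff=float(thresholds[choice]),
        min_abs_diff=float(best),
        n_short=n_short,
        n_long=n_long,
        n_excluded=int((~keep).sum()),
    )


# ---------------------------------------------------------------------------
# ELISA quantification
# ---------------------------------------------------------------------------

@dataclass
class ElisaPlate:
    """One immunoassay plate, absorbances at 450 nm.

    ``standards`` is a list of ``(concentration U/L, absorbance)`` pairs with
    strictly increasing concentrations; ``samples`` maps sample id ->
    ``(absorbance_1, absorbance_2)`` technical duplicates; QC wells carry
    their declared acceptable concentration range.
    """

    blank: float
    standards: list
    samples: dict
    qc_low: tuple | None = None   # ((abs1, abs2), (conc_lo, conc_hi))
    qc_high: tuple | None = None

    def validate(self) -> None:
        concs = [c for c, _ in self.standards]
        if len(concs) < 2:
            raise BiomarkerError("need at least 2 standards")
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise BiomarkerError("standard concentrations must be strictly increasing")
        all_abs = [a for _, a in self.standards] + [
            a for pair in self.samples.values() for a in pair
        ]
        if any(a < 0 for a in all_abs):
            raise BiomarkerError("absorbances must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"well": "blank", "role": "blank", "absorbance": self.blank, "known_conc": np.nan}]
        for i, (c, a) in enumerate(self.standards):
            rows.append({"well": f"std{i+1}", "role": "standard", "absorbance": a, "known_conc": c})
        for name, (a1, a2) in self.samples.items():
            rows.append({"well": f"{name}_1", "role": "sample", "absorbance": a1, "known_conc": np.nan})
            rows.append({"well": f"{name}_2", "role": "sample", "absorbance": a2, "known_conc": np.nan})
        return pd.DataFrame(rows)


def _four_pl(x, a, d, c, b):
    # a = response at 0, d = saturating response, c = inflection conc, b = slope
    return d + (a - d) / (1.0 + (x / c) ** b)


def _four_pl_inverse(y, a, d, c, b):
    return c * ((a - d) / (y - d) - 1.0) ** (1.0 / b)


def elisa_quantify(plate: ElisaPlate, model: str = "4pl") -> pd.DataFrame:
    """Convert sample absorbances to concentrations in U/L.

    All wells are blank-corrected; the calibration curve is a 4-parameter
    logistic fitted to the standards (log-linear interpolation is the
    fallback when the 4PL fit fails); technical duplicates are averaged
    before conversion.  Samples whose mean absorbance falls outside the
    standards' absorbance range are flagged ``out_of_range`` with NaN
    concentration rather than extrapolated.  QC wells outside their declared
    concentration range raise :class:`ElisaQcError`.
    """
    plate.validate()
    std_conc = np.array([c for c, _ in plate.standards], dtype=float)
    std_abs = np.array([a for _, a in plate.standards], dtype=float) - plate.blank

    curve = None
    if model == "4pl":
        try:
            span = float(std_abs.max() - std_abs.min())
            p0 = (
                float(std_abs.min() - 0.01 * span),
                float(std_abs.max() + 0.05 * span),
                float(np.exp(np.mean(np.log(std_conc)))),
                1.0,
            )
            popt, _ = optimize.curve_fit(
                _four_pl,
                std_conc,
                std_abs,
                p0=p0,
                bounds=(
                    [-np.inf, float(std_abs.max()), 1e-12, 1e-3],
                    [float(std_abs.min()), np.inf, np.inf, np.inf],
                ),
                maxfev=20000,
            )
            curve = ("4pl", popt)
        except (RuntimeError, ValueError):
            curve = None
    if curve is None:
        # monotone log-linear interpolation through the standards
        curve = ("interp", None)

    def to_conc(y):
        if curve[0] == "4pl":
            a, d, c, b = curve[1]
            if not (min(a, d) < y < max(a, d)):
                return np.nan
            return float(_four_pl_inverse(y, a, d, c, b))
        return float(np.exp(np.interp(y, std_abs, np.log(std_conc))))

    lo_abs, hi_abs = float(std_abs.min()), float(std_abs.max())

    def quantify_pair(pair):
        mean_abs = float(np.mean(pair)) - plate.blank
        out_of_range = not (lo_abs <= mean_abs <= hi_abs)
        conc = np.nan if out_of_range else to_conc(mean_abs)
        return mean_abs, conc, out_of_range

    for name, qc in (("qc_low", plate.qc_low), ("qc_high", plate.qc_high)):
        if qc is None:
            continue
        wells, (c_lo, c_hi) = qc
        _, conc, oob = quantify_pair(wells)
        if oob or np.isnan(conc) or not (c_lo <= conc <= c_hi):
            raise ElisaQcError(
                f"{name} quantified at {conc!r} U/L, outside declared range [{c_lo}, {c_hi}]"
            )

    rows = []
    for name, pair in plate.samples.items():
        mean_abs, conc, oob = quantify_pair(pair)
        rows.append(
            {
                "sample": name,
                "mean_absorbance": mean_abs,
                "concentration": conc,
                "flag": "out_of_range" if oob else "ok",
            }
        )
    return pd.DataFrame(rows, columns=["sample", "mean_absorbance", "concentration", "flag"])
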