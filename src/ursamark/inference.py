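"""Inferential layer: exposure-corrected goodness-of-fit, exact binomial
post hocs with Bonferroni correction, the binomial GLM for debarking
probability, AICc model comparison, and one-way ANOVA with Tukey HSD.

The chi-square goodness-of-fit test compares observed event counts per bin
(months, diel periods) against expectations proportional to an *exposure*
vector (camera-trap days per month; summed period durations), so unequal
bin sizes do not masquerade as activity patterns.  Post hoc exact binomial
tests ask, bin by bin, whether the observed share differs from the exposure
share; two-sidedness is obtained by doubling the smaller tail (capped at
1), and Bonferroni correction multiplies by the number of bins tested.

The debarking model is an ordinary binomial-family GLM (logit link) fitted
by IRLS through statsmodels; candidate term sets are compared by AICc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .errors import ConvergenceError, SeparationError

# ---------------------------------------------------------------------------
# chi-square goodness of fit with exposure correction


@dataclass(frozen=True)
class GofResult:
    """Exposure-corrected chi-square goodness-of-fit result."""

    chi2: float
    df: int
    p: float
    bins: tuple
    observed: np.ndarray
    expected: np.ndarray
    posthoc: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "bins": list(self.bins),
            "observed": [float(x) for x in self.observed],
            "expected": [float(x) for x in self.expected],
        }
        if self.posthoc is not None:
            out["posthoc"] = self.posthoc.reset_index().to_dict(orient="records")
        return out


def chisq_gof_exposure(observed, exposure, bins=None, posthoc: bool = True) -> GofResult:
    """Chi-square goodness of fit against exposure-proportional expectations.

    ``expected_i = N * exposure_i / sum(exposure)`` where N is the total
    observed count; chi2 = sum((O-E)^2 / E) on bins-1 degrees of freedom.
    When ``posthoc`` is set, per-bin exact binomial tests (Bonferroni m =
    number of bins) are attached.
    """
    observed = np.asarray(observed, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if observed.shape != exposure.shape:
        raise ValueError("observed and exposure must have the same length")
    if observed.sum() <= 0:
        raise ValueError("total observed count must be positive")
    if np.any(exposure <= 0):
        raise ValueError("all exposures must be positive")
    if bins is None:
        bins = tuple(range(len(observed)))

    expected = observed.sum() * exposure / exposure.sum()
    if np.any(expected < 1):
        warnings.warn(
            "some expected cell counts are below 1; chi-square approximation "
            "may be unreliable",
            stacklevel=2,
        )
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = len(observed) - 1
    p = float(stats.chi2.sf(chi2, df))
    ph = binomial_posthoc(observed, exposure, m=len(observed), bins=bins) if posthoc else None
    return GofResult(
        chi2=chi2, df=df, p=p, bins=tuple(bins), observed=observed, expected=expected,
        posthoc=ph,
    )


def exact_binomial_two_sided(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value by doubling the smaller tail.

    p = min(1, 2 * min(P(X <= k), P(X >= k))) for X ~ Binomial(n, p0).
    Doubling (rather than summing outcomes less likely than k) keeps the
    p-value monotone in |k - n p0|.
    """
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2 * min(lower, upper)))


def binomial_posthoc(observed, exposure, m: int, bins=None) -> pd.DataFrame:
    """Per-bin exact binomial tests against the exposure share, Bonferroni-adjusted.

    Bin i is tested as k_i successes in N = sum(observed) trials at
    p0 = exposure_i / sum(exposure); adjusted p = min(1, m * raw p).
    """
    observed = np.asarray(observed, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if m < 1:
        raise ValueError("m must be >= 1")
    if bins is None:
        bins = tuple(range(len(observed)))
    n = int(round(observed.sum()))
    shares = exposure / exposure.sum()
    rows = []
    for label, k, p0 in zip(bins, observed, shares):
        k = int(round(k))
        raw = exact_binomial_two_sided(k, n, p0)
        rows.append(
            dict(
                bin=label,
                observed=k,
                expected=n * p0,
                raw_p=raw,
                adjusted_p=min(1.0, m * raw),
                direction="above" if k > n * p0 else ("below" if k < n * p0 else "equal"),
            )
        )
    return pd.DataFrame(rows).set_index("bin")


# ---------------------------------------------------------------------------
# binomial GLM for debarking probability


def _build_design(data: pd.DataFrame, terms) -> tuple[np.ndarray, list[str]]:
    """Design matrix from a simple term list.

    Terms: "1"/"intercept" for the constant, a column name, or "a:b" for a
    product interaction.
    """
    cols, names = [], []
    for term in terms:
        if term in ("1", "intercept", "Intercept"):
            cols.append(np.ones(len(data)))
            names.append("intercept")
        elif ":" in term:
            a, b = term.split(":")
            cols.append(np.asarray(data[a], float) * np.asarray(data[b], float))
            names.append(term)
        else:
            cols.append(np.asarray(data[term], float))
            names.append(term)
    return np.column_stack(cols), names


@dataclass(frozen=True)
class LogisticFit:
    """A fitted binomial GLM: per-term estimates and information criteria."""

    terms: tuple[str, ...]
    estimate: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    loglik: float
    aicc: float
    n: int
    converged: bool = True

    @property
    def k(self) -> int:
        return len(self.terms)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.estimate,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "se": self.se,
                "z": self.z,
                "p": self.p,
            },
            index=list(self.terms),
        )

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "coefficients": self.table().reset_index(names="term").to_dict(orient="records"),
            "loglik": self.loglik,
            "aicc": self.aicc,
            "n": self.n,
        }

    def summary(self) -> str:
        head = (
            f"Binomial GLM (logit link), n = {self.n}, "
            f"log-likelihood = {self.loglik:.3f}, AICc = {self.aicc:.3f}"
        )
        return head + "\n" + self.table().round(4).to_string()


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined for n <= k + 1")
    return -2 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_debarking_model(data: pd.DataFrame, terms, response: str = "debark") -> LogisticFit:
    """Fit the debarking-probability GLM (binomial family, logit link).

    Parameters
    ----------
    data
        One row per behavioral event with the response column (bool/0-1)
        and covariates (e.g. ``julian_date``, ``sun_time``).
    terms
        Term list for the linear predictor, e.g.
        ``["1", "sun_time", "julian_date", "sun_time:julian_date"]``.
    """
    y = np.asarray(data[response], dtype=float)
    n = len(y)
    if n <= len(terms) + 2:
        raise ValueError("too few observations for the requested model")
    if y.min() == y.max():
        raise ValueError("response has a single class; nothing to model")
    x, names = _build_design(data, terms)

    model = sm.GLM(y, x, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = model.fit(maxiter=50, tol=1e-8)
        except (PerfectSeparationWarning, PerfectSeparationError):
            raise SeparationError(
                "complete separation detected while fitting " + " + ".join(names)
            ) from None
    if not res.converged:
        raise ConvergenceError(f"IRLS did not converge within 50 iterations ({names})")
    big = np.abs(res.params) > 30
    if big.any():
        raise SeparationError(
            f"term(s) {[names[i] for i in np.where(big)[0]]} appear to separate the response"
        )

    est = np.asarray(res.params)
    se = np.asarray(res.bse)
    z = est / se
    p = 2 * stats.norm.sf(np.abs(z))
    return LogisticFit(
        terms=tuple(names),
        estimate=est,
        se=se,
        z=z,
        p=p,
        ci_lower=est - 1.96 * se,
        ci_upper=est + 1.96 * se,
        loglik=float(res.llf),
        aicc=aicc(float(res.llf), len(names), n),
        n=n,
        converged=bool(res.converged),
    )


def compare_models_aicc(fits) -> pd.DataFrame:
    """Rank fits by AICc; models within 2 AICc of the best are 'competing'."""
    fits = list(fits)
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits were made on different sample sizes: {sorted(ns)}")
    rows = [
        dict(model=" + ".join(f.terms), k=f.k, loglik=f.loglik, aicc=f.aicc) for f in fits
    ]
    out = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    out["delta_aicc"] = out.aicc - out.aicc.min()
    out["competing"] = out.delta_aicc < 2
    return out


class DebarkingModel:
    """Binomial GLM of visual-marking probability against time covariates.

    A light statsmodels-style facade: construct from a per-event data frame
    (``from_dataframe``), then ``fit()`` one term set or ``fit_all()`` a
    candidate set and compare by AICc.
    """

    DEFAULT_TERM_SETS = (
        ("1",),
        ("1", "julian_date"),
        ("1", "sun_time"),
        ("1", "sun_time", "julian_date"),
        ("1", "sun_time", "julian_date", "sun_time:julian_date"),
    )

    def __init__(self, data: pd.DataFrame, response: str = "debark"):
        self.data = data
        self.response = response

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str = "debark"):
        return cls(data, response=response)

    def fit(self, terms=("1", "sun_time", "julian_date", "sun_time:julian_date")) -> LogisticFit:
        return fit_debarking_model(self.data, terms, response=self.response)

    def fit_all(self, term_sets=None):
        term_sets = term_sets or self.DEFAULT_TERM_SETS
        fits = [self.fit(terms) for terms in term_sets]
        return fits, compare_models_aicc(fits)


# ---------------------------------------------------------------------------
# one-way ANOVA + Tukey HSD


@dataclass(frozen=True)
class AnovaTukey:
    """One-way ANOVA F test with Tukey HSD pairwise comparisons."""

    F: float
    df1: int
    df2: int
    p: float
    pairwise: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "pairwise": self.pairwise.to_dict(orient="records"),
        }

    def summary(self) -> str:
        head = f"One-way ANOVA: F({self.df1}, {self.df2}) = {self.F:.3f}, p = {self.p:.4g}"
        return head + "\n" + self.pairwise.round(4).to_string(index=False)


def anova_tukey(groups, values) -> AnovaTukey:
    """Classical one-way ANOVA followed by Tukey HSD on all group pairs.

    Parameters
    ----------
    groups
        Group label per observation.
    values
        Observation values (e.g. per-event behavior durations, seconds).
    """
    df = pd.DataFrame({"group": list(groups), "value": np.asarray(values, float)})
    by = {g: sub.value.to_numpy() for g, sub in df.groupby("group", sort=True)}
    if len(by) < 2:
        raise ValueError("need at least two groups")
    for g, v in by.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than two observations")

    samples = list(by.values())
    labels = list(by)
    F, p = stats.f_oneway(*samples)
    k = len(samples)
    n_total = sum(len(v) for v in samples)
    df1, df2 = k - 1, n_total - k

    # pooled within-group variance for the pairwise t statistics
    msw = sum(((v - v.mean()) ** 2).sum() for v in samples) / df2
    hsd = stats.tukey_hsd(*samples)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = samples[i].mean() - samples[j].mean()
            se = np.sqrt(msw * (1 / len(samples[i]) + 1 / len(samples[j])))
            rows.append(
                dict(
                    group_a=labels[i],
                    group_b=labels[j],
                    difference=float(diff),
                    t=float(diff / se) if se > 0 else 0.0,
                    adjusted_p=float(hsd.pvalue[i, j]),
                )
            )
    return AnovaTukey(
        F=float(F), df1=df1, df2=df2, p=float(p), pairwise=pd.DataFrame(rows)
    )


__all__ = [
    "GofResult",
    "chisq_gof_exposure",
    "exact_binomial_two_sided",
    "binomial_posthoc",
    "LogisticFit",
    "aicc",
    "fit_debarking_model",
    "compare_models_aicc",
    "DebarkingModel",
    "AnovaTukey",
    "anova_tukey",
]
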