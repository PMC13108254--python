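"""Fragment-length summaries, per-site damage fraction λ and decay rate k.

Post-mortem depurination nicks the DNA backbone independently at each
phosphodiester bond, so surviving fragment lengths are (discretely)
exponentially distributed and the log of the length-frequency spectrum falls
linearly with length.  λ, the per-site breakage probability, is estimated as
minus the slope of that log-linear regression; regressing per-sample λ on
specimen age then yields the decay rate k (per site per year), the discrete
analogue of the relation λ = k · age.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import FragmentLengthHistogram

logger = logging.getLogger(__name__)

#: Per-sample λ fit is accepted when R² exceeds this and P is below P_MAX.
LAMBDA_R2_MIN = 0.95
LAMBDA_P_MAX = 0.05


@dataclass(frozen=True)
class LengthSummary:
    """Lognormal fit of the fragment-length distribution.

    ``log_mean``/``log_sd`` are the maximum-likelihood parameters of the
    lognormal (mean and SD of natural-log lengths); ``median_length`` is the
    empirical median (lower of the two middle values for even n).
    """

    log_mean: float
    log_sd: float
    median_length: int
    n_fragments: int


@dataclass(frozen=True)
class LambdaFit:
    """Result of the log-linear exponential-decay fit of the length spectrum."""

    lam: float
    r_squared: float
    p_value: float
    n_points: int
    fit_range: tuple[int, int]
    passes_gate: bool
    flag: str = ""


@dataclass(frozen=True)
class DecayRateFit:
    """λ-versus-age regression for one group (genus or the whole cohort).

    ``k_se`` is the classical OLS slope standard error; ``k_se_robust`` the
    HC3 heteroscedasticity-consistent one.  Per-sample λ estimates get
    noisier with age (older samples have sparser long-fragment tails), so
    the robust error is the appropriate basis for confidence intervals.
    """

    k: float
    intercept: float
    r_squared: float
    p_value: float
    n_samples: int
    group: str = "all"
    through_origin: bool = False
    k_se: float = math.nan
    k_se_robust: float = math.nan

    def k_ci(self, confidence: float = 0.95, robust: bool = True):
        """Two-sided confidence interval for k (t distribution, n-2 df)."""
        se = self.k_se_robust if robust else self.k_se
        df = self.n_samples - (1 if self.through_origin else 2)
        half = stats.t.ppf(0.5 + confidence / 2, df) * se
        return self.k - half, self.k + half


def fit_length_distribution(hist: FragmentLengthHistogram) -> LengthSummary:
    """Maximum-likelihood lognormal fit plus empirical median.

    Equivalent to fitting the expanded length multiset with a lognormal MLE
    (``log_mean`` = mean of log lengths, ``log_sd`` = MLE standard deviation).
    """
    lengths = np.array(sorted(hist), dtype=float)
    counts = np.array([hist[int(l)] for l in lengths], dtype=float)
    n = int(counts.sum())
    if n < 2:
        raise ValueError(f"need at least 2 fragments, got {n}")
    if (lengths < 1).any():
        raise ValueError("fragment lengths must be >= 1")

    logs = np.log(lengths)
    log_mean = float(np.average(logs, weights=counts))
    log_var = float(np.average((logs - log_mean) ** 2, weights=counts))
    log_sd = math.sqrt(log_var)
    if log_sd == 0.0:
        logger.warning("all fragment lengths identical; log_sd = 0")

    # lower-median convention on the expanded multiset
    cum = np.cumsum(counts)
    median = int(lengths[np.searchsorted(cum, (n - 1) // 2 + 1)])
    return LengthSummary(log_mean, log_sd, median, n)


def estimate_lambda(
    hist: FragmentLengthHistogram,
    fit_range: tuple[int, int] | None = None,
    pseudo_count: float = 0.5,
    r2_min: float = LAMBDA_R2_MIN,
    p_max: float = LAMBDA_P_MAX,
) -> LambdaFit:
    """Estimate the per-site damage fraction λ from the length spectrum.

    Ordinary least squares of ln(count + pseudo_count) on length over bins
    inside ``fit_range``; λ is minus the slope.  The default range runs
    from the modal length (where the exponential right tail starts and
    left-truncation by read-merging minima is avoided) to the longest
    observed fragment.

    The default half-count offset keeps empty and near-empty bins in the
    fit; on sampled histograms it removes most of the upward bias that
    ln-of-small-counts plus zero-bin dropping would otherwise put into the
    sparse long-fragment tail (worst for old, heavily fragmented samples).
    Set ``pseudo_count=0`` for the pure log-linear fit, which then drops
    zero-count bins and is exactly scale invariant.

    The gate (``passes_gate``) requires R² > ``r2_min`` and a two-sided
    slope-t P below ``p_max``, both strict.
    """
    if not hist:
        return LambdaFit(math.nan, math.nan, math.nan, 0, (0, 0), False,
                         flag="insufficient")
    if fit_range is None:
        modal = max(hist, key=lambda L: (hist[L], -L))
        fit_range = (int(modal), int(max(hist)))

    lo, hi = fit_range
    all_lengths = np.arange(lo, hi + 1)
    all_counts = np.array([hist.get(int(L), 0) for L in all_lengths], dtype=float)
    usable = all_counts + pseudo_count > 0
    lengths = all_lengths[usable].astype(float)
    counts = all_counts[usable] + pseudo_count
    if len(lengths) < 4:
        return LambdaFit(math.nan, math.nan, math.nan, len(lengths),
                         (lo, hi), False, flag="insufficient")

    log_counts = np.log(counts)
    if np.ptp(log_counts) == 0.0:  # perfectly flat spectrum: no decay signal
        return LambdaFit(0.0, 0.0, 1.0, len(lengths), (lo, hi), False)
    res = stats.linregress(lengths, log_counts)
    lam = -res.slope
    r2 = res.rvalue ** 2
    p = res.pvalue
    gate = bool(r2 > r2_min and p < p_max)
    return LambdaFit(float(lam), float(r2), float(p), len(lengths), (lo, hi), gate)


def estimate_decay_rate(
    ages,
    lambdas,
    group: str = "all",
    through_origin: bool = False,
) -> DecayRateFit:
    """Regress λ on age; the slope is the decay rate k (per site per year).

    The default fit includes an intercept.  ``through_origin=True`` forces the
    regression through zero, reflecting the idealised relation λ = k·age
    (an undamaged specimen of age 0 has λ = 0); its R² is then computed about
    zero rather than about the mean.
    """
    ages = np.asarray(ages, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    n = len(ages)
    if n < 3:
        raise ValueError(f"need >= 3 samples for a decay-rate fit, got {n}")
    if (ages <= 0).any():
        raise ValueError("ages must be positive")
    if np.ptp(ages) == 0:
        raise ValueError("zero variance in age")

    if through_origin:
        k = float(ages @ lambdas / (ages @ ages))
        resid = lambdas - k * ages
        ss_res = float(resid @ resid)
        ss_tot = float(lambdas @ lambdas)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        df = n - 1
        se = math.sqrt(ss_res / df / (ages @ ages)) if df > 0 else math.nan
        t = k / se if se > 0 else math.inf
        p = 2 * stats.t.sf(abs(t), df)
        return DecayRateFit(k, 0.0, r2, float(p), n, group, True,
                            k_se=float(se), k_se_robust=float(se))

    res = stats.linregress(ages, lambdas)
    r2 = res.rvalue ** 2 if np.std(lambdas) > 0 else 0.0
    p = res.pvalue
    se_robust = _hc3_slope_se(ages, lambdas)
    return DecayRateFit(
        float(res.slope), float(res.intercept), float(r2), float(p), n, group,
        k_se=float(res.stderr), k_se_robust=float(se_robust),
    )


def _hc3_slope_se(x: np.ndarray, y: np.ndarray) -> float:
    """HC3 (leverage-adjusted) standard error of the simple-OLS slope."""
    n = len(x)
    design = np.column_stack([np.ones(n), x])
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ design.T @ y
    resid = y - design @ beta
    leverage = np.einsum("ij,jk,ik->i", design, xtx_inv, design)
    weights = (resid / (1.0 - leverage)) ** 2
    meat = design.T @ (design * weights[:, None])
    cov = xtx_inv @ meat @ xtx_inv
    return math.sqrt(cov[1, 1])
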