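"""Terminal misincorporation profiles, authentication fit, divergence correction.

Cytosine deamination in degraded DNA produces an excess of C>T mismatches at
the 5' ends of reads (mirrored as G>A at 3' ends in double-stranded
libraries) that decays roughly exponentially with distance from the terminus.
This module computes position-wise substitution frequencies, scores the
exponential pattern for authentication with a bounded three-parameter fit

    f(p) = A * exp(-r * (p - 1)) + c,        A >= 0, r >= 0, c >= 0,

and corrects the first-base C>T frequency for sample-reference divergence by
subtracting the mean frequency of the ten non-deamination substitution types.
The damage proxy carried downstream is the observed first-base frequency
f_CT(1); the fit exists only to authenticate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .io import (
    DEAMINATION_TYPES,
    SUBSTITUTION_TYPES,
    TerminalSubstitutionCounts,
    _BASE_INDEX,
    _SUB_INDEX,
)

logger = logging.getLogger(__name__)

#: Authentication gate thresholds (strict inequalities).
DECAY_R2_MIN = 0.5
DECAY_P_MAX = 0.05


@dataclass
class TerminalProfile:
    """Substitution frequencies f(p) for one terminus and one type.

    ``frequencies[p-1]`` is NaN where the reference-base denominator is zero.
    """

    terminus: str
    substitution: str
    frequencies: np.ndarray
    denominators: np.ndarray

    @property
    def n_positions(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class DecayFit:
    """Bounded exponential fit of a terminal profile (authentication score)."""

    amplitude: float
    rate: float
    offset: float
    r_squared: float
    p_one_sided: float
    passes_gate: bool
    converged: bool = True


@dataclass(frozen=True)
class BaselineRate:
    """Mean non-deamination substitution frequency (divergence + error proxy)."""

    b: float
    per_type: dict = field(default_factory=dict)


def terminal_frequencies(
    counts: TerminalSubstitutionCounts, substitution: str
) -> TerminalProfile:
    """Per-position frequency of one substitution type at one terminus.

    f(p) = substitution count at p / reference count of the source base at p.
    """
    src = substitution[0]
    denom = counts.ref_counts[:, _BASE_INDEX[src]].astype(float)
    num = counts.sub_counts[:, _SUB_INDEX[substitution]].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(denom > 0, num / np.maximum(denom, 1), np.nan)
    return TerminalProfile(counts.terminus, substitution, freq, denom)


def _exp_model(p, amplitude, rate, offset):
    return amplitude * np.exp(-rate * (p - 1)) + offset


def fit_damage_decay(
    profile: TerminalProfile,
    r2_min: float = DECAY_R2_MIN,
    p_max: float = DECAY_P_MAX,
) -> DecayFit:
    """Fit the bounded exponential model and test for genuine terminal damage.

    Nonlinear least squares with multi-start initial rates (0.1, 0.3, 1.0);
    the start with the lowest residual sum of squares wins.  Significance is
    a one-sided t-test of the amplitude (H1: A > 0) with n - 3 degrees of
    freedom, using the asymptotic standard error from the fit covariance.
    ``passes_gate`` requires R² > ``r2_min`` and one-sided P < ``p_max``.
    """
    mask = np.isfinite(profile.frequencies)
    p = np.arange(1, profile.n_positions + 1, dtype=float)[mask]
    f = profile.frequencies[mask]
    n = len(f)
    if n < 6:
        return DecayFit(math.nan, math.nan, math.nan, math.nan, math.nan,
                        False, converged=False)

    tail = f[p >= max(p.max() - 9, 1)]
    a0 = max(float(f[0] - tail.mean()), 1e-6)
    c0 = max(float(tail.mean()), 0.0)
    best = None
    for r0 in (0.1, 0.3, 1.0):
        try:
            popt, pcov = optimize.curve_fit(
                _exp_model, p, f,
                p0=(a0, r0, c0),
                bounds=([0.0, 0.0, 0.0], [1.0, np.inf, 1.0]),
                maxfev=5000,
            )
        except (RuntimeError, ValueError):
            continue
        ss_res = float(np.sum((f - _exp_model(p, *popt)) ** 2))
        if best is None or ss_res < best[0]:
            best = (ss_res, popt, pcov)
    if best is None:
        logger.warning("damage-decay fit failed to converge (%s %s)",
                       profile.terminus, profile.substitution)
        return DecayFit(math.nan, math.nan, math.nan, math.nan, math.nan,
                        False, converged=False)

    ss_res, popt, pcov = best
    amplitude, rate, offset = (float(v) for v in popt)
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    se_a = math.sqrt(pcov[0, 0]) if np.isfinite(pcov[0, 0]) else math.nan
    df = n - 3
    if se_a > 0 and math.isfinite(se_a):
        p_one = float(stats.t.sf(amplitude / se_a, df))
    else:
        # amplitude pinned at a bound or covariance singular: no evidence
        p_one = 1.0 if amplitude <= 0 else 0.0 if ss_res == 0 and amplitude > 0 else 1.0
    gate = bool(r2 > r2_min and p_one < p_max)
    return DecayFit(amplitude, rate, offset, float(r2), p_one, gate)


def baseline_rate(
    five_prime: TerminalSubstitutionCounts,
    three_prime: TerminalSubstitutionCounts,
) -> BaselineRate:
    """Mean frequency of the 10 non-deamination substitution types.

    Averaged over per-type, per-position frequencies at both termini
    (positions 1..P_max); cells with zero denominator are excluded.  C>T and
    G>A are excluded because they carry the post-mortem deamination signal.
    """
    per_type: dict[str, float] = {}
    all_cells: list[float] = []
    for sub in SUBSTITUTION_TYPES:
        if sub in DEAMINATION_TYPES:
            continue
        cells = []
        for tab in (five_prime, three_prime):
            prof = terminal_frequencies(tab, sub)
            cells.extend(prof.frequencies[np.isfinite(prof.frequencies)])
        if cells:
            per_type[sub] = float(np.mean(cells))
            all_cells.extend(cells)
    if not all_cells:
        raise ValueError("all denominators zero: baseline rate undefined")
    return BaselineRate(float(np.mean(all_cells)), per_type)


def correct_deamination(f_ct1: float, baseline: BaselineRate | float) -> float:
    """Divergence-corrected deamination: max(0, f_CT(1) - b)."""
    b = baseline.b if isinstance(baseline, BaselineRate) else float(baseline)
    d = f_ct1 - b
    if d < 0:
        logger.warning(
            "corrected deamination floored at 0 (f_ct1=%.4g < baseline=%.4g)",
            f_ct1, b,
        )
        return 0.0
    return d
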