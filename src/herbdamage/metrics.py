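"""Per-sample damage metrics: one row of the profiling pipeline.

Ties together the four per-library damage statistics — endogenous fraction,
fragment-length summary, damage fraction per site λ, and first-base terminal
deamination with its authentication fit and divergence correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import pandas as pd

from . import deamination as dm
from . import fragmentation as fr
from .io import DamageTables, endogenous_fraction


@dataclass
class SampleDamageMetrics:
    """All per-sample quantities consumed by QC and cohort statistics."""

    sample_id: str
    total_reads: int | None = None
    mapped_reads: int | None = None
    endogenous: float = math.nan
    log_mean_length: float = math.nan
    log_sd_length: float = math.nan
    median_length: float = math.nan
    lam: float = math.nan
    lambda_r2: float = math.nan
    lambda_p: float = math.nan
    lambda_pass: bool | None = None
    f_ct1_5p: float = math.nan
    f_ga1_3p: float = math.nan
    decay_amplitude: float = math.nan
    decay_rate: float = math.nan
    decay_offset: float = math.nan
    decay_r2: float = math.nan
    decay_p_one_sided: float = math.nan
    deamination_pass: bool | None = None
    baseline_b: float = math.nan
    d_corr: float = math.nan


def compute_sample_metrics(
    tables: DamageTables,
    lambda_fit_range: tuple[int, int] | None = None,
    lambda_r2_min: float = fr.LAMBDA_R2_MIN,
    decay_r2_min: float = dm.DECAY_R2_MIN,
    p_max: float = fr.LAMBDA_P_MAX,
) -> SampleDamageMetrics:
    """Compute every per-sample metric from raw damage tables."""
    m = SampleDamageMetrics(
        sample_id=tables.sample_id,
        total_reads=tables.summary.total_reads,
        mapped_reads=tables.summary.mapped_reads,
    )
    if tables.summary.total_reads > 0:
        m.endogenous = endogenous_fraction(tables.summary)

    hist = tables.length_histogram
    if hist.n_fragments() >= 2:
        summary = fr.fit_length_distribution(hist)
        m.log_mean_length = summary.log_mean
        m.log_sd_length = summary.log_sd
        m.median_length = summary.median_length

    lam_fit = fr.estimate_lambda(
        hist, fit_range=lambda_fit_range, r2_min=lambda_r2_min, p_max=p_max,
    )
    m.lam = lam_fit.lam
    m.lambda_r2 = lam_fit.r_squared
    m.lambda_p = lam_fit.p_value
    m.lambda_pass = lam_fit.passes_gate

    prof5 = dm.terminal_frequencies(tables.five_prime, "C>T")
    prof3 = dm.terminal_frequencies(tables.three_prime, "G>A")
    if math.isfinite(prof5.frequencies[0]):
        m.f_ct1_5p = float(prof5.frequencies[0])
    if math.isfinite(prof3.frequencies[0]):
        m.f_ga1_3p = float(prof3.frequencies[0])

    fit = dm.fit_damage_decay(prof5, r2_min=decay_r2_min, p_max=p_max)
    m.decay_amplitude = fit.amplitude
    m.decay_rate = fit.rate
    m.decay_offset = fit.offset
    m.decay_r2 = fit.r_squared
    m.decay_p_one_sided = fit.p_one_sided
    m.deamination_pass = fit.passes_gate

    try:
        base = dm.baseline_rate(tables.five_prime, tables.three_prime)
    except ValueError:
        base = None
    if base is not None:
        m.baseline_b = base.b
        if math.isfinite(m.f_ct1_5p):
            m.d_corr = dm.correct_deamination(m.f_ct1_5p, base)
    return m


def metrics_to_frame(metrics: list[SampleDamageMetrics]) -> pd.DataFrame:
    """Stack per-sample metrics into one tidy DataFrame (one row per sample)."""
    return pd.DataFrame([asdict(m) for m in metrics])
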