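"""Sample retention rules and attrition reporting.

A specimen library is kept for cohort analysis only when
(i) it has more than ``min_reads`` mapped merged reads (reliable frequency
estimation needs thousands of reads),
(ii) its fragment-length spectrum fits exponential decay (λ gate,
R² > 0.95, P < 0.05), and
(iii) its 5' C>T profile fits the exponential damage model (authentication
gate, R² > 0.5, one-sided P < 0.05).
All gates are applied jointly; a sample failing several lists every reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .metrics import SampleDamageMetrics

MIN_READS = 5000

REASON_READ_COUNT = "read_count"
REASON_LAMBDA = "lambda_gate"
REASON_AUTHENTICITY = "authenticity_gate"
REASON_INCOMPLETE = "incomplete_metrics"


@dataclass
class FilterReport:
    """Attrition bookkeeping for one filtering pass."""

    n_input: int
    n_removed: int
    n_retained: int
    reasons: dict[str, list[str]] = field(default_factory=dict)

    @property
    def removal_fraction(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0

    def summary_line(self) -> str:
        pct = 100.0 * self.removal_fraction
        return (
            f"In total, {self.n_removed} ({pct:.0f}%) samples were removed, "
            f"leaving a final dataset containing {self.n_retained} samples."
        )


def apply_sample_filters(
    metrics: list[SampleDamageMetrics],
    min_reads: int = MIN_READS,
    use_total_reads: bool = False,
) -> tuple[list[SampleDamageMetrics], FilterReport]:
    """Apply the retention rules; return (retained, report).

    The read-count threshold is strict (> ``min_reads``) and applied by
    default to mapped merged reads, the unit every damage statistic uses;
    ``use_total_reads=True`` switches it to all merged reads.  Output order
    follows input order for retained samples; the reasons mapping is keyed by
    sample id, so the result is invariant to input order.
    """
    retained: list[SampleDamageMetrics] = []
    reasons: dict[str, list[str]] = {}
    for m in metrics:
        why: list[str] = []
        n_reads = m.total_reads if use_total_reads else m.mapped_reads
        if m.lambda_pass is None or m.deamination_pass is None:
            why.append(REASON_INCOMPLETE)
        if n_reads is None:
            why.append(REASON_INCOMPLETE)
        elif n_reads <= min_reads:
            why.append(REASON_READ_COUNT)
        if m.lambda_pass is False:
            why.append(REASON_LAMBDA)
        if m.deamination_pass is False:
            why.append(REASON_AUTHENTICITY)
        if why:
            reasons[m.sample_id] = sorted(set(why))
        else:
            retained.append(m)
    report = FilterReport(
        n_input=len(metrics),
        n_removed=len(reasons),
        n_retained=len(retained),
        reasons=reasons,
    )
    return retained, report
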