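"""Pipeline orchestration: profile samples, filter, and run cohort statistics.

Chains ingestion -> per-sample metrics -> QC filtering -> cohort inference,
with deterministic TSV outputs whose '#' headers record the seed and
thresholds used.  The CLI in :mod:`herbdamage.cli` is a thin wrapper over
these functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import CohortModelResult, fit_decay_and_compare
from .deamination import DECAY_R2_MIN
from .fragmentation import LAMBDA_R2_MIN
from .io import add_age, parse_alignments, read_damage_tables, read_metadata
from .metrics import compute_sample_metrics, metrics_to_frame
from .qc import MIN_READS, FilterReport, apply_sample_filters

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and bookkeeping shared by the pipeline stages."""

    reference_year: int = 2026
    lambda_r2_min: float = LAMBDA_R2_MIN
    decay_r2_min: float = DECAY_R2_MIN
    p_max: float = 0.05
    min_reads: int = MIN_READS
    n_perm: int = 999
    seed: int = 0
    k_through_origin: bool = False

    def validate(self) -> None:
        for name in ("lambda_r2_min", "decay_r2_min", "p_max"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ValueError(f"{name} must be in (0, 1), got {value}")

    def header(self) -> str:
        return (
            f"# herbdamage {__version__} seed={self.seed} "
            f"lambda_r2_min={self.lambda_r2_min} "
            f"decay_r2_min={self.decay_r2_min} p_max={self.p_max} "
            f"min_reads={self.min_reads} n_perm={self.n_perm}\n"
        )


def load_sample(path) -> "DamageTables":
    """Load one sample: a damage-table directory or a SAM/BAM file."""
    path = Path(path)
    if path.is_dir():
        return read_damage_tables(path)
    return parse_alignments(path)


def run_profile(
    sample_paths,
    metadata_path,
    config: RunConfig,
    out_dir=None,
):
    """Per-sample profiling: metrics table plus filter report.

    Returns ``(metrics_frame, report)`` where the frame carries one row per
    sample merged with its metadata (and an ``age`` column).
    """
    config.validate()
    metrics = []
    for path in sample_paths:
        tables = load_sample(path)
        metrics.append(compute_sample_metrics(
            tables,
            lambda_r2_min=config.lambda_r2_min,
            decay_r2_min=config.decay_r2_min,
            p_max=config.p_max,
        ))
    if not metrics:
        raise ValueError("no valid samples found")

    retained, report = apply_sample_filters(metrics, min_reads=config.min_reads)
    frame = metrics_to_frame(metrics)
    frame["retained"] = ~frame["sample_id"].isin(report.reasons)
    frame["removal_reasons"] = frame["sample_id"].map(
        lambda s: ";".join(report.reasons.get(s, []))
    )

    meta = read_metadata(metadata_path)
    meta = add_age(meta, config.reference_year)
    frame = frame.merge(meta, on="sample_id", how="left", validate="1:1")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_tsv(frame, out_dir / "sample_metrics.tsv", config)
        with open(out_dir / "filter_report.txt", "w") as fh:
            fh.write(config.header())
            fh.write(report.summary_line() + "\n")
            for sid in sorted(report.reasons):
                fh.write(f"{sid}\t{';'.join(report.reasons[sid])}\n")
    return frame, report


def run_cohort(
    metrics_frame: pd.DataFrame,
    config: RunConfig,
    out_dir=None,
    retained_only: bool = True,
) -> CohortModelResult:
    """Cohort statistics over a (filtered) metrics table."""
    config.validate()
    table = metrics_frame
    if retained_only and "retained" in table.columns:
        table = table[table["retained"]]
    if len(table) < 3:
        raise ValueError(f"need >= 3 retained samples, got {len(table)}")
    result = fit_decay_and_compare(
        table,
        n_perm=config.n_perm,
        seed=config.seed,
        k_through_origin=config.k_through_origin,
    )
    for notice in result.notices:
        logger.info("%s", notice)
    if out_dir is not None:
        write_cohort_tables(result, Path(out_dir), config)
    return result


def _write_tsv(frame: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(config.header())
        frame.to_csv(fh, sep="\t", index=False)


def write_cohort_tables(result: CohortModelResult, out_dir: Path,
                        config: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    reg_rows = []
    for metric, fits in result.regressions.items():
        for group, fit in fits.items():
            reg_rows.append({
                "metric": metric, "group": group, "slope": fit.slope,
                "intercept": fit.intercept, "r2": fit.r_squared,
                "p": fit.p_value, "n": fit.n,
            })
    for group, fit in result.decay_rates.items():
        reg_rows.append({
            "metric": "k(lambda~age)", "group": group, "slope": fit.k,
            "intercept": fit.intercept, "r2": fit.r_squared,
            "p": fit.p_value, "n": fit.n_samples,
        })
    _write_tsv(pd.DataFrame(reg_rows), out_dir / "regressions.tsv", config)

    anc_rows = []
    for metric, a in result.ancovas.items():
        anc_rows.append({
            "metric": metric,
            "f_covariate": a.f_covariate, "p_covariate": a.p_covariate,
            "f_factor": a.f_factor, "p_factor": a.p_factor,
            "f_interaction": a.f_interaction, "p_interaction": a.p_interaction,
            "chosen_model": a.chosen_model,
            "r2_chosen": a.r_squared_chosen, "n": a.n,
        })
    _write_tsv(pd.DataFrame(anc_rows), out_dir / "ancova.tsv", config)

    vp_rows = []
    for metric, part in result.variance_partitions.items():
        for subset, value in sorted(
            part.cells.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
        ):
            label = "&".join(sorted(subset))
            vp_rows.append({
                "metric": metric, "fraction": label, "adj_r2": value,
                "perm_p": part.permutation_p.get(label, float("nan")),
            })
        vp_rows.append({
            "metric": metric, "fraction": "residual",
            "adj_r2": part.residual, "perm_p": float("nan"),
        })
        vp_rows.append({
            "metric": metric, "fraction": "full_model",
            "adj_r2": part.total_adj_r2,
            "perm_p": part.permutation_p.get("full", float("nan")),
        })
    _write_tsv(pd.DataFrame(vp_rows), out_dir / "variance_partition.tsv", config)
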