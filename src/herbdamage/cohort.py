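"""Cohort-level inference: regressions, ANCOVA, and variance partitioning.

Three layers of inference over the per-sample damage metrics:

* simple linear regressions of each metric on collection year or specimen
  age (per genus and overall), including the decay rate k as the slope of
  λ on age;
* analysis of covariance with age as covariate and genus as factor,
  sequential (Type I) sums of squares in the order covariate, factor,
  interaction, plus the nested-model F-test that decides whether regression
  slopes differ between genera;
* variance partitioning of each metric over 2-4 blocks of explanatory
  variables (temperature, precipitation, age, genus) on the adjusted-R²
  scale, with unique and shared fractions obtained by inclusion-exclusion
  over all subset regressions and unique-fraction significance assessed by
  Freedman-Lane residual permutation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fragmentation import DecayRateFit, estimate_decay_rate

logger = logging.getLogger(__name__)

INTERACTION_P_MAX = 0.05
DEFAULT_N_PERMUTATIONS = 999


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS of a metric on one covariate."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def linear_fit(x, y) -> RegressionResult:
    """Closed-form simple OLS with the standard two-sided slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need >= 3 observations, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: slope undefined")
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2 if np.std(y) > 0 else 0.0
    return RegressionResult(
        float(res.slope), float(res.intercept), float(r2), float(res.pvalue),
        len(x),
    )


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AncovaResult:
    """ANCOVA of metric ~ covariate x factor with nested-model comparison."""

    f_covariate: float
    p_covariate: float
    f_factor: float
    p_factor: float
    f_interaction: float
    p_interaction: float
    f_model_comparison: float
    p_model_comparison: float
    r_squared_full: float
    r_squared_chosen: float
    f_chosen_model: float
    p_chosen_model: float
    chosen_model: str  # "interaction" or "no-interaction"
    n: int


def _rss(y: np.ndarray, design: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def ancova(
    y, covariate, factor, ss_type: int = 1,
    interaction_p_max: float = INTERACTION_P_MAX,
) -> AncovaResult:
    """ANCOVA with a continuous covariate and a categorical factor.

    Sequential (Type I) sums of squares in the order covariate, factor,
    interaction, each tested against the full-model residual mean square;
    ``ss_type=2`` switches the covariate and factor terms to Type II
    (each adjusted for the other, interaction unchanged).  The nested-model
    F-test compares ``y ~ covariate * factor`` against
    ``y ~ covariate + factor``; when the interaction is not significant
    (P > ``interaction_p_max``) the simpler model is chosen, i.e. slopes are
    declared parallel across factor levels.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(covariate, dtype=float)
    g = np.asarray(factor)
    n = len(y)
    levels, codes = np.unique(g, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("factor needs >= 2 levels")
    counts = np.bincount(codes)
    if counts.min() < 3:
        raise ValueError(
            f"every factor level needs >= 3 observations, got {counts.min()}"
        )
    k = len(levels)
    dummies = np.eye(k)[codes][:, 1:]  # treatment coding, first level reference

    ones = np.ones((n, 1))
    xc = x[:, None]
    inter = dummies * xc
    m0 = ones
    m_x = np.hstack([ones, xc])
    m_g = np.hstack([ones, dummies])
    m_xg = np.hstack([ones, xc, dummies])
    m_full = np.hstack([ones, xc, dummies, inter])
    if np.linalg.matrix_rank(m_full) < m_full.shape[1]:
        raise ValueError("rank-deficient ANCOVA design")

    rss0 = _rss(y, m0)
    rss_x = _rss(y, m_x)
    rss_g = _rss(y, m_g)
    rss_xg = _rss(y, m_xg)
    rss_full = _rss(y, m_full)

    df_factor = k - 1
    df_inter = k - 1
    df_resid = n - m_full.shape[1]
    mse = rss_full / df_resid

    if ss_type == 1:
        ss_cov = rss0 - rss_x
        ss_fac = rss_x - rss_xg
    elif ss_type == 2:
        ss_cov = rss_g - rss_xg
        ss_fac = rss_x - rss_xg
    else:
        raise ValueError("ss_type must be 1 or 2")
    ss_int = rss_xg - rss_full

    # treat residuals at floating-point rounding level as an exact fit
    tol = rss0 * 1e-12

    def term_f(ss, df_num):
        # degenerate zero-residual fits: a zero extra SS carries no signal
        if mse <= tol:
            return (0.0, 1.0) if ss <= tol else (math.inf, 0.0)
        f = ss / df_num / mse
        return float(f), float(stats.f.sf(f, df_num, df_resid))

    f_cov, p_cov = term_f(ss_cov, 1)
    f_fac, p_fac = term_f(ss_fac, df_factor)
    f_int, p_int = term_f(ss_int, df_inter)

    # nested comparison: with vs without interaction (identical to the
    # sequential interaction test, reported separately for clarity)
    f_cmp, p_cmp = f_int, p_int

    r2_full = 1.0 - rss_full / rss0 if rss0 > 0 else 0.0
    chosen = "no-interaction" if p_int > interaction_p_max else "interaction"
    if chosen == "no-interaction":
        rss_chosen, p_chosen_params = rss_xg, m_xg.shape[1]
    else:
        rss_chosen, p_chosen_params = rss_full, m_full.shape[1]
    r2_chosen = 1.0 - rss_chosen / rss0 if rss0 > 0 else 0.0
    df_model = p_chosen_params - 1
    df_res_chosen = n - p_chosen_params
    if rss_chosen > 0 and df_model > 0:
        f_model = ((rss0 - rss_chosen) / df_model) / (rss_chosen / df_res_chosen)
        p_model = float(stats.f.sf(f_model, df_model, df_res_chosen))
    else:
        f_model, p_model = math.inf, 0.0

    return AncovaResult(
        float(f_cov), p_cov, float(f_fac), p_fac, float(f_int), p_int,
        float(f_cmp), p_cmp, float(r2_full), float(r2_chosen),
        float(f_model), p_model, chosen, n,
    )


# ---------------------------------------------------------------------------
# variance partitioning
# ---------------------------------------------------------------------------

@dataclass
class VariancePartition:
    """Adjusted-R² decomposition over explanatory blocks.

    ``cells`` maps a frozenset of block names (the blocks a fraction is
    shared by exactly) to its adjusted-R² fraction; ``subset_adj_r2`` keeps
    the raw subset regressions the cells were derived from.  Cells may be
    negative, as is usual on the adjusted-R² scale.
    """

    block_names: tuple[str, ...]
    cells: dict[frozenset, float]
    subset_adj_r2: dict[frozenset, float]
    total_adj_r2: float
    residual: float
    n: int
    permutation_p: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0

    def unique(self, block: str) -> float:
        return self.cells[frozenset([block])]

    def shared(self, *blocks: str) -> float:
        return self.cells[frozenset(blocks)]


def adjusted_r2(r2: float, n: int, n_params: int) -> float:
    """Ezekiel's adjustment: 1 - (1 - R²)(n - 1)/(n - p - 1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def _as_matrix(block) -> np.ndarray:
    arr = np.asarray(block, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def variance_partition(
    y,
    blocks: dict[str, object],
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
) -> VariancePartition:
    """Partition the adjusted R² of ``y`` among 2-4 explanatory blocks.

    For every non-empty subset of blocks the response is regressed on the
    union of their covariates and the R² converted to adjusted R².  The
    2^B - 1 unique/shared fractions follow by inclusion-exclusion, so all
    fractions plus the residual sum to 1 exactly (to solver precision).
    Unique fractions (and the full model) are tested by Freedman-Lane
    permutation of reduced-model residuals; P = (hits + 1)/(n_perm + 1).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    names = tuple(blocks)
    if not 2 <= len(names) <= 4:
        raise ValueError("variance partitioning supports 2 to 4 blocks")
    mats = {name: _as_matrix(blocks[name]) for name in names}
    for name, mat in mats.items():
        if mat.shape[0] != n:
            raise ValueError(f"block {name!r} has {mat.shape[0]} rows, y has {n}")
        if mat.shape[1] == 0:
            raise ValueError(f"block {name!r} is empty")
    total_params = sum(m.shape[1] for m in mats.values())
    if n <= total_params + 2:
        raise ValueError("too few observations for the requested blocks")

    ones = np.ones((n, 1))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("response has zero variance")

    subsets = [
        frozenset(c)
        for r in range(1, len(names) + 1)
        for c in itertools.combinations(names, r)
    ]
    adj: dict[frozenset, float] = {}
    for sub in subsets:
        design = np.hstack([ones] + [mats[b] for b in names if b in sub])
        p = design.shape[1] - 1
        if np.linalg.matrix_rank(design) < design.shape[1]:
            logger.warning("singular design for blocks %s; using pseudoinverse",
                           sorted(sub))
        r2 = 1.0 - _rss(y, design) / ss_tot
        adj[sub] = adjusted_r2(r2, n, p)

    # union measures -> exact cells: F(S) = sum of cells T with T & S != {}
    m = len(subsets)
    a = np.zeros((m, m))
    for i, s in enumerate(subsets):
        for j, t in enumerate(subsets):
            a[i, j] = 1.0 if s & t else 0.0
    cell_values = np.linalg.solve(a, np.array([adj[s] for s in subsets]))
    cells = dict(zip(subsets, (float(v) for v in cell_values)))

    total = adj[frozenset(names)]
    part = VariancePartition(
        block_names=names,
        cells=cells,
        subset_adj_r2=adj,
        total_adj_r2=float(total),
        residual=float(1.0 - total),
        n=n,
        n_permutations=n_perm,
    )
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        full = np.hstack([ones] + [mats[b] for b in names])
        for name in names:
            reduced = np.hstack(
                [ones] + [mats[b] for b in names if b != name]
            )
            part.permutation_p[name] = _freedman_lane(
                y, reduced, full, mats[name].shape[1], n_perm, rng,
            )
        part.permutation_p["full"] = _freedman_lane(
            y, ones, full, total_params, n_perm, rng,
        )
    return part


def _partial_f(rss_red, rss_full, df_num, df_den):
    return ((rss_red - rss_full) / df_num) / (rss_full / df_den)


def _freedman_lane(y, reduced, full, df_num, n_perm, rng):
    """Permutation P for adding the tested columns to the reduced model.

    Residuals of the reduced model are permuted and added back to its fitted
    values; the partial F is recomputed for each permuted response.
    """
    n = len(y)
    q_red, _ = np.linalg.qr(reduced)
    q_full, _ = np.linalg.qr(full)
    df_den = n - full.shape[1]

    def rss_pair(ymat):
        tot = np.sum(ymat * ymat, axis=0)
        red = tot - np.sum((q_red.T @ ymat) ** 2, axis=0)
        ful = tot - np.sum((q_full.T @ ymat) ** 2, axis=0)
        return red, ful

    rss_red, rss_full = rss_pair(y[:, None])
    f_obs = _partial_f(rss_red[0], rss_full[0], df_num, df_den)

    fitted = q_red @ (q_red.T @ y)
    resid = y - fitted
    perms = np.empty((n, n_perm))
    for j in range(n_perm):
        perms[:, j] = resid[rng.permutation(n)]
    ystar = fitted[:, None] + perms
    red_s, full_s = rss_pair(ystar)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_star = _partial_f(red_s, full_s, df_num, df_den)
    hits = int(np.sum(f_star >= f_obs))
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# the bundled cohort analysis
# ---------------------------------------------------------------------------

#: metric column -> covariate column used for the simple regressions
DEFAULT_METRIC_COVARIATES = {
    "endogenous": "collection_year",
    "log_mean_length": "collection_year",
    "lam": "age",
    "f_ct1_5p": "age",
    "d_corr": "age",
}

CLIMATE_BLOCKS = ("temperature", "precipitation", "age", "genus")


@dataclass
class CohortModelResult:
    """Bundle of per-metric cohort statistics."""

    regressions: dict[str, dict[str, RegressionResult]] = field(default_factory=dict)
    decay_rates: dict[str, DecayRateFit] = field(default_factory=dict)
    ancovas: dict[str, AncovaResult] = field(default_factory=dict)
    variance_partitions: dict[str, VariancePartition] = field(default_factory=dict)
    notices: list[str] = field(default_factory=list)


def fit_decay_and_compare(
    table: pd.DataFrame,
    metrics: dict[str, str] | None = None,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
    k_through_origin: bool = False,
    ss_type: int = 1,
) -> CohortModelResult:
    """Run the full cohort analysis on a filtered metrics table.

    ``table`` needs columns ``genus`` and ``age`` plus the metric columns
    (and optionally ``collection_year``, ``temperature``, ``precipitation``).
    Produces per-genus and overall regressions for each metric, decay rates
    k from λ-vs-age, ANCOVA per metric (skipped with a notice when fewer
    than two genera qualify), and a variance partition of each metric over
    the available climate/age/genus blocks.
    """
    if metrics is None:
        metrics = {
            k: v for k, v in DEFAULT_METRIC_COVARIATES.items()
            if k in table.columns
        }
    result = CohortModelResult()
    genera = sorted(table["genus"].dropna().unique())

    for metric, covariate in metrics.items():
        if covariate not in table.columns:
            result.notices.append(
                f"{metric}: covariate {covariate!r} missing, regression skipped"
            )
            continue
        sub = table[[metric, covariate, "genus"]].dropna(subset=[metric, covariate])
        fits: dict[str, RegressionResult] = {}
        if len(sub) >= 3:
            fits["all"] = linear_fit(sub[covariate], sub[metric])
        for genus in genera:
            block = sub[sub["genus"] == genus]
            if len(block) >= 3:
                fits[genus] = linear_fit(block[covariate], block[metric])
        result.regressions[metric] = fits

    lam_tab = table[["lam", "age", "genus"]].dropna(subset=["lam", "age"])
    if len(lam_tab) >= 3:
        result.decay_rates["all"] = estimate_decay_rate(
            lam_tab["age"], lam_tab["lam"], "all", k_through_origin,
        )
    for genus in genera:
        block = lam_tab[lam_tab["genus"] == genus]
        if len(block) >= 3:
            result.decay_rates[genus] = estimate_decay_rate(
                block["age"], block["lam"], genus, k_through_origin,
            )

    for metric in metrics:
        if metric not in table.columns:
            continue
        sub = table[[metric, "age", "genus"]].dropna()
        qualified = sub["genus"].value_counts()
        if (qualified >= 3).sum() < 2:
            result.notices.append(
                f"{metric}: fewer than two genera with >= 3 samples, "
                "ANCOVA skipped"
            )
            continue
        keep = sub["genus"].isin(qualified[qualified >= 3].index)
        sub = sub[keep]
        result.ancovas[metric] = ancova(
            sub[metric], sub["age"], sub["genus"], ss_type=ss_type,
        )

    for metric in metrics:
        if metric not in table.columns:
            continue
        part = _metric_variance_partition(table, metric, n_perm, seed)
        if isinstance(part, str):
            result.notices.append(part)
        else:
            result.variance_partitions[metric] = part
    return result


def _metric_variance_partition(table, metric, n_perm, seed):
    available = [
        b for b in CLIMATE_BLOCKS
        if b in table.columns and table[b].notna().any()
    ]
    dropped = [b for b in CLIMATE_BLOCKS if b not in available]
    if dropped:
        logger.warning("%s: blocks %s unavailable, dropped", metric, dropped)
    if len(available) < 2:
        return f"{metric}: fewer than two explanatory blocks, partition skipped"
    cols = [metric] + [b for b in available]
    sub = table[cols].dropna()
    blocks: dict[str, object] = {}
    for b in available:
        if b == "genus":
            levels = sorted(sub["genus"].unique())
            if len(levels) < 2:
                continue
            codes = pd.Categorical(sub["genus"], categories=levels).codes
            blocks["genus"] = np.eye(len(levels))[codes][:, 1:]
        else:
            blocks[b] = sub[b].to_numpy(dtype=float)
    if len(blocks) < 2:
        return f"{metric}: fewer than two usable blocks, partition skipped"
    total_params = sum(_as_matrix(m).shape[1] for m in blocks.values())
    if len(sub) <= total_params + 2:
        return f"{metric}: too few complete cases for a partition"
    return variance_partition(sub[metric], blocks, n_perm=n_perm, seed=seed)
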