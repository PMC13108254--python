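"""Regressions, ANCOVA and variance partitioning against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from herbdamage.cohort import (
    adjusted_r2,
    ancova,
    fit_decay_and_compare,
    linear_fit,
    variance_partition,
)


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(1, 11, dtype=float)
        fit = linear_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_hand_computed_five_points(self):
        # Σ-formula by hand: slope 0.8, R² 0.64
        fit = linear_fit([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert fit.slope == pytest.approx(0.8)
        assert fit.r_squared == pytest.approx(0.64)
        assert fit.n == 5

    def test_constant_response(self):
        fit = linear_fit([1, 2, 3, 4], [7, 7, 7, 7])
        assert fit.slope == pytest.approx(0.0, abs=1e-15)
        assert fit.r_squared == 0.0

    def test_matches_sigma_formula_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=5)
            fit = linear_fit(x, y)
            slope = np.sum((x - x.mean()) * (y - y.mean())) / \
                np.sum((x - x.mean()) ** 2)
            assert fit.slope == pytest.approx(slope, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="constant"):
            linear_fit([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match=">= 3"):
            linear_fit([1, 2], [1, 2])


def statsmodels_ancova_oracle(y, x, g):
    """Independent route: statsmodels nested-model anova_lm in the
    covariate -> factor -> interaction order."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({"y": y, "x": x, "g": g})
    m0 = smf.ols("y ~ 1", data=df).fit()
    m_x = smf.ols("y ~ x", data=df).fit()
    m_xg = smf.ols("y ~ x + g", data=df).fit()
    full = smf.ols("y ~ x * g", data=df).fit()
    seq = anova_lm(m0, m_x, m_xg, full)
    cmp_tab = anova_lm(m_xg, full)
    return seq, cmp_tab, full, m_xg


class TestAncova:
    def _dataset(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 10, n)
        g = np.array(["A", "B"] * (n // 2))
        y = 1.5 * x + (g == "B") * 2.0 + (g == "B") * x * 0.5 + rng.normal(0, 1, n)
        return y, x, g

    def test_matches_statsmodels_sequential_anova(self):
        y, x, g = self._dataset()
        res = ancova(y, x, g)
        seq, cmp_tab, full, reduced = statsmodels_ancova_oracle(y, x, g)
        # rebuild sequential F against the full-model residual mean square
        mse = full.ssr / full.df_resid
        assert res.f_covariate == pytest.approx(
            seq["ss_diff"].iloc[1] / mse, abs=1e-8)
        assert res.f_factor == pytest.approx(
            seq["ss_diff"].iloc[2] / mse, abs=1e-8)
        assert res.f_interaction == pytest.approx(
            seq["ss_diff"].iloc[3] / mse, abs=1e-8)
        assert res.f_model_comparison == pytest.approx(
            cmp_tab["F"].iloc[1], abs=1e-8)
        assert res.p_model_comparison == pytest.approx(
            cmp_tab["Pr(>F)"].iloc[1], abs=1e-10)
        assert res.r_squared_full == pytest.approx(full.rsquared, abs=1e-10)

    def test_identical_groups_zero_noise(self):
        x = np.tile(np.arange(1.0, 7.0), 2)
        g = np.repeat(["A", "B"], 6)
        y = 3.0 * x + 1.0
        res = ancova(y, x, g)
        assert res.f_factor == 0.0 and res.p_factor == 1.0
        assert res.f_interaction == 0.0 and res.p_interaction == 1.0
        assert res.chosen_model == "no-interaction"

    def test_sequential_ss_sum_to_total(self):
        y, x, g = self._dataset(seed=3, n=40)
        res = ancova(y, x, g)
        # reconstruct SS from F * mse and compare with total SS about the mean
        rss_full = np.sum(
            (y - np.column_stack([
                np.ones_like(x), x, (g == "B").astype(float),
                x * (g == "B"),
            ]) @ np.linalg.lstsq(
                np.column_stack([
                    np.ones_like(x), x, (g == "B").astype(float),
                    x * (g == "B"),
                ]), y, rcond=None)[0]) ** 2
        )
        mse = rss_full / (len(y) - 4)
        ss_terms = (res.f_covariate + res.f_factor + res.f_interaction) * mse
        assert ss_terms + rss_full == pytest.approx(
            np.sum((y - y.mean()) ** 2), rel=1e-10)

    def test_detects_planted_slope_difference(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(20):
            x = rng.uniform(0, 1, 200)
            g = np.repeat(["A", "B"], 100)
            slopes = np.where(g == "B", 2.0, 1.0)
            y = slopes * x + rng.normal(0, 0.5, 200)
            if ancova(y, x, g).p_interaction < 0.05:
                hits += 1
        assert hits >= 19

    def test_errors(self):
        with pytest.raises(ValueError, match=">= 3 observations"):
            ancova([1, 2, 3, 4], [1, 2, 3, 4], ["A", "A", "A", "B"])
        with pytest.raises(ValueError, match=">= 2 levels"):
            ancova([1, 2, 3], [1, 2, 3], ["A", "A", "A"])


def varpart_oracle(y, blocks):
    """Independent derivation of the unique/shared cells via Möbius
    inversion on intersection measures (distinct from the package's
    linear-system route): I(T) = Σ_{∅≠S⊆T} (-1)^{|S|+1} F(S), then
    c(T) = Σ_{V⊇T} (-1)^{|V|-|T|} I(V)."""
    names = list(blocks)
    n = len(y)
    y = np.asarray(y, dtype=float)
    ss_tot = np.sum((y - y.mean()) ** 2)

    def adj(subset):
        cols = [np.atleast_2d(np.asarray(blocks[b], dtype=float).T).T
                for b in names if b in subset]
        design = np.hstack([np.ones((n, 1))] + cols)
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        r2 = 1 - np.sum((y - design @ beta) ** 2) / ss_tot
        return adjusted_r2(r2, n, design.shape[1] - 1)

    subsets = [frozenset(c) for r in range(1, len(names) + 1)
               for c in itertools.combinations(names, r)]
    F = {s: adj(s) for s in subsets}
    I = {
        t: sum((-1) ** (len(s) + 1) * F[s]
               for s in subsets if s <= t)
        for t in subsets
    }
    cells = {
        t: sum((-1) ** (len(v) - len(t)) * I[v]
               for v in subsets if v >= t)
        for t in subsets
    }
    return cells, F


class TestVariancePartition:
    def test_orthogonal_blocks_share_nothing(self):
        n = 500
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        # exact orthogonalization (and centering) of x2 against x1
        x1 = x1 - x1.mean()
        x2 = x2 - x2.mean()
        x2 = x2 - (x1 @ x2) / (x1 @ x1) * x1
        # moderate effects: on the adjusted-R2 scale the spurious shared
        # cell of an orthogonal design grows like ~2 R2 / n
        y = 0.4 * x1 + 0.4 * x2 + rng.normal(0, 1, n)
        part = variance_partition(y, {"one": x1, "two": x2}, n_perm=0)
        assert abs(part.shared("one", "two")) < 1e-3
        assert part.unique("one") == pytest.approx(
            part.subset_adj_r2[frozenset(["one"])], abs=1e-3)
        assert part.unique("two") == pytest.approx(
            part.subset_adj_r2[frozenset(["two"])], abs=1e-3)

    def test_duplicate_blocks_fully_shared(self):
        n = 200
        rng = np.random.default_rng(1)
        x = rng.normal(size=n)
        y = 2 * x + rng.normal(0, 1, n)
        part = variance_partition(y, {"a": x, "b": x.copy()}, n_perm=0)
        assert abs(part.unique("a")) < 0.01
        assert abs(part.unique("b")) < 0.01
        assert part.shared("a", "b") == pytest.approx(
            part.subset_adj_r2[frozenset(["a"])], abs=0.01)

    def test_three_blocks_match_moebius_oracle_and_sum_to_one(self):
        n = 200
        rng = np.random.default_rng(2)
        blocks = {
            "temp": rng.normal(size=n),
            "age": rng.normal(size=n),
            "genus": rng.integers(0, 2, n).astype(float),
        }
        y = (blocks["temp"] * 0.5 + blocks["age"] * 1.0
             + blocks["genus"] * 0.8 + rng.normal(0, 1, n))
        part = variance_partition(y, blocks, n_perm=0)
        cells_oracle, _ = varpart_oracle(y, blocks)
        assert len(part.cells) == 7
        for subset, value in part.cells.items():
            assert value == pytest.approx(cells_oracle[subset], abs=1e-10)
        assert sum(part.cells.values()) + part.residual == pytest.approx(
            1.0, abs=1e-10)

    def test_permutation_p_range_and_reproducibility(self):
        n = 120
        rng = np.random.default_rng(3)
        blocks = {"x": rng.normal(size=n), "z": rng.normal(size=n)}
        y = blocks["x"] * 0.8 + rng.normal(0, 1, n)
        p1 = variance_partition(y, blocks, n_perm=99, seed=5).permutation_p
        p2 = variance_partition(y, blocks, n_perm=99, seed=5).permutation_p
        assert p1 == p2
        for value in p1.values():
            assert 1 / 100 <= value <= 1.0
        assert p1["x"] == 1 / 100  # strong signal: never beaten by chance

    def test_block_count_limits(self):
        rng = np.random.default_rng(4)
        data = {f"b{i}": rng.normal(size=50) for i in range(5)}
        y = rng.normal(size=50)
        with pytest.raises(ValueError, match="2 to 4"):
            variance_partition(y, data)
        with pytest.raises(ValueError, match="2 to 4"):
            variance_partition(y, {"b0": data["b0"]})


class TestFitDecayAndCompare:
    def _cohort_frame(self, seed=0, n_per_genus=60):
        rng = np.random.default_rng(seed)
        rows = []
        for genus, k, alpha in (("Hordeum", 2.64e-4, 0.01),
                                ("Oryza", 1.79e-4, 0.02)):
            ages = rng.integers(10, 220, n_per_genus)
            for a in ages:
                rows.append({
                    "sample_id": f"{genus}{a}{rng.integers(1e6)}",
                    "genus": genus, "age": a,
                    "collection_year": 2025 - a,
                    "endogenous": rng.beta(8, 2),
                    "log_mean_length": 4.2 - 0.001 * a + rng.normal(0, 0.05),
                    "lam": k * a + rng.normal(0, 1e-3),
                    "f_ct1_5p": alpha + 6e-5 * a + rng.normal(0, 2e-3),
                    "temperature": rng.normal(18, 6),
                    "precipitation": rng.normal(1000, 300),
                })
        return pd.DataFrame(rows)

    def test_bundle_structure_and_k_recovery(self):
        table = self._cohort_frame()
        res = fit_decay_and_compare(table, n_perm=49, seed=0)
        assert set(res.decay_rates) == {"all", "Hordeum", "Oryza"}
        fit = res.decay_rates["Hordeum"]
        lo, hi = fit.k_ci()
        assert lo <= 2.64e-4 <= hi
        assert "f_ct1_5p" in res.ancovas
        assert "lam" in res.variance_partitions
        part = res.variance_partitions["lam"]
        assert sum(part.cells.values()) + part.residual == pytest.approx(1.0,
                                                                         abs=1e-9)

    def test_single_genus_skips_ancova_with_notice(self):
        table = self._cohort_frame()
        table = table[table["genus"] == "Hordeum"]
        res = fit_decay_and_compare(table, n_perm=0)
        assert res.ancovas == {}
        assert any("ANCOVA skipped" in n for n in res.notices)
        assert "lam" in res.regressions  # regressions still produced

    def test_missing_climate_block_dropped(self):
        table = self._cohort_frame().drop(columns=["temperature"])
        res = fit_decay_and_compare(table, n_perm=0)
        part = res.variance_partitions["lam"]
        assert "temperature" not in part.block_names
        assert "precipitation" in part.block_names
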