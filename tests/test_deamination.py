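"""Terminal profiles, authentication fit, baseline and divergence correction."""

import math

import numpy as np
import pytest

from herbdamage.deamination import (
    baseline_rate,
    correct_deamination,
    fit_damage_decay,
    terminal_frequencies,
)
from herbdamage.io import (
    SUBSTITUTION_TYPES,
    TerminalSubstitutionCounts,
    _BASE_INDEX,
    _SUB_INDEX,
    parse_alignments,
)
from herbdamage.deamination import TerminalProfile

from conftest import tally_by_hand


def uniform_counts(terminus, n_ref=1000, rates=None, p_max=20):
    """Counts with every position holding n_ref of each base and exact
    per-type substitution rates (must divide evenly)."""
    tab = TerminalSubstitutionCounts.zeros(terminus, p_max)
    tab.ref_counts[:, :] = n_ref
    for sub, rate in (rates or {}).items():
        count = rate * n_ref
        assert count == int(count), "choose rates that give integer counts"
        tab.sub_counts[:, _SUB_INDEX[sub]] = int(count)
    return tab


class TestTerminalFrequencies:
    def test_direct_ratio(self):
        tab = TerminalSubstitutionCounts.zeros("5p")
        tab.ref_counts[0, _BASE_INDEX["C"]] = 100
        tab.sub_counts[0, _SUB_INDEX["C>T"]] = 5
        prof = terminal_frequencies(tab, "C>T")
        assert prof.frequencies[0] == 0.05
        assert math.isnan(prof.frequencies[1])  # zero denominator flagged

    def test_zero_substitutions(self):
        tab = uniform_counts("5p")
        prof = terminal_frequencies(tab, "C>T")
        assert (prof.frequencies == 0).all()

    def test_matches_hand_ratios_on_parsed_toy(self, toy_sam, toy_reads):
        tables = parse_alignments(toy_sam)
        ref5, sub5, _, _, _ = tally_by_hand(toy_reads)
        prof = terminal_frequencies(tables.five_prime, "C>T")
        for p in range(1, 21):
            n_c = ref5[p]["C"]
            if n_c == 0:
                assert math.isnan(prof.frequencies[p - 1])
            else:
                assert prof.frequencies[p - 1] == sub5[p].get("C>T", 0) / n_c


def exp_profile(a, r, c, p_max=20, denominators=5000):
    p = np.arange(1, p_max + 1)
    f = a * np.exp(-r * (p - 1)) + c
    return TerminalProfile("5p", "C>T", f, np.full(p_max, float(denominators)))


class TestFitDamageDecay:
    def test_noiseless_recovery_to_four_significant_figures(self):
        fit = fit_damage_decay(exp_profile(0.02, 0.3, 0.005))
        assert fit.amplitude == pytest.approx(0.02, rel=1e-4)
        assert fit.rate == pytest.approx(0.3, rel=1e-4)
        assert fit.offset == pytest.approx(0.005, rel=1e-4)
        assert fit.r_squared > 1 - 1e-9
        assert fit.passes_gate

    def test_flat_profile_fails_gate(self):
        prof = TerminalProfile("5p", "C>T", np.full(20, 0.008), np.full(20, 5000.0))
        fit = fit_damage_decay(prof)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-6)
        assert not fit.passes_gate

    def test_binomial_sampled_amplitude_and_gate(self):
        # true profile sampled with binomial noise at 5,000 ref bases/position
        a, r, c, n_ref = 0.015, 0.4, 0.006, 5000
        p = np.arange(1, 21)
        truth = a * np.exp(-r * (p - 1)) + c
        rng = np.random.default_rng(2024)
        passed, within = 0, 0
        for _ in range(25):
            f = rng.binomial(n_ref, truth) / n_ref
            fit = fit_damage_decay(
                TerminalProfile("5p", "C>T", f, np.full(20, float(n_ref)))
            )
            se = math.sqrt(truth[0] * (1 - truth[0]) / n_ref)
            within += abs(fit.amplitude - a) < 4 * se
            passed += fit.passes_gate
        assert passed >= 24
        assert within >= 24

    def test_too_few_positions(self):
        prof = TerminalProfile("5p", "C>T", np.full(20, np.nan), np.zeros(20))
        fit = fit_damage_decay(prof)
        assert not fit.converged and not fit.passes_gate

    def test_gate_monotone_in_thresholds(self):
        rng = np.random.default_rng(9)
        p = np.arange(1, 21)
        for _ in range(15):
            f = rng.binomial(3000, 0.01 * np.exp(-0.3 * (p - 1)) + 0.005) / 3000
            prof = TerminalProfile("5p", "C>T", f, np.full(20, 3000.0))
            strict = fit_damage_decay(prof, r2_min=0.5, p_max=0.05)
            relaxed = fit_damage_decay(prof, r2_min=0.3, p_max=0.1)
            if strict.passes_gate:
                assert relaxed.passes_gate


class TestBaseline:
    def test_uniform_error_all_types(self):
        five = uniform_counts("5p", rates={s: 0.004 for s in SUBSTITUTION_TYPES})
        three = uniform_counts("3p", rates={s: 0.004 for s in SUBSTITUTION_TYPES})
        assert baseline_rate(five, three).b == pytest.approx(0.004)

    def test_deamination_types_excluded(self):
        rates = {s: 0.002 for s in SUBSTITUTION_TYPES}
        rates["C>T"] = 0.02
        rates["G>A"] = 0.02
        five = uniform_counts("5p", rates=rates)
        three = uniform_counts("3p", rates=rates)
        base = baseline_rate(five, three)
        assert base.b == pytest.approx(0.002)
        assert "C>T" not in base.per_type

    def test_zero_substitutions(self):
        assert baseline_rate(uniform_counts("5p"), uniform_counts("3p")).b == 0.0

    def test_all_zero_denominators(self):
        five = TerminalSubstitutionCounts.zeros("5p")
        three = TerminalSubstitutionCounts.zeros("3p")
        with pytest.raises(ValueError, match="denominators"):
            baseline_rate(five, three)


class TestCorrectDeamination:
    @pytest.mark.parametrize("f,b,expected", [
        (0.0213, 0.0076, 0.0137),
        (0.0100, 0.0100, 0.0),
        (0.0050, 0.0100, 0.0),   # floored
    ])
    def test_subtraction_with_floor(self, f, b, expected):
        assert correct_deamination(f, b) == pytest.approx(expected)

    @pytest.mark.parametrize("q", [0.002, 0.008])
    def test_uniform_divergence_cancels(self, q):
        """Adding a uniform divergence q to every substitution type shifts
        both f_CT(1) and the baseline by q, leaving d_corr unchanged."""
        rate = 1 / 500  # exact with n_ref = 1000
        damage = {s: rate for s in SUBSTITUTION_TYPES}
        damage["C>T"] = 0.02
        clean5 = uniform_counts("5p", rates=damage)
        clean3 = uniform_counts("3p", rates=damage)
        shifted = {s: r + q for s, r in damage.items()}
        dirty5 = uniform_counts("5p", rates=shifted)
        dirty3 = uniform_counts("3p", rates=shifted)

        f_clean = terminal_frequencies(clean5, "C>T").frequencies[0]
        f_dirty = terminal_frequencies(dirty5, "C>T").frequencies[0]
        d_clean = correct_deamination(f_clean, baseline_rate(clean5, clean3))
        d_dirty = correct_deamination(f_dirty, baseline_rate(dirty5, dirty3))
        assert d_dirty == pytest.approx(d_clean, abs=1e-12)


class TestMirroredDeamination:
    def test_five_and_three_prime_amplitudes_agree(self):
        """Double-stranded-style tables built with equal 5' C>T and 3' G>A
        generation give highly correlated first-base frequencies."""
        from herbdamage.simulate import SimulationConfig, GenusConfig, simulate_cohort
        from herbdamage.deamination import terminal_frequencies
        from scipy import stats as sps

        cfg = SimulationConfig(
            genera={"Mixta": GenusConfig(
                n_samples=200, k=2.08e-4, age_range=(10, 220),
                alpha=0.002, beta_age=6e-5,
                temperature_mean=18.0, temperature_sd=6.0,
                precipitation_mean=1000.0, precipitation_sd=300.0,
                baseline=0.006,
            )},
            # deep libraries: first-base binomial noise must be small
            # relative to the between-sample damage spread
            reads_range=(400_000, 400_000),
            seed=77,
        )
        _, tables, _ = simulate_cohort(cfg)
        f5 = [terminal_frequencies(t.five_prime, "C>T").frequencies[0]
              for t in tables]
        f3 = [terminal_frequencies(t.three_prime, "G>A").frequencies[0]
              for t in tables]
        r = sps.pearsonr(f5, f3)
        assert r.statistic ** 2 > 0.95
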