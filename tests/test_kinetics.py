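"""Kinetics core: conservation laws, analytic limits, theory-figure regime."""

import numpy as np
import pytest
from scipy.linalg import expm

from kinflow import kinetics as kin
from kinflow.errors import DegenerateInputError, InputError, ParameterError


def two_state_rates(k_off_dna, k_on_dna=1.0):
    return kin.RateConstants.from_kd(
        k_on_dna=k_on_dna, k_off_dna=k_off_dna, k_pol=0.0, kd_app_nt=30.0
    )


class TestRateConstants:
    def test_kd_consistency_enforced(self):
        with pytest.raises(ParameterError, match="inconsistent"):
            kin.RateConstants(
                k_on_dna=1, k_off_dna=1, k_on_nt=100, k_off_nt=5.0, k_pol=1, kd_app_nt=30
            )

    def test_from_kd_derives_off_rate(self):
        r = kin.RateConstants.from_kd(k_on_dna=1, k_off_dna=1, k_pol=1, kd_app_nt=30)
        assert r.k_off_nt == pytest.approx(30 * 100)

    @pytest.mark.parametrize("bad", [-1.0, float("nan"), float("inf")])
    def test_invalid_rates_rejected(self, bad):
        with pytest.raises(ParameterError):
            kin.RateConstants.from_kd(k_on_dna=bad, k_off_dna=1, k_pol=1, kd_app_nt=30)


class TestSimulateTimecourse:
    def test_symmetric_two_state_binding_reaches_half(self):
        # no nucleotide, no chemistry, association flux == off-rate -> %SC 0.5
        rates = two_state_rates(k_off_dna=5.0, k_on_dna=1.0)
        mix = kin.ReactionMix(enzyme_total=0.01, dna_total=5.0, nucleotide=0.0)
        t = np.linspace(0, 10, 500)
        tc = kin.simulate_timecourse(rates, mix, t, mode="clamped")
        assert tc.percent_sc_series[-1] == pytest.approx(0.5, abs=1e-6)

    def test_two_state_closed_form_relaxation(self):
        # %SC(t) = f/(f+koff) (1 - exp(-(f+koff) t)) for pure binding
        f, koff = 3.0, 7.0
        rates = two_state_rates(k_off_dna=koff, k_on_dna=f / 2.0)
        mix = kin.ReactionMix(enzyme_total=0.05, dna_total=2.0, nucleotide=0.0)
        t = np.linspace(0, 2, 400)
        tc = kin.simulate_timecourse(rates, mix, t, mode="clamped")
        expected = f / (f + koff) * (1 - np.exp(-(f + koff) * t))
        assert np.allclose(tc.percent_sc_series, expected, atol=1e-6)

    def test_matches_matrix_exponential_oracle(self):
        # clamped DNA + fixed nucleotide -> linear ODE solved exactly by expm
        rates = kin.RateConstants.from_kd(
            k_on_dna=2.0, k_off_dna=40.0, k_pol=5.0, kd_app_nt=25.0
        )
        mix = kin.ReactionMix(enzyme_total=0.1, dna_total=3.0, nucleotide=80.0)
        t = np.linspace(0, 1.0, 101)
        tc = kin.simulate_timecourse(rates, mix, t, mode="clamped")

        a = rates.k_on_dna * mix.dna_total
        kb = rates.k_on_nt * mix.nucleotide
        km1, km2, kpol = rates.k_off_dna, rates.k_off_nt, rates.k_pol
        # states [E, B0, T0, B1]
        A = np.array(
            [
                [-a, km1, 0.0, km1],
                [a, -(km1 + kb), km2, 0.0],
                [0.0, kb, -(km2 + kpol), 0.0],
                [0.0, 0.0, kpol, -km1],
            ]
        )
        y0 = np.array([mix.enzyme_total, 0.0, 0.0, 0.0])
        exact = np.stack([expm(A * ti) @ y0 for ti in t])
        sc_exact = exact[:, 1:].sum(axis=1) / mix.enzyme_total
        assert np.allclose(tc.percent_sc_series, sc_exact, atol=1e-6)

    def test_initial_state_all_free(self):
        rates = two_state_rates(10.0)
        mix = kin.ReactionMix(0.1, 1.0, 50.0)
        tc = kin.simulate_timecourse(rates, mix, np.linspace(0, 1, 50))
        assert tc.species["E"][0] == pytest.approx(0.1)
        assert tc.species["D0"][0] == pytest.approx(1.0)
        assert tc.sc_series[0] == 0.0

    @pytest.mark.parametrize("mode", ["single_turnover", "flow"])
    @pytest.mark.parametrize("n_inc", [1, 3])
    def test_mass_conservation(self, mode, n_inc):
        rates = kin.RateConstants.from_kd(
            k_on_dna=80.0, k_off_dna=500.0, k_pol=9.0, kd_app_nt=30.0
        )
        mix = kin.ReactionMix(0.15, 1.5, 100.0)
        t = np.linspace(0, 20, 300)
        tc = kin.simulate_timecourse(rates, mix, t, mode=mode, n_incorporations=n_inc)
        E = tc.species["E"].copy()
        D = np.zeros_like(E)
        for i in range(n_inc + 1):
            E += tc.species[f"B{i}"]
            D += tc.species[f"D{i}"] + tc.species[f"B{i}"]
        for i in range(n_inc):
            E += tc.species[f"T{i}"]
            D += tc.species[f"T{i}"]
        assert np.all(np.abs(E - mix.enzyme_total) <= 1e-6 * mix.enzyme_total)
        assert np.all(np.abs(D - mix.dna_total) <= 1e-6 * mix.dna_total)
        for s in tc.species.values():
            assert np.all(s >= -1e-9)

    def test_sc_is_sum_of_complexes(self):
        rates = two_state_rates(10.0)
        mix = kin.ReactionMix(0.1, 1.0, 50.0)
        tc = kin.simulate_timecourse(rates, mix, np.linspace(0, 1, 50))
        total = tc.species["B0"] + tc.species["B1"] + tc.species["T0"]
        assert np.array_equal(tc.sc_series, total)

    def test_bad_grid_rejected(self):
        rates = two_state_rates(10.0)
        mix = kin.ReactionMix(0.1, 1.0, 0.0)
        with pytest.raises(InputError):
            kin.simulate_timecourse(rates, mix, np.array([0.1, 0.2]))
        with pytest.raises(InputError):
            kin.simulate_timecourse(rates, mix, np.array([0.0, 0.0, 1.0]))


class TestSteadyState:
    def test_no_nucleotide_flux_equals_off_rate(self):
        rates = two_state_rates(k_off_dna=8.0, k_on_dna=2.0)
        mix = kin.ReactionMix(0.01, 4.0, 0.0)  # flux 8 == koff
        assert kin.steady_state_percent_sc(rates, mix) == pytest.approx(0.5)

    def test_mismatch_plateau_is_one_fifth(self):
        _, mism = kin.fig2_rate_constants(500.0)
        assert kin.steady_state_percent_sc(
            mism, kin.fig2_mix(5.0, is_correct=False)
        ) == pytest.approx(0.2, abs=0.01)

    def test_zero_off_rate_degenerate(self):
        rates = two_state_rates(0.0)
        with pytest.raises(DegenerateInputError):
            kin.steady_state_percent_sc(rates, kin.ReactionMix(0.1, 1.0, 0.0))

    def test_matches_ode_long_time_limit_random_draws(self, rng):
        # 100 random parameter draws: analytic value equals the clamped-DNA
        # ODE integrated past the system's slowest relaxation mode.  Draws
        # whose relaxation would take hours (slowest mode < 1e-3 1/s) are
        # outside the regimes the model targets and are redrawn.
        n_checked = 0
        while n_checked < 100:
            rates = kin.RateConstants.from_kd(
                k_on_dna=10 ** rng.uniform(-1, 1.5),
                k_off_dna=10 ** rng.uniform(0, 3),
                k_pol=10 ** rng.uniform(-1, 1.5),
                kd_app_nt=10 ** rng.uniform(0, 2.5),
            )
            mix = kin.ReactionMix(
                enzyme_total=0.01,
                dna_total=10 ** rng.uniform(-0.3, 1.3),
                nucleotide=10 ** rng.uniform(0, 2.7),
            )
            a = rates.k_on_dna * mix.dna_total
            kb = rates.k_on_nt * mix.nucleotide
            km1, km2, kpol = rates.k_off_dna, rates.k_off_nt, rates.k_pol
            A = np.array(
                [
                    [-a, km1, 0.0, km1],
                    [a, -(km1 + kb), km2, 0.0],
                    [0.0, kb, -(km2 + kpol), 0.0],
                    [0.0, 0.0, kpol, -km1],
                ]
            )
            lam = np.abs(np.linalg.eigvals(A).real)
            slowest = lam[lam > 1e-12].min()
            if slowest < 1e-3:
                continue
            n_checked += 1
            t_end = 30.0 / slowest
            t = np.linspace(0, t_end, 50)
            tc = kin.simulate_timecourse(rates, mix, t, mode="clamped")
            assert kin.steady_state_percent_sc(rates, mix) == pytest.approx(
                tc.percent_sc_series[-1], abs=1e-4
            )


class TestFig2Regime:
    """The theory-figure parameter regime (k-1 = 500 1/s unless scanned)."""

    def test_correct_max_sc_near_point_eight_at_500uM(self):
        corr, _ = kin.fig2_rate_constants(500.0)
        t = np.linspace(0, 2, 2000)
        tc = kin.simulate_timecourse(corr, kin.fig2_mix(500.0), t, mode="clamped")
        assert tc.percent_sc_series.max() == pytest.approx(0.8, abs=0.05)

    @pytest.mark.parametrize("conc", [5.0, 50.0, 500.0])
    def test_mismatch_plateau_near_point_two(self, conc):
        _, mism = kin.fig2_rate_constants(500.0)
        t = np.linspace(0, 1, 500)
        tc = kin.simulate_timecourse(mism, kin.fig2_mix(conc, is_correct=False), t, mode="clamped")
        assert tc.percent_sc_series[-1] == pytest.approx(0.2, abs=0.02)

    def test_slow_off_rate_saturates_both_classes(self):
        # low ionic strength (k-1 = 0.2 1/s): correct and mismatch both ~100%
        corr, mism = kin.fig2_rate_constants(0.2)
        mix = kin.fig2_mix(100.0)
        for rates in (corr, mism):
            assert kin.steady_state_percent_sc(rates, mix) > 0.97

    def test_fast_off_rate_separates_classes(self):
        corr, mism = kin.fig2_rate_constants(500.0)
        t = np.linspace(0, 1, 500)
        hi = kin.simulate_timecourse(corr, kin.fig2_mix(100.0), t, mode="clamped")
        lo = kin.simulate_timecourse(mism, kin.fig2_mix(100.0), t, mode="clamped")
        assert hi.percent_sc_series.max() > lo.percent_sc_series.max() * 2


class TestMaxAndSsAmp:
    def test_constant_series(self):
        m, s, r = kin.max_and_ss_amp(np.full(100, 3.0), ss_window=10)
        assert (m, s, r) == (3.0, 3.0, 1.0)

    def test_monotone_decay_max_at_first_sample(self):
        series = np.exp(-np.linspace(0, 5, 100))
        m, s, r = kin.max_and_ss_amp(series, ss_window=10)
        assert m == series[0]
        assert r > 1

    def test_empty_and_short_series_rejected(self):
        with pytest.raises(InputError):
            kin.max_and_ss_amp(np.array([]), 1)
        with pytest.raises(InputError):
            kin.max_and_ss_amp(np.ones(5), 5)

    def test_correct_trace_ratio_exceeds_mismatch(self):
        # simulated finite-DNA flow traces at high off-rate: the correct
        # nucleotide's transient gives MaxAmp/SSAmp > 1 and > mismatch's
        from kinflow import simulate as sim

        corr, mism = sim.sequencing_rate_constants(500.0)
        mix = kin.ReactionMix(sim.SEQ_ENZYME_TOTAL, sim.SEQ_DNA_TOTAL, 100.0)
        t = np.linspace(0, 36, 360)
        tc_c = kin.simulate_timecourse(corr, mix, t, mode="flow")
        tc_m = kin.simulate_timecourse(mism, mix, t, mode="flow")
        _, _, r_c = kin.max_and_ss_amp(tc_c.percent_sc_series, 50)
        _, _, r_m = kin.max_and_ss_amp(tc_m.percent_sc_series, 50)
        assert r_c > 1.5
        assert r_c > r_m


class TestParameterScan:
    def test_off_rate_scan_structure(self):
        corr, mism = kin.fig2_rate_constants()
        table = kin.parameter_scan(
            corr, mism, kin.fig2_mix(100.0), "k_off_dna", np.array([0.2, 100.0, 500.0])
        )
        assert len(table) == 6
        at_02 = table[table.value == 0.2]
        assert (at_02.steady_percent_sc > 0.97).all()
        fast = table[table.value >= 100.0]
        for v in (100.0, 500.0):
            sub = fast[fast.value == v].set_index("label")
            assert sub.loc["correct", "max_percent_sc"] > sub.loc["mismatch", "max_percent_sc"]

    def test_mismatch_steady_decreases_with_off_rate(self):
        corr, mism = kin.fig2_rate_constants()
        grid = np.array([50.0, 150.0, 500.0, 1000.0])
        table = kin.parameter_scan(corr, mism, kin.fig2_mix(100.0), "k_off_dna", grid)
        mm = table[table.label == "mismatch"].sort_values("value")
        assert np.all(np.diff(mm.steady_percent_sc.to_numpy()) < 0)
        # and it matches the analytic two-state-like formula
        assert np.allclose(mm.steady_percent_sc, mm.analytic_steady, atol=1e-4)

    def test_correct_max_sc_nondecreasing_in_nucleotide(self):
        corr, mism = kin.fig2_rate_constants(500.0)
        grid = np.array([5.0, 20.0, 100.0, 500.0])
        table = kin.parameter_scan(corr, mism, kin.fig2_mix(5.0), "nucleotide", grid)
        cc = table[table.label == "correct"].sort_values("value")
        assert np.all(np.diff(cc.max_percent_sc.to_numpy()) > -1e-9)

    def test_match_mismatch_ratio_nondecreasing_in_off_rate(self):
        corr, mism = kin.fig2_rate_constants()
        grid = np.array([100.0, 300.0, 1000.0])
        table = kin.parameter_scan(corr, mism, kin.fig2_mix(100.0), "k_off_dna", grid)
        ratio = []
        for v in grid:
            sub = table[table.value == v].set_index("label")
            ratio.append(sub.loc["correct", "max_percent_sc"] / sub.loc["mismatch", "max_percent_sc"])
        assert np.all(np.diff(ratio) > -1e-9)

    def test_empty_grid_rejected(self):
        corr, mism = kin.fig2_rate_constants()
        with pytest.raises(InputError):
            kin.parameter_scan(corr, mism, kin.fig2_mix(100.0), "k_off_dna", np.array([]))
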