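"""1:1 and bivalent SPR models, global fitting, and tandem competition."""

import numpy as np
import pytest

from rrmbindkit.errors import DegenerateDataError, InputError
from rrmbindkit.kinetics import (
    STANDARD_SCHEDULE,
    BivalentParams,
    BridgingParams,
    InjectionSchedule,
    Kinetic1to1Params,
    Sensorgram,
    fit_1to1,
    fit_bivalent,
    instantaneous_off_rate,
    kd_from_rates,
    simulate_1to1,
    simulate_bivalent,
    simulate_tandem_competition,
)
from rrmbindkit.msi1 import REPORTED_KINETICS
from rrmbindkit.synth import gen_sensorgrams

# light schedule for ODE-heavy tests
SMALL = InjectionSchedule((1.5625e-8, 6.25e-8, 2.5e-7), t_assoc=90.0, t_dissoc=200.0, dt=1.0)


class TestSimulate1to1:
    def test_zero_concentration_gives_zero_response(self):
        p = Kinetic1to1Params(1e6, 0.1, 100.0)
        sched = InjectionSchedule((0.0,), t_assoc=60, t_dissoc=60, dt=1.0)
        (g,) = simulate_1to1(p, sched)
        assert np.all(g.response == 0.0)

    def test_half_saturation_plateau(self):
        """At C = KD1 the association plateau is Rmax/2."""
        p = Kinetic1to1Params(1e6, 0.01, 100.0)  # KD1 = 10 nM
        sched = InjectionSchedule((1e-8,), t_assoc=5000.0, t_dissoc=10.0, dt=1.0)
        (g,) = simulate_1to1(p, sched)
        plateau = g.response[g.time <= sched.t_assoc][-1]
        assert plateau == pytest.approx(50.0, abs=1e-3)

    def test_closed_form_agrees_with_ode_integration(self):
        p = Kinetic1to1Params(3.5e6, 0.167, 100.0)
        closed = simulate_1to1(p, STANDARD_SCHEDULE, method="closed")
        ode = simulate_1to1(p, STANDARD_SCHEDULE, method="ode")
        worst = max(np.abs(a.response - b.response).max() for a, b in zip(closed, ode))
        assert worst <= 1e-6


class TestSimulateBivalent:
    def test_reduces_to_1to1_when_ka2_zero(self):
        biv = BivalentParams(3.5e6, 0.167, 0.0, 1e-3, 100.0)
        mono = Kinetic1to1Params(3.5e6, 0.167, 100.0)
        gb = simulate_bivalent(biv, SMALL)
        gm = simulate_1to1(mono, SMALL)
        worst = max(np.abs(a.response - b.response).max() for a, b in zip(gb, gm))
        assert worst <= 1e-6

    def test_surface_site_conservation(self):
        p = BivalentParams(3e6, 0.1, 5e-4, 5e-3, 150.0)
        _, states = simulate_bivalent(p, SMALL, return_states=True)
        for st in states:
            drift = np.abs(st["AL"] + 2 * st["AL2"] + st["Lfree"] - p.Ltot) / p.Ltot
            assert drift.max() <= 1e-8

    def test_biphasic_dissociation_off_rate_decreases(self):
        """With avidity (ka2 > 0) the instantaneous off-rate −d lnR/dt is
        monotonically nonincreasing: fast initial loss, then stabilisation."""
        p = BivalentParams(3e6, 0.1, 5e-4, 5e-3, 200.0)
        grams = simulate_bivalent(p, SMALL)
        off = instantaneous_off_rate(grams[-1])
        assert np.all(np.diff(off) <= 1e-6)
        assert off[0] > 2 * off[-1]


class TestFit1to1:
    def test_recovers_study_rate_constants_noiselessly(self):
        """Noiseless data from the single-site oligo / RRM1 rates are
        refitted to <=0.1% relative."""
        row = REPORTED_KINETICS[("RRM1", "oligo-L2")]
        truth = Kinetic1to1Params(row.ka1, row.kd1, 100.0)
        fit = fit_1to1(simulate_1to1(truth, STANDARD_SCHEDULE))
        assert fit.converged
        assert fit.params["ka1"] == pytest.approx(row.ka1, rel=1e-3)
        assert fit.params["kd1"] == pytest.approx(row.kd1, rel=1e-3)
        assert fit.params["KD1"] == pytest.approx(row.kd1 / row.ka1, rel=1e-3)

    @pytest.mark.parametrize("key", sorted(REPORTED_KINETICS), ids="-".join)
    def test_kd1_recovery_for_every_reported_row(self, key):
        """Simulation truth -> noiseless global fit returns KD1 = kd1/ka1 to
        <=0.5% relative, for every published row."""
        row = REPORTED_KINETICS[key]
        truth = Kinetic1to1Params(row.ka1, row.kd1, 100.0)
        fit = fit_1to1(simulate_1to1(truth, STANDARD_SCHEDULE), n_starts=3)
        assert fit.params["KD1"] == pytest.approx(row.kd1 / row.ka1, rel=5e-3)

    def test_ci_coverage_under_noise(self):
        """σ = 1 RU Gaussian noise, 20 seeds: the true ka1 and kd1 fall inside
        the 95% CI in at least 17/20 fits."""
        truth = Kinetic1to1Params(3.5e6, 0.167, 100.0)
        hits_ka = hits_kd = 0
        for seed in range(20):
            grams = gen_sensorgrams("1to1", truth, STANDARD_SCHEDULE, sigma=1.0, seed=seed)
            fit = fit_1to1(grams, n_starts=3)
            hits_ka += fit.ci95["ka1"][0] <= truth.ka1 <= fit.ci95["ka1"][1]
            hits_kd += fit.ci95["kd1"][0] <= truth.kd1 <= fit.ci95["kd1"][1]
        assert hits_ka >= 17 and hits_kd >= 17

    def test_all_zero_response_is_degenerate(self):
        t = np.arange(0.0, 100.0, 1.0)
        g = Sensorgram(t, np.zeros_like(t), 1e-8, 50.0)
        with pytest.raises(DegenerateDataError):
            fit_1to1([g])

    def test_single_concentration_flagged(self):
        p = Kinetic1to1Params(1e6, 0.05, 80.0)
        sched = InjectionSchedule((5e-8,), t_assoc=90, t_dissoc=200, dt=1.0)
        fit = fit_1to1(simulate_1to1(p, sched))
        assert any("single-concentration" in w for w in fit.warnings)


class TestFitBivalent:
    def test_noiseless_recovery_of_all_four_rates(self):
        truth = BivalentParams(3e6, 0.1, 5e-4, 5e-3, 150.0)
        fit = fit_bivalent(simulate_bivalent(truth, SMALL))
        for name, true_val in (("ka1", truth.ka1), ("kd1", truth.kd1),
                               ("ka2", truth.ka2), ("kd2", truth.kd2)):
            assert fit.params[name] == pytest.approx(true_val, rel=1e-2)
        assert fit.params["KD1"] == fit.params["kd1"] / fit.params["ka1"]

    def test_nested_model_consistency_at_ka2_zero(self):
        """Data without a bivalent component: fitted bivalent fraction ~0 and
        KD1 agrees with the plain 1:1 fit."""
        mono = Kinetic1to1Params(2e6, 0.08, 120.0)
        grams = simulate_1to1(mono, SMALL)
        biv_fit = fit_bivalent(grams)
        mono_fit = fit_1to1(grams)
        assert biv_fit.params["bivalent_fraction"] < 0.02
        assert biv_fit.params["KD1"] == pytest.approx(mono_fit.params["KD1"], rel=0.02)


class TestKdFromRates:
    @pytest.mark.parametrize(
        "ka, kd, expected_nM, printed_nM, tol_nM",
        [
            (4.5e5, 0.069, 153.33, 153.0, 8.6),
            (2.1e6, 0.055, 26.19, 26.4, 1.6),
        ],
    )
    def test_reported_table_rows(self, ka, kd, expected_nM, printed_nM, tol_nM):
        kd1_nM = kd_from_rates(ka, kd) * 1e9
        assert kd1_nM == pytest.approx(expected_nM, abs=0.01)
        assert abs(kd1_nM - printed_nM) <= tol_nM

    def test_zero_kd_gives_zero(self):
        assert kd_from_rates(1e6, 0.0) == 0.0

    def test_zero_ka_raises(self):
        with pytest.raises(ZeroDivisionError):
            kd_from_rates(0.0, 0.1)


class TestTandemCompetition:
    def test_no_bridging_identical_domains_is_doubled_flux_1to1(self):
        traces = simulate_tandem_competition((3e6, 0.1), (3e6, 0.1),
                                             BridgingParams(), 100.0, SMALL)
        doubled = simulate_1to1(Kinetic1to1Params(6e6, 0.1, 100.0), SMALL)
        worst = max(
            np.abs(t.sensorgram.response - g.response).max()
            for t, g in zip(traces, doubled)
        )
        assert worst <= 1e-6

    def test_no_bridging_dissociation_is_monoexponential(self):
        traces = simulate_tandem_competition((3e6, 0.1), (3e6, 0.1),
                                             BridgingParams(), 100.0, SMALL)
        g = traces[-1].sensorgram
        mask = (g.time > g.t_assoc) & (g.response > 1e-6)
        t, logr = g.time[mask], np.log(g.response[mask])
        slope, intercept = np.polyfit(t, logr, 1)
        r2 = 1 - np.sum((logr - (slope * t + intercept)) ** 2) / np.sum(
            (logr - logr.mean()) ** 2
        )
        assert r2 >= 0.999

    def test_bridging_produces_biphasic_dissociation(self):
        traces = simulate_tandem_competition((3e6, 0.1), (1e6, 0.05),
                                             BridgingParams(2e-3, 2e-3), 150.0, SMALL)
        off = instantaneous_off_rate(traces[-1].sensorgram)
        assert np.all(np.diff(off) <= 1e-6)

    def test_one_dead_domain_reduces_to_1to1(self):
        traces = simulate_tandem_competition((3e6, 0.1), (0.0, 0.05),
                                             BridgingParams(), 100.0, SMALL)
        mono = simulate_1to1(Kinetic1to1Params(3e6, 0.1, 100.0), SMALL)
        worst = max(
            np.abs(t.sensorgram.response - g.response).max()
            for t, g in zip(traces, mono)
        )
        assert worst <= 1e-6

    def test_site_conservation(self):
        traces = simulate_tandem_competition((3e6, 0.1), (1e6, 0.05),
                                             BridgingParams(2e-3, 1e-3), 150.0, SMALL)
        for tr in traces:
            st = tr.states
            total = st["B1"] + st["B2"] + 2 * st["X"] + st["Lfree"]
            assert np.abs(total - 150.0).max() / 150.0 <= 1e-8


class TestValidation:
    def test_negative_concentration_rejected(self):
        with pytest.raises(InputError):
            InjectionSchedule((-1e-9,))

    def test_non_monotone_time_rejected(self):
        with pytest.raises(InputError):
            Sensorgram(np.array([0.0, 1.0, 1.0]), np.zeros(3), 1e-9, 0.5)
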