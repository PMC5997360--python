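"""Core-clock network and CCG dynamics: formula checks, limit cycle, limits."""

import numpy as np
import pytest

from circaclock.dde import HistoryFunction, integrate
from circaclock.models import (
    GENES,
    CCGParameters,
    CoreClockParameters,
    TissueModel,
    available_tissues,
    ccg_rhs,
    core_clock_rhs,
    load_tissue_parameters,
    simulate_ccg,
    simulate_core_clock,
)
from circaclock.phases import estimate_period, find_peaks

from conftest import constant_trajectory


def saturating(params: CoreClockParameters) -> CoreClockParameters:
    """Push every dissociation constant to 1e12: all regulatory terms -> 1."""
    keys = ("ar1", "ar4", "cr2", "cr3", "cr4", "cr5", "gr2", "gr3", "gr4",
            "gr5", "ba2", "ba3", "ba4", "ba5", "fa2", "fa3", "fa4")
    return params.replace(**{k: 1e12 for k in keys})


class TestParameterTypes:
    def test_bundled_fixtures_present(self):
        assert set(available_tissues()) >= {
            "liver", "muscle", "adipose", "lung", "all_tissues"}

    def test_all_tissues_column_values(self, all_tissues_model):
        p = all_tissues_model.params
        assert p.delays == (6.28, 0.56, 3.95, 3.84, 3.00)
        assert p.degradations == (0.39, 0.58, 0.27, 0.22, 0.42)

    def test_nonpositive_parameter_rejected(self, all_tissues_model):
        with pytest.raises(ValueError, match="must be > 0"):
            all_tissues_model.params.replace(d_Bmal1=-0.1)

    def test_nan_parameter_rejected(self, all_tissues_model):
        with pytest.raises(ValueError, match="finite"):
            all_tissues_model.params.replace(tau_Per2=float("nan"))

    def test_ccg_counts_must_be_integers(self):
        with pytest.raises(ValueError, match="non-negative integer"):
            CCGParameters(b=2, ba=1, cr=1, gr=1, ar=1, f=2, fa=1, d=0.3,
                          n1=1.5, n2=0, n3=0)


class TestCoreClockRhs:
    def test_production_term_at_dissociation_constant(self, all_tissues_model):
        # Rev-Erba delayed value equal to ar1 -> Bmal1 production (1/2)^2
        p = all_tissues_model.params
        rhs = core_clock_rhs(p)
        state = np.zeros(5)
        delayed = [np.zeros(5) for _ in range(5)]
        delayed[1][1] = p.ar1  # RevErba(t - tau_RevErba)
        dy = rhs(0.0, state, delayed)
        assert dy[0] == pytest.approx(0.25)

    def test_saturating_limit_relaxes_to_inverse_degradation(self, all_tissues_model):
        params = saturating(all_tissues_model.params).replace(d_Bmal1=0.5)
        model = TissueModel("degenerate", params)
        traj = simulate_core_clock(model, duration=120.0, burn_in=100.0)
        final = traj.evaluate(119.0)
        expect = 1.0 / np.array(params.degradations)
        np.testing.assert_allclose(final, expect, rtol=1e-4)
        assert final[0] == pytest.approx(2.0, rel=1e-4)


@pytest.mark.parametrize("tissue", ["liver", "muscle", "adipose", "lung",
                                    "all_tissues"])
class TestLimitCycle:
    def test_sustained_oscillation_shared_period(self, tissue):
        from circaclock.fastsim import simulate_grid

        params = load_tissue_parameters(tissue).params
        t, Y = simulate_grid(params, 360.0)
        post = t >= 240.0
        grid = (t[post], Y[post])
        periods = [estimate_period(grid, g) for g in GENES]
        for T in periods:
            assert 20.0 < T < 28.0
        assert (max(periods) - min(periods)) / min(periods) < 0.005
        for i in range(5):
            y = Y[post][:, i]
            assert y.max() / y.min() > 1.2


def test_liver_peak_ordering(liver_model):
    from circaclock.fastsim import simulate_grid

    t, Y = simulate_grid(liver_model.params, 360.0)
    post = t >= 240.0
    tp, Yp = t[post], Y[post]
    period = estimate_period((tp, Yp), 0)
    peaks = {g: find_peaks(tp, Yp[:, i])[0] for i, g in enumerate(GENES)}
    rev0 = peaks["RevErba"][1]
    lag = {g: (peaks[g][np.searchsorted(peaks[g], rev0) % len(peaks[g])] - rev0)
              % period for g in GENES}
    assert lag["Dbp"] < lag["Per2"] < lag["Cry1"]


class TestCCG:
    def test_zero_counts_relax_to_inverse_degradation(self, core_trajectory,
                                                      all_tissues_model):
        ccg = CCGParameters(b=2, ba=1, cr=1, gr=1, ar=1, f=2, fa=1, d=0.5,
                            n1=0, n2=0, n3=0)
        traj = simulate_ccg(ccg, core_trajectory, all_tissues_model.params,
                            duration=40.0, burn_in=35.0)
        assert traj.evaluate(traj.t_end - 0.5)[0] == pytest.approx(2.0, rel=1e-3)

    def test_single_ebox_constant_core(self, all_tissues_model):
        # constant core with Bmal1 = ba, Per2 = Cry1 = 0-ish, b = 3:
        # production = ((1+3)/2) * 1 * 1 = 2 -> steady state 2/d
        p = all_tissues_model.params
        core = constant_trajectory([1.0, 0.0, 1e-12, 1e-12, 0.0],
                                   t_span=(0.0, 100.0))
        ccg = CCGParameters(b=3.0, ba=1.0, cr=1e6, gr=1e6, ar=1.0, f=2.0,
                            fa=1.0, d=0.4, n1=1, n2=0, n3=0)
        rhs = ccg_rhs(ccg, core, p)
        dy = rhs(50.0, np.array([0.0]), [])
        assert dy[0] == pytest.approx(2.0, rel=1e-5)
        traj = simulate_ccg(ccg, core, p, duration=60.0, burn_in=50.0)
        assert traj.evaluate(traj.t_end - 1.0)[0] == pytest.approx(2.0 / 0.4,
                                                                   rel=1e-3)

    def test_periodic_forcing_gives_periodic_ccg(self, core_trajectory,
                                                 all_tissues_model):
        ccg = CCGParameters(b=3.0, ba=1.0, cr=2.0, gr=1.5, ar=1.0, f=4.0,
                            fa=0.5, d=0.3, n1=2, n2=1, n3=1)
        period = estimate_period(core_trajectory, "Bmal1")
        traj = simulate_ccg(ccg, core_trajectory, all_tissues_model.params,
                            duration=110.0, burn_in=50.0)
        ts = np.linspace(traj.t0, traj.t0 + period, 101)
        one = traj.evaluate(ts)[:, 0]
        two = traj.evaluate(ts + period)[:, 0]
        np.testing.assert_allclose(one, two, rtol=2e-3)

    def test_core_too_short_names_required_extension(self, all_tissues_model):
        core = constant_trajectory([1.0] * 5, t_span=(0.0, 50.0))
        ccg = CCGParameters(b=2, ba=1, cr=1, gr=1, ar=1, f=2, fa=1, d=0.3,
                            n1=1, n2=0, n3=0)
        with pytest.raises(ValueError, match="extend core"):
            simulate_ccg(ccg, core, all_tissues_model.params, duration=80.0)

    def test_fast_periodic_profile_matches_engine(self, core_trajectory,
                                                  all_tissues_model):
        # dual route: integrating-factor limit cycle vs DDE-engine burn-in
        from circaclock.estimation import CCGForcing, periodic_ccg_profile
        from circaclock.profiles import cycle_profile

        params = all_tissues_model.params
        ccg = CCGParameters(b=3.0, ba=1.0, cr=2.0, gr=1.5, ar=1.0, f=4.0,
                            fa=0.5, d=0.3, n1=1, n2=1, n3=1)
        ts = np.arange(core_trajectory.t0, core_trajectory.t_end, 0.01)
        prof = cycle_profile(ts, core_trajectory.evaluate(ts))
        forcing = CCGForcing.from_profile(prof, params)
        fast = periodic_ccg_profile(forcing, ccg)
        engine = simulate_ccg(ccg, core_trajectory, params, duration=110.0,
                              burn_in=80.0)
        anchor = prof.t[0] + max(params.delays)
        ts = np.linspace(engine.t0, engine.t_end - 0.5, 120)
        assert ts.size > 0 and engine.t_end > engine.t0
        phase = np.mod(ts - anchor, forcing.period)
        fast_at = np.interp(phase, forcing.grid, fast)
        np.testing.assert_allclose(fast_at, engine.evaluate(ts)[:, 0], rtol=5e-3)


class TestInvariants:
    def test_positivity_and_boundedness(self, core_grid, all_tissues_model):
        t, Y = core_grid
        assert np.all(Y > 0)
        p = all_tissues_model.params
        # production bounded by product of fold-change powers; Dbp's is b5^3
        caps = np.array([
            1.0, p.b2 ** 3 * p.f2, p.b3 ** 2 * p.f3, p.b4 ** 2 * p.f4,
            p.b5 ** 3,
        ])
        bound = caps / np.array(p.degradations)
        assert np.all(Y[t > 50.0] <= bound * 1.01)

    def test_period_drift_below_one_percent(self, core_grid):
        t, Y = core_grid
        post = t >= 240.0
        times, _ = find_peaks(t[post], Y[post][:, 0])
        intervals = np.diff(times)
        assert np.all(np.abs(np.diff(intervals)) / intervals[:-1] < 0.01)
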