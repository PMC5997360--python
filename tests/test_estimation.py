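"""Estimation: residual stacking, bounded fits, Wald CIs, CCG fits."""

import numpy as np
import pytest

from circaclock.estimation import (
    CORE_FREE,
    CCGForcing,
    FitResult,
    FitSpec,
    ccg_residuals,
    fit,
    fit_ccg,
    fit_consensus,
    periodic_ccg_profile,
    predicted_observed,
    residuals,
    wald_ci,
    PENALTY_RESIDUAL,
)
from circaclock.models import CCGParameters
from circaclock.synth import generate_ccg_timecourse, generate_timecourse

BURN, WINDOW = 120.0, 60.0


@pytest.fixture(scope="module")
def spec(all_tissues_model=None):
    from circaclock.models import load_tissue_parameters

    params = load_tissue_parameters("all_tissues").params
    return FitSpec(base=params, burn_in=BURN, window=WINDOW)


@pytest.fixture(scope="module")
def truth(spec):
    return np.array([getattr(spec.base, n) for n in CORE_FREE])


@pytest.fixture(scope="module")
def clean_data(spec):
    datasets, _ = generate_timecourse({"liver": spec.base}, noise_cv=0.0,
                                      seed=1, burn_in=BURN, window=WINDOW)
    return datasets


class TestResiduals:
    def test_noise_free_self_consistency(self, spec, truth, clean_data):
        r = residuals(np.append(truth, 0.0), clean_data, spec)
        assert r.size == 5 * 18 * 3
        assert np.max(np.abs(r)) < 1e-3

    def test_single_perturbed_observation(self, spec, truth, clean_data):
        import copy

        datasets = copy.deepcopy(clean_data)
        datasets[2].values[7, 1] += 0.5
        r = residuals(np.append(truth, 0.0), datasets, spec)
        hits = np.where(np.abs(r) > 1e-6)[0]
        assert hits.size == 1
        assert r[hits[0]] == pytest.approx(-0.5, abs=1e-6)

    def test_stacking_matches_independent_oracle(self, spec, truth):
        # independent re-implementation of the stacking order
        datasets, _ = generate_timecourse(
            {"a": spec.base, "b": spec.base}, noise_cv=0.10, seed=3,
            burn_in=BURN, window=WINDOW)
        x = np.append(truth, 0.0)
        r = residuals(x, datasets, spec)

        from circaclock.fastsim import simulate_grid
        from circaclock.models import GENE_INDEX
        from circaclock.profiles import cycle_profile

        t, Y = simulate_grid(spec.base, BURN + WINDOW, dt=spec.dt)
        prof = cycle_profile(t[t >= BURN], Y[t >= BURN])
        parts = []
        for ds in datasets:
            model = prof.sample(GENE_INDEX[ds.gene], ds.times, offset=0.0)
            for k in range(ds.times.size):
                for rep in range(ds.n_replicates):
                    parts.append(model[k] - ds.values[k, rep])
        oracle = np.array(parts)
        assert abs(float(r @ r) - float(oracle @ oracle)) < 1e-12

    def test_non_oscillatory_params_penalty(self, spec, clean_data):
        from test_models import saturating

        flat_spec = FitSpec(base=saturating(spec.base), burn_in=BURN,
                            window=WINDOW)
        x = np.append([4.0] * 5 + [0.5] * 5, 0.0)
        r = residuals(x, clean_data, flat_spec)
        assert np.all(np.isfinite(r))
        assert np.all(r == PENALTY_RESIDUAL)


class TestFit:
    def test_noise_free_truth_start(self, spec, truth, clean_data):
        res = fit(clean_data, spec, start=truth, max_nfev=50)
        assert res.objective < 1e-6
        np.testing.assert_allclose(res.estimates, truth, rtol=1e-3)
        assert res.converged

    def test_bounds_respected(self, spec, truth, clean_data):
        res = fit(clean_data, spec, start=truth, max_nfev=30)
        assert np.all(res.estimates >= res.bounds_lo)
        assert np.all(res.estimates <= res.bounds_hi)

    def test_objective_trace_non_increasing_overall(self, spec, truth):
        datasets, _ = generate_timecourse({"x": spec.base}, noise_cv=0.10,
                                          seed=17, burn_in=BURN, window=WINDOW)
        res = fit(datasets, spec, start=truth * 1.15, max_nfev=40)
        assert res.trace[0] >= res.objective
        # trace includes finite-difference probe points, which may dip
        # marginally below the accepted optimum
        assert res.objective <= min(res.trace) * (1.0 + 1e-5)

    def test_noisy_delay_recovery(self, spec, truth):
        datasets, _ = generate_timecourse(
            {t: spec.base for t in ("a", "b", "c", "d")}, noise_cv=0.10,
            seed=7, burn_in=240.0)
        res = fit(datasets, spec, start=truth * 1.2, max_nfev=120)
        est = res.as_dict()
        for name in ("tau_Per2", "tau_Cry1"):
            tv = getattr(spec.base, name)
            assert abs(est[name] - tv) / tv < 0.20


class TestConsensus:
    def test_identical_tissues_match_single_fit(self, spec, truth, clean_data):
        doubled = []
        for ds in clean_data:
            doubled.append(ds)
            import dataclasses

            doubled.append(dataclasses.replace(ds, tissue="copy"))
        single = fit(clean_data, spec, start=truth * 1.05, max_nfev=40)
        joint = fit_consensus(doubled, spec, start=truth * 1.05, max_nfev=40)
        np.testing.assert_allclose(joint.estimates, single.estimates, rtol=1e-4)

    def test_consensus_objective_at_least_sum_of_per_tissue(self, spec, truth):
        pa = spec.base
        pb = spec.base.replace(tau_Per2=pa.tau_Per2 * 1.2,
                               d_Cry1=pa.d_Cry1 * 0.8)
        datasets, _ = generate_timecourse({"a": pa, "b": pb}, noise_cv=0.05,
                                          seed=23, burn_in=BURN, window=WINDOW)
        a_sets = [d for d in datasets if d.tissue == "a"]
        b_sets = [d for d in datasets if d.tissue == "b"]
        fa = fit(a_sets, spec, start=truth, max_nfev=60)
        fb = fit(b_sets, spec, start=truth, max_nfev=60)
        fj = fit_consensus(datasets, spec, start=truth, max_nfev=60)
        assert fj.objective >= fa.objective + fb.objective - 1e-6


class TestWaldCI:
    def test_zero_residuals_zero_width(self):
        res = FitResult(
            names=("p",), estimates=np.array([2.0]),
            bounds_lo=np.array([0.0]), bounds_hi=np.array([10.0]),
            residual=np.zeros(5), jacobian=np.ones((5, 1)), df=4,
            sigma2=0.0, ci=np.zeros((1, 2)), objective=0.0)
        ci = wald_ci(res)
        np.testing.assert_allclose(ci, [[2.0, 2.0]])

    def test_two_point_regression_oracle(self):
        # y = p*x with x=(1,2), y=(2,4.3): closed-form simple regression
        x = np.array([1.0, 2.0])
        y = np.array([2.0, 4.3])
        p_hat = float(x @ y / (x @ x))
        r = p_hat * x - y
        res = FitResult(
            names=("p",), estimates=np.array([p_hat]),
            bounds_lo=np.array([0.0]), bounds_hi=np.array([10.0]),
            residual=r, jacobian=x[:, None], df=1,
            sigma2=float(r @ r), ci=np.zeros((1, 2)),
            objective=float(r @ r))
        ci = wald_ci(res)
        from scipy.stats import t as student_t

        ssr = float(r @ r)
        half_oracle = student_t.ppf(0.975, 1) * np.sqrt(ssr / 1 / (x @ x))
        assert p_hat == pytest.approx(2.12)
        assert ssr == pytest.approx(0.018)
        assert half_oracle == pytest.approx(12.7062 * 0.06, abs=1e-3)
        np.testing.assert_allclose(ci, [[p_hat - half_oracle,
                                         p_hat + half_oracle]], atol=1e-10)

    def test_literal_sigma_mode_differs(self):
        x = np.array([1.0, 2.0])
        y = np.array([2.0, 4.3])
        p_hat = float(x @ y / (x @ x))
        r = p_hat * x - y
        res = FitResult(
            names=("p",), estimates=np.array([p_hat]),
            bounds_lo=np.array([0.0]), bounds_hi=np.array([10.0]),
            residual=r, jacobian=x[:, None], df=1, sigma2=0.0,
            ci=np.zeros((1, 2)), objective=float(r @ r))
        std = wald_ci(res, sigma_mode="standard")
        lit = wald_ci(res, sigma_mode="literal")
        # literal mode uses ||r||/df (unsquared): wider here since ||r|| > ||r||^2
        assert lit[0, 1] - lit[0, 0] > std[0, 1] - std[0, 0]

    def test_singular_jacobian_flagged(self):
        res = FitResult(
            names=("a", "b"), estimates=np.array([1.0, 1.0]),
            bounds_lo=np.zeros(2), bounds_hi=np.full(2, 10.0),
            residual=np.array([0.1, -0.1, 0.05]),
            jacobian=np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]),
            df=1, sigma2=0.0, ci=np.zeros((2, 2)), objective=0.0)
        with pytest.warns(RuntimeWarning, match="pseudo-inverse"):
            ci = wald_ci(res)
        assert res.non_identifiable
        assert np.all(np.isfinite(ci))

    def test_ci_contains_estimate(self, spec, truth):
        datasets, _ = generate_timecourse({"x": spec.base}, noise_cv=0.10,
                                          seed=29, burn_in=BURN, window=WINDOW)
        res = fit(datasets, spec, start=truth, max_nfev=60)
        assert np.all(res.ci[:, 0] <= res.estimates)
        assert np.all(res.ci[:, 1] >= res.estimates)
        assert res.df == res.residual.size - 11  # 10 params + offset


@pytest.fixture(scope="module")
def forcing(spec):
    return CCGForcing.from_params(spec.base, burn_in=BURN, window=WINDOW)


class TestCCGFit:
    def make_truth(self):
        return CCGParameters(b=3.5, ba=0.8, cr=1.6, gr=1.2, ar=0.9, f=5.0,
                             fa=0.7, d=0.35, n1=2, n2=1, n3=1)

    def test_noise_free_recovery_from_truth(self, spec, forcing):
        ccg = self.make_truth()
        datasets, _ = generate_ccg_timecourse(
            spec.base, {"a": {"gene1": ccg}}, noise_cv=0.0, seed=1,
            burn_in=BURN, window=WINDOW)
        start = np.array([ccg.b, ccg.ba, ccg.cr, ccg.gr, ccg.ar, ccg.f,
                          ccg.fa, ccg.d])
        results = fit_ccg({"a": datasets}, forcing, (2, 1, 1), start=start,
                          max_nfev=60)
        res = results["a"]
        assert res.objective < 1e-4
        est = res.as_dict()
        assert est["d"] == pytest.approx(ccg.d, rel=1e-2)

    def test_predicted_vs_observed_r2(self, spec, forcing):
        ccg = self.make_truth()
        datasets, _ = generate_ccg_timecourse(
            spec.base, {"a": {"gene1": ccg}}, noise_cv=0.10, seed=6,
            burn_in=BURN, window=WINDOW)
        results = fit_ccg({"a": datasets}, forcing, (2, 1, 1), seed=2,
                          n_starts=3, max_nfev=80)
        pv = predicted_observed(results["a"], forcing, (2, 1, 1), datasets)
        ss_res = np.sum((pv.observed - pv.predicted) ** 2)
        ss_tot = np.sum((pv.observed - pv.observed.mean()) ** 2)
        assert 1.0 - ss_res / ss_tot > 0.8

    def test_all_counts_zero_flags_flat(self, spec, forcing):
        datasets, _ = generate_ccg_timecourse(
            spec.base, {"a": {"gene1": self.make_truth()}}, noise_cv=0.05,
            seed=4, burn_in=BURN, window=WINDOW)
        results = fit_ccg({"a": datasets}, forcing, (0, 0, 0), seed=0,
                          n_starts=2, max_nfev=30)
        res = results["a"]
        assert "structurally flat" in res.message
        assert res.names == ("d",)
        # best structurally-flat profile is the constant 1 (normalized 1/d)
        prof = periodic_ccg_profile(
            forcing, CCGParameters(b=2, ba=1, cr=1, gr=1, ar=1, f=2, fa=1,
                                   d=float(res.estimates[0]), n1=0, n2=0, n3=0))
        np.testing.assert_allclose(prof / prof.mean(), 1.0, rtol=1e-9)

    def test_periodic_profile_zero_counts_closed_form(self, forcing):
        ccg = CCGParameters(b=2, ba=1, cr=1, gr=1, ar=1, f=2, fa=1, d=0.5,
                            n1=0, n2=0, n3=0)
        prof = periodic_ccg_profile(forcing, ccg)
        np.testing.assert_allclose(prof, 2.0, rtol=1e-4)

    def test_residual_penalty_on_invalid(self, forcing, spec):
        datasets, _ = generate_ccg_timecourse(
            spec.base, {"a": {"g": self.make_truth()}}, noise_cv=0.0, seed=1,
            burn_in=BURN, window=WINDOW)
        r = ccg_residuals(np.array([-1.0]), ("d",),
                          CCGParameters(b=2, ba=1, cr=1, gr=1, ar=1, f=2,
                                        fa=1, d=0.3, n1=0, n2=0, n3=0),
                          forcing, datasets)
        assert np.all(r == PENALTY_RESIDUAL)
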