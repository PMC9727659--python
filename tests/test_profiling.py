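"""Profile likelihoods, mesh construction, thresholds and confidence intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import biphasefit as bf
from biphasefit.inference import SIGMA
from biphasefit.models import GrowthModel
from biphasefit.profiling import ProfileResult


class TestThresholds:
    @pytest.mark.parametrize(
        "level, expected",
        [(0.95, -1.92), (0.99, -3.32), (0.999, -5.41)],
    )
    def test_chi_squared_thresholds(self, level, expected):
        assert round(bf.loglik_threshold(level), 2) == expected

    def test_invalid_inputs(self):
        for bad in (0.0, 1.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                bf.loglik_threshold(bad)
        with pytest.raises(ValueError):
            bf.loglik_threshold(0.95, df=0)


class TestBuildMesh:
    def test_small_example(self):
        mesh = bf.build_mesh(0.0, -4.0, 4.0, points_per_side=4)
        assert np.allclose(mesh.lower_side, [-1.0, -2.0, -3.0, -4.0])
        assert np.allclose(mesh.upper_side, [1.0, 2.0, 3.0, 4.0])
        assert np.allclose(mesh.sorted_values, np.arange(-4.0, 5.0))
        assert list(mesh)[0] == 0.0

    def test_default_has_81_distinct_values(self):
        mesh = bf.build_mesh(1.3, 0.0, 10.0)
        values = mesh.sorted_values
        assert values.size == 81
        assert np.unique(values).size == 81
        assert values[0] == 0.0 and values[-1] == 10.0

    def test_mle_at_bound_degenerates_one_side(self):
        mesh = bf.build_mesh(0.0, 0.0, 5.0, points_per_side=5)
        assert mesh.degenerate_lower and not mesh.degenerate_upper
        assert mesh.lower_side.size == 0
        assert mesh.sorted_values[0] == 0.0

    def test_mle_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            bf.build_mesh(11.0, 0.0, 10.0)
        with pytest.raises(ValueError):
            bf.build_mesh(5.0, 0.0, 10.0, points_per_side=1)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        lo=st.floats(-100, 0),
        width=st.floats(0.1, 100),
        frac=st.floats(0.01, 0.99),
        pps=st.integers(2, 60),
    )
    def test_uniform_spacing_property(self, lo, width, frac, pps):
        hi = lo + width
        mle = lo + frac * width
        mesh = bf.build_mesh(mle, lo, hi, points_per_side=pps)
        assert mesh.lower_side.size == pps and mesh.upper_side.size == pps
        assert np.allclose(np.diff(mesh.lower_side), (lo - mle) / pps)
        assert np.allclose(np.diff(mesh.upper_side), (hi - mle) / pps)
        assert mesh.lower_side[-1] == lo and mesh.upper_side[-1] == hi


_SIGMA0 = 1.5


@pytest.fixture(scope="module")
def fit_and_profile(constant_model, gaussian_data):
    fit = bf.fit_mle(
        constant_model,
        gaussian_data,
        start={"C0": 8.0},
        bounds={"C0": (5.0, 15.0)},
        fixed={SIGMA: _SIGMA0},
        solver="closed_form",
    )
    prof = bf.profile_parameter(
        constant_model,
        gaussian_data,
        fit,
        "C0",
        bounds={"C0": (5.0, 15.0)},
        fixed={SIGMA: _SIGMA0},
        solver="closed_form",
    )
    return fit, prof


class TestGaussianMeanOracle:
    """Flat model with known sigma: the profile of C0 is exactly quadratic."""

    sigma0 = _SIGMA0

    def test_mle_is_sample_mean(self, fit_and_profile, gaussian_data):
        fit, _ = fit_and_profile
        assert fit.mle["C0"] == pytest.approx(gaussian_data.observations.mean(), abs=1e-6)

    def test_profile_matches_closed_form(self, fit_and_profile, gaussian_data):
        _, prof = fit_and_profile
        ybar = gaussian_data.observations.mean()
        I = len(gaussian_data)
        expected = -I * (prof.mesh - ybar) ** 2 / (2.0 * self.sigma0**2)
        assert np.allclose(prof.profile_values, expected, atol=1e-6)

    def test_interval_matches_normal_theory(self, fit_and_profile, gaussian_data):
        _, prof = fit_and_profile
        ybar = gaussian_data.observations.mean()
        I = len(gaussian_data)
        half = 1.96 * self.sigma0 / np.sqrt(I)
        ci = prof.intervals[0.95]
        spacing = np.diff(prof.mesh).max()
        assert ci.lower == pytest.approx(ybar - half, abs=spacing)
        assert ci.upper == pytest.approx(ybar + half, abs=spacing)

    def test_zero_at_mle_point(self, fit_and_profile):
        _, prof = fit_and_profile
        assert prof.profile_values[prof.mle_index] == 0.0
        assert np.nanmax(prof.profile_values) <= 1e-6


class TestProfileAgainstGridSearch:
    def test_profile_beats_coarse_nuisance_grid(self):
        """At each mesh point the warm-started optimum must dominate a 20^3
        brute-force grid over the three nuisances (C0, r, sigma)."""
        model = bf.get_model("delayed_normalized_logistic")
        spec = bf.case_study_fixture("proliferation")
        data = bf.generate_synthetic(model, spec.params, spec.times[::4], spec.sigma, 8)
        bounds = spec.bounds
        fit = bf.fit_mle(
            model, data, start=spec.full_params, bounds=bounds, solver="closed_form"
        )
        prof = bf.profile_parameter(
            model, data, fit, "T",
            bounds=bounds, points_per_side=4, solver="closed_form",
        )
        c0s = np.linspace(*bounds["C0"], 20)
        rs = np.linspace(*bounds["r"], 20)
        sigmas = np.linspace(*bounds[SIGMA], 20)
        for psi, value in zip(prof.mesh, prof.profile_values):
            best = -np.inf
            for c0 in c0s:
                for r in rs:
                    for s in sigmas:
                        p = {"T": psi, "C0": c0, "r": r, SIGMA: s}
                        ll = bf.log_likelihood(p, data, model, solver="closed_form")
                        best = max(best, ll - fit.max_loglik)
            assert value >= best - 1e-4

    def test_profile_matches_fine_grid_on_two_parameter_model(
        self, constant_model, gaussian_data
    ):
        """Flat model with unknown sigma: exhaustive sigma maximization is the
        oracle for the C0 profile."""
        bounds = {"C0": (5.0, 15.0), SIGMA: (0.3, 6.0)}
        fit = bf.fit_mle(
            constant_model,
            gaussian_data,
            start={"C0": 9.0, SIGMA: 1.0},
            bounds=bounds,
            solver="closed_form",
        )
        prof = bf.profile_parameter(
            constant_model, gaussian_data, fit, "C0",
            bounds=bounds, points_per_side=10, solver="closed_form",
        )
        y = gaussian_data.observations
        sig_grid = np.linspace(0.3, 6.0, 4001)
        for psi, value in zip(prof.mesh, prof.profile_values):
            lls = [
                bf.log_likelihood(
                    {"C0": psi, SIGMA: s}, gaussian_data, constant_model,
                    solver="closed_form",
                )
                for s in sig_grid
            ]
            assert value == pytest.approx(max(lls) - fit.max_loglik, abs=1e-3)


class TestReparametrizationInvariance:
    def test_affine_reparametrization_preserves_profile(self, coral_data, coral_spec):
        """Profiling q = 2K + 1 must reproduce the K profile at the
        back-transformed mesh (parametrization invariance of the likelihood)."""
        base = bf.get_model("delayed_logistic")

        def q_to_K(q):
            return (q - 1.0) / 2.0

        reparam = GrowthModel(
            "delayed_logistic_reparam",
            phase1_rate=lambda C, p: 0.0,
            phase2_rate=lambda C, p: p["r"] * C * (1.0 - C / q_to_K(p["Kq"])),
            param_names=("T", "C0", "r", "Kq"),
            closed_form=lambda p, t: base.closed_form(
                {**p, "K": q_to_K(p["Kq"])}, t
            ),
        )
        bounds = dict(coral_spec.bounds)
        kb = bounds.pop("K")
        bounds_q = {**bounds, "Kq": (2 * kb[0] + 1, 2 * kb[1] + 1)}
        start_q = {k: v for k, v in coral_spec.full_params.items() if k != "K"}
        start_q["Kq"] = 2 * coral_spec.params["K"] + 1

        fit_K = bf.fit_mle(
            base, coral_data, start=coral_spec.full_params,
            bounds=coral_spec.bounds, solver="closed_form",
        )
        fit_q = bf.fit_mle(
            reparam, coral_data, start=start_q, bounds=bounds_q, solver="closed_form"
        )
        assert fit_q.max_loglik == pytest.approx(fit_K.max_loglik, abs=1e-5)

        prof_K = bf.profile_parameter(
            base, coral_data, fit_K, "K",
            bounds=coral_spec.bounds, points_per_side=8, solver="closed_form",
        )
        prof_q = bf.profile_parameter(
            reparam, coral_data, fit_q, "Kq",
            bounds=bounds_q, points_per_side=8, solver="closed_form",
        )
        # affine bounds + affine MLE -> the meshes correspond point by point
        assert np.allclose(q_to_K(prof_q.mesh), prof_K.mesh, atol=1e-4)
        assert np.allclose(prof_q.profile_values, prof_K.profile_values, atol=2e-3)


class TestCoralProfiles:
    def test_normalized_and_bounded(self, coral_profiles):
        for prof in coral_profiles.values():
            assert np.nanmax(prof.profile_values) <= 1e-6
            assert prof.profile_values[prof.mle_index] == 0.0
            assert prof.n_failed == 0

    def test_intervals_nest(self, coral_profiles):
        for prof in coral_profiles.values():
            ci95, ci99, ci999 = (prof.intervals[l] for l in (0.95, 0.99, 0.999))
            assert ci99.lower <= ci95.lower <= ci95.upper <= ci99.upper
            assert ci999.lower <= ci99.lower <= ci99.upper <= ci999.upper

    def test_generating_values_inside_999_intervals(self, coral_profiles, coral_spec):
        # single-replicate smoke check; expected to hold in a typical run
        truth = coral_spec.full_params
        for name, prof in coral_profiles.items():
            ci = prof.intervals[0.999]
            assert ci.lower <= truth[name] <= ci.upper

    def test_concentrated_profile_matches_full_optimization(
        self, coral_model, coral_data, coral_fit, coral_spec, coral_profiles
    ):
        full = bf.profile_parameter(
            coral_model, coral_data, coral_fit, "K",
            bounds=coral_spec.bounds, points_per_side=20,
            solver="closed_form", concentrate_sigma=False,
        )
        conc = coral_profiles["K"]
        assert np.allclose(full.profile_values, conc.profile_values, atol=2e-3)


def _toy_profile(mesh, values, mle_index, intervals=None):
    mesh = np.asarray(mesh, float)
    return ProfileResult(
        interest_name="x",
        mesh=mesh,
        profile_values=np.asarray(values, float),
        nuisance_names=(),
        nuisance_optima=np.empty((mesh.size, 0)),
        mle_value=float(mesh[mle_index]),
        mle_index=mle_index,
        intervals=intervals or {},
    )


class TestConfidenceIntervalExtraction:
    def test_flat_side_hits_bound_and_flags(self):
        # flat profile at 0 on the left (change point indistinguishable from 0)
        mesh = np.linspace(0.0, 10.0, 21)
        values = np.where(mesh <= 5.0, 0.0, -0.5 * (mesh - 5.0) ** 2)
        prof = _toy_profile(mesh, values, mle_index=10)
        ci = bf.confidence_interval(prof, 0.95)
        assert ci.lower == 0.0 and ci.lower_at_bound
        assert not ci.upper_at_bound
        assert 5.0 < ci.upper < 10.0

    def test_interpolated_crossing_of_quadratic(self):
        mesh = np.linspace(-4.0, 4.0, 81)
        prof = _toy_profile(mesh, -0.5 * mesh**2, mle_index=40)
        ci = bf.confidence_interval(prof, 0.95)
        assert ci.lower == pytest.approx(-1.96, abs=0.01)
        assert ci.upper == pytest.approx(1.96, abs=0.01)
        assert not (ci.lower_at_bound or ci.upper_at_bound or ci.multimodal)

    def test_multimodal_outermost_crossings_reported(self):
        mesh = np.linspace(-10.0, 10.0, 201)
        bump = lambda c: -4.0 * (1 - np.exp(-((mesh - c) ** 2)))
        values = np.maximum(bump(0.0), bump(6.0))
        values -= values.max()
        prof = _toy_profile(mesh, values, mle_index=int(np.argmax(values)))
        ci = bf.confidence_interval(prof, 0.95)
        assert ci.multimodal
        assert ci.upper > 6.0  # outermost crossing, beyond the secondary mode

    def test_nan_gaps_are_skipped(self):
        mesh = np.linspace(-4.0, 4.0, 41)
        values = -0.5 * mesh**2
        values[5] = np.nan
        values[30] = np.nan
        prof = _toy_profile(mesh, values, mle_index=20)
        ci = bf.confidence_interval(prof, 0.95)
        assert -2.2 < ci.lower < -1.7 and 1.7 < ci.upper < 2.2

    def test_failure_rate_above_20_percent_errors(
        self, coral_model, coral_data, coral_fit, coral_spec, monkeypatch
    ):
        import biphasefit.profiling as profiling

        def always_fail(*args, **kwargs):
            raise RuntimeError("synthetic optimizer failure")

        monkeypatch.setattr(profiling, "_nelder_mead", always_fail)
        with pytest.raises(RuntimeError, match="failed"):
            bf.profile_parameter(
                coral_model, coral_data, coral_fit, "K",
                bounds=coral_spec.bounds, points_per_side=5, solver="closed_form",
            )

    def test_unknown_interest_parameter_rejected(
        self, coral_model, coral_data, coral_fit
    ):
        with pytest.raises(ValueError, match="interest"):
            bf.profile_parameter(coral_model, coral_data, coral_fit, "zeta")
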