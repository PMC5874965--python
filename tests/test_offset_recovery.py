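"""Applied-vs-detected analysis: linearity fits, verdicts, coupling."""

import numpy as np
import pytest

from tomospc import (
    DegenerateDesignError,
    EmptySelectionError,
    ExperimentSpec,
    OffsetTrial,
    cross_axis_matrix,
    fit_linearity,
    generate_experiment,
    recovery_analysis,
)

GRID = (-5.0, -2.0, -1.0, -0.5, 0.5, 1.0, 2.0, 5.0)


def ideal_trials(grid=GRID, replicates=3):
    out = []
    for axis_i, axis in enumerate(("IECX", "IECY", "IECZ")):
        for a in grid:
            detected = [0.0, 0.0, 0.0]
            detected[axis_i] = a
            out.extend(
                OffsetTrial(axis, a, tuple(detected), replicate=r)
                for r in range(1, replicates + 1)
            )
    return out


def normal_equations_fit(x, y):
    """Independent oracle: solve X'X b = X'y directly."""
    X = np.column_stack([np.ones_like(x), x])
    b = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ b
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    return b[1], b[0], r2


class TestFitLinearity:
    def test_exact_line(self):
        pairs = [(x, 2.0 * x + 1.0) for x in range(-5, 6)]
        fit = fit_linearity(pairs)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response_has_zero_r_squared(self):
        fit = fit_linearity([(x, 3.0) for x in range(5)])
        assert fit.slope == 0.0 and fit.r_squared == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(40):
            n = rng.integers(3, 12)
            x = rng.uniform(-5, 5, size=n)
            while len(np.unique(x)) < 3:
                x = rng.uniform(-5, 5, size=n)
            y = rng.uniform(-1, 1) * x + rng.normal(0, 0.5, size=n)
            fit = fit_linearity(zip(x, y))
            slope, intercept, r2 = normal_equations_fit(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)
            assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_degenerate_design_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_linearity([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])

    def test_phase_response_linearity_at_default_noise(self, default_experiment):
        trials, truth = default_experiment
        pairs = [
            (t.applied_mm, t.gantry_phase_deg) for t in trials if t.axis == "IECX"
        ]
        fit = fit_linearity(pairs)
        assert fit.slope == pytest.approx(truth["phase_slope_deg_per_mm"], abs=0.05)
        assert fit.r_squared >= 0.99


class TestRecoveryAnalysis:
    def test_ideal_detector_all_clear(self):
        verdicts = recovery_analysis(ideal_trials())
        assert len(verdicts) == 3
        for v in verdicts:
            assert v.max_abs_deviation_mm == 0.0
            assert v.within_action
            assert v.coupling_detected == []

    def test_injected_vertical_bias_recovered(self):
        # +1.19 mm detection bias at 5 mm applied, 25 replicates
        spec = ExperimentSpec(replicates=25, seed=17)
        trials, _ = generate_experiment(spec)
        verdict = {v.axis: v for v in recovery_analysis(trials)}["IECZ"]
        assert verdict.max_abs_deviation_mm == pytest.approx(1.19, abs=0.1)
        assert abs(verdict.worst_applied_mm) == 5.0
        assert verdict.within_action  # 1.19 < 2.0 tolerance

    def test_cobra_coupling_detected_from_z_into_y(self, default_experiment):
        trials, _ = default_experiment
        verdict = {v.axis: v for v in recovery_analysis(trials)}["IECZ"]
        pairs = [(c.source_axis, c.target_axis) for c in verdict.coupling_detected]
        assert ("IECZ", "IECY") in pairs
        mag = next(
            c.magnitude_mm for c in verdict.coupling_detected if c.target_axis == "IECY"
        )
        assert mag == pytest.approx(0.234 * 5, abs=0.15)

    def test_no_spurious_coupling_on_clean_axes(self, default_experiment):
        trials, _ = default_experiment
        verdicts = {v.axis: v for v in recovery_analysis(trials)}
        assert verdicts["IECX"].coupling_detected == []
        assert verdicts["IECY"].coupling_detected == []

    def test_sign_symmetric_deviations_for_unbiased_system(self):
        spec = ExperimentSpec(
            replicates=25, on_axis_bias_slope={"IECX": 0, "IECY": 0, "IECZ": 0}, seed=23
        )
        trials, _ = generate_experiment(spec)
        for v in recovery_analysis(trials):
            for a in (0.5, 1.0, 2.0, 5.0):
                plus = v.deviation_by_applied[a]
                minus = v.deviation_by_applied[-a]
                assert abs(abs(plus) - abs(minus)) <= 3 * 0.2

    def test_empty_trial_list_rejected(self):
        with pytest.raises(EmptySelectionError):
            recovery_analysis([])


class TestCrossAxisMatrix:
    def test_ideal_system_gives_identity(self):
        mat = cross_axis_matrix(ideal_trials())
        np.testing.assert_allclose(mat.to_numpy(), np.eye(3), atol=1e-12)

    def test_injected_x_to_y_coupling_slope_recovered(self):
        spec = ExperimentSpec(
            coupling=(("IECX", "IECY", 0.05),), replicates=10, seed=31,
            on_axis_bias_slope={"IECX": 0, "IECY": 0, "IECZ": 0},
        )
        trials, _ = generate_experiment(spec)
        mat = cross_axis_matrix(trials)
        assert mat.loc["IECX", "IECY"] == pytest.approx(0.05, abs=0.02)

    def test_bounded_off_axis_response_gives_small_x_row(self, default_experiment):
        trials, _ = default_experiment
        mat = cross_axis_matrix(trials)
        assert abs(mat.loc["IECX", "IECY"]) <= 0.06
        assert abs(mat.loc["IECX", "IECZ"]) <= 0.06

    def test_insufficient_span_rejected(self):
        trials = [
            OffsetTrial(axis, 1.0, (0, 0, 0), replicate=1)
            for axis in ("IECX", "IECY", "IECZ")
        ]
        with pytest.raises(DegenerateDesignError):
            cross_axis_matrix(trials)
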