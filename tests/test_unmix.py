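"""Mixture-model assembly, solving and diagnostics."""

import numpy as np
import pytest

from astamix.calibration import CalibrationCurve, SourceProfile
from astamix.channels import CHANNELS
from astamix.errors import ConfigurationError, IdentifiabilityError, InputError
from astamix.unmix import (
    PeakObservation,
    assemble_model,
    check_range,
    detect_sources,
    predict_channel_areas,
    recovery_rates,
    solve_concentrations,
    solve_per_replicate,
)
from conftest import random_full_rank_model


def cramer_solve_3x3(A, b):
    """Independent determinant-expansion oracle for a 3×3 solve."""

    def det3(M):
        return (
            M[0][0] * (M[1][1] * M[2][2] - M[1][2] * M[2][1])
            - M[0][1] * (M[1][0] * M[2][2] - M[1][2] * M[2][0])
            + M[0][2] * (M[1][0] * M[2][1] - M[1][1] * M[2][0])
        )

    A = [list(row) for row in A]
    d = det3(A)
    out = []
    for j in range(3):
        M = [row[:] for row in A]
        for m in range(3):
            M[m][j] = b[m]
        out.append(det3(M) / d)
    return out


def single_channel_profile(source="s", channel="3S,3'R", a=2.0, b=1.0):
    return SourceProfile(
        source,
        (CalibrationCurve(source, channel, a, b, 1.0, (0.0, 100.0)),),
    )


class TestAssemble:
    def test_reference_intercept_sums(self, ref_model):
        np.testing.assert_allclose(
            ref_model.intercept_vector, [-4.0403, -2.3492, -10.6925], atol=1e-12
        )

    def test_reference_dextro_channel_row(self, ref_model):
        np.testing.assert_allclose(
            ref_model.slope_matrix[2], [32.543, 0.0, 17.259], atol=0
        )

    def test_single_source_single_channel_layout(self):
        model = assemble_model([single_channel_profile()])
        np.testing.assert_array_equal(model.slope_matrix, [[0.0], [2.0], [0.0]])
        np.testing.assert_array_equal(model.intercept_vector, [0.0, 1.0, 0.0])

    def test_zero_entries_mark_missing_curves(self, ref_model):
        # yeast has no levo channel, alga no dextro channel
        assert ref_model.slope_matrix[0, 0] == 0.0
        assert ref_model.slope_matrix[2, 1] == 0.0

    def test_intercept_identity_against_curves(self, rng):
        profiles = []
        for j in range(3):
            curves = tuple(
                CalibrationCurve(
                    f"s{j}", CHANNELS[m], float(rng.uniform(1, 30)),
                    float(rng.uniform(-10, 10)), 1.0, (0.0, 100.0),
                )
                for m in range(3)
                if (j + m) % 2 == 0  # leave some (source, channel) pairs uncalibrated
            )
            profiles.append(SourceProfile(f"s{j}", curves))
        model = assemble_model(profiles)
        for m, chan in enumerate(CHANNELS):
            expected = sum(
                c.intercept_b for p in profiles for c in p.curves if c.channel_id == chan
            )
            assert model.intercept_vector[m] == expected  # exact, not approximate

    def test_duplicate_profiles_rejected(self):
        p = single_channel_profile()
        with pytest.raises(ConfigurationError):
            assemble_model([p, p])

    def test_empty_profile_list_rejected(self):
        with pytest.raises(ConfigurationError):
            assemble_model([])


class TestPredict:
    def test_zero_mixture_returns_intercept_sums(self, ref_model):
        areas = predict_channel_areas(ref_model, [0.0, 0.0, 0.0])
        np.testing.assert_allclose(
            [areas[c] for c in CHANNELS], ref_model.intercept_vector
        )

    def test_equal_concentration_dextro_total(self, ref_model):
        areas = predict_channel_areas(ref_model, [25.0, 25.0, 25.0])
        assert areas["3R,3'R"] == pytest.approx(1234.3575, abs=1e-9)

    def test_one_source_one_channel(self):
        model = assemble_model([single_channel_profile(a=2.0, b=1.0)])
        assert predict_channel_areas(model, [3.0])["3S,3'R"] == pytest.approx(7.0)

    def test_negative_concentration_rejected(self, ref_model):
        with pytest.raises(InputError):
            predict_channel_areas(ref_model, [-1.0, 0.0, 0.0])


class TestSolve:
    @pytest.mark.parametrize(
        "S,expected",
        [
            ((215.80, 272.68, 861.04), (24.15, 5.23, 4.96)),
            ((2429.42, 1825.07, 2179.89), (51.78, 74.55, 29.27)),
        ],
    )
    def test_reference_mixtures_match_published_solutions(self, ref_model, S, expected):
        obs = PeakObservation(channel_totals=dict(zip(CHANNELS, S)))
        res = solve_concentrations(ref_model, obs)
        for src, want in zip(ref_model.source_order, expected):
            assert res.concentrations[src] == pytest.approx(want, abs=0.2)

    def test_round_trip_is_identity(self, ref_model):
        x_true = dict(zip(ref_model.source_order, (12.0, 48.5, 73.25)))
        obs = PeakObservation(channel_totals=predict_channel_areas(ref_model, x_true))
        res = solve_concentrations(ref_model, obs)
        for src, want in x_true.items():
            assert res.concentrations[src] == pytest.approx(want, abs=1e-9)
        assert all(abs(r) < 1e-9 for r in res.residuals.values())

    def test_agrees_with_cramers_rule_oracle(self, rng):
        for _ in range(50):
            model = random_full_rank_model(rng)
            x = rng.uniform(0, 100, size=3)
            S = predict_channel_areas(model, x)
            res = solve_concentrations(
                model, PeakObservation(channel_totals=S)
            )
            oracle = cramer_solve_3x3(
                model.slope_matrix,
                [S[c] - k for c, k in zip(CHANNELS, model.intercept_vector)],
            )
            for src, want in zip(model.source_order, oracle):
                assert res.concentrations[src] == pytest.approx(
                    want, rel=1e-9, abs=1e-9
                )

    def test_permutation_equivariance(self, ref_model, ref_mixtures):
        from astamix import datasets

        profiles = datasets.reference_profiles()
        permuted = assemble_model([profiles[2], profiles[0], profiles[1]])
        obs = ref_mixtures[0].observation
        res1 = solve_concentrations(ref_model, obs)
        res2 = solve_concentrations(permuted, obs)
        for src in ref_model.source_order:
            assert res2.concentrations[src] == pytest.approx(
                res1.concentrations[src], abs=1e-9
            )

    def test_nnls_matches_exact_when_solution_nonnegative(self, ref_model, ref_mixtures):
        obs = ref_mixtures[1].observation
        exact = solve_concentrations(ref_model, obs, method="exact")
        nnls = solve_concentrations(ref_model, obs, method="nnls")
        for src in ref_model.source_order:
            assert nnls.concentrations[src] == pytest.approx(
                exact.concentrations[src], abs=1e-8
            )

    def test_nnls_clamps_infeasible_observation(self, ref_model):
        # a large levo area with empty meso/dextro channels is inconsistent
        # with any non-negative composition
        obs = PeakObservation(
            channel_totals={"3S,3'S": 1000.0, "3S,3'R": 0.0, "3R,3'R": 0.0}
        )
        exact = solve_concentrations(ref_model, obs, method="exact")
        assert exact.negative_sources  # flagged, not clamped
        nnls = solve_concentrations(ref_model, obs, method="nnls")
        assert all(v >= 0 for v in nnls.concentrations.values())

    def test_underdetermined_two_source_solve(self):
        p1 = single_channel_profile("a", "3S,3'S", 2.0, 0.0)
        p2 = single_channel_profile("b", "3R,3'R", 4.0, 0.0)
        model = assemble_model([p1, p2])
        obs = PeakObservation(channel_totals={"3S,3'S": 20.0, "3S,3'R": 0.0, "3R,3'R": 40.0})
        res = solve_concentrations(model, obs)
        assert res.concentrations["a"] == pytest.approx(10.0)
        assert res.concentrations["b"] == pytest.approx(10.0)

    def test_rank_deficiency_names_colinear_sources(self):
        c1 = single_channel_profile("dup1", "3S,3'R", 2.0, 0.0)
        c2 = single_channel_profile("dup2", "3S,3'R", 4.0, 0.0)
        model = assemble_model([c1, c2])
        obs = PeakObservation(channel_totals={c: 1.0 for c in CHANNELS})
        with pytest.raises(IdentifiabilityError) as err:
            solve_concentrations(model, obs)
        assert set(err.value.colinear_sources) == {"dup1", "dup2"}

    def test_more_than_three_sources_rejected(self):
        profiles = [
            single_channel_profile(f"s{i}", CHANNELS[i % 3], 1.0 + i, 0.0)
            for i in range(4)
        ]
        model = assemble_model(profiles)
        obs = PeakObservation(channel_totals={c: 1.0 for c in CHANNELS})
        with pytest.raises(InputError, match="at most 3 sources"):
            solve_concentrations(model, obs)

    def test_sensitivity_bounded_by_condition_number(self, rng, ref_model):
        x = rng.uniform(10, 90, size=3)
        S = predict_channel_areas(ref_model, x)
        base = solve_concentrations(ref_model, PeakObservation(channel_totals=S))
        delta = rng.normal(0, 1.0, size=3)
        S_pert = {c: S[c] + d for c, d in zip(CHANNELS, delta)}
        pert = solve_concentrations(ref_model, PeakObservation(channel_totals=S_pert))
        dx = np.array(
            [pert.concentrations[s] - base.concentrations[s] for s in ref_model.source_order]
        )
        x_vec = np.array([base.concentrations[s] for s in ref_model.source_order])
        S_vec = np.array([S[c] for c in CHANNELS])
        k = ref_model.intercept_vector
        rel_dx = np.linalg.norm(dx) / np.linalg.norm(x_vec)
        rel_db = np.linalg.norm(delta) / np.linalg.norm(S_vec - k)
        assert rel_dx <= base.condition_number * rel_db * (1 + 1e-9)


class TestReplicates:
    def test_mean_area_solve_close_to_replicate_mean_solve(self, ref_model):
        reps = [
            {"3S,3'S": 1080.0, "3S,3'R": 1185.0, "3R,3'R": 1205.0},
            {"3S,3'S": 1089.6, "3S,3'R": 1194.2, "3R,3'R": 1217.1},
        ]
        obs = PeakObservation.from_replicates(reps)
        mean_conc, sd, results = solve_per_replicate(ref_model, obs)
        on_mean = solve_concentrations(ref_model, obs)
        assert len(results) == 2 and sd is not None
        for src in ref_model.source_order:
            # linear model: solving mean areas == averaging per-replicate solves
            assert mean_conc[src] == pytest.approx(
                on_mean.concentrations[src], abs=1e-9
            )

    def test_replicate_aggregation_stats(self):
        reps = [{"3S,3'S": 10.0}, {"3S,3'S": 14.0}]
        obs = PeakObservation.from_replicates(reps)
        assert obs.channel_totals["3S,3'S"] == pytest.approx(12.0)
        assert obs.sd["3S,3'S"] == pytest.approx(np.std([10, 14], ddof=1))


class TestDiagnostics:
    def test_recovery_rates_reference_values(self):
        from astamix.unmix import UnmixResult

        res = UnmixResult(
            concentrations={"a": 24.15, "b": 5.23, "c": 4.96},
            residuals={}, presence={}, condition_number=1.0, method="exact",
        )
        rep = recovery_rates(res, {"a": 25.0, "b": 5.0, "c": 5.0})
        assert rep.recovery_pct["a"] == pytest.approx(96.6, abs=0.01)
        assert rep.max_deviation == pytest.approx(0.85, abs=1e-9)

    def test_recovery_at_truth_is_100(self):
        from astamix.unmix import UnmixResult

        res = UnmixResult(
            concentrations={"a": 51.78}, residuals={}, presence={},
            condition_number=1.0, method="exact",
        )
        rep = recovery_rates(res, {"a": 50.0})
        assert rep.recovery_pct["a"] == pytest.approx(103.56, abs=0.01)
        exact = recovery_rates(res, {"a": 51.78})
        assert exact.recovery_pct["a"] == pytest.approx(100.0)
        assert exact.max_deviation == 0.0

    def test_zero_actual_flags_undefined_recovery(self):
        from astamix.unmix import UnmixResult

        res = UnmixResult(
            concentrations={"a": 3.0}, residuals={}, presence={},
            condition_number=1.0, method="exact",
        )
        rep = recovery_rates(res, {"a": 0.0})
        assert rep.recovery_pct["a"] is None
        assert rep.undefined_sources == ("a",)

    @pytest.mark.parametrize(
        "conc,expected",
        [
            ({"a": 24.15, "b": 5.23, "c": 4.96}, {"a": True, "b": True, "c": False}),
            ({"a": 0.0, "b": 0.0, "c": 0.0}, {"a": False, "b": False, "c": False}),
            ({"a": 25.0, "b": 25.0, "c": 25.0}, {"a": True, "b": True, "c": True}),
        ],
    )
    def test_presence_threshold_rule(self, conc, expected):
        from astamix.unmix import UnmixResult

        res = UnmixResult(
            concentrations=conc, residuals={}, presence={},
            condition_number=1.0, method="exact",
        )
        assert detect_sources(res, threshold=5.0) == expected

    def test_range_flags(self):
        from astamix.unmix import UnmixResult

        res = UnmixResult(
            concentrations={"a": 105.52, "b": 25.0, "c": -0.4},
            residuals={}, presence={}, condition_number=1.0, method="exact",
            negative_sources=("c",),
        )
        flags = check_range(res)
        kinds = {(f.source_id, f.kind) for f in flags}
        assert ("a", "above") in kinds
        assert ("c", "negative") in kinds and ("c", "below") in kinds
        assert not any(f.source_id == "b" for f in flags)
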