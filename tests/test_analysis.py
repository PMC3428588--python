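"""Behavior profiles: probabilities, Eq-style z-scores, ranking, export."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from brainbehavior import (
    FociTable,
    FocusRecord,
    ROIMask,
    analyze,
    assemble_pdf4d,
    effect_z,
    expected_probability,
    export_profile,
    observed_probability,
    read_profile,
)
from brainbehavior.analysis import plot_profile


class TestEffectZ:
    def test_zero_effect_gives_zero(self):
        assert effect_z(0.3, 0.3, 17) == 0.0

    def test_whole_brain_degenerate_case(self):
        assert effect_z(1.0, 1.0, 1000) == 0.0
        assert effect_z(0.0, 0.0, 5) == 0.0

    def test_zero_variance_nonzero_effect_is_infinite(self):
        assert effect_z(1.0, 0.0, 10) == math.inf
        assert effect_z(0.0, 1.0, 10) == -math.inf

    def test_undefined_for_zero_trials(self):
        assert math.isnan(effect_z(0.2, 0.1, 0))

    def test_against_high_precision_arithmetic(self):
        # recompute with exact rationals: p_o=0.2, p_e=0.05, N=1000
        p_o, p_e, n = Fraction(1, 5), Fraction(1, 20), 1000
        var = (p_o * (1 - p_o) + p_e * (1 - p_e)) / n
        expected = float(p_o - p_e) / math.sqrt(float(var))
        assert abs(expected - 10.41) <= 0.01  # sanity on the frozen value
        assert abs(effect_z(0.2, 0.05, 1000) - expected) < 1e-12

    def test_rejects_invalid_probability(self):
        with pytest.raises(ValueError):
            effect_z(1.2, 0.1, 10)

    @given(
        st.floats(0.0, 1.0),
        st.floats(0.0, 1.0),
        st.integers(1, 10 ** 6),
    )
    def test_sign_follows_effect(self, p_o, p_e, n):
        z = effect_z(p_o, p_e, n)
        if p_o > p_e:
            assert z > 0
        elif p_o < p_e:
            assert z < 0
        else:
            assert z == 0


def _toy_pdf(toy_grid, foci_by_sid):
    t = FociTable()
    for sid, coords in foci_by_sid.items():
        for c in coords:
            t.append(FocusRecord("e", sid, *map(float, c)))
    return assemble_pdf4d(t, toy_grid)


class TestProbabilities:
    def test_whole_grid_roi_reaches_unity(self, toy_grid):
        pdf = _toy_pdf(toy_grid, {1: [toy_grid.voxel_to_coord([i, i, i]) for i in range(5)]})
        roi = ROIMask(toy_grid, np.ones(toy_grid.shape, dtype=bool))
        assert observed_probability(pdf, roi, 1) == 1.0

    def test_empty_roi_is_zero(self, toy_grid):
        pdf = _toy_pdf(toy_grid, {1: [toy_grid.voxel_to_coord([0, 0, 0])]})
        roi = ROIMask(toy_grid, np.zeros(toy_grid.shape, dtype=bool))
        assert observed_probability(pdf, roi, 1) == 0.0

    def test_single_voxel_roi_counts_exactly(self, toy_grid):
        c = toy_grid.voxel_to_coord([2, 2, 2])
        other = toy_grid.voxel_to_coord([0, 0, 0])
        pdf = _toy_pdf(toy_grid, {1: [c, c, c, other, other]})
        roi = np.zeros(toy_grid.shape, dtype=bool)
        roi[2, 2, 2] = True
        assert observed_probability(pdf, ROIMask(toy_grid, roi), 1) == 3 / 5

    def test_grid_mismatch_instructs_resample(self, toy_grid):
        from brainbehavior import GridSpec

        pdf = _toy_pdf(toy_grid, {1: [toy_grid.voxel_to_coord([0, 0, 0])]})
        other = GridSpec(1.0, toy_grid.origin, toy_grid.shape)
        roi = ROIMask(other, np.ones(other.shape, dtype=bool))
        with pytest.raises(ValueError, match="[Rr]esample"):
            observed_probability(pdf, roi, 1)

    def test_expected_probability_cases(self, toy_grid):
        brain = ROIMask(toy_grid, np.ones(toy_grid.shape, dtype=bool))
        assert expected_probability(brain, brain) == 1.0
        empty = ROIMask(toy_grid, np.zeros(toy_grid.shape, dtype=bool))
        assert expected_probability(empty, brain) == 0.0

    def test_expected_probability_is_volume_ratio(self):
        from brainbehavior import GridSpec

        grid = GridSpec(2.0, (0, 0, 0), (100, 100, 20))
        brain = ROIMask(grid, np.ones(grid.shape, dtype=bool))
        roi = np.zeros(grid.shape, dtype=bool)
        roi.ravel()[:1000] = True  # 8000 mm^3 of a 1,600,000 mm^3 brain
        assert expected_probability(ROIMask(grid, roi), brain) == 0.005

    def test_empty_brain_is_hard_error(self, toy_grid):
        empty = ROIMask(toy_grid, np.zeros(toy_grid.shape, dtype=bool))
        with pytest.raises(ValueError, match="brain"):
            expected_probability(empty, empty)

    @given(st.integers(0, 10 ** 6))
    def test_growing_roi_never_decreases_p_obs(self, seed):
        from brainbehavior import GridSpec

        grid = GridSpec(2.0, (-4.0, -6.0, -4.0), (6, 6, 6))
        r = np.random.default_rng(seed)
        coords = grid.voxel_to_coord(r.integers(0, 6, size=(30, 3)))
        pdf = _toy_pdf(grid, {1: coords})
        small = r.random(grid.shape) > 0.7
        big = small | (r.random(grid.shape) > 0.7)
        p_small = observed_probability(pdf, ROIMask(grid, small), 1)
        p_big = observed_probability(pdf, ROIMask(grid, big), 1)
        assert p_big >= p_small


class TestAnalyze:
    def test_empty_roi_profile(self, toy_grid):
        pdf = _toy_pdf(toy_grid, {1: [toy_grid.voxel_to_coord([0, 0, 0])]})
        brain = ROIMask(toy_grid, np.ones(toy_grid.shape, dtype=bool))
        roi = ROIMask(toy_grid, np.zeros(toy_grid.shape, dtype=bool))
        profile = analyze(pdf, roi, brain)
        assert profile.significant_ids() == ()
        assert all(r.p_obs == 0.0 for r in profile.rows)

    def test_rows_ranked_by_descending_z(self, suite, recovery_pdf):
        profile = analyze(recovery_pdf, suite.recovery.roi, suite.brain)
        zs = [r.z for r in profile.rows if not math.isnan(r.z)]
        assert zs == sorted(zs, reverse=True)
        assert len(profile.rows) == 51

    def test_foci_in_roi_consistent_with_p_obs(self, suite, recovery_pdf):
        profile = analyze(recovery_pdf, suite.recovery.roi, suite.brain)
        for row in profile.rows:
            assert row.foci_in_roi == round(row.p_obs * row.n_foci)

    def test_roi_outside_density_support_is_nonpositive(self, suite, disjoint_pdf):
        """An ROI placed where no synthetic foci fall (the analogue of a
        white-matter ROI) yields no positive z for any populated channel."""
        from brainbehavior import roi_sphere

        roi = roi_sphere((0.0, -60.0, 0.0), 10.0, suite.grid)  # far from all clusters
        profile = analyze(disjoint_pdf, roi, suite.brain)
        populated = [r for r in profile.rows if r.n_foci > 0]
        assert populated and all(r.z <= 0 for r in populated)
        assert profile.significant_ids() == ()


class TestExport:
    def _profile(self, suite, recovery_pdf):
        return analyze(recovery_pdf, suite.recovery.roi, suite.brain)

    def test_csv_has_header_and_51_ranked_rows(self, tmp_path, suite, recovery_pdf):
        profile = self._profile(suite, recovery_pdf)
        path = tmp_path / "profile.csv"
        export_profile(profile, path, format="csv")
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 52
        header = lines[0].split(",")
        first = dict(zip(header, lines[1].split(",")))
        assert float(first["z"]) == max(r.z for r in profile.rows)

    def test_json_round_trip(self, tmp_path, suite, recovery_pdf):
        profile = self._profile(suite, recovery_pdf)
        path = tmp_path / "profile.json"
        export_profile(profile, path, format="json")
        assert read_profile(path) == profile

    def test_plot_writes_figure(self, tmp_path, suite, recovery_pdf):
        path = tmp_path / "profile.png"
        plot_profile(self._profile(suite, recovery_pdf), path, top=15)
        assert path.stat().st_size > 0
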