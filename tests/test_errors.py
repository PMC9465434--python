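"""Error injection: magnitude grids, application semantics, labels."""

from __future__ import annotations

import numpy as np
import pytest

from doseqa.errors import (
    LEVEL2_THRESHOLDS,
    Bank,
    ErrorSpec,
    ErrorType,
    Relevance,
    apply_error,
    label_pair,
    level2_label,
    magnitude_grid,
)
from doseqa.plans import generate_plan, render_dose


class TestMagnitudeGrid:
    @pytest.mark.parametrize("etype", list(ErrorType))
    def test_twenty_nonzero_symmetric_values(self, etype):
        grid = magnitude_grid(etype)
        assert len(grid) == 20
        assert 0.0 not in grid
        np.testing.assert_allclose(np.sort(-grid), np.sort(grid))

    def test_collimator_grid_values(self):
        grid = magnitude_grid(ErrorType.COLLIMATOR)
        expected = np.round(np.concatenate([np.arange(-2.0, 0.0, 0.2), np.arange(0.2, 2.2, 0.2)]), 10)
        np.testing.assert_allclose(grid, expected)

    def test_mu_grid_is_integer_steps(self):
        grid = magnitude_grid(ErrorType.MU_SYSTEMATIC)
        assert set(grid) == set(range(-10, 11)) - {0}

    def test_step_multiplier_coarsens_grid(self):
        grid = magnitude_grid(ErrorType.MLC_SYSTEMATIC, step_multiplier=2)
        assert len(grid) == 10
        assert grid.max() == pytest.approx(2.0)

    @pytest.mark.parametrize("etype", list(ErrorType))
    def test_grid_straddles_relevance_threshold(self, etype):
        """Both relevance classes are populated by the grid."""
        labels = {level2_label(etype, m) for m in magnitude_grid(etype)}
        assert labels == {Relevance.RELEVANT, Relevance.IRRELEVANT}


class TestLevel2Label:
    @pytest.mark.parametrize(
        "etype, magnitude, expected",
        [
            (ErrorType.COLLIMATOR, 0.2, Relevance.IRRELEVANT),
            (ErrorType.COLLIMATOR, -1.2, Relevance.RELEVANT),
            (ErrorType.MLC_RANDOM, -0.6, Relevance.RELEVANT),
            (ErrorType.MLC_SYSTEMATIC, 0.8, Relevance.IRRELEVANT),
            (ErrorType.MU_SYSTEMATIC, 5.0, Relevance.RELEVANT),  # inclusive boundary
            (ErrorType.MU_RANDOM, -2.9, Relevance.IRRELEVANT),
        ],
    )
    def test_threshold_classification(self, etype, magnitude, expected):
        assert level2_label(etype, magnitude) is expected

    def test_zero_magnitude_rejected(self):
        with pytest.raises(ValueError):
            level2_label(ErrorType.COLLIMATOR, 0.0)

    @pytest.mark.parametrize("etype", list(ErrorType))
    def test_threshold_value_itself_is_relevant(self, etype):
        thr = LEVEL2_THRESHOLDS[etype]
        assert level2_label(etype, thr) is Relevance.RELEVANT
        assert level2_label(etype, -thr) is Relevance.RELEVANT


@pytest.fixture(scope="module")
def plan(small_sim_config):
    return generate_plan(small_sim_config)


class TestApplyError:
    def test_collimator_adds_angle_to_every_segment(self, plan):
        out = apply_error(plan, ErrorSpec(ErrorType.COLLIMATOR, 2.0)).plan
        for arc_o, arc_p in zip(plan.arcs, out.arcs):
            for so, sp in zip(arc_o, arc_p):
                assert sp.collimator_angle == so.collimator_angle + 2.0

    def test_mu_systematic_scales_total_mu(self, plan):
        out = apply_error(plan, ErrorSpec(ErrorType.MU_SYSTEMATIC, 10.0)).plan
        assert out.total_mu() == pytest.approx(1.10 * plan.total_mu(), rel=1e-12)

    def test_mlc_both_banks_translates_aperture(self, plan):
        out = apply_error(
            plan, ErrorSpec(ErrorType.MLC_SYSTEMATIC, 0.6, banks_affected=Bank.BOTH)
        ).plan
        so, sp = plan.arcs[0][0], out.arcs[0][0]
        np.testing.assert_allclose(sp.leaf_positions_bank_a, so.leaf_positions_bank_a + 0.6)
        np.testing.assert_allclose(sp.leaf_positions_bank_b, so.leaf_positions_bank_b + 0.6)

    def test_mlc_single_bank_opens_field_for_positive_magnitude(self, plan):
        out = apply_error(
            plan, ErrorSpec(ErrorType.MLC_SYSTEMATIC, 0.6, banks_affected=Bank.A)
        ).plan
        so, sp = plan.arcs[0][0], out.arcs[0][0]
        np.testing.assert_allclose(sp.leaf_positions_bank_a, so.leaf_positions_bank_a - 0.6)
        np.testing.assert_allclose(sp.leaf_positions_bank_b, so.leaf_positions_bank_b)

    @pytest.mark.parametrize(
        "spec",
        [
            ErrorSpec(ErrorType.COLLIMATOR, 1.4),
            ErrorSpec(ErrorType.MLC_SYSTEMATIC, 0.8, banks_affected=Bank.BOTH),
        ],
    )
    def test_inverse_magnitude_restores_geometry(self, plan, spec):
        fwd = apply_error(plan, spec).plan
        back = apply_error(fwd, ErrorSpec(spec.error_type, -spec.magnitude,
                                          banks_affected=spec.banks_affected)).plan
        for ao, ab in zip(plan.arcs, back.arcs):
            for so, sb in zip(ao, ab):
                assert sb.collimator_angle == pytest.approx(so.collimator_angle, abs=1e-9)
                np.testing.assert_allclose(
                    sb.leaf_positions_bank_a, so.leaf_positions_bank_a, atol=1e-9
                )

    def test_original_plan_is_untouched(self, plan):
        before = plan.copy()
        apply_error(plan, ErrorSpec(ErrorType.MU_SYSTEMATIC, -7.0))
        apply_error(plan, ErrorSpec(ErrorType.MLC_RANDOM, 1.0), np.random.default_rng(0))
        for ab, aa in zip(before.arcs, plan.arcs):
            for sb, sa in zip(ab, aa):
                assert sb.mu == sa.mu
                np.testing.assert_array_equal(sb.leaf_positions_bank_a, sa.leaf_positions_bank_a)

    @pytest.mark.parametrize("etype", [ErrorType.MLC_RANDOM, ErrorType.MU_RANDOM])
    def test_random_label_is_mean_of_recorded_draws(self, plan, etype):
        applied = apply_error(plan, ErrorSpec(etype, 1.0), np.random.default_rng(9))
        spec = applied.spec
        assert spec.per_unit_draws is not None
        assert spec.magnitude == pytest.approx(float(spec.per_unit_draws.mean()), abs=1e-12)

    def test_mlc_random_draw_count_is_two_per_leaf_pair(self, plan):
        applied = apply_error(plan, ErrorSpec(ErrorType.MLC_RANDOM, 0.5), np.random.default_rng(2))
        n_units = sum(2 * s.n_leaf_pairs for arc in plan.arcs for s in arc)
        assert applied.spec.per_unit_draws.size == n_units

    def test_mu_random_draw_count_is_one_per_segment(self, plan):
        applied = apply_error(plan, ErrorSpec(ErrorType.MU_RANDOM, 4.0), np.random.default_rng(2))
        n_segments = sum(len(arc) for arc in plan.arcs)
        assert applied.spec.per_unit_draws.size == n_segments

    def test_random_without_rng_or_draws_raises(self, plan):
        with pytest.raises(ValueError, match="rng"):
            apply_error(plan, ErrorSpec(ErrorType.MU_RANDOM, 4.0))

    def test_bank_overlap_is_clamped_to_zero_gap(self, plan):
        # closing bank B by more than the aperture width must clamp, not cross
        applied = apply_error(
            plan, ErrorSpec(ErrorType.MLC_SYSTEMATIC, -2.0, banks_affected=Bank.A)
        )
        narrow = plan.copy()
        for arc in narrow.arcs:
            for seg in arc:
                seg.leaf_positions_bank_a[:] = -0.5
                seg.leaf_positions_bank_b[:] = 0.5
        applied = apply_error(
            narrow, ErrorSpec(ErrorType.MLC_SYSTEMATIC, -2.0, banks_affected=Bank.A)
        )
        for arc in applied.plan.arcs:
            for seg in arc:
                assert np.all(seg.leaf_positions_bank_a <= seg.leaf_positions_bank_b)
                np.testing.assert_allclose(seg.leaf_positions_bank_a, seg.leaf_positions_bank_b)

    def test_magnitude_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            ErrorSpec(ErrorType.COLLIMATOR, 3.5)
        with pytest.raises(ValueError):
            ErrorSpec(ErrorType.MU_SYSTEMATIC, 0.0)

    def test_labels_property(self, plan):
        applied = apply_error(plan, ErrorSpec(ErrorType.COLLIMATOR, -1.6))
        assert applied.labels.level1 is ErrorType.COLLIMATOR
        assert applied.labels.level2 is Relevance.RELEVANT


class TestDoseResponse:
    """Perturbed dose behaves sensibly as a function of error magnitude."""

    @pytest.mark.parametrize(
        "etype, magnitudes",
        [
            (ErrorType.COLLIMATOR, [0.2, 1.0, 2.0]),
            (ErrorType.MLC_SYSTEMATIC, [0.2, 1.0, 2.0]),
            (ErrorType.MU_SYSTEMATIC, [1.0, 5.0, 10.0]),
        ],
    )
    def test_max_dose_deviation_monotone_in_magnitude(
        self, small_sim_config, plan, etype, magnitudes
    ):
        ref = render_dose(plan, small_sim_config, arc_index=0)
        devs = []
        for m in magnitudes:
            pert = apply_error(plan, ErrorSpec(etype, m)).plan
            dose = render_dose(pert, small_sim_config, arc_index=0)
            devs.append(np.abs(dose.pixels - ref.pixels).max())
        assert devs == sorted(devs)
        # the smallest grid step stays close to the reference
        assert devs[0] < 0.1 * ref.max()
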