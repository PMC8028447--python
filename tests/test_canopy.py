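import numpy as np
import pytest

from helpers import anova_f_by_definition

from ojipcanopy import (
    ValidationError,
    VerticalProfile,
    anova_lsd,
    classify_stage_category,
    detect_reversal_stage,
    layer_relative_ratios,
    standard_error,
    vertical_slope,
    within_leaf_gradient,
)
from ojipcanopy.canopy import CATEGORY_SIGNATURES


def make_profile(means, nitrogen="N1", stage="V1"):
    layers = tuple(f"L{i}" for i in range(1, len(means) + 1))
    return VerticalProfile(nitrogen, stage, "chl", layers,
                           np.asarray(means, float), np.zeros(len(means)),
                           tuple([4] * len(means)))


class TestStandardError:
    def test_constant_sample_is_zero(self):
        assert standard_error([5, 5, 5, 5]) == 0.0

    def test_known_value(self):
        assert standard_error([1, 2, 3, 4]) == pytest.approx(0.6455, abs=1e-4)

    def test_single_value_rejected(self):
        with pytest.raises(ValidationError):
            standard_error([3.0])


class TestAnovaLsd:
    def test_identical_groups_share_a_letter(self):
        res = anova_lsd([[5, 5, 5], [5, 5, 5], [5, 5, 5]])
        assert res.letters == ("a", "a", "a")
        assert res.p_value == 1.0

    def test_separated_groups_get_distinct_letters(self):
        res = anova_lsd([[0, 0, 0.1, -0.1], [10, 10, 10.1, 9.9]])
        assert res.letters[0] != res.letters[1]
        assert res.p_value < 0.05
        # higher-mean group is lettered 'a'
        assert res.letters[1] == "a"

    def test_f_statistic_matches_definition(self, rng):
        for _ in range(50):
            k = rng.integers(2, 5)
            groups = [rng.normal(rng.uniform(0, 3), 1.0, rng.integers(3, 8)) for _ in range(k)]
            res = anova_lsd(groups)
            assert res.f_statistic == pytest.approx(anova_f_by_definition(groups), rel=1e-10)

    def test_zero_variance_unequal_means(self):
        res = anova_lsd([[1.0, 1.0], [2.0, 2.0]])
        assert res.letters[0] != res.letters[1]
        assert res.p_value <= np.finfo(float).tiny

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            anova_lsd([[1.0], [2.0, 3.0]])

    def test_letter_partition_invariant_under_relabeling(self, rng):
        groups = [rng.normal(m, 1.0, 6) for m in (0.0, 0.5, 5.0, 5.2)]
        res = anova_lsd(groups)
        order = [2, 0, 3, 1]
        res_perm = anova_lsd([groups[i] for i in order])

        def share(letters):
            k = len(letters)
            return {(i, j): bool(set(letters[i]) & set(letters[j]))
                    for i in range(k) for j in range(k)}

        base = share(res.letters)
        perm = share(res_perm.letters)
        for (i, j), val in perm.items():
            assert val == base[(order[i], order[j])]


class TestWithinLeafGradient:
    @pytest.mark.parametrize(
        "triple, expected",
        [
            ((10, 20, 30), "increasing"),
            ((30, 20, 10), "decreasing"),
            ((10, 30, 20), "non_monotonic"),
            ((10, 10.05, 10.02), "flat"),
        ],
    )
    def test_classification(self, triple, expected):
        assert within_leaf_gradient(*triple, delta=0.01) == expected


class TestLayerRelativeRatios:
    def test_control_identity(self):
        ratios = layer_relative_ratios(make_profile([3.0, 3.0, 3.0]))
        assert all(r == pytest.approx(1.0) for r in ratios.values())

    def test_simple_division(self):
        ratios = layer_relative_ratios(make_profile([2.0, 2.5, 3.0]))
        assert ratios["L3"] == pytest.approx(1.5)

    def test_invariant_under_common_rescaling(self):
        a = layer_relative_ratios(make_profile([2.0, 3.0, 5.0]))
        b = layer_relative_ratios(make_profile([20.0, 30.0, 50.0]))
        for layer in a:
            assert a[layer] == pytest.approx(b[layer])

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValidationError):
            layer_relative_ratios(make_profile([0.0, 1.0, 2.0]))


def flat_panel(value=1.0):
    names = set().union(*(p | v for p, v in CATEGORY_SIGNATURES.values()))
    return {name: {f"L{i}": value for i in range(1, 6)} for name in names}


class TestStageCategories:
    def test_constructed_category_one(self):
        panel = flat_panel()
        for name in ("PI_ABS", "ET0_RC", "ET0_CS", "phi_Eo", "psi_Eo"):
            panel[name] = {"L1": 1.0, "L2": 1.1, "L3": 1.5, "L4": 1.5, "L5": 1.5}
        match = classify_stage_category(panel)
        assert match.category == 1 and not match.tie

    def test_constructed_category_four(self):
        panel = flat_panel()
        for name in ("DI0_RC", "DI0_CS"):
            panel[name] = {f"L{i}": r for i, r in enumerate([1.0, 1.2, 1.5, 1.5, 1.5], 1)}
        for name in ("PI_ABS", "ET0_RC", "phi_Eo", "ET0_CS"):
            panel[name] = {f"L{i}": r for i, r in enumerate([1.0, 0.8, 0.6, 0.6, 0.6], 1)}
        match = classify_stage_category(panel)
        assert match.category == 4 and not match.tie

    def test_all_flat_ties_to_category_one(self):
        match = classify_stage_category(flat_panel())
        assert match.category == 1
        assert match.tie
        assert match.score == 0

    def test_rescaling_all_profiles_changes_nothing(self):
        panel = flat_panel()
        for name in ("RE0_RC", "RE0_CS", "phi_Ro"):
            panel[name] = {f"L{i}": r for i, r in enumerate([1.0, 1.1, 1.4, 1.4, 1.4], 1)}
        # layer-relative panels are built from L1-normalised means, so a common
        # rescaling of the raw means leaves the panel, and the match, unchanged
        match = classify_stage_category(panel)
        assert match.category == 3

    def test_missing_parameter_named_in_error(self):
        panel = flat_panel()
        del panel["PI_ABS"]
        with pytest.raises(ValidationError, match="PI_ABS"):
            classify_stage_category(panel)


class TestReversalDetection:
    def test_constructed_sign_change(self):
        profiles = {}
        for stage in ("V1", "V2", "V3", "R1"):
            profiles[stage] = make_profile([30, 27, 24], stage=stage)
        for stage in ("R2", "R3", "R4", "R5"):
            profiles[stage] = make_profile([24, 27, 30], stage=stage)
        assert detect_reversal_stage(profiles) == "R2"

    def test_all_bottom_heavy_returns_none(self):
        profiles = {s: make_profile([30, 25, 20], stage=s) for s in ("V1", "V2", "R1")}
        assert detect_reversal_stage(profiles) is None

    def test_short_profile_skipped_with_warning(self):
        profiles = {
            "V1": make_profile([30, 27], stage="V1"),
            "V2": make_profile([30, 27, 24], stage="V2"),
            "R1": make_profile([24, 27, 30], stage="R1"),
        }
        with pytest.warns(UserWarning):
            assert detect_reversal_stage(profiles) == "R1"

    def test_slope_sign_summary(self):
        assert vertical_slope(make_profile([10, 20, 30])) > 0
        assert vertical_slope(make_profile([30, 20, 10])) < 0


class TestVerticalProfileInvariants:
    def test_layers_must_start_at_l1(self):
        with pytest.raises(ValidationError):
            VerticalProfile("N1", "V1", "chl", ("L2", "L3"), np.array([1.0, 2.0]),
                            np.zeros(2), (4, 4))
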