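import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allelosep.data_model import DesignSpec, GroupSummary, load_paper_fixture
from allelosep.indices import (
    MissingCellError,
    UndefinedIndexError,
    competitive_ratio,
    compute_index_table,
    inhibitory_rate,
    relative_competition_intensity,
    relative_neighbor_effect,
)

perf = st.floats(min_value=1e-3, max_value=1e4, allow_nan=False)
proportion = st.floats(min_value=0.05, max_value=0.95)


class TestRelativeCompetitionIntensity:
    @pytest.mark.parametrize(
        "p_mono,p_mix,expected",
        [
            (8.73, 10.26, -0.1753),  # facilitation of the donor by its neighbor
            (7.32, 2.66, 0.6366),  # strong suppression of the weed
            (5.0, 5.0, 0.0),
            (10.0, 0.0, 1.0),
        ],
    )
    def test_known_values(self, p_mono, p_mix, expected):
        assert round(relative_competition_intensity(p_mono, p_mix), 4) == expected

    def test_dead_control_is_undefined(self):
        with pytest.raises(UndefinedIndexError):
            relative_competition_intensity(0.0, 1.0)


class TestRelativeNeighborEffect:
    def test_equals_rci_when_monoculture_dominates(self):
        assert relative_neighbor_effect(0.152, 0.081) == pytest.approx(
            relative_competition_intensity(0.152, 0.081)
        )
        assert round(relative_neighbor_effect(0.152, 0.081), 4) == 0.4671

    def test_facilitation_uses_larger_denominator(self):
        # oracle: evaluate both candidate denominators and keep the larger
        p_mono, p_mix = 0.412, 0.472
        oracle = (p_mono - p_mix) / max(p_mono, p_mix)
        assert relative_neighbor_effect(p_mono, p_mix) == pytest.approx(oracle)
        assert relative_neighbor_effect(p_mono, p_mix) == pytest.approx(-0.12712, abs=5e-6)

    def test_no_interaction_is_zero(self):
        assert relative_neighbor_effect(3.3, 3.3) == 0.0

    def test_both_zero_is_undefined(self):
        with pytest.raises(UndefinedIndexError):
            relative_neighbor_effect(0.0, 0.0)

    @settings(max_examples=200, derandomize=True)
    @given(p_mono=perf, p_mix=st.floats(min_value=0, max_value=1e4))
    def test_bounds_sign_and_attenuation(self, p_mono, p_mix):
        rne = relative_neighbor_effect(p_mono, p_mix)
        rci = relative_competition_intensity(p_mono, p_mix)
        assert -1.0 <= rne <= 1.0
        assert math.copysign(1, rne) == math.copysign(1, rci) or rne == rci == 0
        assert abs(rne) <= abs(rci) + 1e-12
        if p_mono >= p_mix:
            assert rne == pytest.approx(rci)


class TestCompetitiveRatio:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((8.73, 10.26, 7.32, 2.66), 3.2342),  # rice over weed, root length
            ((7.32, 2.66, 8.73, 10.26), 0.3092),  # swapped orientation
            ((0.446, 0.403, 0.152, 0.115), 1.1943),
            ((2.0, 2.0, 2.0, 2.0), 1.0),
        ],
    )
    def test_known_values(self, args, expected):
        assert round(competitive_ratio(*args), 4) == expected

    def test_nonpositive_performance_is_undefined(self):
        with pytest.raises(UndefinedIndexError):
            competitive_ratio(1.0, 0.0, 1.0, 1.0)

    @settings(max_examples=200, derandomize=True)
    @given(a=perf, b=perf, c=perf, d=perf, z=proportion)
    def test_reciprocity_including_unequal_sowing(self, a, b, c, d, z):
        cr = competitive_ratio(a, b, c, d, z_focal=z, z_partner=1 - z)
        rcr = competitive_ratio(c, d, a, b, z_focal=1 - z, z_partner=z)
        assert cr > 0
        assert cr * rcr == pytest.approx(1.0, abs=1e-9)

    def test_sowing_correction_matches_hand_formula(self):
        base = competitive_ratio(8.73, 10.26, 7.32, 2.66)
        corrected = competitive_ratio(8.73, 10.26, 7.32, 2.66,
                                      z_focal=2 / 3, z_partner=1 / 3)
        assert corrected == pytest.approx(base * 0.5)


class TestInhibitoryRate:
    @pytest.mark.parametrize(
        "control,treatment,expected",
        [(7.32, 5.01, 31.56), (4.2, 4.2, 0.0), (10.0, 12.0, -20.0)],
    )
    def test_known_values(self, control, treatment, expected):
        assert round(inhibitory_rate(control, treatment), 2) == expected

    def test_equals_scaled_rci(self):
        assert inhibitory_rate(0.152, 0.081) == pytest.approx(
            100 * relative_competition_intensity(0.152, 0.081)
        )


@settings(max_examples=100, derandomize=True)
@given(p_mono=perf, p_mix=perf, k=st.floats(min_value=1e-3, max_value=1e3))
def test_indices_are_scale_invariant(p_mono, p_mix, k):
    assert relative_competition_intensity(k * p_mono, k * p_mix) == pytest.approx(
        relative_competition_intensity(p_mono, p_mix)
    )
    assert relative_neighbor_effect(k * p_mono, k * p_mix) == pytest.approx(
        relative_neighbor_effect(p_mono, p_mix)
    )
    assert competitive_ratio(k * p_mono, k * p_mix, 3.0, 2.0) == pytest.approx(
        competitive_ratio(p_mono, p_mix, 3.0, 2.0)
    )


def _pair_summaries(mono_a, mix_a, mono_b, mix_b):
    return [
        GroupSummary("A", "monoculture", "none", "RL", mono_a, 0.0, 3),
        GroupSummary("A", "mixed", "B", "RL", mix_a, 0.0, 3),
        GroupSummary("B", "monoculture", "none", "RL", mono_b, 0.0, 3),
        GroupSummary("B", "mixed", "A", "RL", mix_b, 0.0, 3),
    ]


class TestIndexTable:
    def test_reproduces_published_index_table(self, table1_summaries):
        table = compute_index_table(table1_summaries)
        printed = load_paper_fixture("table2_printed")
        for row in printed.itertuples(index=False):
            computed = table.value(row.focal, row.partner, row.trait, row.index)
            decimals = len(row.printed.split(".")[1])
            assert round(computed, decimals) == float(row.printed), row

    def test_no_interaction_collapses_to_null_indices(self):
        table = compute_index_table(_pair_summaries(4.0, 4.0, 9.0, 9.0))
        for trait_kind, expected in (("RCI", 0.0), ("RNE", 0.0), ("CR", 1.0)):
            assert table.value("A", "B", "RL", trait_kind) == pytest.approx(expected)

    def test_missing_monoculture_cell_is_named(self):
        summaries = _pair_summaries(4.0, 3.0, 9.0, 8.0)[1:]  # drop A's control
        with pytest.raises(MissingCellError, match="monoculture"):
            compute_index_table(summaries)

    def test_design_proportions_feed_the_ratio(self):
        design = DesignSpec("A", "B", target_count=20, neighbor_count=10)
        table = compute_index_table(_pair_summaries(4.0, 3.0, 9.0, 8.0), design=design)
        equal = compute_index_table(_pair_summaries(4.0, 3.0, 9.0, 8.0))
        assert table.value("A", "B", "RL", "CR") == pytest.approx(
            equal.value("A", "B", "RL", "CR") * 0.5
        )
        assert table.value("A", "B", "RL", "CR") * table.value(
            "B", "A", "RL", "CR"
        ) == pytest.approx(1.0, abs=1e-9)

    def test_serialization_round_trips_through_frame(self, table1_summaries, tmp_path):
        table = compute_index_table(table1_summaries)
        table.to_csv(tmp_path / "idx.csv")
        md = table.to_markdown()
        assert "CR RL" in md and (tmp_path / "idx.csv").exists()
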