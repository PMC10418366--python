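"""The S_NO non-overlap statistic: densities, pairing, selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import i0

from chi1sno.angle_io import DihedralSeries
from chi1sno.sno import (
    BinningError,
    Density,
    PairSnoTable,
    SelectionConfig,
    aggregate_sno,
    make_density,
    pairwise_sno,
    select_responsive,
    sno,
    sno_series,
)
from chi1sno.synth import sample_regime, single_well_regime, WellSpec


def _series(angles, residue_id=1):
    t = 0.1 * (1 + np.arange(len(angles)))
    return DihedralSeries(residue_id, "XAA", t, np.asarray(angles, float))


def _uniform_density(lo, hi, edges):
    """Unit-area density flat on [lo, hi) over the given 5-degree bins."""
    heights = np.zeros(len(edges) - 1)
    centers = (edges[:-1] + edges[1:]) / 2
    inside = (centers >= lo) & (centers < hi)
    heights[inside] = 1.0 / (hi - lo)
    return Density(edges=edges, heights=heights)


EDGES = np.arange(0.0, 361.0, 5.0)


class TestDensity:
    def test_delta_sample_single_bin(self):
        d = make_density(np.full(100, 12.0), binwidth=5.0, window_start=0.0)
        occupied = d.heights[d.heights > 0]
        assert occupied.size == 1
        assert occupied[0] == pytest.approx(1.0 / 5.0)

    def test_uniform_grid_is_flat_unit_area(self):
        d = make_density(np.arange(0.0, 360.0, 0.5), binwidth=5.0, window_start=0.0)
        assert np.sum(d.heights * 5.0) == pytest.approx(1.0)
        assert np.allclose(d.heights, d.heights[0])

    def test_von_mises_mode_bin_contains_mean(self):
        series, _ = sample_regime(single_well_regime(n_frames=20000, seed=3))
        from chi1sno.angle_io import stack_angles

        d = make_density(stack_angles(series), binwidth=5.0)
        mode = int(np.argmax(d.heights))
        assert d.edges[mode] <= 190.0 < d.edges[mode + 1]

    def test_binwidth_must_divide_360(self):
        with pytest.raises(BinningError):
            make_density(np.array([1.0]), binwidth=7.0, window_start=0.0)


class TestSno:
    def test_identical_distributions_zero(self):
        p = _uniform_density(0, 180, EDGES)
        assert sno(p, p) == 0.0

    def test_disjoint_supports_one(self):
        p = _uniform_density(0, 90, EDGES)
        q = _uniform_density(180, 270, EDGES)
        assert sno(p, q) == 1.0

    def test_half_overlapping_uniforms(self):
        # overlap integral of U[0,180) and U[90,270) is 90/180 = 0.5
        p = _uniform_density(0, 180, EDGES)
        q = _uniform_density(90, 270, EDGES)
        assert sno(p, q) == pytest.approx(0.5)

    def test_mismatched_edges_rejected(self):
        p = _uniform_density(0, 180, EDGES)
        q = Density(EDGES + 5.0, np.full(len(EDGES) - 1, 1.0 / 360.0))
        with pytest.raises(BinningError):
            sno(p, q)

    def test_in_site_vs_out_of_site_wells_near_one(self):
        """Wells 190 +/- 9 vs 285 +/- 12 are separated far beyond their
        spreads; S_NO from data matches the analytic-density oracle."""

        def analytic_heights(mu, sigma, edges):
            kappa = 1.0 / np.deg2rad(sigma) ** 2
            probs = []
            for a, b in zip(edges[:-1], edges[1:]):
                theta = np.deg2rad(np.linspace(a, b, 41))
                pdf = np.exp(kappa * np.cos(theta - np.deg2rad(mu))) / (
                    2 * np.pi * i0(kappa)
                )
                probs.append(np.trapezoid(pdf, theta))
            probs = np.array(probs) / np.sum(probs)
            return probs / np.diff(edges)

        edges = np.arange(100.0, 461.0, 5.0)
        p_ref = analytic_heights(190.0, 9.0, edges)
        q_ref = analytic_heights(285.0, 12.0, edges)
        oracle = 1.0 - np.sum(np.minimum(p_ref, q_ref) * 5.0)
        assert oracle > 0.99

        a, _ = sample_regime(
            single_well_regime(WellSpec(190.0, 9.0, "in"), n_frames=20000, seed=1)
        )
        b, _ = sample_regime(
            single_well_regime(WellSpec(285.0, 12.0, "out"), n_frames=20000, seed=2)
        )
        assert sno_series(a, b) == pytest.approx(oracle, abs=0.02)

    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=10.0), min_size=2, max_size=8
        ),
        st.lists(
            st.floats(min_value=0.0, max_value=10.0), min_size=2, max_size=8
        ),
    )
    def test_equivalence_with_overlap_coefficient(self, hp, hq):
        n = min(len(hp), len(hq))
        hp, hq = np.array(hp[:n]), np.array(hq[:n])
        if hp.sum() == 0 or hq.sum() == 0:
            return
        bw = 360.0 / n
        edges = np.arange(n + 1) * bw
        p = Density(edges, hp / (hp.sum() * bw))
        q = Density(edges, hq / (hq.sum() * bw))
        value = sno(p, q)
        overlap = np.sum(np.minimum(p.heights, q.heights) * bw)
        assert value == pytest.approx(1.0 - overlap, abs=1e-9)
        assert value == pytest.approx(sno(q, p))
        assert 0.0 <= value <= 1.0
        assert sno(p, p) == 0.0

    def test_shift_invariance_under_common_rotation(self, rng):
        a = np.rad2deg(rng.vonmises(np.deg2rad(190) - np.pi, 40, 5000)) + 180
        b = np.rad2deg(rng.vonmises(np.deg2rad(250) - np.pi, 25, 5000)) + 180
        base = sno_series(_series(a), _series(b))
        for offset in (37.0, 123.0, 292.0):
            shifted = sno_series(
                _series((a + offset) % 360), _series((b + offset) % 360)
            )
            assert shifted == pytest.approx(base, abs=0.05)

    def test_refinement_stability(self):
        a, _ = sample_regime(single_well_regime(n_frames=10000, seed=4))
        b, _ = sample_regime(
            single_well_regime(WellSpec(230.0, 15.0, "w"), n_frames=10000, seed=5)
        )
        coarse = sno_series(a, b, binwidth=5.0)
        fine = sno_series(a, b, binwidth=2.5)
        assert abs(coarse - fine) < 0.05


class TestPairingAndSelection:
    def test_identical_single_replicates_give_zero(self):
        s = _series([10.0, 20.0, 30.0])
        table = pairwise_sno({1: [s]}, {1: [s]}, pairing="matched")
        assert table.values.shape == (1, 1)
        assert table.values[0, 0] == 0.0

    def test_all_pairs_count_contract(self, small_study):
        table = pairwise_sno(
            small_study.by_condition("pH7"),
            small_study.by_condition("pH2"),
            pairing="all_pairs",
        )
        assert table.values.shape == (3, 9)

    def test_matched_requires_equal_replicates(self):
        s = _series([1.0, 2.0])
        with pytest.raises(ValueError, match="matched"):
            pairwise_sno({1: [s, s]}, {1: [s]}, pairing="matched")

    def test_responsive_exceeds_non_responsive(self, small_study):
        table = pairwise_sno(
            small_study.by_condition("pH7"), small_study.by_condition("pH2")
        )
        by_res = dict(zip(table.residues, table.values))
        assert by_res[271].min() > max(by_res[270].max(), by_res[272].max())

    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0.0, 0.0, 0.0], []),
            ([0.6, 0.7, 0.2], [9]),
            ([0.6, 0.4, 0.4], []),
            ([0.5, 0.5, 0.5], []),  # strict inequality at the threshold
        ],
    )
    def test_selection_rule(self, values, expected):
        table = PairSnoTable(
            residues=(9,),
            pairs=(("a1", "b1"), ("a2", "b2"), ("a3", "b3")),
            values=np.array([values]),
        )
        assert select_responsive(table, SelectionConfig()) == expected

    def test_selection_config_validation(self):
        with pytest.raises(ValueError):
            SelectionConfig(threshold=1.5)
        with pytest.raises(ValueError):
            SelectionConfig(min_pairs=4, n_pairs=3)


class TestAggregate:
    def test_constant_values(self):
        assert aggregate_sno([0.5, 0.5, 0.5]) == (0.5, 0.0)

    def test_two_point_sample_sd(self):
        mean, sd = aggregate_sno([0.0, 1.0])
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_mean_within_bounds(self, small_study):
        from chi1sno import pairwise_sno as pw

        table = pw(
            small_study.by_condition("pH7"), small_study.by_condition("pH2")
        )
        for row in table.values:
            mean, _ = aggregate_sno(row)
            assert row.min() <= mean <= row.max()

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            aggregate_sno([0.3])
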