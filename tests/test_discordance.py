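import numpy as np
import pytest

from pairedcna.discordance import (
    assign_windows,
    compare_pair,
    genome_fractions,
    tile_genome,
)
from pairedcna.profiles_io import GenomeLayout, ValidationError

from conftest import build_profile, uniform_profile
from oracles import (
    brute_compare,
    brute_genome_fractions,
    brute_window_states,
    random_profile,
)


class TestTiling:
    @pytest.mark.parametrize(
        "length,ws,expected",
        [(30_000, 10_000, 3), (25_000, 10_000, 3), (10_000, 10_000, 1), (9_999, 10_000, 1)],
    )
    def test_window_count_is_ceiling(self, length, ws, expected):
        grid = tile_genome(GenomeLayout((("chr1", length),)), ws)
        assert len(grid) == expected

    def test_short_final_window_retained(self):
        grid = tile_genome(GenomeLayout((("chr1", 25_000),)), 10_000)
        assert list(grid.windows())[-1] == ("chr1", 20_000, 25_000)

    def test_layout_order_preserved(self):
        grid = tile_genome(GenomeLayout((("chrB", 10_000), ("chrA", 10_000))), 10_000)
        assert [w[0] for w in grid.windows()] == ["chrB", "chrA"]

    def test_empty_layout_gives_empty_grid(self):
        assert len(tile_genome(GenomeLayout(()), 10_000)) == 0

    def test_nonpositive_window_size_rejected(self, toy_layout):
        with pytest.raises(ValidationError):
            tile_genome(toy_layout, 0)


class TestAssignment:
    def test_window_inside_segment(self, toy_layout):
        grid = tile_genome(toy_layout, 10_000)
        track = assign_windows(
            build_profile(toy_layout, [("chr1", 0, 100_000, 3, 1)]), grid
        )
        sl = grid.chrom_slice("chr1")
        assert (track.total_cn[sl] == 3).all()
        assert not track.loh[sl].any()

    def test_largest_overlap_wins(self, toy_layout):
        """6 kb of (2,0) beats 4 kb of (4,2) inside one window."""
        grid = tile_genome(toy_layout, 10_000)
        profile = build_profile(
            toy_layout, [("chr1", 0, 6_000, 2, 0), ("chr1", 6_000, 10_000, 4, 2)]
        )
        track = assign_windows(profile, grid)
        assert track.total_cn[0] == 2
        assert bool(track.loh[0])

    def test_overlap_tie_goes_to_leftmost(self, toy_layout):
        grid = tile_genome(toy_layout, 10_000)
        profile = build_profile(
            toy_layout, [("chr1", 0, 5_000, 5, 1), ("chr1", 5_000, 10_000, 1, 0)]
        )
        assert assign_windows(profile, grid).total_cn[0] == 5

    def test_uncovered_window_missing(self, toy_layout):
        grid = tile_genome(toy_layout, 10_000)
        track = assign_windows(
            build_profile(toy_layout, [("chr1", 0, 10_000, 2, 1)]), grid
        )
        assert not track.missing[0]
        assert track.missing[1:].all()


class TestComparePair:
    def _tracks(self, layout, segs_p, segs_m, ws=10_000):
        grid = tile_genome(layout, ws)
        return (
            assign_windows(build_profile(layout, segs_p, sample_id="P"), grid),
            assign_windows(build_profile(layout, segs_m, sample_id="M"), grid),
        )

    def test_identical_tracks_fully_concordant(self, toy_layout):
        segs = [(c, 0, toy_layout.length(c), 3, 1) for c in toy_layout.names]
        p, m = self._tracks(toy_layout, segs, segs)
        res = compare_pair(p, m)
        assert res.cn_discordant_fraction == 0.0
        assert res.loh_unchanged_fraction == 1.0

    def test_doubling_forgiven_with_correction(self, toy_layout):
        """A +2 change without LOH change is concordant under the
        doubling correction, discordant without it."""
        segs_p = [(c, 0, toy_layout.length(c), 2, 1) for c in toy_layout.names]
        segs_m = [(c, 0, toy_layout.length(c), 4, 2) for c in toy_layout.names]
        p, m = self._tracks(toy_layout, segs_p, segs_m)
        assert compare_pair(p, m, wgd_correction=True).cn_discordant_fraction == 0.0
        assert compare_pair(p, m, wgd_correction=False).cn_discordant_fraction == 1.0

    def test_loh_change_at_equal_total_is_cn_concordant(self):
        """(2,0) vs (2,1): copy number concordant but classified as
        heterozygosity retained in the metastasis."""
        layout = GenomeLayout((("chr1", 10_000),))
        p, m = self._tracks(layout, [("chr1", 0, 10_000, 2, 0)], [("chr1", 0, 10_000, 2, 1)])
        res = compare_pair(p, m)
        assert res.cn_discordant_fraction == 0.0
        assert res.loh_primary_only_fraction == 1.0

    def test_loh_acquired_in_met(self):
        layout = GenomeLayout((("chr1", 10_000),))
        p, m = self._tracks(layout, [("chr1", 0, 10_000, 2, 1)], [("chr1", 0, 10_000, 2, 0)])
        res = compare_pair(p, m)
        assert res.loh_met_only_fraction == 1.0
        assert res.cn_discordant_fraction == 0.0

    def test_plus_three_discordant_even_with_correction(self):
        layout = GenomeLayout((("chr1", 10_000),))
        p, m = self._tracks(layout, [("chr1", 0, 10_000, 2, 1)], [("chr1", 0, 10_000, 5, 2)])
        assert compare_pair(p, m).cn_discordant_fraction == 1.0

    def test_plus_one_with_loh_change_not_forgiven(self):
        layout = GenomeLayout((("chr1", 10_000),))
        p, m = self._tracks(layout, [("chr1", 0, 10_000, 2, 1)], [("chr1", 0, 10_000, 3, 0)])
        assert compare_pair(p, m).cn_discordant_fraction == 1.0

    def test_windows_missing_in_either_sample_excluded(self, toy_layout):
        p, m = self._tracks(
            toy_layout,
            [("chr1", 0, 50_000, 2, 1)],
            [("chr1", 0, 30_000, 2, 1), ("chr1", 30_000, 100_000, 5, 1)],
        )
        res = compare_pair(p, m)
        assert res.n_windows_compared == 5  # chr1 0-50kb only
        assert res.cn_discordant_fraction == pytest.approx(2 / 5)

    def test_correction_is_one_sided(self, toy_layout):
        """Swapping the samples under the correction turns forgiven +2
        differences into unforgiven -2 differences."""
        segs_p = [(c, 0, toy_layout.length(c), 2, 1) for c in toy_layout.names]
        segs_m = [(c, 0, toy_layout.length(c), 4, 2) for c in toy_layout.names]
        p, m = self._tracks(toy_layout, segs_p, segs_m)
        assert compare_pair(p, m, wgd_correction=True).cn_discordant_fraction == 0.0
        assert compare_pair(m, p, wgd_correction=True).cn_discordant_fraction == 1.0
        # without correction the metric is symmetric
        assert (
            compare_pair(p, m, wgd_correction=False).cn_discordant_fraction
            == compare_pair(m, p, wgd_correction=False).cn_discordant_fraction
        )

    def test_loh_fractions_sum_to_one(self, toy_layout):
        rng = np.random.default_rng(11)
        grid = tile_genome(toy_layout, 10_000)
        for i in range(20):
            p = assign_windows(random_profile(rng, toy_layout, "P"), grid)
            m = assign_windows(random_profile(rng, toy_layout, "M"), grid)
            both = ~p.missing & ~m.missing
            if not both.any():
                continue
            res = compare_pair(p, m)
            assert (
                res.loh_unchanged_fraction
                + res.loh_met_only_fraction
                + res.loh_primary_only_fraction
            ) == pytest.approx(1.0)

    def test_different_grids_rejected(self, toy_layout):
        g1 = tile_genome(toy_layout, 10_000)
        g2 = tile_genome(toy_layout, 5_000)
        p = assign_windows(build_profile(toy_layout, [("chr1", 0, 10_000, 2, 1)]), g1)
        m = assign_windows(build_profile(toy_layout, [("chr1", 0, 10_000, 2, 1)]), g2)
        with pytest.raises(ValidationError, match="grid"):
            compare_pair(p, m)


class TestGenomeFractions:
    def test_diploid_genome_unaltered(self, toy_layout):
        assert genome_fractions(uniform_profile(toy_layout, 2, 1)) == (0.0, 0.0)

    def test_copy_neutral_loh_not_a_cn_change(self, toy_layout):
        """Uniform (2,0): no copy-number alteration, full LOH."""
        assert genome_fractions(uniform_profile(toy_layout, 2, 0)) == (0.0, 1.0)

    def test_half_genome_gained(self):
        layout = GenomeLayout((("chr1", 100_000),))
        p = build_profile(
            layout, [("chr1", 0, 50_000, 3, 1), ("chr1", 50_000, 100_000, 2, 1)]
        )
        assert genome_fractions(p) == (0.5, 0.0)

    def test_denominator_is_covered_bases(self):
        layout = GenomeLayout((("chr1", 100_000),))
        p = build_profile(layout, [("chr1", 0, 20_000, 5, 0)])
        assert genome_fractions(p) == (1.0, 1.0)

    def test_empty_profile_errors(self, toy_layout):
        import pandas as pd

        from pairedcna.profiles_io import SegmentedProfile

        empty = SegmentedProfile(
            "S1",
            pd.DataFrame(columns=["chromosome", "start", "end", "total_cn", "minor_cn"]),
            toy_layout,
        )
        with pytest.raises(ValidationError):
            genome_fractions(empty)


class TestOracleEquivalence:
    def test_assignment_and_fractions_match_per_base_oracle(self, toy_layout):
        rng = np.random.default_rng(19)
        grid = tile_genome(toy_layout, 1_000)
        for i in range(25):
            profile = random_profile(rng, toy_layout, f"S{i}")
            track = assign_windows(profile, grid)
            bt, bm = brute_window_states(profile, toy_layout, 1_000)
            np.testing.assert_array_equal(track.total_cn, bt)
            np.testing.assert_array_equal(track.minor_cn, bm)
            assert genome_fractions(profile) == pytest.approx(
                brute_genome_fractions(profile, toy_layout), abs=0
            )

    def test_pair_comparison_matches_per_base_oracle(self, toy_layout):
        rng = np.random.default_rng(23)
        grid = tile_genome(toy_layout, 1_000)
        for i in range(15):
            p_prof = random_profile(rng, toy_layout, "P")
            m_prof = random_profile(rng, toy_layout, "M")
            p = assign_windows(p_prof, grid)
            m = assign_windows(m_prof, grid)
            both = ~p.missing & ~m.missing
            if not both.any():
                continue
            for corr in (True, False):
                res = compare_pair(p, m, wgd_correction=corr)
                bt_p, bm_p = brute_window_states(p_prof, toy_layout, 1_000)
                bt_m, bm_m = brute_window_states(m_prof, toy_layout, 1_000)
                n, cn, unch, lm, lp = brute_compare(bt_p, bm_p, bt_m, bm_m, corr)
                assert res.n_windows_compared == n
                assert res.cn_discordant_fraction == pytest.approx(cn / n, abs=0)
                assert res.loh_unchanged_fraction == pytest.approx(unch / n, abs=0)
                assert res.loh_met_only_fraction == pytest.approx(lm / n, abs=0)
                assert res.loh_primary_only_fraction == pytest.approx(lp / n, abs=0)
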