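"""Permutation inference: randomization law, test statistics, local z,
screening and consensus construction."""

import numpy as np
import pytest
from scipy import stats

from prdm9scan import (
    BreakpointSet,
    DegenerateMotif,
    GenomeAssembly,
    Interval,
    MotifVariant,
    RegionSet,
    combination_seed,
    consensus_motif,
    expand_degenerate,
    is_significant,
    local_zscore,
    make_windows,
    perm_test,
    randomize_regions,
    screen_all,
)
from prdm9scan.perm_inference import PlacementSampler


class TestRandomizeRegions:
    def test_forced_placement(self):
        asm = GenomeAssembly(chroms=[("c", 10)])
        rs = RegionSet("r", [Interval("c", 0, 10)])
        for seed in range(5):
            out = randomize_regions(rs, asm, np.random.default_rng(seed))
            assert out.intervals == [Interval("c", 0, 10)]

    def test_placement_uniform_over_valid_starts(self):
        """Interval length 5 on an 8-bp chromosome: starts 0..3, uniform
        (chi-square GOF over 40,000 draws)."""
        asm = GenomeAssembly(chroms=[("c", 8)])
        sampler = PlacementSampler(asm, 5)
        rng = np.random.default_rng(123)
        _, starts = sampler.sample(rng, 40_000)
        counts = np.bincount(starts, minlength=4)
        assert set(np.flatnonzero(counts)) <= {0, 1, 2, 3}
        assert stats.chisquare(counts).pvalue > 0.001

    def test_mask_excludes_placements(self):
        asm = GenomeAssembly(chroms=[("c", 1000)], gap_mask={"c": [(0, 500)]})
        rs = RegionSet("r", [Interval("c", 600, 700)])
        rng = np.random.default_rng(5)
        for _ in range(200):
            iv = randomize_regions(rs, asm, rng).intervals[0]
            assert 500 <= iv.start <= 900
            assert iv.end <= 1000

    def test_lengths_preserved_and_chromosome_weighting(self):
        asm = GenomeAssembly(chroms=[("big", 9_000), ("small", 1_000)])
        rs = RegionSet("r", [Interval("big", 0, 10)] * 2000)
        rng = np.random.default_rng(9)
        out = randomize_regions(rs, asm, rng)
        assert all(iv.length == 10 for iv in out.intervals)
        frac_big = np.mean([iv.chrom == "big" for iv in out.intervals])
        # P(big) = 8991/9982 ~ 0.9007
        assert abs(frac_big - 0.9007) < 0.03

    def test_interval_longer_than_any_unmasked_stretch_rejected(self):
        asm = GenomeAssembly(chroms=[("c", 100)], gap_mask={"c": [(40, 60)]})
        with pytest.raises(ValueError, match="un-masked stretch"):
            PlacementSampler(asm, 61)

    def test_deterministic_given_state(self):
        asm = GenomeAssembly(chroms=[("c", 1000), ("d", 500)])
        rs = RegionSet("r", [Interval("c", 0, 10), Interval("d", 3, 40)])
        a = randomize_regions(rs, asm, np.random.default_rng(77))
        b = randomize_regions(rs, asm, np.random.default_rng(77))
        assert a.intervals == b.intervals


def _simple_setup(n_windows=5, width=10, length=1000):
    asm = GenomeAssembly(chroms=[("c", length)])
    positions = [("c", 100 + 150 * i) for i in range(n_windows)]
    windows = make_windows(BreakpointSet("t", positions), width, asm)
    return asm, windows


class TestPermTest:
    def test_empty_hits_degenerate_null(self):
        asm, windows = _simple_setup()
        with pytest.warns(UserWarning, match="zero spread"):
            r = perm_test(windows, RegionSet("h", []), asm, n_perm=50, seed=1)
        assert r.observed == 0
        assert r.perm_mean == 0.0
        assert r.perm_sd == 0.0
        assert r.p_value == 1.0
        assert not r.z_defined

    def test_windows_equal_hits_gives_count_once_maximum(self):
        asm, windows = _simple_setup()
        hits = RegionSet("h", list(windows.intervals))
        r = perm_test(windows, hits, asm, n_perm=50, seed=1)
        assert r.observed == len(windows)

    def test_empty_window_set_rejected(self):
        asm = GenomeAssembly(chroms=[("c", 100)])
        from prdm9scan import WindowSet

        with pytest.raises(ValueError, match="empty"):
            perm_test(WindowSet(label="w", intervals=[]), RegionSet("h", []), asm)

    def test_p_value_floor_is_one_over_nperm_plus_one(self):
        asm, windows = _simple_setup()
        hits = RegionSet("h", list(windows.intervals))
        r = perm_test(windows, hits, asm, n_perm=1000, seed=2)
        assert r.p_value >= 1 / 1001
        assert r.p_value == pytest.approx(1 / 1001)  # obs unreachable by chance here

    def test_alternative_auto_resolution(self):
        asm, windows = _simple_setup()
        hits = RegionSet("h", list(windows.intervals))
        r = perm_test(windows, hits, asm, n_perm=100, seed=3, alternative="auto")
        assert r.alternative == "greater"

    def test_reproducible_given_seed(self):
        asm, windows = _simple_setup()
        rng = np.random.default_rng(8)
        hits = RegionSet(
            "h", [Interval("c", int(s), int(s) + 5) for s in rng.integers(0, 990, 30)]
        )
        a = perm_test(windows, hits, asm, n_perm=200, seed=5, keep_null=True)
        b = perm_test(windows, hits, asm, n_perm=200, seed=5, keep_null=True)
        assert (a.null_counts == b.null_counts).all()
        assert a.p_value == b.p_value and a.z_score == b.z_score

    def test_randomize_hits_mode_same_observed(self):
        asm, windows = _simple_setup()
        rng = np.random.default_rng(8)
        hits = RegionSet(
            "h", [Interval("c", int(s), int(s) + 5) for s in rng.integers(0, 990, 30)]
        )
        a = perm_test(windows, hits, asm, n_perm=100, seed=5, randomize="windows")
        b = perm_test(windows, hits, asm, n_perm=100, seed=5, randomize="hits")
        assert a.observed == b.observed

    def test_null_matches_exact_enumeration_tiny_instance(self):
        """Empirical permutation distribution of the overlap statistic vs the
        exactly enumerated placement distribution (3 windows of length 2 on a
        12-bp chromosome): total-variation < 0.05 at n_perm = 20,000."""
        import itertools

        L, wlen, n_w = 12, 2, 3
        asm = GenomeAssembly(chroms=[("c", L)])
        hits = RegionSet("h", [Interval("c", 4, 6), Interval("c", 9, 11)])
        windows = make_windows(
            BreakpointSet("t", [("c", 3), ("c", 6), ("c", 9)]), wlen, asm
        )

        def stat(starts):
            return sum(
                1
                for s in starts
                if any(s < he and hs < s + wlen for hs, he in [(4, 6), (9, 11)])
            )

        valid = range(L - wlen + 1)
        exact = np.zeros(n_w + 1)
        for combo in itertools.product(valid, repeat=n_w):
            exact[stat(combo)] += 1
        exact /= exact.sum()

        r = perm_test(windows, hits, asm, n_perm=20_000, seed=11, keep_null=True)
        emp = np.bincount(r.null_counts, minlength=n_w + 1) / r.n_perm
        tv = 0.5 * np.abs(exact - emp[: n_w + 1]).sum()
        assert tv < 0.05


class TestLocalZ:
    def _enriched(self):
        # hits exactly at window centers, windows isolated by >= 10 x max_shift
        asm = GenomeAssembly(chroms=[("c", 600_000)])
        centers = [10_000 + 55_000 * i for i in range(10)]
        hits = RegionSet("h", [Interval("c", c - 6, c + 7) for c in centers])
        windows = make_windows(BreakpointSet("t", [("c", c) for c in centers]), 100, asm)
        parent = perm_test(windows, hits, asm, n_perm=500, seed=21)
        return asm, windows, hits, parent

    def test_zero_shift_equals_parent_exactly(self):
        asm, windows, hits, parent = self._enriched()
        prof = local_zscore(parent, windows, hits, asm)
        zero = int(np.flatnonzero(prof.shifts == 0)[0])
        assert prof.z_at_shift[zero] == parent.z_score

    def test_shifting_by_a_window_width_destroys_the_signal(self):
        asm, windows, hits, parent = self._enriched()
        prof = local_zscore(parent, windows, hits, asm)  # max_shift 500, step 50
        zero = int(np.flatnonzero(prof.shifts == 0)[0])
        far = np.abs(prof.shifts) >= 100
        assert (prof.z_at_shift[zero] > prof.z_at_shift[far]).all()

    def test_z_decays_to_null_level_at_extreme_shifts(self):
        asm, windows, hits, parent = self._enriched()
        prof = local_zscore(parent, windows, hits, asm)
        assert prof.z_at_shift[0] < prof.z_at_shift[len(prof.shifts) // 2]
        assert prof.z_at_shift[-1] < prof.z_at_shift[len(prof.shifts) // 2]

    def test_undefined_parent_z_rejected(self):
        asm, windows = _simple_setup()
        with pytest.warns(UserWarning):
            parent = perm_test(windows, RegionSet("h", []), asm, n_perm=20, seed=1)
        with pytest.raises(ValueError, match="undefined z"):
            local_zscore(parent, windows, RegionSet("h", []), asm)

    def test_step_must_divide_max_shift(self):
        asm, windows, hits, parent = self._enriched()
        with pytest.raises(ValueError, match="multiple of step"):
            local_zscore(parent, windows, hits, asm, max_shift=100, step=33)


class TestSignificanceRule:
    @pytest.mark.parametrize(
        "p,z,expected",
        [
            (0.2, 1.0, False),
            (0.001, 8.628, True),
            (0.04, 2.9, False),   # |z| too small
            (0.06, 10.0, False),  # p too large
            (0.01, -4.0, True),   # depletion side counts too
        ],
    )
    def test_rule(self, p, z, expected):
        assert is_significant(p, z) is expected


class TestScreenAll:
    def _screen(self, n_perm=100, base_seed=0):
        from prdm9scan import SyntheticConfig, generate_breakpoints, generate_genome, scan_all_variants

        motif = DegenerateMotif("CNNC")
        planted = next(
            v for v in expand_degenerate(motif) if v.sequence == "CCAC"
        )
        cfg = SyntheticConfig(
            n_chroms=1,
            chrom_length=200_000,
            motif=motif,
            planted_variant=planted,
            n_planted_sites=60,
            n_breakpoints=40,
            enrichment_fraction=0.8,
            proximity_distance=20,
            seed=4,
        )
        asm, truth = generate_genome(cfg)
        bset = generate_breakpoints(cfg, truth, label="BRC")
        scan = scan_all_variants(asm, motif)
        variants = expand_degenerate(motif)
        return screen_all(
            variants,
            [bset],
            [100],
            asm,
            n_perm=n_perm,
            base_seed=base_seed,
            hits_by_variant={v.variant_id: scan.per_variant[v.variant_id] for v in variants},
            motif=motif,
        )

    def test_row_count_is_full_cross_product(self):
        st = self._screen()
        assert len(st.table) == 16  # 16 variants x 1 label x 1 width

    def test_planted_variant_flagged_and_top_ranked(self):
        st = self._screen()
        top = st.table.iloc[0]
        assert top["variant_seq"] == "CCAC"
        assert bool(top["significant"])
        planted_id = next(
            v.variant_id for v in expand_degenerate(DegenerateMotif("CNNC")) if v.sequence == "CCAC"
        )
        assert planted_id in st.significant_variants("any")

    def test_sorted_by_p_then_abs_z(self):
        t = self._screen().table
        p = t["p_value"].to_numpy()
        assert (np.diff(p) >= 0).all()

    def test_deterministic_given_base_seed(self, tmp_path):
        a, b = self._screen(base_seed=9), self._screen(base_seed=9)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.to_tsv(pa)
        b.to_tsv(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_combination_seed_stable_and_isolatable(self):
        s = combination_seed(3, 7, "BRC", 100)
        assert s == combination_seed(3, 7, "BRC", 100)
        assert 0 <= s < 2**31
        assert s != combination_seed(3, 7, "BRC", 500)

    def test_q_values_present_for_ok_rows(self):
        t = self._screen().table
        assert t.loc[t["status"] == "ok", "q_value"].notna().all()


class TestConsensus:
    def test_single_sequence(self):
        cm = consensus_motif([MotifVariant("CCACCATCACCAC", 0)])
        assert cm.consensus == "CCACCATCACCAC"
        assert (cm.counts.sum(axis=1) == 1).all()

    def test_iupac_union_of_two(self):
        cm = consensus_motif([MotifVariant("CAT", 0), MotifVariant("CCT", 1)])
        assert cm.consensus == "CMT"
        assert cm.counts[1].tolist() == [1, 1, 0, 0]

    def test_closure_all_expansions_give_back_pattern(self):
        variants = expand_degenerate(DegenerateMotif("CCNCCNTNNCCNC"))
        cm = consensus_motif(variants)
        assert cm.consensus == "CCNCCNTNNCCNC"
        assert (cm.counts.sum(axis=1) == 1024).all()

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="mixed lengths"):
            consensus_motif([MotifVariant("CAT", 0), MotifVariant("CATT", 1)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no variants"):
            consensus_motif([])
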