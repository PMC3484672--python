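"""Simulator laws: library statistics, pooling, detection, sibs, reactions."""

import numpy as np
import pytest
from scipy import stats

from wormko import screensim as ss
from wormko.errors import ConfigError


def scenario(**kw):
    base = dict(
        n_wells=96,
        genomes_per_well=100,
        deletion_rate_per_target=0.001,
        seed=0,
    )
    base.update(kw)
    return ss.ScreenScenario(**base)


def library_with_carriers(sc, wells):
    """Deterministic library: {(plate, row, col): carrier_count}."""
    m = np.zeros((sc.n_plates, sc.plate_rows, sc.plate_cols), dtype=np.int64)
    for (p, r, c), n in wells.items():
        m[p, r, c] = n
    return ss.Library(mutants=m, genomes_per_well=sc.genomes_per_well)


class TestScenario:
    def test_wells_must_fill_whole_plates(self):
        with pytest.raises(ConfigError):
            scenario(n_wells=100)

    def test_published_scale_annotation(self):
        assert scenario(n_wells=960, genomes_per_well=500).published_scale
        assert not scenario(n_wells=96, genomes_per_well=10).published_scale


class TestBuildLibrary:
    def test_rate_zero_and_one(self):
        lib0 = ss.build_library(scenario(deletion_rate_per_target=0.0))
        assert lib0.total_mutants == 0
        lib1 = ss.build_library(scenario(deletion_rate_per_target=1.0))
        assert (lib1.mutants == lib1.genomes_per_well).all()

    def test_total_mutants_within_binomial_band(self):
        sc = scenario(n_wells=960, genomes_per_well=200,
                      deletion_rate_per_target=0.002, seed=42)
        lib = ss.build_library(sc)
        n = sc.n_wells * sc.genomes_per_well
        mean = n * sc.deletion_rate_per_target
        sd = np.sqrt(mean * (1 - sc.deletion_rate_per_target))
        assert abs(lib.total_mutants - mean) < 4 * sd

    def test_deterministic_per_seed(self):
        a = ss.build_library(scenario(seed=7))
        b = ss.build_library(scenario(seed=7))
        assert (a.mutants == b.mutants).all()


class TestPooling:
    def test_twenty_pools_per_96_well_plate(self):
        sc = scenario()
        grid = ss.pool_dna(ss.build_library(sc))
        n_pools = grid.row_fraction.size + grid.col_fraction.size
        assert n_pools == 20

    def test_single_mutant_well_hits_one_row_and_one_column(self):
        sc = scenario()
        lib = library_with_carriers(sc, {(0, 3, 7): 5})
        grid = ss.pool_dna(lib)
        assert (grid.row_mutants > 0).sum() == 1
        assert (grid.col_mutants > 0).sum() == 1
        assert grid.row_mutants[0, 3] == 5 and grid.col_mutants[0, 7] == 5

    def test_mutant_content_conserved_between_views(self):
        sc = scenario(seed=3, deletion_rate_per_target=0.01)
        lib = ss.build_library(sc)
        grid = ss.pool_dna(lib)
        row_content = (grid.row_fraction * sc.plate_cols).sum()
        col_content = (grid.col_fraction * sc.plate_rows).sum()
        total = lib.well_fraction().sum()
        assert row_content == pytest.approx(total)
        assert col_content == pytest.approx(total)


class TestScreenPools:
    def test_full_sensitivity_always_detects(self):
        sc = scenario(pcr_sensitivity=1.0)
        lib = library_with_carriers(sc, {(0, 2, 5): 1})
        grid = ss.pool_dna(lib)
        for seed in range(50):
            screen = ss.screen_pools(grid, sc, np.random.default_rng(seed))
            assert screen.positive_rows == ((0, 2),)
            assert screen.positive_cols == ((0, 5),)

    def test_mutant_free_library_never_fires(self):
        sc = scenario(deletion_rate_per_target=0.0, pcr_sensitivity=0.9)
        grid = ss.pool_dna(ss.build_library(sc))
        for seed in range(500):
            assert not ss.screen_pools(
                grid, sc, np.random.default_rng(seed)
            ).any_positive

    def test_duplicate_or_rule_closed_form(self):
        # One template at s = 0.5 under duplicate screening: 1-(1-s)^2 = 0.75.
        assert ss.detection_probability(1, 0.5, duplicate=True) == 0.75
        assert ss.detection_probability(1, 0.5, duplicate=False) == 0.5
        assert ss.detection_probability(0, 1.0, duplicate=True) == 0.0

    def test_single_template_empirical_rate(self):
        # Tiny aliquot: the zero-truncated Poisson degenerates to one
        # template, so the duplicate positive rate is 0.75 at s = 0.5.
        sc = scenario(pcr_sensitivity=0.5, duplicate_screening=True,
                      templates_per_reaction=1e-9)
        lib = library_with_carriers(sc, {(0, 0, 0): 1})
        grid = ss.pool_dna(lib)
        rng = np.random.default_rng(77)
        n = 10_000
        hits = sum(
            bool(ss.screen_pools(grid, sc, rng).positive_rows) for _ in range(n)
        )
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(hits / n - 0.75) < 4 * se


class TestAddressing:
    def test_single_intersection(self):
        sc = scenario(pcr_sensitivity=1.0)
        lib = library_with_carriers(sc, {(0, 2, 5): 3})
        grid = ss.pool_dna(lib)
        screen = ss.screen_pools(grid, sc, np.random.default_rng(0))
        addr = ss.address_positive(grid, lib, screen, sc, np.random.default_rng(0))
        assert addr.confirmed_wells == ((0, 2, 5),)
        assert addr.reactions == 1
        assert not addr.lost_at_addressing

    def test_two_by_two_gives_four_candidates(self):
        sc = scenario(pcr_sensitivity=1.0)
        lib = library_with_carriers(sc, {(0, 1, 2): 3, (0, 4, 9): 3})
        grid = ss.pool_dna(lib)
        screen = ss.screen_pools(grid, sc, np.random.default_rng(0))
        addr = ss.address_positive(grid, lib, screen, sc, np.random.default_rng(0))
        assert addr.reactions == 4
        assert set(addr.confirmed_wells) == {(0, 1, 2), (0, 4, 9)}

    def test_false_negative_column_raises_lost_flag(self):
        # A positive row with no positive column on the plate cannot be
        # addressed; reachable at s < 1 for some seed.
        sc = scenario(pcr_sensitivity=0.5, duplicate_screening=False,
                      templates_per_reaction=1e-9)
        lib = library_with_carriers(sc, {(0, 2, 5): 1})
        grid = ss.pool_dna(lib)
        seen_lost = False
        for seed in range(200):
            rng = np.random.default_rng(seed)
            screen = ss.screen_pools(grid, sc, rng)
            if bool(screen.positive_rows) != bool(screen.positive_cols):
                addr = ss.address_positive(grid, lib, screen, sc, rng)
                assert addr.lost_at_addressing
                assert addr.confirmed_wells == ()
                seen_lost = True
                break
        assert seen_lost


class TestSibSelection:
    def test_nonlethal_full_carrier_reaches_homozygosity_fast(self):
        # With every animal heterozygous and s = 1, each 24-pick round
        # terminates homozygous with probability >= 1 - (3/4)^24 ~ 0.999.
        sc = scenario(pcr_sensitivity=1.0, sib_plan=(24, 24, 24))
        n_hom_round1 = 0
        for seed in range(100):
            res = ss.run_sib_selection(
                sc.genomes_per_well, sc, np.random.default_rng(seed)
            )
            assert res.recovered == "homozygous"
            if len(res.rounds) == 1:
                n_hom_round1 += 1
        assert n_hom_round1 >= 95

    def test_lethal_never_recovers_homozygous(self):
        sc = scenario(pcr_sensitivity=1.0, lethal=True, sib_plan=(24, 24, 24))
        for seed in range(200):
            res = ss.run_sib_selection(
                sc.genomes_per_well, sc, np.random.default_rng(seed)
            )
            assert res.recovered in ("persistent_heterozygous", "lost")

    def test_selfing_segregation_1_2_1(self, rng):
        wt, het, hom = ss.mendelian_offspring(rng, 0, 1, 0, 10_000, lethal=False)
        chi2 = stats.chisquare([wt, het, hom], f_exp=[2500, 5000, 2500])
        assert chi2.pvalue > 0.01

    def test_lethal_selfing_survivors_2_to_1(self):
        rng = np.random.default_rng(0)
        wt, het, hom = ss.mendelian_offspring(rng, 0, 1, 0, 10_000, lethal=True)
        assert hom == 0
        chi2 = stats.chisquare([wt, het], f_exp=[(wt + het) / 3, 2 * (wt + het) / 3])
        assert chi2.pvalue > 0.01

    def test_het_fraction_halves_per_generation(self):
        rng = np.random.default_rng(8)
        wt, het, hom = 0, 1, 0
        for gen in range(1, 5):
            wt, het, hom = ss.mendelian_offspring(
                rng, wt, het, hom, 200_000, lethal=False
            )
            frac = het / (wt + het + hom)
            expect = 0.5 ** gen
            se = np.sqrt(expect * (1 - expect) / 200_000)
            assert abs(frac - expect) < 5 * se

    def test_round_trace_records_each_round(self):
        sc = scenario(pcr_sensitivity=1.0, lethal=True, sib_plan=(24, 12, 6))
        res = ss.run_sib_selection(sc.genomes_per_well, sc,
                                   np.random.default_rng(1))
        assert [t.wells_tested for t in res.rounds] == [24, 12, 6]
        assert res.sib_reactions == 42


class TestReactions:
    def test_ten_plates_duplicate_no_hits(self):
        sc = scenario(n_wells=960, deletion_rate_per_target=0.0,
                      duplicate_screening=True)
        res = ss.run_screen(sc)
        counts = ss.count_reactions(res, sc)
        assert counts["pool_reactions"] == 400
        assert counts["total"] == 400
        assert counts["baseline_no_pooling"] == 960

    def test_single_hit_full_path_113(self):
        sc = scenario(pcr_sensitivity=1.0, lethal=True, sib_plan=(24, 24, 24))
        rng = np.random.default_rng(5)
        lib = library_with_carriers(sc, {(0, 2, 5): sc.genomes_per_well})
        grid = ss.pool_dna(lib)
        screen = ss.screen_pools(grid, sc, rng)
        addr = ss.address_positive(grid, lib, screen, sc, rng)
        sib = ss.run_sib_selection(sc.genomes_per_well, sc, rng)
        total = screen.reactions + addr.reactions + sib.sib_reactions
        assert (screen.reactions, addr.reactions, sib.sib_reactions) == (40, 1, 72)
        assert total == 113

    def test_pooling_beats_per_well_screening(self):
        sc = scenario(n_wells=960, deletion_rate_per_target=0.0,
                      duplicate_screening=False)
        res = ss.run_screen(sc)
        assert res.reactions_used < sc.n_wells

    def test_empty_trace_counts_zero(self):
        sc = scenario()
        res = ss.ScreenResult(
            detected=False, addressed_well=None, rounds=(),
            recovered="lost", reactions_used=0,
        )
        assert ss.count_reactions(res, sc)["total"] == 0


class TestEndToEnd:
    def test_run_screen_reproducible_per_seed(self):
        sc = scenario(n_wells=96, genomes_per_well=200,
                      deletion_rate_per_target=0.005, seed=11)
        assert ss.run_screen(sc) == ss.run_screen(sc)

    def test_detection_monotone_in_sensitivity(self):
        # Coupled runs (same seeds, identical draw sequence) make pool
        # detection pointwise monotone in s.
        base = dict(n_wells=96, genomes_per_well=100,
                    deletion_rate_per_target=0.0, duplicate_screening=False,
                    templates_per_reaction=1e-9)
        rates = []
        for s in (0.2, 0.5, 0.8, 1.0):
            sc = ss.ScreenScenario(pcr_sensitivity=s, **base)
            hits = 0
            for seed in range(200):
                lib = library_with_carriers(sc, {(0, 4, 4): 1})
                screen = ss.screen_pools(
                    ss.pool_dna(lib), sc, np.random.default_rng(seed)
                )
                hits += screen.any_positive
            rates.append(hits)
        assert rates == sorted(rates)
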