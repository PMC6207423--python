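"""Synthetic generators: determinism, degenerate settings, ground truth."""

import numpy as np
import pytest

from manakin.io_formats import read_table, write_table, FATIGUE_SCHEMA
from manakin.range_reconstruction import percent_overlap
from manakin.synthetic_data import (
    DisplaySpeciesConfig,
    RangeSimConfig,
    TwitchSpeciesConfig,
    default_display_configs,
    default_twitch_configs,
    displays_to_table,
    phases_to_table,
    simulate_bm_ranges,
    simulate_display_population,
    simulate_twitch_trains,
    trains_to_table,
)
from manakin.twitch_kinetics import fatigue_slope


class TestRanges:
    def test_deterministic(self):
        a = simulate_bm_ranges(seed=2)
        b = simulate_bm_ranges(seed=2)
        for sp in a.tip_polygons:
            assert a.tip_polygons[sp].geom.equals(b.tip_polygons[sp].geom)

    def test_zero_rate_keeps_root_shape(self):
        sim = simulate_bm_ranges(RangeSimConfig(sigma2=0.0), seed=0)
        polys = list(sim.true_polygons.values())
        for p in polys[1:]:
            assert percent_overlap(p, polys[0]) == pytest.approx(100.0, abs=1e-6)

    def test_all_nodes_have_truth(self):
        sim = simulate_bm_ranges(seed=1)
        assert set(sim.true_polygons) == set(sim.tree.labels)
        assert set(sim.tip_polygons) == set(sim.tree.tip_labels)
        for pts in sim.true_points.values():
            assert pts.as_array().shape == (12, 2)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_bm_ranges(RangeSimConfig(sigma2=-1.0))

    def test_overlap_decreases_with_rate(self):
        """Sister-tip overlap under high diffusion is (on average) below
        the near-zero-rate overlap."""
        lo_vals, hi_vals = [], []
        for seed in range(10):
            lo = simulate_bm_ranges(RangeSimConfig(sigma2=1e-6), seed=seed)
            hi = simulate_bm_ranges(RangeSimConfig(sigma2=3e-3), seed=seed)
            lo_vals.append(percent_overlap(lo.tip_polygons["candei"],
                                           lo.tip_polygons["aurantiacus"]))
            hi_vals.append(percent_overlap(hi.tip_polygons["candei"],
                                           hi.tip_polygons["aurantiacus"]))
        assert np.mean(hi_vals) < np.mean(lo_vals)


class TestDisplays:
    def test_deterministic(self):
        ra, _ = simulate_display_population(seed=5)
        rb, _ = simulate_display_population(seed=5)
        assert ra.equals(rb)

    def test_default_study_scale(self):
        records, truth = simulate_display_population(seed=0)
        counts = records.groupby("species")["individual"].nunique()
        assert counts["golden_collared"] == 34
        assert counts["white_collared"] == 24
        assert counts["orange_collared"] == 25
        assert counts["white_bearded"] == 76
        assert truth["golden_collared"]["bound_slope"] == -0.56
        assert truth["orange_collared"]["onset_quantile"] is None

    def test_hard_cap_binds_fraction(self):
        """With onset quantile q and no length variation (so the cap is the
        same line for everyone), about 1-q of individuals are capped."""
        cfg = DisplaySpeciesConfig(name="x", n_individuals=600,
                                   mean_speed=58.0, bound_slope=-0.5,
                                   onset_quantile=0.2, length_sd=0.0)
        _, truth = simulate_display_population(cfg, seed=1)
        assert truth["x"]["fraction_capped"] == pytest.approx(0.8, abs=0.06)

    def test_no_constraint_no_capping(self):
        cfg = DisplaySpeciesConfig(name="x", n_individuals=50, mean_speed=55.0)
        records, truth = simulate_display_population(cfg, seed=2)
        assert truth["x"]["fraction_capped"] == 0.0

    def test_soft_mechanism_allowed(self):
        cfg = DisplaySpeciesConfig(name="x", n_individuals=40, mean_speed=55.0,
                                   bound_slope=-0.5, onset_quantile=0.5,
                                   mechanism="soft")
        records, _ = simulate_display_population(cfg, seed=3)
        assert len(records) > 0

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            DisplaySpeciesConfig(name="x", n_individuals=5, mean_speed=55.0,
                                 onset_quantile=1.5)
        with pytest.raises(ValueError):
            DisplaySpeciesConfig(name="x", n_individuals=5, mean_speed=55.0,
                                 individual_sd=-1.0)

    def test_table_roundtrip(self, tmp_path):
        records, _ = simulate_display_population(seed=4)
        table = displays_to_table(records)
        p = tmp_path / "acoustics.tsv"
        write_table(table, p)
        back = read_table(p, table.schema)
        assert len(back) == len(table)

    def test_calibrated_golden_mean(self):
        """Observed golden-collared mean display speed sits near 58.4 Hz."""
        means = []
        for seed in range(5):
            records, _ = simulate_display_population(seed=seed)
            g = records[records.species == "golden_collared"]
            means.append(g.groupby("individual")["speed"].mean().mean())
        assert np.mean(means) == pytest.approx(58.4, abs=0.8)


class TestTwitch:
    def test_deterministic(self):
        a = simulate_twitch_trains(seed=3)
        b = simulate_twitch_trains(seed=3)
        for ta, tb in zip(a.trains, b.trains):
            assert np.array_equal(ta.percent_relaxation, tb.percent_relaxation)

    def test_kappa_zero_flat_slopes(self):
        cfg = TwitchSpeciesConfig(name="x", kappa=0.0, noise_sd=0.0,
                                  fourpl=(100.0, 0.0, 0.1, 200.0))
        sim = simulate_twitch_trains(cfg, seed=0)
        for f in cfg.frequencies:
            fs = fatigue_slope([t for t in sim.trains if t.frequency_hz == f])
            assert fs.slope == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_slopes_match_truth(self):
        cfg = TwitchSpeciesConfig(name="x", kappa=0.3, noise_sd=0.0,
                                  critical_frequency=60.0,
                                  fourpl=(100.0, 0.0, 0.05, 150.0))
        sim = simulate_twitch_trains(cfg, seed=0)
        for f, expected in sim.truth["expected_slopes"].items():
            fs = fatigue_slope([t for t in sim.trains if t.frequency_hz == f])
            assert fs.slope == pytest.approx(expected, abs=1e-9)

    def test_replicate_and_control_structure(self):
        cfg = default_twitch_configs()["golden_collared"]
        sim = simulate_twitch_trains(cfg, seed=1)
        assert len(sim.trains) == (cfg.n_individuals * len(cfg.frequencies)
                                   * cfg.n_replicates)
        assert len(sim.control_first) == cfg.n_individuals
        assert len(sim.control_repeat) == cfg.n_individuals
        assert sim.control_first[0].frequency_hz == cfg.control_frequency

    def test_tables_roundtrip(self, tmp_path):
        sim = simulate_twitch_trains(seed=2)
        table = trains_to_table(sim.trains)
        p = tmp_path / "fatigue.tsv"
        write_table(table, p)
        back = read_table(p, FATIGUE_SCHEMA)
        assert len(back) == len(table)
        phases = phases_to_table(sim.trains)
        assert {"shortening_ms", "lengthening_ms"} <= set(phases.df.columns)

    def test_defaults_match_protocols(self):
        cfgs = default_twitch_configs()
        assert cfgs["golden_collared"].frequencies == (30, 40, 50, 60, 70, 80,
                                                       90, 100)
        assert cfgs["white_collared"].frequencies == (30, 40, 50, 55, 58, 65,
                                                      70, 80, 90)
        assert cfgs["golden_collared"].control_frequency == 20.0
        assert cfgs["white_collared"].control_frequency == 30.0
        assert cfgs["white_collared"].kappa == 0.0

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            TwitchSpeciesConfig(name="x", kappa=-0.1)
        with pytest.raises(ValueError):
            TwitchSpeciesConfig(name="x", critical_frequency=0.0)
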