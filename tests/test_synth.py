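"""Ground-truth generator: determinism, composition model, distributions."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

import isletmorph as im
from isletmorph.synth import (
    GeneratorConfig,
    composition_for_size,
    donor_islet_table,
    expected_beta_share,
    generate_donor,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"endocrine_fraction_head": -0.1},
            {"endocrine_fraction_tail": 1.5},
            {"pixel_size_um": 0.0},
            {"n_blocks": -1},
            {"pancreas_weight_g": 0.0},
            {"beta_fraction_small": 0.95, "delta_fraction": 0.2},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            GeneratorConfig(**kw)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = GeneratorConfig(seed=9, n_blocks=3)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert GeneratorConfig.from_yaml(tmp_path / "cfg.yaml") == cfg


class TestComposition:
    def test_small_islets_sixty_percent_beta(self):
        cfg = GeneratorConfig()
        for cells in (1, 4, 20, 40):  # all < 100 µm effective diameter
            beta, alpha, delta = composition_for_size(cells, cfg)
            assert beta == pytest.approx(0.60)
            assert delta == pytest.approx(cfg.delta_fraction)

    def test_zero_slope_uniform_composition(self):
        cfg = GeneratorConfig(beta_fraction_slope_per_log2bin=0.0)
        assert composition_for_size(2, cfg) == composition_for_size(5000, cfg)

    def test_beta_declines_in_large_bins(self):
        cfg = GeneratorConfig()
        small = composition_for_size(10, cfg)
        large = composition_for_size(2**10, cfg)
        assert large[0] < small[0]
        assert large[1] > small[1]  # alpha picks up the difference

    @given(
        cells=st.floats(min_value=1.0, max_value=1e6),
        slope=st.floats(min_value=-0.2, max_value=0.2),
    )
    def test_fractions_valid_and_sum_to_one(self, cells, slope):
        cfg = GeneratorConfig(beta_fraction_slope_per_log2bin=slope)
        beta, alpha, delta = composition_for_size(cells, cfg)
        assert abs(beta + alpha + delta - 1.0) < 1e-9
        for f in (beta, alpha, delta):
            assert -1e-12 <= f <= 1.0 + 1e-12


class TestGenerateDonor:
    def test_empty_donor(self):
        donor = generate_donor(GeneratorConfig(n_blocks=0, seed=5))
        assert donor.islets == []
        assert all(v == 0.0 for v in donor.true_mass_mg.values())

    def test_determinism(self):
        cfg = GeneratorConfig(n_blocks=4, section_size_px=(1024, 1024), seed=11)
        a, b = generate_donor(cfg), generate_donor(cfg)
        assert a.true_mass_mg == b.true_mass_mg
        assert a.islets == b.islets
        assert np.array_equal(a.true_block_fractions, b.true_block_fractions)

    def test_degenerate_size_distribution(self):
        cfg = GeneratorConfig(
            n_blocks=2,
            section_size_px=(2048, 2048),
            islet_size_log_mean=math.log(16.0),
            islet_size_log_sd=0.0,
            seed=3,
        )
        donor = generate_donor(cfg)
        assert len(donor.islets) > 10
        for s in donor.islets:
            assert s.cell_count == pytest.approx(16.0, rel=1e-12)
            assert im.effective_diameter(s.true_area_um2) == pytest.approx(60.2, abs=0.1)

    def test_ground_truth_consistency(self, table_donor):
        """Tissue-weighted block fractions equal the donor-level fraction."""
        donor, _ = table_donor
        w = donor.block_tissue_areas_um2
        weighted = float(np.average(donor.true_block_fractions, weights=w))
        donor_frac = donor.true_mass_mg["endocrine"] / (
            donor.config.pancreas_weight_g * 1000.0
        )
        assert weighted == pytest.approx(donor_frac, abs=1e-12)
        # and it tracks the configured mean closely
        assert weighted == pytest.approx(donor.config.donor_endocrine_fraction, rel=0.01)

    def test_mass_consistency_per_hormone(self, table_donor):
        donor, _ = table_donor
        total_tissue = donor.block_tissue_areas_um2.sum()
        beta_area = sum(s.beta_fraction * s.true_area_um2 for s in donor.islets)
        expect = beta_area / total_tissue * donor.config.pancreas_weight_g * 1000.0
        assert donor.true_mass_mg["beta"] == pytest.approx(expect, rel=1e-12)

    def test_head_to_tail_gradient(self):
        cfg = GeneratorConfig(seed=2, block_noise_cv=0.1)
        donor = generate_donor(cfg)
        from scipy import stats

        rho = stats.spearmanr(
            np.arange(cfg.n_blocks), donor.true_block_fractions
        ).statistic
        assert rho > 0.5

    def test_size_distribution_recovery(self):
        """Empirical log cell-count moments match the configured log-normal
        conditioned on >= 1 cell (closed-form truncated-normal oracle)."""
        from scipy import stats

        cfg = GeneratorConfig(n_blocks=112, seed=4)
        donor = generate_donor(cfg)
        logs = np.log([s.cell_count for s in donor.islets])
        n = len(logs)
        assert n >= 10_000
        a = (0.0 - cfg.islet_size_log_mean) / cfg.islet_size_log_sd
        tn = stats.truncnorm(
            a, np.inf, loc=cfg.islet_size_log_mean, scale=cfg.islet_size_log_sd
        )
        t_mean, t_var = tn.stats()
        t_sd = math.sqrt(float(t_var))
        assert abs(logs.mean() - float(t_mean)) < 3 * t_sd / math.sqrt(n)
        assert abs(logs.std(ddof=1) - t_sd) < 3 * t_sd / math.sqrt(2 * n)


class TestTableMode:
    def test_records_mirror_ground_truth(self, table_donor):
        donor, records = table_donor
        assert len(records) == len(donor.islets)
        r, s = records[0], donor.islets[0]
        assert r.area_um2 == pytest.approx(s.true_area_um2)
        assert r.beta_area_um2 == pytest.approx(s.beta_fraction * s.true_area_um2)
        assert r.feret_um == pytest.approx(2 * s.semi_axes_um[0])
        assert 0 < r.circularity <= 1.0

    def test_default_scale_produces_thousands_of_islets(self, table_donor):
        _, records = table_donor
        assert len(records) >= 2000


class TestTargetCalibration:
    def test_expected_share_matches_monte_carlo(self):
        cfg = GeneratorConfig()
        rng = np.random.default_rng(0)
        n = rng.lognormal(cfg.islet_size_log_mean, cfg.islet_size_log_sd, 400_000)
        n = n[n >= 1.0]  # generator sizes are conditioned on >= 1 cell
        beta = np.array([composition_for_size(x, cfg)[0] for x in n])
        mc = float((beta * n).sum() / n.sum())
        assert expected_beta_share(cfg) == pytest.approx(mc, abs=0.005)

    def test_config_hits_target_beta_pct(self):
        cfg = im.config_for_target_beta_pct(0.7, n_blocks=12, seed=21)
        donor = generate_donor(cfg)
        assert donor.true_pct["beta"] == pytest.approx(0.7, rel=0.03)
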