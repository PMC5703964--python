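"""Block aggregation, regional profiles and mass conversion."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import isletmorph as im
from isletmorph.quantify import IsletRecord
from isletmorph.stereology import BlockSummary, DonorMetadata


def _islet(area, beta=None, block=1, rid="i1"):
    beta = area if beta is None else beta
    return IsletRecord(
        islet_id=rid, donor_id="d", block_index=block,
        area_um2=area, perimeter_um=1.0, circularity=1.0, feret_um=1.0,
        beta_area_um2=beta, alpha_area_um2=0.0, delta_area_um2=0.0,
        centroid_x_um=0.0, centroid_y_um=0.0,
    )


def _block(idx, pct, tissue=1e6):
    return BlockSummary(
        block_index=idx, tissue_area_um2=tissue,
        endocrine_area_um2=pct / 100 * tissue,
        beta_area_um2=pct / 100 * tissue, alpha_area_um2=0.0, delta_area_um2=0.0,
    )


META = DonorMetadata(donor_id="d", age=41.0, sex="M", bmi=24.0, pancreas_weight_g=100.0)


class TestBlockSummary:
    def test_no_islets_zero_percent(self):
        b = im.block_summary([], 1e6, 1)
        assert b.pct_endocrine == b.pct_beta == 0.0

    def test_percent_arithmetic(self):
        b = im.block_summary([_islet(1000.0)], 1_000_000.0, 1)
        assert b.pct_beta == pytest.approx(0.1)
        assert b.pct_endocrine == pytest.approx(0.1)

    def test_zero_tissue_raises(self):
        with pytest.raises(ValueError):
            im.block_summary([], 0.0, 1)

    def test_wrong_block_raises(self):
        with pytest.raises(ValueError):
            im.block_summary([_islet(10.0, block=2)], 1e6, 1)

    def test_matches_generator_block_fraction(self, table_donor):
        donor, records = table_donor
        b1 = [r for r in records if r.block_index == 1]
        summary = im.block_summary(b1, float(donor.block_tissue_areas_um2[0]), 1)
        assert summary.pct_endocrine == pytest.approx(
            100 * donor.true_block_fractions[0], rel=1e-9
        )


class TestRegionalProfile:
    def test_identical_blocks_zero_sem(self):
        prof = im.regional_profile([_block(i, 0.5) for i in range(1, 6)])
        assert prof.sem_pct == 0.0
        assert prof.mean_pct == pytest.approx(0.5)

    def test_closed_form_sem(self):
        prof = im.regional_profile([_block(1, 1.0), _block(2, 2.0), _block(3, 3.0)])
        assert prof.mean_pct == pytest.approx(2.0)
        assert prof.sem_pct == pytest.approx(1.0 / math.sqrt(3.0))

    def test_weighted_mean_uses_tissue_areas(self):
        blocks = [_block(1, 1.0, tissue=3e6), _block(2, 4.0, tissue=1e6)]
        prof = im.regional_profile(blocks)
        assert prof.mean_pct == pytest.approx(2.5)
        assert prof.weighted_mean_pct == pytest.approx(1.75)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            im.regional_profile([])

    def test_gradient_reproduced(self, table_donor):
        """Blocks trend upward head→tail as configured in the generator."""
        from scipy import stats

        donor, records = table_donor
        blocks = [
            im.block_summary(
                [r for r in records if r.block_index == b + 1],
                float(donor.block_tissue_areas_um2[b]),
                b + 1,
            )
            for b in range(donor.config.n_blocks)
        ]
        prof = im.regional_profile(blocks)
        rho = stats.spearmanr(np.arange(len(blocks)), prof.pct_series).statistic
        assert rho > 0.3


class TestMass:
    def test_zero_percent_zero_mass(self):
        blocks = [_block(1, 0.0)]
        blocks[0].beta_area_um2 = 0.0
        est = im.donor_mass_from_blocks(blocks, META)
        assert est.mass_beta_mg == 0.0

    def test_mass_arithmetic(self):
        est = im.donor_mass_from_blocks([_block(1, 0.5)], META)
        assert est.mass_beta_mg == pytest.approx(500.0)
        assert est.volume_beta_ul == pytest.approx(500.0)  # density 1 g/mL

    @given(st.floats(min_value=50.0, max_value=300.0))
    def test_weight_linearity(self, weight):
        blocks = [_block(1, 0.4), _block(2, 0.8)]
        m1 = im.donor_mass_from_blocks(blocks, META)
        meta2 = DonorMetadata("d", 41.0, "M", 24.0, pancreas_weight_g=2 * META.pancreas_weight_g)
        m2 = im.donor_mass_from_blocks(blocks, meta2)
        assert m2.mass_beta_mg == pytest.approx(2 * m1.mass_beta_mg)
        assert m2.pct_beta == m1.pct_beta

    def test_additivity_without_endocrine_profile(self):
        prof = {
            name: im.regional_profile([_block(1, 0.3)], metric="pct_beta")
            for name in ("beta", "alpha", "delta")
        }
        est = im.estimate_mass(prof, META)
        assert est.mass_endocrine_mg == pytest.approx(
            est.mass_beta_mg + est.mass_alpha_mg + est.mass_delta_mg
        )

    def test_missing_weight_rejected(self):
        with pytest.raises(ValueError):
            DonorMetadata("d", 41.0, "M", 24.0, pancreas_weight_g=-1.0)

    def test_density_scales_volume_not_mass(self):
        est = im.donor_mass_from_blocks([_block(1, 0.5)], META, density_g_per_ml=1.1)
        assert est.mass_beta_mg == pytest.approx(500.0)
        assert est.volume_beta_ul == pytest.approx(500.0 / 1.1)

    def test_table_mode_recovery_over_seeds(self):
        """Aggregation recovers generator truth across 20 seeded donors."""
        errs = []
        for seed in range(20):
            cfg = im.GeneratorConfig(
                n_blocks=8, section_size_px=(2000, 2000), seed=seed
            )
            report, donor = im.run_synthetic_pipeline(cfg, table_only=True)
            errs.append(report.mass.pct_beta / donor.true_pct["beta"] - 1.0)
        errs = np.abs(errs)
        assert np.median(errs) <= 0.05


class TestTissueDensity:
    @pytest.mark.parametrize("m,v", [(100.0, 100.0), (77.0, 77.0)])
    def test_unit_density(self, m, v):
        assert im.tissue_density(m, v) == pytest.approx(1.0)

    def test_nonpositive_volume_raises(self):
        with pytest.raises(ValueError):
            im.tissue_density(100.0, 0.0)

    def test_density_fit_matches_lstsq_oracle(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(50, 250, size=64)
        m = 1.02 * v + rng.normal(0, 5, size=64)
        fit = im.density_fit(m, v)
        oracle = float(np.linalg.lstsq(v[:, None], m, rcond=None)[0][0])
        assert fit == pytest.approx(oracle, rel=1e-12)
        assert fit == pytest.approx(1.0, abs=0.05)
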