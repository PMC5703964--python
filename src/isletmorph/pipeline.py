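"""End-to-end orchestration: quantify → stereology → sizedist → isletcount.

`analyze_donor` is the single entry point both for measured data (islet
records plus per-block tissue areas plus donor metadata) and for
synthetic donors (`run_synthetic_pipeline`, which optionally rasterizes
and re-segments every block to exercise the imaging stage, or takes the
fast analytic table route).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import io as iomod
from .isletcount import IEQConstants, IsletNumberEstimate, islet_numbers
from .quantify import IsletRecord, SegParams, segment_structures, tissue_area
from .sizedist import BinSummary, bin_summaries
from .stereology import (
    BlockSummary,
    DonorMetadata,
    MassEstimate,
    RegionalProfile,
    block_summary,
    estimate_mass,
    regional_profile,
)
from .synth import GeneratorConfig, SyntheticDonor, donor_islet_table, generate_donor, render_block

log = logging.getLogger(__name__)


@dataclass
class DonorReport:
    """Everything the pipeline computes for one donor."""

    metadata: DonorMetadata
    blocks: list[BlockSummary]
    profiles: dict[str, RegionalProfile]
    mass: MassEstimate
    bins: list[BinSummary]
    counts: IsletNumberEstimate
    islets: list[IsletRecord] = field(default_factory=list, repr=False)
    seed: int | None = None

    def summary(self) -> dict:
        """Compact JSON-serializable summary."""
        return {
            "donor_id": self.metadata.donor_id,
            "seed": self.seed,
            "n_blocks": len(self.blocks),
            "n_islets": len(self.islets),
            "pct_beta": self.mass.pct_beta,
            "pct_alpha": self.mass.pct_alpha,
            "pct_delta": self.mass.pct_delta,
            "pct_endocrine": self.mass.pct_endocrine,
            "mass_beta_mg": self.mass.mass_beta_mg,
            "mass_endocrine_mg": self.mass.mass_endocrine_mg,
            "mean_pct_endocrine_blocks": self.profiles["endocrine"].mean_pct,
            "sem_pct_endocrine_blocks": self.profiles["endocrine"].sem_pct,
            **{k: v for k, v in self.counts.rounded().items() if k != "per_bin"},
        }


def analyze_donor(
    islets: Sequence[IsletRecord],
    block_tissue_areas_um2: Mapping[int, float],
    metadata: DonorMetadata,
    constants: IEQConstants = IEQConstants(),
    seed: int | None = None,
) -> DonorReport:
    """Aggregate measured islets into the full donor report."""
    blocks = []
    by_block: dict[int, list[IsletRecord]] = {b: [] for b in block_tissue_areas_um2}
    for r in islets:
        if r.block_index not in by_block:
            raise ValueError(f"islet {r.islet_id} in unknown block {r.block_index}")
        by_block[r.block_index].append(r)
    for b in sorted(block_tissue_areas_um2):
        blocks.append(block_summary(by_block[b], block_tissue_areas_um2[b], b))
    profiles = {
        name: regional_profile(blocks, metric=f"pct_{name}")
        for name in ("beta", "alpha", "delta", "endocrine")
    }
    mass = estimate_mass(profiles, metadata, constants.density_g_per_ml)
    bins = bin_summaries(islets)
    counts = islet_numbers(mass, bins, islets, constants)
    return DonorReport(
        metadata=metadata,
        blocks=blocks,
        profiles=profiles,
        mass=mass,
        bins=bins,
        counts=counts,
        islets=list(islets),
        seed=seed,
    )


def run_synthetic_pipeline(
    config: GeneratorConfig,
    table_only: bool = True,
    seg_params: SegParams | None = None,
    out_dir: str | Path | None = None,
) -> tuple[DonorReport, SyntheticDonor]:
    """Generate a synthetic donor and push it through the whole pipeline.

    In table mode the analytic ground-truth measurement table feeds the
    aggregation stages directly; otherwise every block is rasterized,
    segmented and measured, so the report reflects the imaging pipeline
    end to end. Returns (report, donor-with-ground-truth).
    """
    donor = generate_donor(config)
    tissue_areas = {
        b + 1: float(donor.block_tissue_areas_um2[b]) for b in range(config.n_blocks)
    }
    if table_only:
        records = donor_islet_table(donor)
    else:
        seg_params = seg_params or SegParams()
        records = []
        for b in range(1, config.n_blocks + 1):
            image = render_block(donor, b)
            tissue_areas[b] = tissue_area(image, seg_params)
            records.extend(segment_structures(image, seg_params))
            if out_dir is not None:
                iomod.write_section(image, Path(out_dir) / f"block_{b:02d}.tiff")
    report = analyze_donor(
        records,
        tissue_areas,
        donor.metadata,
        IEQConstants(density_g_per_ml=config.tissue_density_g_per_ml),
        seed=config.seed,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        iomod.write_islet_table(records, out / "islets.csv")
        iomod.write_block_table(report.blocks, out / "blocks.csv")
        iomod.write_bin_table(report.bins, out / "bins.csv")
        iomod.write_metadata(donor.metadata, out / "metadata.json")
        iomod.write_mass_estimate(report.mass, out / "mass.json")
    return report, donor


def cohort_correlations(
    reports: Sequence[DonorReport],
) -> dict[str, dict[str, float]]:
    """Descriptive Pearson correlations of beta mass against donor covariates.

    Returns {covariate: {"r": r, "n": n}} for BMI, age and pancreas
    weight. Requires at least 3 donors; otherwise returns {} with a
    warning. Correlations are reported descriptively (no significance
    gatekeeping).
    """
    if len(reports) < 3:
        log.warning("cohort correlations need >=3 donors, got %d", len(reports))
        return {}
    mass_beta = np.array([r.mass.mass_beta_mg for r in reports])
    covs = {
        "bmi": np.array([r.metadata.bmi for r in reports]),
        "age": np.array([r.metadata.age for r in reports]),
        "pancreas_weight_g": np.array(
            [r.metadata.pancreas_weight_g for r in reports]
        ),
    }
    out = {}
    for name, x in covs.items():
        if np.std(x) == 0 or np.std(mass_beta) == 0:
            out[name] = {"r": float("nan"), "n": len(reports)}
            continue
        r, _ = stats.pearsonr(mass_beta, x)
        out[name] = {"r": float(r), "n": len(reports)}
    return out
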