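"""Fractional-area stereology: block summaries, regional profiles, mass.

The whole-organ estimator is classical area-fraction stereology: the
fraction of section area occupied by endocrine tissue is taken as the
volume fraction of the organ (Delesse principle), and absolute mass
follows from the measured pancreas weight and a tissue density of
~1 g/mL:

    mass_x [mg] = (pct_x / 100) * pancreas_weight [g] * 1000

Per-block percentages build the head→tail regional profile; the
donor-level fraction is the tissue-area-weighted mean over blocks (the
unbiased whole-organ estimator), with the unweighted mean ± SEM also
reported as the conventional summary bar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .constants import DEFAULT_DENSITY_G_PER_ML
from .quantify import IsletRecord


@dataclass
class DonorMetadata:
    donor_id: str
    age: float
    sex: str
    bmi: float
    pancreas_weight_g: float
    height_cm: float | None = None
    diabetes_status: str = "non-diabetic"

    def __post_init__(self) -> None:
        if self.pancreas_weight_g <= 0:
            raise ValueError("pancreas_weight_g must be positive")


@dataclass
class BlockSummary:
    """Tissue and endocrine areas of one block, with percent ratios.

    ``endocrine_area_um2`` is the sum of total islet-structure areas
    (including unstained intra-islet fractions); the per-hormone areas
    count hormone-positive pixels only, so their sum is ≤ the endocrine
    area.
    """

    block_index: int
    tissue_area_um2: float
    endocrine_area_um2: float
    beta_area_um2: float
    alpha_area_um2: float
    delta_area_um2: float

    @property
    def pct_endocrine(self) -> float:
        return 100.0 * self.endocrine_area_um2 / self.tissue_area_um2

    @property
    def pct_beta(self) -> float:
        return 100.0 * self.beta_area_um2 / self.tissue_area_um2

    @property
    def pct_alpha(self) -> float:
        return 100.0 * self.alpha_area_um2 / self.tissue_area_um2

    @property
    def pct_delta(self) -> float:
        return 100.0 * self.delta_area_um2 / self.tissue_area_um2


@dataclass
class RegionalProfile:
    """Head→tail series of per-block percentages with summary statistics."""

    pct_series: np.ndarray  # ordered head -> tail
    mean_pct: float
    sem_pct: float  # sample SD / sqrt(n) over blocks
    weighted_mean_pct: float  # tissue-area-weighted


@dataclass
class MassEstimate:
    """Absolute per-hormone mass for one donor.

    Volumes in µL are numerically equal to masses in mg at density 1 g/mL.
    ``pct_endocrine`` / ``mass_endocrine_mg`` refer to total islet-structure
    area (≥ the sum of the three hormone percentages).
    """

    donor_id: str
    pct_beta: float
    pct_alpha: float
    pct_delta: float
    pct_endocrine: float
    mass_beta_mg: float
    mass_alpha_mg: float
    mass_delta_mg: float
    mass_endocrine_mg: float
    density_g_per_ml: float = DEFAULT_DENSITY_G_PER_ML

    @property
    def volume_beta_ul(self) -> float:
        return self.mass_beta_mg / self.density_g_per_ml

    @property
    def volume_alpha_ul(self) -> float:
        return self.mass_alpha_mg / self.density_g_per_ml

    @property
    def volume_delta_ul(self) -> float:
        return self.mass_delta_mg / self.density_g_per_ml

    @property
    def volume_endocrine_ul(self) -> float:
        return self.mass_endocrine_mg / self.density_g_per_ml


def block_summary(
    islets: Sequence[IsletRecord], tissue_area_um2: float, block_index: int
) -> BlockSummary:
    """Aggregate the islets of one block into a :class:`BlockSummary`."""
    if tissue_area_um2 <= 0:
        raise ValueError("tissue area must be positive (percent ratio undefined)")
    for r in islets:
        if r.block_index != block_index:
            raise ValueError(
                f"islet {r.islet_id} belongs to block {r.block_index}, not {block_index}"
            )
    return BlockSummary(
        block_index=block_index,
        tissue_area_um2=float(tissue_area_um2),
        endocrine_area_um2=float(sum(r.area_um2 for r in islets)),
        beta_area_um2=float(sum(r.beta_area_um2 for r in islets)),
        alpha_area_um2=float(sum(r.alpha_area_um2 for r in islets)),
        delta_area_um2=float(sum(r.delta_area_um2 for r in islets)),
    )


def regional_profile(
    blocks: Sequence[BlockSummary], metric: str = "pct_endocrine"
) -> RegionalProfile:
    """Head→tail profile of one percent metric over ordered blocks.

    ``metric`` is one of ``pct_endocrine``, ``pct_beta``, ``pct_alpha``,
    ``pct_delta``. SEM is the sample SD over blocks divided by √n (0 for a
    single block).
    """
    if len(blocks) == 0:
        raise ValueError("need at least one block")
    pct = np.array([getattr(b, metric) for b in blocks], dtype=float)
    w = np.array([b.tissue_area_um2 for b in blocks], dtype=float)
    sem = float(pct.std(ddof=1) / math.sqrt(len(pct))) if len(pct) > 1 else 0.0
    return RegionalProfile(
        pct_series=pct,
        mean_pct=float(pct.mean()),
        sem_pct=sem,
        weighted_mean_pct=float(np.average(pct, weights=w)),
    )


def estimate_mass(
    profiles: Mapping[str, RegionalProfile],
    metadata: DonorMetadata,
    density_g_per_ml: float = DEFAULT_DENSITY_G_PER_ML,
) -> MassEstimate:
    """Convert fractional-area profiles to absolute mass for one donor.

    ``profiles`` maps ``beta``/``alpha``/``delta`` (and optionally
    ``endocrine``) to their regional profiles; the donor-level percent is
    each profile's tissue-weighted mean. If no ``endocrine`` profile is
    supplied, the endocrine percent is the sum of the three hormone
    percents (in which case masses are exactly additive).

    A measured pancreas weight is required by design: substituting
    population-based organ volume is a known source of bias and is
    deliberately not offered.
    """
    if density_g_per_ml <= 0:
        raise ValueError("density must be positive")
    missing = [k for k in ("beta", "alpha", "delta") if k not in profiles]
    if missing:
        raise KeyError(f"missing profiles: {missing}")
    pct = {k: profiles[k].weighted_mean_pct for k in ("beta", "alpha", "delta")}
    if "endocrine" in profiles:
        pct_endo = profiles["endocrine"].weighted_mean_pct
    else:
        pct_endo = sum(pct.values())

    def _mass(p: float) -> float:
        return p / 100.0 * metadata.pancreas_weight_g * 1000.0

    return MassEstimate(
        donor_id=metadata.donor_id,
        pct_beta=pct["beta"],
        pct_alpha=pct["alpha"],
        pct_delta=pct["delta"],
        pct_endocrine=pct_endo,
        mass_beta_mg=_mass(pct["beta"]),
        mass_alpha_mg=_mass(pct["alpha"]),
        mass_delta_mg=_mass(pct["delta"]),
        mass_endocrine_mg=_mass(pct_endo),
        density_g_per_ml=density_g_per_ml,
    )


def donor_mass_from_blocks(
    blocks: Sequence[BlockSummary],
    metadata: DonorMetadata,
    density_g_per_ml: float = DEFAULT_DENSITY_G_PER_ML,
) -> MassEstimate:
    """Convenience: profiles for all four metrics, then :func:`estimate_mass`."""
    profiles = {
        name: regional_profile(blocks, metric=f"pct_{name}")
        for name in ("beta", "alpha", "delta", "endocrine")
    }
    return estimate_mass(profiles, metadata, density_g_per_ml)


def tissue_density(mass_g: float, volume_ml: float) -> float:
    """Tissue density in g/mL from one (mass, volume) pair."""
    if volume_ml <= 0:
        raise ValueError("volume must be positive")
    return mass_g / volume_ml


def density_fit(
    masses_g: Sequence[float], volumes_ml: Sequence[float]
) -> float:
    """Least-squares density through the origin over (mass, volume) pairs.

    Closed form Σ(m·v)/Σ(v²); reproduces the ~1 g/mL pancreas density
    scatter from accumulated weight/volume tables.
    """
    m = np.asarray(masses_g, dtype=float)
    v = np.asarray(volumes_ml, dtype=float)
    if m.shape != v.shape or m.size == 0:
        raise ValueError("need equal-length non-empty mass and volume arrays")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    return float(np.sum(m * v) / np.sum(v * v))
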