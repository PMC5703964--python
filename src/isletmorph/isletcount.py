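"""Absolute islet-number and IEQ estimation from endocrine mass.

The number of islets follows from dividing the endocrine-cell mass
(converted to volume at ~1 g/mL) by a representative islet volume:

    N = endocrine mass (mg × 10⁻³) / islet volume (µm³ × 10⁻¹²)

applied per doubling-size bin. Mass is allocated to bins by each bin's
observed share of total islet area (2D area fractions read as volume
fractions — the Delesse principle), and the representative volume of a
bin is the mean sphere volume over its observed islets, where each
islet's volume is the sphere on its effective diameter. Islet number
converts to Islet Equivalents (IEQ; one IEQ = the volume of a 150 µm
diameter spherical islet), the standard unit of clinical islet
transplantation, with successful isolations defined as a yield over
400,000 IEQ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import (
    DEFAULT_DENSITY_G_PER_ML,
    IEQ_DIAMETER_UM,
    OVER_DIAMETER_THRESHOLD_UM,
    V_IEQ_UM3,
    YIELD_THRESHOLD_IEQ,
)
from .quantify import IsletRecord
from .sizedist import BinSummary, SizeBin, bin_of, effective_diameter
from .stereology import MassEstimate


@dataclass(frozen=True)
class IEQConstants:
    """Reference constants; override only explicitly."""

    ieq_diameter_um: float = IEQ_DIAMETER_UM
    density_g_per_ml: float = DEFAULT_DENSITY_G_PER_ML
    over_diameter_threshold_um: float = OVER_DIAMETER_THRESHOLD_UM
    yield_threshold_ieq: float = YIELD_THRESHOLD_IEQ

    @property
    def v_ieq_um3(self) -> float:
        return math.pi / 6.0 * self.ieq_diameter_um**3


@dataclass
class BinIsletNumber:
    bin: SizeBin
    allocated_mass_mg: float
    mean_islet_volume_um3: float
    n_islets: float  # real-valued; round for reporting


@dataclass
class IsletNumberEstimate:
    donor_id: str
    per_bin: list[BinIsletNumber]
    total_islets: float
    total_ieq: float
    n_over_40um: float
    meets_400k: bool

    def rounded(self) -> dict:
        """Reporting view with integer counts."""
        return {
            "donor_id": self.donor_id,
            "per_bin": [
                {
                    "bin": b.bin.k,
                    "diameter_range_um": b.bin.diameter_range_int,
                    "allocated_mass_mg": b.allocated_mass_mg,
                    "mean_islet_volume_um3": b.mean_islet_volume_um3,
                    "n_islets": int(round(b.n_islets)),
                }
                for b in self.per_bin
            ],
            "total_islets": int(round(self.total_islets)),
            "total_ieq": int(round(self.total_ieq)),
            "n_over_40um": int(round(self.n_over_40um)),
            "meets_400k": self.meets_400k,
        }


def islet_volume(area_um2: float) -> float:
    """Sphere volume (µm³) on the effective diameter of a 2D area.

    V = (π/6)·d_eff³ = (4/(3√π))·area^1.5.
    """
    if area_um2 < 0:
        raise ValueError("area must be >= 0")
    return 4.0 / (3.0 * math.sqrt(math.pi)) * area_um2**1.5


def islet_numbers(
    mass: MassEstimate,
    bins: Sequence[BinSummary],
    islets: Sequence[IsletRecord],
    constants: IEQConstants = IEQConstants(),
) -> IsletNumberEstimate:
    """Estimate per-bin and total islet numbers, IEQ and the >40 µm count.

    ``mass`` supplies the endocrine mass (total islet-structure mass),
    ``bins`` the area shares, ``islets`` the per-islet areas from which
    representative sphere volumes are taken. Internally real-valued;
    use :meth:`IsletNumberEstimate.rounded` for reporting.
    """
    if len(bins) == 0:
        raise ValueError("need at least one size bin")
    total_volume_um3 = (
        mass.mass_endocrine_mg * 1e-3 / constants.density_g_per_ml * 1e12
    )

    areas_by_bin: dict[int, list[float]] = {}
    for r in islets:
        if r.area_um2 <= 0:
            continue
        k = bin_of(r.area_um2)
        if k >= 1:
            areas_by_bin.setdefault(k, []).append(r.area_um2)

    per_bin: list[BinIsletNumber] = []
    total_n = 0.0
    total_ieq_v = 0.0
    for b in bins:
        areas = areas_by_bin.get(b.bin.k, [])
        if b.area_share > 0 and not areas:
            raise ValueError(
                f"bin {b.bin.k} has area share {b.area_share} but no observed islets"
            )
        alloc_vol = total_volume_um3 * b.area_share
        alloc_mass = mass.mass_endocrine_mg * b.area_share
        mean_vol = float(np.mean([islet_volume(a) for a in areas])) if areas else 0.0
        n = alloc_vol / mean_vol if mean_vol > 0 else 0.0
        per_bin.append(
            BinIsletNumber(
                bin=b.bin,
                allocated_mass_mg=alloc_mass,
                mean_islet_volume_um3=mean_vol,
                n_islets=n,
            )
        )
        total_n += n
        total_ieq_v += n * mean_vol

    ieq = total_ieq_v / constants.v_ieq_um3
    n40 = _count_over_diameter(
        total_volume_um3, islets, constants.over_diameter_threshold_um
    )
    return IsletNumberEstimate(
        donor_id=mass.donor_id,
        per_bin=per_bin,
        total_islets=total_n,
        total_ieq=ieq,
        n_over_40um=n40,
        meets_400k=meets_yield(ieq, constants),
    )


def _count_over_diameter(
    total_volume_um3: float, islets: Sequence[IsletRecord], threshold_um: float
) -> float:
    """Islet-number formula restricted to islets above a diameter cut.

    The cut is applied per islet (sub-bin resolution): the mass share
    attributable to the over-threshold islets is their area share, and
    the representative volume is their mean sphere volume.
    """
    areas = np.array([r.area_um2 for r in islets if r.area_um2 > 0], dtype=float)
    if areas.size == 0:
        return 0.0
    d = 2.0 * np.sqrt(areas / math.pi)
    over = areas[d > threshold_um]
    if over.size == 0:
        return 0.0
    share = over.sum() / areas.sum()
    mean_vol = float(np.mean([islet_volume(a) for a in over]))
    return total_volume_um3 * share / mean_vol


def count_over_diameter(
    mass: MassEstimate,
    islets: Sequence[IsletRecord],
    threshold_um: float = OVER_DIAMETER_THRESHOLD_UM,
    constants: IEQConstants = IEQConstants(),
) -> float:
    """Number of islets with effective diameter above ``threshold_um``."""
    total_volume_um3 = (
        mass.mass_endocrine_mg * 1e-3 / constants.density_g_per_ml * 1e12
    )
    return _count_over_diameter(total_volume_um3, islets, threshold_um)


def total_ieq(estimate: IsletNumberEstimate, constants: IEQConstants = IEQConstants()) -> float:
    """Σ per-bin n_islets × mean volume / V_IEQ; a 150 µm islet counts 1."""
    return (
        sum(b.n_islets * b.mean_islet_volume_um3 for b in estimate.per_bin)
        / constants.v_ieq_um3
    )


def meets_yield(ieq: float, constants: IEQConstants = IEQConstants()) -> bool:
    """Clinical success criterion: strictly over the 400 K IEQ threshold."""
    if ieq < 0:
        raise ValueError("IEQ must be >= 0")
    return ieq > constants.yield_threshold_ieq


def ieq_of_diameter(diameter_um: float, constants: IEQConstants = IEQConstants()) -> float:
    """IEQ contributed by a single spherical islet of the given diameter."""
    return (math.pi / 6.0 * diameter_um**3) / constants.v_ieq_um3


__all__ = [
    "IEQConstants",
    "BinIsletNumber",
    "IsletNumberEstimate",
    "islet_volume",
    "islet_numbers",
    "count_over_diameter",
    "total_ieq",
    "meets_yield",
    "ieq_of_diameter",
    "effective_diameter",
]
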