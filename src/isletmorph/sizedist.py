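"""Log-scale islet size binning, per-bin composition and shape scatter.

Islet cross-sectional areas are made dimensionless by dividing by the
single-cell reference area (178 µm²), giving a cell-equivalent count n.
Bin k (k ≥ 1) spans cell counts [2^(k−1), 2^k) — a doubling scheme — and
maps to an effective-diameter range via d(n) = 2·√(n·178/π). Reported bin
edges are truncated toward zero to integer µm, which reproduces the
conventional printed ranges, e.g. bin 3 = 30–42 µm, bin 5 = 60–85 µm,
bin 7 = 120–170 µm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constants import SINGLE_CELL_AREA_UM2
from .quantify import IsletRecord

log = logging.getLogger(__name__)


def cells_per_islet(area_um2: float) -> float:
    """Dimensionless cell-equivalent count: area / 178 µm² (not rounded)."""
    if area_um2 < 0:
        raise ValueError("area must be >= 0")
    return area_um2 / SINGLE_CELL_AREA_UM2


def effective_diameter(area_um2: float) -> float:
    """Diameter (µm) of the circle with the given area: 2·√(area/π)."""
    if area_um2 < 0:
        raise ValueError("area must be >= 0")
    return 2.0 * math.sqrt(area_um2 / math.pi)


def diameter_to_area(diameter_um: float) -> float:
    """Inverse of :func:`effective_diameter`."""
    return math.pi * (diameter_um / 2.0) ** 2


def bin_of_count(cell_count: float) -> int:
    """Bin index k for a cell-equivalent count (lower edge inclusive).

    Counts below one cell fall in the "sub-cell" bin k = 0, excluded from
    summaries.
    """
    if cell_count < 1.0:
        return 0
    return int(math.floor(math.log2(cell_count))) + 1


def bin_of(area_um2: float) -> int:
    """Bin index of an islet area in µm²."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    return bin_of_count(cells_per_islet(area_um2))


@dataclass(frozen=True)
class SizeBin:
    """One doubling bin on the cell-equivalent scale."""

    k: int
    cell_min: float
    cell_max: float
    diam_min_um: float
    diam_max_um: float

    @property
    def diameter_range_int(self) -> tuple[int, int]:
        """Edges truncated toward zero to integer µm, as conventionally printed."""
        return (int(self.diam_min_um), int(self.diam_max_um))

    @property
    def label(self) -> str:
        lo, hi = self.diameter_range_int
        return f"{lo}-{hi} um"


def size_bin(k: int) -> SizeBin:
    """Bin k: cell counts [2^(k−1), 2^k) and the matching diameter range."""
    if k < 1:
        raise ValueError("k must be >= 1")
    lo, hi = 2.0 ** (k - 1), 2.0**k
    return SizeBin(
        k=k,
        cell_min=lo,
        cell_max=hi,
        diam_min_um=effective_diameter(lo * SINGLE_CELL_AREA_UM2),
        diam_max_um=effective_diameter(hi * SINGLE_CELL_AREA_UM2),
    )


@dataclass
class BinSummary:
    """Per-bin frequency, mean composition (± SEM across islets) and area share."""

    bin: SizeBin
    n_islets_observed: int
    relative_frequency: float
    beta_frac_mean: float
    alpha_frac_mean: float
    delta_frac_mean: float
    beta_frac_sem: float
    alpha_frac_sem: float
    delta_frac_sem: float
    area_share: float


def composition_fractions(islet: IsletRecord) -> tuple[float, float, float] | None:
    """Per-islet hormone-area composition, normalized over the three hormones.

    Returns None for islets with zero total hormone area (unmeasurable
    composition).
    """
    total = islet.hormone_area_um2
    if total <= 0:
        return None
    return (
        islet.beta_area_um2 / total,
        islet.alpha_area_um2 / total,
        islet.delta_area_um2 / total,
    )


def bin_summaries(islets: Sequence[IsletRecord]) -> list[BinSummary]:
    """Summarize a collection of islets into doubling-size bins.

    Composition is area-based: per islet, hormone area / total hormone
    area; per bin, the unweighted mean ± SEM across islets. Frequencies
    and area shares are normalized over all bins k ≥ 1; sub-cell
    structures (k = 0) and islets with no hormone-positive area are
    excluded (with a logged warning for the latter).
    """
    if len(islets) == 0:
        raise ValueError("need at least one islet")
    rows = []
    for r in islets:
        comp = composition_fractions(r)
        if comp is None:
            log.warning("islet %s has zero hormone area; excluded", r.islet_id)
            continue
        k = bin_of(r.area_um2) if r.area_um2 > 0 else 0
        if k < 1:
            continue
        rows.append((k, r.area_um2, *comp))
    if not rows:
        raise ValueError("no binnable islets (all sub-cell or zero hormone area)")

    arr = np.asarray(rows, dtype=float)
    ks = arr[:, 0].astype(int)
    total_n = len(arr)
    total_area = arr[:, 1].sum()
    out = []
    for k in range(ks.min(), ks.max() + 1):
        sel = arr[ks == k]
        if len(sel) == 0:
            continue
        means = sel[:, 2:5].mean(axis=0)
        if len(sel) > 1:
            sems = sel[:, 2:5].std(axis=0, ddof=1) / math.sqrt(len(sel))
        else:
            sems = np.zeros(3)
        out.append(
            BinSummary(
                bin=size_bin(k),
                n_islets_observed=len(sel),
                relative_frequency=len(sel) / total_n,
                beta_frac_mean=float(means[0]),
                alpha_frac_mean=float(means[1]),
                delta_frac_mean=float(means[2]),
                beta_frac_sem=float(sems[0]),
                alpha_frac_sem=float(sems[1]),
                delta_frac_sem=float(sems[2]),
                area_share=float(sel[:, 1].sum() / total_area),
            )
        )
    return out


@dataclass
class ScatterPoint:
    """One islet in the size/shape scatter (log cell count, circularity, Feret)."""

    islet_id: str
    log_area: float  # log10 of cell-equivalent count
    circularity: float
    feret_um: float
    local_density: float


def shape_scatter(
    islets: Sequence[IsletRecord], k_neighbors: int = 15
) -> list[ScatterPoint]:
    """Per-islet scatter points with a kNN local-density value for coloring.

    Density is the inverse k-th nearest-neighbor distance in standardized
    (log10 cell count, circularity, log10 Feret) space, so isolated large
    islets read as sparse. With fewer than ``k_neighbors + 1`` islets the
    density is undefined and set uniformly to 1/n (with a warning).
    """
    islets = [r for r in islets if r.area_um2 > 0 and r.feret_um > 0]
    if not islets:
        return []
    feats = np.array(
        [
            [
                math.log10(max(cells_per_islet(r.area_um2), 1e-12)),
                r.circularity,
                math.log10(r.feret_um),
            ]
            for r in islets
        ]
    )
    n = len(islets)
    if n <= k_neighbors:
        log.warning("only %d islets for k=%d neighbors; uniform density", n, k_neighbors)
        dens = np.full(n, 1.0 / n)
    else:
        sd = feats.std(axis=0)
        sd[sd == 0] = 1.0
        z = (feats - feats.mean(axis=0)) / sd
        dists, _ = cKDTree(z).query(z, k=k_neighbors + 1)
        dens = 1.0 / np.maximum(dists[:, -1], 1e-12)
    return [
        ScatterPoint(
            islet_id=r.islet_id,
            log_area=float(feats[i, 0]),
            circularity=r.circularity,
            feret_um=r.feret_um,
            local_density=float(dens[i]),
        )
        for i, r in enumerate(islets)
    ]
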