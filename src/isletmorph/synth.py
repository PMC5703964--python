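"""Synthetic donor pancreata with known ground truth.

The generator emulates the statistical structure of whole-pancreas
endocrine morphometry so every downstream stage can be tested without
tissue: per-block 2D sections populated with islets whose

* sizes follow a heavily right-skewed log-normal distribution on the
  dimensionless cell-equivalent scale (area = cell count × 178 µm²),
  conditioned on at least one cell (no structure is smaller than a
  single endocrine cell),
* composition depends on size — beta-cells make up ~60% of hormone-
  positive area in small islets and decline in larger size bins, delta
  roughly constant, alpha the remainder,
* shape elongates with size (aspect ratio grows per doubling bin),
* per-block endocrine fraction increases head→tail with large
  multiplicative block-to-block fluctuation.

Ground truth (per-islet specs, realized block fractions, per-hormone
mass) is carried alongside, so parameter-recovery tests can compare the
pipeline's output to what was actually put in. A fast "table mode" emits
measurement tables directly from the analytic ellipse geometry; rendering
to raster sections is only needed to exercise the segmentation stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import yaml
from scipy.stats import norm

from .constants import SINGLE_CELL_AREA_UM2, DEFAULT_DENSITY_G_PER_ML
from .quantify import IsletRecord, SectionImage
from .stereology import DonorMetadata
from . import sizedist

log = logging.getLogger(__name__)

#: Edge of the square "cell" patches used to interleave hormone channels (µm).
_PATCH_UM = math.sqrt(SINGLE_CELL_AREA_UM2)

#: Per-block tissue rectangles cover this fraction range of the frame edge.
_TISSUE_SCALE_RANGE = (0.85, 1.0)

#: Minimum clearance between rendered islets (µm); exceeds twice the default
#: closing radius so distinct islets are not merged during segmentation.
_PLACEMENT_PAD_UM = 20.0


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic donor.

    Defaults mimic the scale of real adult human pancreata: ~0.4–1.0%
    endocrine fractional area rising head→tail, log-normal islet sizes
    with median ~5 cell-equivalents, 60% beta composition in small
    islets, constant ~10% delta, and a pancreas weight within the
    reported 77–219 g organ range.
    """

    n_blocks: int = 24
    pixel_size_um: float = 1.0
    section_size_px: tuple[int, int] = (5000, 5000)  # (width, height)
    endocrine_fraction_head: float = 0.004
    endocrine_fraction_tail: float = 0.010
    block_noise_cv: float = 0.35
    islet_size_log_mean: float = math.log(5.0)  # natural log of cell count
    islet_size_log_sd: float = 1.0
    beta_fraction_small: float = 0.60
    beta_fraction_slope_per_log2bin: float = -0.03
    beta_small_max_bin: int = 6  # last bin treated as "small" (~<100 µm)
    delta_fraction: float = 0.10
    elongation_slope: float = 0.08  # aspect-ratio increase per doubling bin
    pancreas_weight_g: float = 100.0
    tissue_density_g_per_ml: float = DEFAULT_DENSITY_G_PER_ML
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "endocrine_fraction_head",
            "endocrine_fraction_tail",
            "beta_fraction_small",
            "delta_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.islet_size_log_sd < 0 or self.block_noise_cv < 0:
            raise ValueError("dispersions must be >= 0")
        if min(self.section_size_px) <= 0:
            raise ValueError("section size must be positive")
        if self.pancreas_weight_g <= 0 or self.tissue_density_g_per_ml <= 0:
            raise ValueError("weight and density must be positive")
        if self.beta_fraction_small + self.delta_fraction > 1.0 + 1e-12:
            raise ValueError("beta_fraction_small + delta_fraction exceeds 1")

    @property
    def donor_endocrine_fraction(self) -> float:
        """Configured whole-organ endocrine fractional area."""
        return 0.5 * (self.endocrine_fraction_head + self.endocrine_fraction_tail)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["section_size_px"] = list(self.section_size_px)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["section_size_px"] = tuple(d["section_size_px"])
        return cls(**d)


@dataclass
class IsletSpec:
    """Ground-truth description of one islet (the twin of IsletRecord)."""

    block_index: int
    center_x_um: float
    center_y_um: float
    true_area_um2: float
    cell_count: float
    aspect_ratio: float
    orientation: float  # radians
    beta_fraction: float
    alpha_fraction: float
    delta_fraction: float

    def __post_init__(self) -> None:
        if self.true_area_um2 <= 0:
            raise ValueError("true_area_um2 must be positive")
        s = self.beta_fraction + self.alpha_fraction + self.delta_fraction
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"hormone fractions sum to {s}, not 1")

    @property
    def semi_axes_um(self) -> tuple[float, float]:
        a = math.sqrt(self.true_area_um2 * self.aspect_ratio / math.pi)
        return a, a / self.aspect_ratio


@dataclass
class SyntheticDonor:
    config: GeneratorConfig
    metadata: DonorMetadata
    islets: list[IsletSpec]
    block_tissue_areas_um2: np.ndarray
    block_tissue_size_px: list[tuple[int, int]]  # (width, height) per block
    true_block_fractions: np.ndarray  # realized endocrine area fraction
    true_mass_mg: dict[str, float] = field(default_factory=dict)

    @property
    def true_pct(self) -> dict[str, float]:
        """Ground-truth whole-donor percent fractional areas."""
        w = self.config.pancreas_weight_g * 1000.0
        return {k: 100.0 * v / w for k, v in self.true_mass_mg.items()}

    def islets_in_block(self, block_index: int) -> list[IsletSpec]:
        return [s for s in self.islets if s.block_index == block_index]


# ---------------------------------------------------------------------------
# composition and shape models


def composition_for_size(
    cell_count: float, config: GeneratorConfig
) -> tuple[float, float, float]:
    """(beta, alpha, delta) hormone fractions for an islet of given size.

    Beta is ``beta_fraction_small`` for every bin up to
    ``beta_small_max_bin`` (all islets under ~100 µm effective diameter)
    and changes by ``beta_fraction_slope_per_log2bin`` per doubling bin
    beyond it, clamped to [0, 1 − delta]. Delta is constant; alpha is the
    remainder.
    """
    k = max(sizedist.bin_of_count(cell_count), 1)
    excess = max(0, k - config.beta_small_max_bin)
    beta = config.beta_fraction_small + config.beta_fraction_slope_per_log2bin * excess
    beta = min(max(beta, 0.0), 1.0 - config.delta_fraction)
    delta = config.delta_fraction
    return beta, 1.0 - beta - delta, delta


def _aspect_ratio_for_bin(k: int, config: GeneratorConfig, rng: np.random.Generator) -> float:
    base = 1.0 + config.elongation_slope * max(k - 1, 0)
    return max(1.0, base + rng.normal(0.0, 0.05))


def expected_beta_share(config: GeneratorConfig, k_max: int = 64) -> float:
    """Expected beta share of total islet area under the size distribution.

    Closed form from log-normal partial moments: E[n·1{bin k}] =
    e^{µ+σ²/2}·[Φ((ln u − µ − σ²)/σ) − Φ((ln l − µ − σ²)/σ)], weighted by
    the per-bin beta fraction. Used to calibrate configs that target a
    given whole-donor beta percent.
    """
    mu, sd = config.islet_size_log_mean, config.islet_size_log_sd
    if sd == 0:
        return composition_for_size(max(math.exp(mu), 1.0), config)[0]

    def partial(lo: float, hi: float) -> float:
        zhi = (math.log(hi) - mu - sd * sd) / sd if hi != math.inf else math.inf
        zlo = (math.log(lo) - mu - sd * sd) / sd if lo > 0 else -math.inf
        return norm.cdf(zhi) - norm.cdf(zlo)

    # sizes are conditioned on >= 1 cell, so bins start at k = 1 and the
    # conditioning constant cancels in the ratio
    num = den = 0.0
    for k in range(1, k_max + 1):
        w = partial(2.0 ** (k - 1), 2.0**k if k < k_max else math.inf)
        num += w * composition_for_size(2.0 ** (k - 1), config)[0]
        den += w
    return num / den


def config_for_target_beta_pct(
    beta_pct: float, **overrides
) -> GeneratorConfig:
    """Config whose ground-truth whole-donor beta percent is ``beta_pct``.

    Scales the head/tail endocrine fractions (preserving their ratio) by
    the expected beta share of islet area, so the generated donor's true
    beta fractional area lands on the requested value up to sampling
    noise. Keyword overrides are applied before calibration.
    """
    base = GeneratorConfig(**overrides)
    share = expected_beta_share(base)
    scale = (beta_pct / 100.0) / share / base.donor_endocrine_fraction
    return replace(
        base,
        endocrine_fraction_head=base.endocrine_fraction_head * scale,
        endocrine_fraction_tail=base.endocrine_fraction_tail * scale,
    )


# ---------------------------------------------------------------------------
# donor generation


def generate_donor(config: GeneratorConfig) -> SyntheticDonor:
    """Generate one synthetic donor; deterministic for a fixed seed.

    Per-block endocrine fractions interpolate head→tail with
    multiplicative log-normal noise of the configured CV, then are
    renormalized so their tissue-weighted mean equals the configured
    donor-level fraction (noise redistributes endocrine tissue across
    blocks without moving the whole-organ truth). Within each block,
    islet sizes are drawn until the cumulative area is as close as
    possible to the block's target endocrine area.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_blocks
    w_px, h_px = config.section_size_px
    p = config.pixel_size_um

    metadata = DonorMetadata(
        donor_id=f"synthetic-{config.seed}",
        age=float(np.round(rng.normal(41.4, 8.0), 1)),
        sex="M",
        bmi=float(np.round(rng.uniform(16.0, 36.0), 1)),
        pancreas_weight_g=config.pancreas_weight_g,
        height_cm=float(np.round(rng.normal(176.0, 8.0), 1)),
        diabetes_status="non-diabetic",
    )

    if n == 0:
        return SyntheticDonor(
            config=config,
            metadata=metadata,
            islets=[],
            block_tissue_areas_um2=np.zeros(0),
            block_tissue_size_px=[],
            true_block_fractions=np.zeros(0),
            true_mass_mg={k: 0.0 for k in ("beta", "alpha", "delta", "endocrine")},
        )

    # tissue rectangle per block (one scale per block, centered in the frame)
    scales = rng.uniform(*_TISSUE_SCALE_RANGE, size=n)
    sizes = [(int(round(w_px * s)), int(round(h_px * s))) for s in scales]
    tissue_areas = np.array([tw * th * p * p for tw, th in sizes])

    # head->tail profile with multiplicative noise, renormalized so the
    # tissue-weighted mean equals the configured donor fraction
    if n > 1:
        profile = np.linspace(
            config.endocrine_fraction_head, config.endocrine_fraction_tail, n
        )
    else:
        profile = np.array([config.donor_endocrine_fraction])
    if config.block_noise_cv > 0:
        sig = math.sqrt(math.log(1.0 + config.block_noise_cv**2))
        noise = np.exp(rng.normal(-0.5 * sig * sig, sig, size=n))
    else:
        noise = np.ones(n)
    raw = profile * noise
    target_mean = config.donor_endocrine_fraction
    raw *= target_mean * tissue_areas.sum() / np.sum(raw * tissue_areas)

    islets: list[IsletSpec] = []
    realized = np.zeros(n)
    for b in range(n):
        block_islets = _sample_block(
            rng, config, block_index=b + 1,
            tissue_size_px=sizes[b],
            target_area_um2=raw[b] * tissue_areas[b],
        )
        islets.extend(block_islets)
        realized[b] = sum(s.true_area_um2 for s in block_islets) / tissue_areas[b]

    total_tissue = tissue_areas.sum()
    areas = {"beta": 0.0, "alpha": 0.0, "delta": 0.0, "endocrine": 0.0}
    for s in islets:
        areas["beta"] += s.beta_fraction * s.true_area_um2
        areas["alpha"] += s.alpha_fraction * s.true_area_um2
        areas["delta"] += s.delta_fraction * s.true_area_um2
        areas["endocrine"] += s.true_area_um2
    mass = {
        k: float(v / total_tissue * config.pancreas_weight_g * 1000.0)
        for k, v in areas.items()
    }
    return SyntheticDonor(
        config=config,
        metadata=metadata,
        islets=islets,
        block_tissue_areas_um2=tissue_areas,
        block_tissue_size_px=sizes,
        true_block_fractions=realized,
        true_mass_mg=mass,
    )


def _sample_block(
    rng: np.random.Generator,
    config: GeneratorConfig,
    block_index: int,
    tissue_size_px: tuple[int, int],
    target_area_um2: float,
) -> list[IsletSpec]:
    """Draw islets for one block until closest to the target endocrine area."""
    p = config.pixel_size_um
    w_px, h_px = config.section_size_px
    tw, th = tissue_size_px
    # tissue rectangle centered in the frame, in µm
    x0 = (w_px - tw) / 2.0 * p
    y0 = (h_px - th) / 2.0 * p
    x1, y1 = x0 + tw * p, y0 + th * p

    sizes: list[float] = []
    cum = 0.0
    while True:
        cc = _draw_cell_count(rng, config)
        area = cc * SINGLE_CELL_AREA_UM2
        if abs(cum + area - target_area_um2) < abs(cum - target_area_um2):
            sizes.append(cc)
            cum += area
        else:
            break

    placed: list[tuple[float, float, float]] = []  # (x, y, clearance radius)
    out: list[IsletSpec] = []
    for cc in sizes:
        area = cc * SINGLE_CELL_AREA_UM2
        k = sizedist.bin_of_count(cc)
        ar = _aspect_ratio_for_bin(max(k, 1), config, rng)
        a = math.sqrt(area * ar / math.pi)  # semi-major, µm
        theta = float(rng.uniform(0.0, math.pi))
        pos = _place(rng, a, placed, x0, y0, x1, y1)
        if pos is None:
            log.warning(
                "block %d: could not place islet of %.0f µm² without overlap; skipped",
                block_index, area,
            )
            continue
        placed.append((pos[0], pos[1], a + _PLACEMENT_PAD_UM / 2.0))
        beta, alpha, delta = composition_for_size(cc, config)
        out.append(
            IsletSpec(
                block_index=block_index,
                center_x_um=pos[0],
                center_y_um=pos[1],
                true_area_um2=area,
                cell_count=cc,
                aspect_ratio=ar,
                orientation=theta,
                beta_fraction=beta,
                alpha_fraction=alpha,
                delta_fraction=delta,
            )
        )
    return out


def _draw_cell_count(rng: np.random.Generator, config: GeneratorConfig) -> float:
    """Log-normal cell count conditioned on >= 1 cell (rejection sampling)."""
    for _ in range(10_000):
        cc = float(
            rng.lognormal(config.islet_size_log_mean, config.islet_size_log_sd)
        )
        if cc >= 1.0:
            return cc
    return 1.0  # pathological config (mass far below one cell)


def _place(rng, a, placed, x0, y0, x1, y1, max_tries: int = 100):
    """Rejection placement keeping islets inside the tissue and apart."""
    m = a + 2.0
    lox, hix = x0 + m, x1 - m
    loy, hiy = y0 + m, y1 - m
    if lox >= hix or loy >= hiy:  # islet larger than the tissue rectangle
        return None
    r_self = a + _PLACEMENT_PAD_UM / 2.0
    for _ in range(max_tries):
        x = float(rng.uniform(lox, hix))
        y = float(rng.uniform(loy, hiy))
        if all((x - px) ** 2 + (y - py) ** 2 >= (r_self + pr) ** 2 for px, py, pr in placed):
            return x, y
    return None


# ---------------------------------------------------------------------------
# table mode


def _ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's second approximation (error <1e-9 for AR ≤ 5)."""
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + math.sqrt(4.0 - 3.0 * h)))


def spec_to_record(spec: IsletSpec, donor_id: str, islet_id: str) -> IsletRecord:
    """Analytic measurement of a ground-truth islet (no rasterization)."""
    a, b = spec.semi_axes_um
    perim = _ellipse_perimeter(a, b)
    area = spec.true_area_um2
    return IsletRecord(
        islet_id=islet_id,
        donor_id=donor_id,
        block_index=spec.block_index,
        area_um2=area,
        perimeter_um=perim,
        circularity=min(1.0, 4.0 * math.pi * area / perim**2),
        feret_um=2.0 * a,
        beta_area_um2=spec.beta_fraction * area,
        alpha_area_um2=spec.alpha_fraction * area,
        delta_area_um2=spec.delta_fraction * area,
        centroid_x_um=spec.center_x_um,
        centroid_y_um=spec.center_y_um,
        extras={"true_cell_count": spec.cell_count},
    )


def donor_islet_table(donor: SyntheticDonor) -> list[IsletRecord]:
    """Table mode: measurement records straight from ground truth."""
    return [
        spec_to_record(s, donor.metadata.donor_id, f"{donor.metadata.donor_id}-b{s.block_index}-i{i}")
        for i, s in enumerate(donor.islets, start=1)
    ]


# ---------------------------------------------------------------------------
# rendering


def render_section(
    islets: Sequence[IsletSpec],
    config: GeneratorConfig,
    block_index: int,
    tissue_size_px: tuple[int, int] | None = None,
    donor_id: str = "synthetic",
) -> SectionImage:
    """Rasterize one block's islets into a 4-channel section image.

    Channels are ``beta``/``alpha``/``delta`` (value 200 inside positive
    cells, 0 elsewhere) and ``tissue`` (255 on the tissue rectangle).
    Each islet is an ellipse of the specified area/aspect/orientation;
    interior pixels are partitioned among the hormone channels in the
    exact specified proportions, grouped into ~178 µm² cell-like patches
    so channels interleave spatially. Islets extending beyond the canvas
    are skipped with a logged warning.
    """
    p = config.pixel_size_um
    w_px, h_px = config.section_size_px
    chans = {
        name: np.zeros((h_px, w_px), dtype=np.uint8)
        for name in ("beta", "alpha", "delta")
    }
    tissue = np.zeros((h_px, w_px), dtype=np.uint8)
    tw, th = tissue_size_px if tissue_size_px is not None else (w_px, h_px)
    ox, oy = (w_px - tw) // 2, (h_px - th) // 2
    tissue[oy : oy + th, ox : ox + tw] = 255
    chans["tissue"] = tissue

    for i, spec in enumerate(islets):
        if spec.block_index != block_index:
            raise ValueError(
                f"islet of block {spec.block_index} passed to block {block_index}"
            )
        _render_islet(chans, spec, config, islet_index=i)

    return SectionImage(
        channels=chans, pixel_size_um=p, block_index=block_index, donor_id=donor_id
    )


def _render_islet(chans, spec: IsletSpec, config: GeneratorConfig, islet_index: int) -> None:
    p = config.pixel_size_um
    h_px, w_px = chans["beta"].shape
    a, b = spec.semi_axes_um
    cx, cy = spec.center_x_um, spec.center_y_um

    r = a + p  # bounding half-width, µm
    j0, j1 = int((cx - r) / p), int(math.ceil((cx + r) / p)) + 1
    i0, i1 = int((cy - r) / p), int(math.ceil((cy + r) / p)) + 1
    if j0 < 0 or i0 < 0 or j1 > w_px or i1 > h_px:
        log.warning("islet at (%.0f, %.0f) µm extends beyond canvas; skipped", cx, cy)
        return

    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    x = (jj + 0.5) * p - cx
    y = (ii + 0.5) * p - cy
    ct, st = math.cos(spec.orientation), math.sin(spec.orientation)
    u = x * ct + y * st
    v = -x * st + y * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    n_pix = int(inside.sum())
    if n_pix == 0:
        return

    pix_i = ii[inside]
    pix_j = jj[inside]
    # group pixels into cell-sized patches, shuffle patch order
    patch = (pix_j * p // _PATCH_UM).astype(np.int64) * 1_000_003 + (
        pix_i * p // _PATCH_UM
    ).astype(np.int64)
    uniq, inv = np.unique(patch, return_inverse=True)
    rng = np.random.default_rng((config.seed, spec.block_index, islet_index))
    order = np.argsort(rng.permutation(len(uniq))[inv], kind="stable")
    pix_i, pix_j = pix_i[order], pix_j[order]

    n_beta = int(round(spec.beta_fraction * n_pix))
    n_delta = int(round(spec.delta_fraction * n_pix))
    n_delta = min(n_delta, n_pix - n_beta)
    bounds = (n_beta, n_pix - n_delta)
    chans["beta"][pix_i[: bounds[0]], pix_j[: bounds[0]]] = 200
    chans["alpha"][pix_i[bounds[0] : bounds[1]], pix_j[bounds[0] : bounds[1]]] = 200
    chans["delta"][pix_i[bounds[1] :], pix_j[bounds[1] :]] = 200


def render_donor(donor: SyntheticDonor) -> list[SectionImage]:
    """Render every block of a donor (memory-heavy; prefer iterating)."""
    return [
        render_block(donor, b) for b in range(1, donor.config.n_blocks + 1)
    ]


def render_block(donor: SyntheticDonor, block_index: int) -> SectionImage:
    """Render one block of a donor."""
    return render_section(
        donor.islets_in_block(block_index),
        donor.config,
        block_index,
        tissue_size_px=donor.block_tissue_size_px[block_index - 1],
        donor_id=donor.metadata.donor_id,
    )
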