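"""File formats: TIFF sections, CSV measurement tables, JSON reports.

All tables carry a versioned comment header (``# isletmorph <kind> v1``)
and documented column names with units in the names (µm / µm²). Extra
columns in islet tables are preserved on round-trip.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .quantify import IsletRecord, SectionImage
from .sizedist import BinSummary
from .stereology import BlockSummary, DonorMetadata, MassEstimate

SCHEMA_VERSION = 1

CHANNEL_ORDER = ("beta", "alpha", "delta", "tissue")

ISLET_COLUMNS = [
    "islet_id",
    "donor_id",
    "block_index",
    "area_um2",
    "perimeter_um",
    "circularity",
    "feret_um",
    "beta_area_um2",
    "alpha_area_um2",
    "delta_area_um2",
    "centroid_x_um",
    "centroid_y_um",
]


def _write_csv(df: pd.DataFrame, path, kind: str) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# isletmorph {kind} v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# islet tables


def islets_to_frame(records: Sequence[IsletRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        extras = d.pop("extras")
        rows.append({**d, **extras})
    df = pd.DataFrame(rows, columns=ISLET_COLUMNS if not rows else None)
    if rows:
        ordered = ISLET_COLUMNS + [c for c in df.columns if c not in ISLET_COLUMNS]
        df = df[ordered]
    return df


def frame_to_islets(df: pd.DataFrame) -> list[IsletRecord]:
    missing = [c for c in ISLET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"islet table missing column(s): {missing}")
    extra_cols = [c for c in df.columns if c not in ISLET_COLUMNS]
    out = []
    for _, row in df.iterrows():
        out.append(
            IsletRecord(
                islet_id=str(row["islet_id"]),
                donor_id=str(row["donor_id"]),
                block_index=int(row["block_index"]),
                area_um2=float(row["area_um2"]),
                perimeter_um=float(row["perimeter_um"]),
                circularity=float(row["circularity"]),
                feret_um=float(row["feret_um"]),
                beta_area_um2=float(row["beta_area_um2"]),
                alpha_area_um2=float(row["alpha_area_um2"]),
                delta_area_um2=float(row["delta_area_um2"]),
                centroid_x_um=float(row["centroid_x_um"]),
                centroid_y_um=float(row["centroid_y_um"]),
                extras={c: row[c] for c in extra_cols},
            )
        )
    return out


def write_islet_table(records: Sequence[IsletRecord], path) -> None:
    _write_csv(islets_to_frame(records), path, "islets")


def read_islet_table(path) -> list[IsletRecord]:
    return frame_to_islets(_read_csv(path))


# ---------------------------------------------------------------------------
# block / bin tables


def write_block_table(blocks: Sequence[BlockSummary], path) -> None:
    df = pd.DataFrame(
        [
            {
                "block_index": b.block_index,
                "tissue_area_um2": b.tissue_area_um2,
                "endocrine_area_um2": b.endocrine_area_um2,
                "beta_area_um2": b.beta_area_um2,
                "alpha_area_um2": b.alpha_area_um2,
                "delta_area_um2": b.delta_area_um2,
                "pct_endocrine": b.pct_endocrine,
                "pct_beta": b.pct_beta,
                "pct_alpha": b.pct_alpha,
                "pct_delta": b.pct_delta,
            }
            for b in blocks
        ]
    )
    _write_csv(df, path, "blocks")


def read_block_table(path) -> list[BlockSummary]:
    df = _read_csv(path)
    return [
        BlockSummary(
            block_index=int(r["block_index"]),
            tissue_area_um2=float(r["tissue_area_um2"]),
            endocrine_area_um2=float(r["endocrine_area_um2"]),
            beta_area_um2=float(r["beta_area_um2"]),
            alpha_area_um2=float(r["alpha_area_um2"]),
            delta_area_um2=float(r["delta_area_um2"]),
        )
        for _, r in df.iterrows()
    ]


def write_bin_table(bins: Sequence[BinSummary], path) -> None:
    df = pd.DataFrame(
        [
            {
                "k": b.bin.k,
                "cell_min": b.bin.cell_min,
                "cell_max": b.bin.cell_max,
                "diam_min_um": b.bin.diameter_range_int[0],
                "diam_max_um": b.bin.diameter_range_int[1],
                "n_islets": b.n_islets_observed,
                "relative_frequency": b.relative_frequency,
                "beta_frac_mean": b.beta_frac_mean,
                "beta_frac_sem": b.beta_frac_sem,
                "alpha_frac_mean": b.alpha_frac_mean,
                "alpha_frac_sem": b.alpha_frac_sem,
                "delta_frac_mean": b.delta_frac_mean,
                "delta_frac_sem": b.delta_frac_sem,
                "area_share": b.area_share,
            }
            for b in bins
        ]
    )
    _write_csv(df, path, "bins")


# ---------------------------------------------------------------------------
# metadata / reports


def write_metadata(meta: DonorMetadata, path) -> None:
    with open(path, "w") as fh:
        json.dump({"schema": f"isletmorph metadata v{SCHEMA_VERSION}", **asdict(meta)}, fh, indent=2)


def read_metadata(path) -> DonorMetadata:
    with open(path) as fh:
        d = json.load(fh)
    d.pop("schema", None)
    return DonorMetadata(**d)


def write_mass_estimate(mass: MassEstimate, path) -> None:
    d = asdict(mass)
    d["volume_beta_ul"] = mass.volume_beta_ul
    d["volume_alpha_ul"] = mass.volume_alpha_ul
    d["volume_delta_ul"] = mass.volume_delta_ul
    d["volume_endocrine_ul"] = mass.volume_endocrine_ul
    with open(path, "w") as fh:
        json.dump({"schema": f"isletmorph mass v{SCHEMA_VERSION}", **d}, fh, indent=2)


def read_mass_estimate(path) -> MassEstimate:
    with open(path) as fh:
        d = json.load(fh)
    return MassEstimate(
        **{k: d[k] for k in (
            "donor_id", "pct_beta", "pct_alpha", "pct_delta", "pct_endocrine",
            "mass_beta_mg", "mass_alpha_mg", "mass_delta_mg", "mass_endocrine_mg",
            "density_g_per_ml",
        )}
    )


# ---------------------------------------------------------------------------
# section images


def write_section(image: SectionImage, path) -> None:
    """Write a 4-channel TIFF (beta, alpha, delta, tissue) with calibration
    metadata in the image description."""
    stack = np.stack([image.channels[c] for c in CHANNEL_ORDER if c in image.channels])
    desc = json.dumps(
        {
            "channels": [c for c in CHANNEL_ORDER if c in image.channels],
            "pixel_size_um": image.pixel_size_um,
            "block_index": image.block_index,
            "donor_id": image.donor_id,
        }
    )
    tifffile.imwrite(
        path, stack, photometric="minisblack", planarconfig="separate",
        description=desc,
    )


def read_section(path, pixel_size_um: float | None = None) -> SectionImage:
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError):
        meta = {}
    names = meta.get("channels", list(CHANNEL_ORDER[: stack.shape[0]]))
    p = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if p is None:
        raise ValueError("pixel_size_um not in TIFF metadata; pass it explicitly")
    return SectionImage(
        channels={name: stack[i] for i, name in enumerate(names)},
        pixel_size_um=float(p),
        block_index=int(meta.get("block_index", 1)),
        donor_id=str(meta.get("donor_id", "donor")),
    )


# ---------------------------------------------------------------------------
# packaged fixture


def load_reference_cohort() -> pd.DataFrame:
    """Synthetic stand-in for a 10-donor cohort summary table.

    A hand-built table patterned after published whole-pancreas donor
    summaries (age-matched non-diabetic adult males; percent ratios and
    absolute per-hormone masses). It is display data for report and plot
    smoke tests — synthetic, not pipeline output and not measurements.
    """
    with resources.files("isletmorph.data").joinpath(
        "cohort_reference_synthetic.csv"
    ).open() as fh:
        return pd.read_csv(fh, comment="#")
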