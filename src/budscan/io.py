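"""Interchange formats: detection tables (CSV / GeoJSON), density maps
(TIFF + JSON sidecar), hotspot lists (JSON / GeoJSON circles), and the
run configuration.

Interchange files always carry physical micrometer coordinates; raster
indices never leave the process, which prevents spacing mix-ups between
tools.  CSV files use comma separators, dot decimals and ``.`` for
missing values.  Every artifact embeds the tool version and a hash of
the configuration that produced it, so reruns are attributable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .core import Circle, Detection, Label, SlideGeometry, Source
from .density import DensityMap
from .hotspot import Hotspot, HotspotMatchReport, HotspotSource

__all__ = [
    "TOOL_VERSION",
    "DETECTION_COLUMNS",
    "RunConfig",
    "config_hash",
    "detections_to_frame",
    "frame_to_detections",
    "write_detections_csv",
    "read_detections_csv",
    "write_detections_geojson",
    "read_detections_geojson",
    "write_density_map",
    "read_density_map",
    "write_dab_mask",
    "read_dab_mask",
    "write_heatmap_png",
    "write_hotspots_json",
    "read_hotspots_json",
    "write_biomarker_table",
]

TOOL_VERSION = "0.1.0"
MISSING = "."
DETECTION_COLUMNS = ["slide_id", "x_um", "y_um", "likelihood", "label", "certainty", "source"]


@dataclass(frozen=True)
class RunConfig:
    """All tunable defaults in one document.

    Unknown fields in a config file fail fast with the offending field
    path; unspecified fields take the documented defaults below.
    """

    radius_um: float = 500.0
    grid_spacing_um: float = 8.0
    n_hotspots: int = 10
    dice_threshold: float = 0.7
    od_threshold: float = 0.15
    min_area_um2: float = 30.0
    opening_radius_px: int = 1
    likelihood_threshold: float = 0.80
    pseudo_certainty: float = 0.80
    manual_certainty: float = 1.0
    collision_radius_um: float = 15.0
    mask_tolerance_um: float = 0.0
    match_radius_um: float = 25.0
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in (".yaml", ".yml"):
                raw = yaml.safe_load(fh) or {}
            else:
                raw = json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        for key in raw:
            if key not in known:
                raise ValueError(f"unknown config field: {key!r}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of a configuration document."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# detection tables

def detections_to_frame(
    detections: Sequence[Detection], slide_id: str = "slide"
) -> pd.DataFrame:
    rows = [
        {
            "slide_id": slide_id,
            "x_um": d.x,
            "y_um": d.y,
            "likelihood": d.likelihood,
            "label": d.label.value,
            "certainty": d.certainty,
            "source": d.source.value,
        }
        for d in detections
    ]
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def frame_to_detections(df: pd.DataFrame) -> list[Detection]:
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"detection table missing columns: {missing}")
    out: list[Detection] = []
    for row in df.itertuples(index=False):
        like = getattr(row, "likelihood")
        cert = getattr(row, "certainty")
        out.append(
            Detection(
                x=float(row.x_um),
                y=float(row.y_um),
                likelihood=None if pd.isna(like) else float(like),
                label=Label(row.label),
                certainty=None if pd.isna(cert) else float(cert),
                source=Source(row.source),
            )
        )
    return out


def write_detections_csv(
    path: str | Path, detections: Sequence[Detection] | pd.DataFrame, slide_id: str = "slide"
) -> None:
    df = (
        detections
        if isinstance(detections, pd.DataFrame)
        else detections_to_frame(detections, slide_id)
    )
    df.to_csv(path, index=False, na_rep=MISSING)


def read_detections_csv(path: str | Path) -> pd.DataFrame:
    """Read a detection table; unknown columns are preserved."""
    df = pd.read_csv(path, na_values=[MISSING], keep_default_na=True)
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: detection table missing columns: {missing}")
    return df


def write_detections_geojson(
    path: str | Path, detections: Sequence[Detection], slide_id: str = "slide"
) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [d.x, d.y]},
            "properties": {
                "slide_id": slide_id,
                "likelihood": d.likelihood,
                "label": d.label.value,
                "certainty": d.certainty,
                "source": d.source.value,
            },
        }
        for d in detections
    ]
    doc = {
        "type": "FeatureCollection",
        "crs_note": "slide-local frame, coordinates in micrometers",
        "features": features,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_detections_geojson(path: str | Path) -> list[Detection]:
    doc = json.loads(Path(path).read_text())
    out: list[Detection] = []
    for feat in doc.get("features", []):
        x, y = feat["geometry"]["coordinates"]
        props = feat.get("properties", {})
        out.append(
            Detection(
                x=float(x),
                y=float(y),
                likelihood=props.get("likelihood"),
                label=Label(props.get("label", "UNLABELED")),
                certainty=props.get("certainty"),
                source=Source(props.get("source", "DETECTOR")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# density maps

def write_density_map(
    base: str | Path, dmap: DensityMap, config: RunConfig | None = None
) -> tuple[Path, Path]:
    """Write counts as 32-bit single-channel TIFF plus a JSON sidecar.

    ``base`` is the path without extension; returns (tiff_path, json_path).
    """
    base = Path(base)
    tiff_path = base.with_suffix(".tif")
    json_path = base.with_suffix(".json")
    tifffile.imwrite(tiff_path, dmap.counts.astype(np.int32))
    sidecar = {
        "spacing_um": dmap.geometry.spacing_um,
        "width_um": dmap.geometry.width_um,
        "height_um": dmap.geometry.height_um,
        "offset_um": [dmap.geometry.origin_x_um, dmap.geometry.origin_y_um],
        "radius_um": dmap.radius_um,
        "total_buds": dmap.total_buds,
        "zero_density": dmap.zero_density,
        "tool_version": TOOL_VERSION,
        "config_hash": config_hash(config) if config else None,
    }
    json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return tiff_path, json_path


def read_density_map(base: str | Path) -> DensityMap:
    base = Path(base)
    counts = tifffile.imread(base.with_suffix(".tif"))
    meta = json.loads(base.with_suffix(".json").read_text())
    geometry = SlideGeometry(
        width_um=meta["width_um"],
        height_um=meta["height_um"],
        spacing_um=meta["spacing_um"],
        origin_x_um=meta["offset_um"][0],
        origin_y_um=meta["offset_um"][1],
    )
    return DensityMap(
        counts=np.asarray(counts, dtype=np.int32),
        geometry=geometry,
        radius_um=meta["radius_um"],
        total_buds=meta["total_buds"],
        zero_density=meta.get("zero_density", False),
    )


def write_heatmap_png(path: str | Path, dmap: DensityMap) -> None:
    """8-bit visualization of a density map (max count scaled to 255)."""
    counts = dmap.counts.astype(np.float64)
    peak = counts.max()
    img = (255.0 * counts / peak if peak > 0 else counts).astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)


# ---------------------------------------------------------------------------
# DAB masks

def write_dab_mask(base: str | Path, mask: "DabMask") -> tuple[Path, Path]:
    """Write a binary mask as 8-bit TIFF plus a JSON sidecar."""
    from .stain import DabMask  # local import to avoid cycle at module load

    base = Path(base)
    tiff_path = base.with_suffix(".tif")
    json_path = base.with_suffix(".json")
    tifffile.imwrite(tiff_path, (mask.mask.astype(np.uint8) * 255))
    sidecar = {
        "spacing_um": mask.spacing_um,
        "offset_um": list(mask.offset_um),
        "tool_version": TOOL_VERSION,
        "components": [
            {
                "component_id": c.component_id,
                "pixel_count": c.pixel_count,
                "area_um2": c.area_um2,
                "centroid_um": list(c.centroid_um),
            }
            for c in mask.components
        ],
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return tiff_path, json_path


def read_dab_mask(base: str | Path):
    from .stain import DabMask, MaskComponent

    base = Path(base)
    grid = tifffile.imread(base.with_suffix(".tif")) > 0
    meta = json.loads(base.with_suffix(".json").read_text())
    comps = tuple(
        MaskComponent(
            component_id=c["component_id"],
            pixel_count=c["pixel_count"],
            area_um2=c["area_um2"],
            centroid_um=tuple(c["centroid_um"]),
        )
        for c in meta.get("components", [])
    )
    return DabMask(
        mask=grid,
        spacing_um=meta["spacing_um"],
        offset_um=tuple(meta["offset_um"]),
        components=comps,
    )


# ---------------------------------------------------------------------------
# hotspots

def write_hotspots_json(
    path: str | Path,
    hotspots: Sequence[Hotspot],
    slide_id: str = "slide",
    match: HotspotMatchReport | None = None,
    config: RunConfig | None = None,
) -> None:
    doc: dict[str, Any] = {
        "slide_id": slide_id,
        "tool_version": TOOL_VERSION,
        "config_hash": config_hash(config) if config else None,
        "hotspots": [
            {
                "rank": h.rank,
                "cx_um": h.circle.cx,
                "cy_um": h.circle.cy,
                "radius_um": h.circle.radius,
                "count": h.count,
                "source": h.source.value,
            }
            for h in hotspots
        ],
    }
    if match is not None:
        doc["matches"] = {
            "best_rank": match.best_rank,
            "best_dice": match.best_dice,
            "top3_match": match.top3_match,
            "top10_match": match.top10_match,
            "no_match": match.no_match,
        }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_hotspots_json(path: str | Path) -> tuple[str, list[Hotspot]]:
    doc = json.loads(Path(path).read_text())
    hotspots = [
        Hotspot(
            circle=Circle(h["cx_um"], h["cy_um"], h["radius_um"]),
            count=h["count"],
            rank=h.get("rank", i + 1),
            source=HotspotSource(h.get("source", "AUTO")),
        )
        for i, h in enumerate(doc["hotspots"])
    ]
    return doc.get("slide_id", "slide"), hotspots


# ---------------------------------------------------------------------------
# biomarker table

def write_biomarker_table(path: str | Path, rows: Sequence[dict[str, Any]]) -> None:
    """Per-slide biomarker CSV: slide_id, hotspot_count, tier, entropy, ..."""
    pd.DataFrame(rows).to_csv(path, index=False, na_rep=MISSING)
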