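"""File formats: detection CSV, ROI GeoJSON, WAV, landmarks JSON.

Coordinates in all files are micrometres with the origin at the image top-left and
y increasing ventrally; bregma coordinates are millimetres, positive anterior.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .roi import CELL_COLUMNS, RoiAnnotation
from .striatum import StriatalLandmarks


def read_cells_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing detection columns {missing}")
    return df


def write_cells_csv(cells: pd.DataFrame, path: str | Path) -> None:
    cells[CELL_COLUMNS].to_csv(path, index=False)


def read_rois_geojson(path: str | Path) -> list[RoiAnnotation]:
    """ROI FeatureCollection with properties region, hemisphere, bregma_mm."""
    with open(path) as fh:
        data = json.load(fh)
    rois = []
    for feat in data["features"]:
        props = feat.get("properties", {})
        rois.append(
            RoiAnnotation(
                region=props["region"],
                hemisphere=props["hemisphere"],
                bregma_mm=float(props["bregma_mm"]),
                polygon=shape(feat["geometry"]),
            )
        )
    return rois


def write_rois_geojson(
    rois: list[RoiAnnotation],
    path: str | Path,
    section_ids: list[str] | None = None,
) -> None:
    """Write an ROI FeatureCollection; ``section_ids`` (parallel to ``rois``) adds a
    ``section_id`` property so per-section detection tables can be re-associated."""
    if section_ids is not None and len(section_ids) != len(rois):
        raise ValueError("section_ids must parallel rois")
    features = []
    for k, r in enumerate(rois):
        props = {"region": r.region, "hemisphere": r.hemisphere, "bregma_mm": r.bregma_mm}
        if section_ids is not None:
            props["section_id"] = section_ids[k]
        features.append(
            {"type": "Feature", "geometry": mapping(r.polygon), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_rois_geojson_by_section(path: str | Path) -> dict[str, list[RoiAnnotation]]:
    """ROIs grouped by their ``section_id`` property (required in every feature)."""
    with open(path) as fh:
        data = json.load(fh)
    out: dict[str, list[RoiAnnotation]] = {}
    for feat in data["features"]:
        props = feat.get("properties", {})
        if "section_id" not in props:
            raise ValueError(f"{path}: ROI feature lacks a section_id property")
        out.setdefault(props["section_id"], []).append(
            RoiAnnotation(
                region=props["region"],
                hemisphere=props["hemisphere"],
                bregma_mm=float(props["bregma_mm"]),
                polygon=shape(feat["geometry"]),
            )
        )
    return out


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """PCM WAV as float in [-1, 1] plus the sample rate."""
    from scipy.io import wavfile

    sr, data = wavfile.read(path)
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    else:
        x = data.astype(float)
    if x.ndim > 1:
        x = x[:, 0]
    return x, float(sr)


def write_wav(waveform: np.ndarray, sample_rate_hz: float, path: str | Path) -> None:
    """Write float waveform as 16-bit PCM WAV (clipped to full scale)."""
    from scipy.io import wavfile

    x = np.clip(np.asarray(waveform, float), -1.0, 1.0)
    wavfile.write(path, int(sample_rate_hz), (x * 32767).astype(np.int16))


def read_landmarks_json(path: str | Path) -> StriatalLandmarks:
    with open(path) as fh:
        d = json.load(fh)
    return StriatalLandmarks(
        dorsal_edge_left=tuple(d["dorsal_edge_left"]),
        dorsal_edge_right=tuple(d["dorsal_edge_right"]),
        ac_point=tuple(d["ac_point"]),
        nacs_tip=tuple(d["nacs_tip"]),
        lateral_boundary=tuple(d["lateral_boundary"]),
    )


def write_landmarks_json(lm: StriatalLandmarks, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "dorsal_edge_left": list(lm.dorsal_edge_left),
                "dorsal_edge_right": list(lm.dorsal_edge_right),
                "ac_point": list(lm.ac_point),
                "nacs_tip": list(lm.nacs_tip),
                "lateral_boundary": list(lm.lateral_boundary),
            },
            fh,
        )
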