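"""File formats: TIFF stacks, CSV contours/traces/ROIs, JSON sidecars.

All pixel coordinates on disk are 0-based (x = column, y = row).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .contour import DoubleContour, PolarContour
from .tracking import CellTrack, SignalTrace

__all__ = [
    "read_stack",
    "write_stack",
    "read_ellipses",
    "write_contours",
    "read_contours",
    "write_traces",
    "read_traces",
    "read_rois",
    "write_tracked_rois",
    "write_transforms",
    "write_provenance",
]


def read_stack(path) -> np.ndarray:
    """Read a single-channel multi-page TIFF as a float (frames, H, W) array."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"unsupported TIFF layout {arr.shape}; need single-channel pages"
        )
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:-1]):
        raise ValueError("RGB/multi-channel TIFFs are not supported")
    return arr.astype(float)


def write_stack(path, stack: np.ndarray, dtype=None) -> None:
    stack = np.asarray(stack)
    if dtype is not None:
        stack = stack.astype(dtype)
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_ellipses(path):
    """Initialization ellipses CSV: cell_id, cx, cy, a, b, angle_deg."""
    df = pd.read_csv(path)
    required = {"cell_id", "cx", "cy", "a", "b", "angle_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ellipse CSV is missing columns: {sorted(missing)}")
    df = df.sort_values("cell_id")
    return [
        (row.cx, row.cy, row.a, row.b, np.deg2rad(row.angle_deg))
        for row in df.itertuples()
    ]


def _layers(cell):
    if isinstance(cell, DoubleContour):
        return [("cyt", cell.cytoplasm), ("nuc", cell.nucleus)]
    return [("cyt", cell)]


def write_contours(csv_path, tracks: list[CellTrack]) -> Path:
    """Per-frame node coordinates CSV plus a JSON sidecar with poles and radii."""
    csv_path = Path(csv_path)
    rows = []
    sidecar = []
    for tr in tracks:
        for frame, cell in enumerate(tr.contours):
            for layer, contour in _layers(cell):
                pts = contour.node_positions()
                for k, (x, y) in enumerate(pts):
                    rows.append((frame, tr.cell_id, layer, k, x, y))
                sidecar.append(
                    {
                        "frame": frame,
                        "cell_id": tr.cell_id,
                        "layer": layer,
                        "mode": tr.mode,
                        "status": tr.status[frame],
                        "pole": list(map(float, contour.pole)),
                        "radii": list(map(float, contour.node_radii)),
                        "degree": contour.degree,
                    }
                )
    pd.DataFrame(
        rows, columns=["frame", "cell_id", "layer", "node_index", "x", "y"]
    ).to_csv(csv_path, index=False)
    side_path = csv_path.with_suffix(".json")
    side_path.write_text(json.dumps(sidecar))
    return side_path


def read_contours(csv_path) -> list[CellTrack]:
    """Rebuild CellTracks from a contours CSV's JSON sidecar."""
    side_path = Path(csv_path).with_suffix(".json")
    records = json.loads(side_path.read_text())
    by_cell: dict[int, dict] = {}
    for rec in records:
        cell = by_cell.setdefault(rec["cell_id"], {"mode": rec["mode"], "frames": {}})
        fr = cell["frames"].setdefault(rec["frame"], {"status": rec["status"]})
        fr[rec["layer"]] = PolarContour(rec["pole"], rec["radii"], rec["degree"])
    tracks = []
    for cell_id in sorted(by_cell):
        info = by_cell[cell_id]
        tr = CellTrack(cell_id=cell_id, mode=info["mode"])
        for frame in sorted(info["frames"]):
            fr = info["frames"][frame]
            cell = (
                DoubleContour(fr["nuc"], fr["cyt"])
                if "nuc" in fr
                else fr["cyt"]
            )
            tr.contours.append(cell)
            tr.status.append(fr["status"])
            tr.centroids.append(fr["cyt"].pole.copy())
        tracks.append(tr)
    return tracks


def write_traces(path, traces: list[SignalTrace]) -> None:
    rows = []
    for trace in traces:
        for t in range(len(trace.values)):
            rows.append(
                (
                    t,
                    trace.cell_id,
                    trace.values[t],
                    trace.n_pixels[t],
                    trace.status[t] if t < len(trace.status) else "tracked",
                )
            )
    pd.DataFrame(
        rows, columns=["frame", "cell_id", "mean_intensity", "n_pixels", "status"]
    ).to_csv(path, index=False)


def read_traces(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"frame", "cell_id", "mean_intensity"}
    if not need <= set(df.columns):
        raise ValueError(f"trace CSV needs columns {sorted(need)}")
    return df


def read_rois(path) -> dict[int, np.ndarray]:
    """ROI polygons CSV: roi_id, vertex_index, x, y."""
    df = pd.read_csv(path)
    need = {"roi_id", "vertex_index", "x", "y"}
    if not need <= set(df.columns):
        raise ValueError(f"ROI CSV needs columns {sorted(need)}")
    rois = {}
    for roi_id, grp in df.groupby("roi_id"):
        grp = grp.sort_values("vertex_index")
        rois[int(roi_id)] = grp[["x", "y"]].to_numpy(dtype=float)
    return rois


def write_tracked_rois(path, tracked_rois) -> None:
    rows = []
    for roi in tracked_rois:
        for frame in sorted(roi.vertices):
            for k, (x, y) in enumerate(roi.vertices[frame]):
                rows.append((frame, roi.roi_id, k, x, y))
    pd.DataFrame(rows, columns=["frame", "roi_id", "vertex_index", "x", "y"]).to_csv(
        path, index=False
    )


def write_transforms(path, transforms) -> None:
    out = [
        {
            "frames": list(tf.frames),
            "model": tf.model,
            "params": np.asarray(tf.params).tolist(),
            "residual_rms": tf.residual_rms,
        }
        for tf in transforms
    ]
    Path(path).write_text(json.dumps(out, indent=1))


def write_tracks_json(path, tracks: list[CellTrack]) -> None:
    out = [
        {
            "cell_id": tr.cell_id,
            "mode": tr.mode,
            "status": list(tr.status),
            "centroids": [list(map(float, c)) for c in tr.centroids],
        }
        for tr in tracks
    ]
    Path(path).write_text(json.dumps(out, indent=1))


def read_tracks_json(path):
    """Lightweight track records (centroids + status) for landmark fitting."""
    from types import SimpleNamespace

    data = json.loads(Path(path).read_text())
    return [
        SimpleNamespace(
            cell_id=rec["cell_id"],
            status=rec["status"],
            centroids=[np.asarray(c) for c in rec["centroids"]],
        )
        for rec in data
    ]


def write_provenance(out_dir, config: dict, seed: int | None) -> None:
    """Record config hash, seed and tool version next to every run's outputs."""
    from . import __version__

    canonical = yaml.safe_dump(config, sort_keys=True)
    record = {
        "tool": "beastrack",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "config": config,
    }
    Path(out_dir, "provenance.json").write_text(json.dumps(record, indent=1))
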