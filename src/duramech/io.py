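"""Plain-text I/O: legacy-VTK polydata meshes, frame tables, track tables.

Everything the pipeline writes is human-readable text so that datasets can be
inspected and diffed: legacy ASCII VTK polydata for meshes/frames, CSV for
pressure traces, feature tracks and per-element ground truth, JSON for camera
parameters and fitted constitutive parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import TriMesh

__all__ = [
    "write_vtk_polydata",
    "read_vtk_polydata",
    "write_inflation_dataset",
    "read_inflation_dataset",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_cameras_json",
    "read_cameras_json",
]


def write_vtk_polydata(path, points: np.ndarray, triangles: np.ndarray) -> None:
    """Write a triangulated surface as legacy ASCII VTK polydata."""
    points = np.asarray(points, float)
    triangles = np.asarray(triangles, int)
    lines = [
        "# vtk DataFile Version 3.0",
        "duramech surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(points)} double",
    ]
    lines += [" ".join(f"{c:.12g}" for c in p) for p in points]
    m = len(triangles)
    lines.append(f"POLYGONS {m} {4 * m}")
    lines += ["3 " + " ".join(str(i) for i in t) for t in triangles]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_polydata(path) -> tuple[np.ndarray, np.ndarray]:
    """Read points and triangles back from a legacy ASCII VTK polydata file."""
    tokens = Path(path).read_text().split()
    # skip to POINTS
    i = tokens.index("POINTS")
    n = int(tokens[i + 1])
    pts = np.array(tokens[i + 3 : i + 3 + 3 * n], dtype=float).reshape(n, 3)
    j = tokens.index("POLYGONS")
    m = int(tokens[j + 1])
    body = np.array(tokens[j + 3 : j + 3 + 4 * m], dtype=int).reshape(m, 4)
    if np.any(body[:, 0] != 3):
        raise ValueError("only triangle polydata is supported")
    return pts, body[:, 1:]


def write_inflation_dataset(dataset, out_dir) -> Path:
    """Write mesh, per-frame VTK files, frames.csv and ground-truth sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_vtk_polydata(out / "reference.vtk", dataset.mesh.nodes,
                       dataset.mesh.triangles)
    times = (dataset.times if dataset.times is not None
             else np.arange(dataset.n_frames, dtype=float))
    rows = []
    for k in range(dataset.n_frames):
        write_vtk_polydata(out / f"frame_{k:04d}.vtk", dataset.frames[k],
                           dataset.mesh.triangles)
        rows.append((k, dataset.pressures[k], times[k]))
    pd.DataFrame(rows, columns=["frame_index", "pressure_Pa", "time_s"]).to_csv(
        out / "frames.csv", index=False)
    gt = dataset.ground_truth
    if gt:
        for k in range(dataset.n_frames):
            df = pd.DataFrame({
                "element_id": np.arange(dataset.mesh.n_elements),
                "F11": gt["F"][k][:, 0, 0], "F12": gt["F"][k][:, 0, 1],
                "F21": gt["F"][k][:, 1, 0], "F22": gt["F"][k][:, 1, 1],
                "lambda1": gt["lambda1"][k], "lambda2": gt["lambda2"][k],
                "h_m": gt["h"][k],
                "sigma1_Pa": gt["sigma1"][k], "sigma2_Pa": gt["sigma2"][k],
            })
            df.to_csv(out / f"truth_{k:04d}.csv", index=False)
    return out


def read_inflation_dataset(in_dir):
    """Read a dataset written by :func:`write_inflation_dataset`."""
    from .mesh import InflationDataset

    src = Path(in_dir)
    pts, tris = read_vtk_polydata(src / "reference.vtk")
    table = pd.read_csv(src / "frames.csv")
    frames = np.stack([
        read_vtk_polydata(src / f"frame_{int(k):04d}.vtk")[0]
        for k in table["frame_index"]
    ])
    return InflationDataset(
        mesh=TriMesh(pts, tris),
        frames=frames,
        pressures=table["pressure_Pa"].to_numpy(),
        times=table["time_s"].to_numpy(),
    )


def write_tracks_csv(path, tracks: pd.DataFrame) -> None:
    """Tracks table: track_id, frame, cam in {L,R}, u_px, v_px."""
    cols = ["track_id", "frame", "cam", "u_px", "v_px"]
    tracks[cols].to_csv(path, index=False)


def read_tracks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"track_id", "frame", "cam", "u_px", "v_px"} - set(df.columns)
    if missing:
        raise ValueError(f"tracks CSV missing columns: {sorted(missing)}")
    return df


def write_cameras_json(path, cam_left, cam_right) -> None:
    payload = {"left": cam_left.to_dict(), "right": cam_right.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_cameras_json(path):
    from .stereo import CameraModel

    payload = json.loads(Path(path).read_text())
    return (CameraModel.from_dict(payload["left"]),
            CameraModel.from_dict(payload["right"]))
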