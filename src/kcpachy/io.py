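"""Reading and writing masks, traces, profiles and staging results.

Masks travel as single-channel PNG (0=background, 1=epithelium, 2=stroma)
with a JSON sidecar carrying the pixel geometry and scan metadata; boundary
traces and thickness profiles as tidy CSV; discriminant models and ROC
curves as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from PIL import Image

from .boundaries import BoundarySet, BoundaryTrace
from .geometry import ImageGeometry, StageLabel
from .pachymetry import ThicknessProfile
from .phantom import LabelMask
from .staging import DiscriminantModel, RocResult


def write_mask(mask: LabelMask, path: str | Path, **metadata) -> None:
    """Write a label mask as PNG plus a `.json` geometry sidecar."""
    path = Path(path)
    Image.fromarray(mask.labels.astype(np.uint8), mode="L").save(path)
    g = mask.geometry
    sidecar = {
        "width_px": g.width_px,
        "height_px": g.height_px,
        "pitch_h": g.pitch_h,
        "pitch_v": g.pitch_v,
        **metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_mask(path: str | Path) -> tuple[LabelMask, dict]:
    """Read a PNG mask and its JSON sidecar; returns (mask, metadata)."""
    path = Path(path)
    labels = np.asarray(Image.open(path), dtype=np.uint8)
    meta = json.loads(path.with_suffix(".json").read_text())
    geometry = ImageGeometry(
        width_px=meta.pop("width_px"),
        height_px=meta.pop("height_px"),
        pitch_h=meta.pop("pitch_h"),
        pitch_v=meta.pop("pitch_v"),
    )
    return LabelMask(labels, geometry), meta


def write_traces(bset: BoundarySet, path: str | Path) -> None:
    """Serialize the three traces of a scan as tidy CSV."""
    frames = []
    for trace in bset.traces:
        frames.append(
            pd.DataFrame(
                {
                    "surface": trace.surface,
                    "column": np.round(trace.x / bset.geometry.pitch_h).astype(int),
                    "x_um": trace.x,
                    "y_um": trace.y,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False)


def read_traces(path: str | Path, geometry: ImageGeometry, **metadata) -> BoundarySet:
    df = pd.read_csv(path)
    traces = {}
    for surface, sub in df.groupby("surface"):
        sub = sub.sort_values("x_um")
        traces[surface] = BoundaryTrace(
            surface, sub["x_um"].to_numpy(), sub["y_um"].to_numpy()
        )
    return BoundarySet(
        anterior=traces["anterior"],
        epithelial_interface=traces["epithelial_interface"],
        posterior=traces["posterior"],
        geometry=geometry,
        **metadata,
    )


def profiles_to_frame(profiles: Iterable[ThicknessProfile]) -> pd.DataFrame:
    """Long-form DataFrame: one row per (profile, sample position)."""
    rows = []
    for p in profiles:
        for pos, val in zip(p.positions, p.values):
            rows.append(
                dict(
                    eye_id=p.eye_id,
                    stage=p.stage.name if p.stage is not None else "",
                    laterality=p.laterality,
                    meridian=p.meridian,
                    tissue=p.tissue,
                    position_mm=pos,
                    thickness_um=val,
                )
            )
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame) -> list[ThicknessProfile]:
    """Inverse of :func:`profiles_to_frame`."""
    out = []
    keys = ["eye_id", "stage", "laterality", "meridian", "tissue"]
    for (eye, stage, lat, mer, tissue), sub in df.groupby(keys, sort=False):
        sub = sub.sort_values("position_mm")
        out.append(
            ThicknessProfile(
                meridian=mer,
                tissue=tissue,
                positions=sub["position_mm"].to_numpy(),
                values=sub["thickness_um"].to_numpy(),
                eye_id=eye,
                stage=StageLabel.from_name(stage) if stage else None,
                laterality=lat,
            )
        )
    return out


def write_screen_results(results, path: str | Path) -> None:
    """Write per-stage discriminant models and ROC curves as JSON."""
    payload = {}
    for stage, (model, roc) in results.items():
        payload[stage.name] = {
            "weights": model.weights.tolist(),
            "offset": model.offset,
            "fpr": roc.fpr.tolist(),
            "tpr": roc.tpr.tolist(),
            "auc": roc.auc,
        }
    Path(path).write_text(json.dumps(payload, indent=1))
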