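"""File formats: OME-TIFF stacks, CSV traces/tables, run manifests.

Stacks are written as OME-TIFF with axes TCYX, named channels
("numerator", "denominator"), and the frame interval in the OME
TimeIncrement field; extra provenance (group/mouse/slice, protocol,
seed, drift truth) goes into a JSON blob alongside the OME block.
Channel roles are read back from the OME channel names; if the names
are missing or ambiguous the caller must supply the order explicitly —
ambiguity is an error, never a guess.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .cohort import Cohort
from .pipeline import DriftPath, RatioTrace
from .render import MovieStack

__all__ = [
    "write_movie",
    "read_movie",
    "write_trace",
    "read_trace",
    "write_drift_path",
    "write_cohort",
    "read_manifest",
]

_CHANNEL_NAMES = ("numerator", "denominator")


def _jsonable(meta: dict[str, Any]) -> dict[str, Any]:
    out = {}
    for k, v in meta.items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, (np.integer, np.floating)):
            out[k] = v.item()
        else:
            out[k] = v
    return out


def write_movie(movie: MovieStack, path: str | Path) -> Path:
    """Write a two-channel stack as OME-TIFF (axes TCYX)."""
    path = Path(path)
    data = np.stack([movie.numerator, movie.denominator], axis=1).astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "TCYX",
            "Channel": {"Name": list(_CHANNEL_NAMES)},
            "TimeIncrement": 1.0 / movie.frame_rate,
            "TimeIncrementUnit": "s",
        },
        description=None,
    )
    # provenance sidecar embedded as a TIFF tag is fragile across writers;
    # store it as a JSON companion file
    meta_path = path.with_suffix(path.suffix + ".json")
    meta_path.write_text(json.dumps(_jsonable(movie.metadata), indent=1))
    return path


def read_movie(path: str | Path, *, channel_order: tuple[str, str] | None = None) -> MovieStack:
    """Read a two-channel OME-TIFF stack written by :func:`write_movie`.

    ``channel_order`` maps the file's channel axis to roles when the OME
    channel names are absent; with neither available the read fails.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        axes = tf.series[0].axes
        ome = tf.ome_metadata or ""
    if axes != "TCYX":
        raise ValueError(f"expected TCYX axes, found {axes!r}")
    names: list[str] = []
    frame_rate = None
    if ome:
        import re

        names = re.findall(r'Channel[^>]*Name="([^"]+)"', ome)
        m = re.search(r'TimeIncrement="([0-9.eE+-]+)"', ome)
        if m:
            frame_rate = 1.0 / float(m.group(1))
    if len(names) == 2:
        order = tuple(names)
    elif channel_order is not None:
        order = channel_order
    else:
        raise ValueError("channel roles ambiguous: no OME channel names and no explicit order")
    if sorted(order) != sorted(_CHANNEL_NAMES):
        raise ValueError(f"unrecognised channel roles {order!r}")
    idx = {role: i for i, role in enumerate(order)}
    if frame_rate is None:
        raise ValueError("frame rate missing from OME metadata")

    meta_path = path.with_suffix(path.suffix + ".json")
    metadata: dict[str, Any] = {}
    if meta_path.exists():
        metadata = json.loads(meta_path.read_text())
        if "drift_truth" in metadata:
            metadata["drift_truth"] = np.asarray(metadata["drift_truth"], dtype=int)
    return MovieStack(
        numerator=data[:, idx["numerator"]].astype(float),
        denominator=data[:, idx["denominator"]].astype(float),
        frame_rate=frame_rate,
        metadata=metadata,
    )


def write_trace(trace: RatioTrace, path: str | Path) -> Path:
    path = Path(path)
    n_masked = trace.meta.get("n_masked_pixels")
    df = pd.DataFrame(
        {
            "t_s": trace.t,
            "ratio": trace.r,
            "n_masked_pixels": n_masked if n_masked is not None else -1,
        }
    )
    df.to_csv(path, index=False)
    return path


def read_trace(path: str | Path, frame_rate: float | None = None,
               smoothing_window: int = 1, meta: dict[str, Any] | None = None) -> RatioTrace:
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy(dtype=float)
    if frame_rate is None:
        dt = np.diff(t)
        if len(dt) == 0 or not np.allclose(dt, dt[0]):
            raise ValueError("cannot infer frame rate from a non-uniform time base")
        frame_rate = 1.0 / float(dt[0])
    return RatioTrace(
        t=t,
        r=df["ratio"].to_numpy(dtype=float),
        frame_rate=frame_rate,
        smoothing_window=smoothing_window,
        meta=meta or {},
    )


def write_drift_path(path_obj: DriftPath, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "frame": np.arange(len(path_obj.offsets)),
            "dy_px": path_obj.offsets[:, 0],
            "dx_px": path_obj.offsets[:, 1],
            "score": path_obj.scores,
        }
    ).to_csv(path, index=False)
    return path


def write_cohort(cohort: Cohort, outdir: str | Path, *, config_hash: str = "") -> tuple[Path, Path]:
    """Write stacks (if rendered) or traces, the manifest, and the truth table.

    Returns (manifest_path, truth_path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.records:
        if rec.movie is not None:
            fname = f"{rec.stack_id}.ome.tif"
            write_movie(rec.movie, outdir / fname)
        elif rec.trace is not None:
            fname = f"{rec.stack_id}.trace.csv"
            write_trace(rec.trace, outdir / fname)
        else:
            raise ValueError(f"record {rec.stack_id} has neither movie nor trace")
        rows.append(
            {
                "file": fname,
                "stack_id": rec.stack_id,
                "group": rec.group,
                "mouse": rec.mouse,
                "slice": rec.slice,
                "protocol": cohort.protocol.name,
                "seed": cohort.spec.seed,
                "config_hash": config_hash,
            }
        )
    manifest_path = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    truth_path = outdir / "truth.csv"
    cohort.truth.to_csv(truth_path, index=False)
    return manifest_path, truth_path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"file", "stack_id", "group", "mouse", "slice", "protocol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["stack_id"].duplicated().any():
        raise ValueError("manifest stack ids must be unique")
    return df
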