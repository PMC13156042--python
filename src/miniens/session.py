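"""Session container: one self-describing directory per session.

Layout::

    <session>/
      traces.npy               neurons x frames float64
      footprints_data.npy      concatenated flattened patches
      footprints_shapes.npy    n x 2 patch shapes
      footprints_offsets.npy   n x 2 patch offsets (row, col)
      meta.json                fps, session_id, fov, counts, seed

A session *pair* written by the simulator adds a sibling
``ground_truth.json`` (spike times, identity map, session membership)
next to the two session directories. All files are plain .npy/.json so a
byte-level comparison of two runs is meaningful; writes go through a
temporary file and an atomic rename.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np

from .errors import SchemaError
from .simulate import Footprint, FootprintSet, GroundTruth, SessionData, TraceMatrix

__all__ = ["write_session", "read_session", "write_pair", "read_ground_truth"]


def _atomic_write_bytes(path: Path, data: bytes) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_bytes(data)
    os.replace(tmp, path)


def _save_npy(path: Path, arr: np.ndarray) -> None:
    import io

    buf = io.BytesIO()
    np.save(buf, arr)
    _atomic_write_bytes(path, buf.getvalue())


def write_session(session: SessionData, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _save_npy(path / "traces.npy", session.traces.values)
    fps_set = session.footprints
    shapes = np.array([fp.weights.shape for fp in fps_set], dtype=np.int64)
    offsets = np.array([fp.offset for fp in fps_set], dtype=np.int64)
    data = (
        np.concatenate([fp.weights.ravel() for fp in fps_set])
        if len(fps_set)
        else np.zeros(0)
    )
    _save_npy(path / "footprints_data.npy", data)
    _save_npy(path / "footprints_shapes.npy", shapes)
    _save_npy(path / "footprints_offsets.npy", offsets)
    meta = {
        "fps": session.fps,
        "session_id": session.session_id,
        "fov": list(fps_set.fov),
        "n_neurons": session.traces.n_neurons,
        "n_frames": session.traces.n_frames,
        **{k: v for k, v in session.meta.items() if _jsonable(v)},
    }
    _atomic_write_bytes(
        path / "meta.json", json.dumps(meta, sort_keys=True, indent=1).encode()
    )
    return path


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_session(path: str | Path) -> SessionData:
    path = Path(path)
    for fname in (
        "traces.npy",
        "footprints_data.npy",
        "footprints_shapes.npy",
        "footprints_offsets.npy",
        "meta.json",
    ):
        if not (path / fname).exists():
            raise SchemaError(f"session container missing component: {fname}")
    meta = json.loads((path / "meta.json").read_text())
    for key in ("fps", "session_id", "fov", "n_neurons", "n_frames"):
        if key not in meta:
            raise SchemaError(f"meta.json missing field: {key}")
    traces = np.load(path / "traces.npy")
    if not np.all(np.isfinite(traces)):
        raise SchemaError("traces: contains NaN or infinite values")
    if traces.shape != (meta["n_neurons"], meta["n_frames"]):
        raise SchemaError(
            f"traces: shape {traces.shape} does not match meta "
            f"({meta['n_neurons']}, {meta['n_frames']})"
        )
    data = np.load(path / "footprints_data.npy")
    shapes = np.load(path / "footprints_shapes.npy")
    offsets = np.load(path / "footprints_offsets.npy")
    if shapes.shape[0] != traces.shape[0]:
        raise SchemaError(
            f"footprints: {shapes.shape[0]} footprints for {traces.shape[0]} trace rows"
        )
    sizes = shapes.prod(axis=1)
    if sizes.sum() != data.size:
        raise SchemaError("footprints: patch data length mismatch")
    fov = tuple(int(v) for v in meta["fov"])
    fps_list = []
    pos = 0
    for (h, w), (r0, c0) in zip(shapes, offsets):
        patch = data[pos : pos + h * w].reshape(h, w)
        pos += h * w
        fps_list.append(Footprint(patch, (int(r0), int(c0)), fov))
    extra = {
        k: v
        for k, v in meta.items()
        if k not in ("fps", "session_id", "fov", "n_neurons", "n_frames")
    }
    return SessionData(
        TraceMatrix(traces, fps=meta["fps"], session_id=meta["session_id"]),
        FootprintSet(fps_list, fov),
        fps=meta["fps"],
        session_id=meta["session_id"],
        meta=extra,
    )


def write_pair(
    s1: SessionData, s2: SessionData, gt: GroundTruth | None, path: str | Path
) -> Path:
    path = Path(path)
    write_session(s1, path / "session1")
    write_session(s2, path / "session2")
    if gt is not None:
        payload = {
            "spike_times": {
                sid: [t.tolist() for t in trains] for sid, trains in gt.spike_times.items()
            },
            "identity_map": [list(p) for p in gt.identity_map],
            "session_membership": gt.session_membership,
        }
        _atomic_write_bytes(
            path / "ground_truth.json", json.dumps(payload, sort_keys=True).encode()
        )
    return path


def read_ground_truth(path: str | Path) -> GroundTruth | None:
    """Load pair-level ground truth if present, else None."""
    p = Path(path) / "ground_truth.json"
    if not p.exists():
        return None
    payload = json.loads(p.read_text())
    return GroundTruth(
        spike_times={
            sid: [np.asarray(t) for t in trains]
            for sid, trains in payload["spike_times"].items()
        },
        identity_map=[tuple(p_) for p_ in payload["identity_map"]],
        session_membership=payload["session_membership"],
    )
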