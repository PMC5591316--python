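"""Reading and writing trace data.

Single traces travel as TSV (columns frame, excitation, I_ch3, I_ch5,
I_ch7); collections of traces, optionally with simulated ground truth, are
stored in an HDF5 container.  FRET series export as TSV via
:meth:`ribofret.fret.FretSeries.to_frame`.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import DYES, GroundTruth, RawTrace

logger = logging.getLogger(__name__)

__all__ = ["write_trace_tsv", "read_trace_tsv", "write_traces_h5", "read_traces_h5"]

_COLUMNS = ["frame", "excitation", "I_ch3", "I_ch5", "I_ch7"]


class TraceFormatError(ValueError):
    pass


def write_trace_tsv(trace: RawTrace, path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(trace.n_frames),
            "excitation": trace.excitation,
            "I_ch3": trace.intensities[:, 0],
            "I_ch5": trace.intensities[:, 1],
            "I_ch7": trace.intensities[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_trace_tsv(path, frame_duration: float = 0.05) -> RawTrace | None:
    """Read one TSV trace; returns None (with a warning) for an empty file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        logger.warning("empty trace file %s", path)
        return None
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        logger.warning("empty trace file %s", path)
        return None
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing column(s) {missing}")
    bad = ~df["excitation"].isin(["G", "R"])
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise TraceFormatError(
            f"{path}: unknown excitation label "
            f"{df['excitation'][bad].iloc[0]!r} at line {line}"
        )
    ragged = df[["I_ch3", "I_ch5", "I_ch7"]].isna().any(axis=1)
    if ragged.any():
        line = int(df.index[ragged][0]) + 2
        raise TraceFormatError(f"{path}: ragged/missing channel values at line {line}")
    return RawTrace(
        intensities=df[["I_ch3", "I_ch5", "I_ch7"]].to_numpy(dtype=float),
        excitation=df["excitation"].to_numpy(dtype="U1"),
        frame_duration=frame_duration,
        trace_id=path.stem,
    )


def read_traces_dir(directory, pattern: str = "*.tsv") -> list[RawTrace]:
    traces = []
    for p in sorted(Path(directory).glob(pattern)):
        t = read_trace_tsv(p)
        if t is not None:
            traces.append(t)
    return traces


def write_traces_h5(pairs, path) -> None:
    """Write (RawTrace, GroundTruth | None) pairs to an HDF5 container."""
    with h5py.File(path, "w") as f:
        for i, (trace, gt) in enumerate(pairs):
            grp = f.create_group(f"trace{i:05d}")
            grp.create_dataset("intensities", data=trace.intensities)
            grp.create_dataset(
                "excitation", data=np.char.encode(trace.excitation, "ascii")
            )
            grp.attrs["frame_duration"] = trace.frame_duration
            grp.attrs["trace_id"] = trace.trace_id
            if gt is not None:
                g = grp.create_group("ground_truth")
                g.create_dataset(
                    "state_segments",
                    data=np.array(
                        [(s.encode(), a, b) for s, a, b in gt.state_segments],
                        dtype=[("state", "S8"), ("start", "i8"), ("end", "i8")],
                    ),
                )
                g.create_dataset(
                    "binding_events",
                    data=np.array(
                        [(a, -1 if b is None else b) for a, b in gt.binding_events],
                        dtype=[("on", "i8"), ("off", "i8")],
                    ),
                )
                g.attrs["t_inject"] = gt.t_inject
                for dye in DYES:
                    bf = gt.bleach_frames.get(dye)
                    g.attrs[f"bleach_{dye}"] = -1 if bf is None else bf


def read_traces_h5(path) -> list[tuple[RawTrace, GroundTruth | None]]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f):
            grp = f[key]
            trace = RawTrace(
                intensities=grp["intensities"][...],
                excitation=np.char.decode(grp["excitation"][...], "ascii"),
                frame_duration=float(grp.attrs["frame_duration"]),
                trace_id=str(grp.attrs["trace_id"]),
            )
            gt = None
            if "ground_truth" in grp:
                g = grp["ground_truth"]
                segs = [
                    (s.decode(), int(a), int(b))
                    for s, a, b in g["state_segments"][...]
                ]
                events = [
                    (int(a), None if b < 0 else int(b))
                    for a, b in g["binding_events"][...]
                ]
                bleach = {
                    dye: (None if g.attrs[f"bleach_{dye}"] < 0 else int(g.attrs[f"bleach_{dye}"]))
                    for dye in DYES
                }
                gt = GroundTruth(
                    state_segments=segs,
                    binding_events=events,
                    bleach_frames=bleach,
                    t_inject=float(g.attrs["t_inject"]),
                )
            out.append((trace, gt))
    return out
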