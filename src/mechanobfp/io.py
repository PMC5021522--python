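"""Session persistence: tidy CSV traces plus a JSON sidecar.

A session directory holds one CSV per cycle trace (columns ``time_s``,
``force_pN``, ``probe_nm``, ``target_nm``) and ``session.json`` with the
simulation parameters, per-cycle outcomes/ground truth and the calcium
trace.  The format is versioned and the round trip is lossless (floats are
written at full precision).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CalciumTrace, ForceTrace, GroundTruth, SimParams, UnfoldTruth

__all__ = ["write_session", "read_session", "trace_checksum", "SessionParseError"]

FORMAT_VERSION = 1
TRACE_COLUMNS = ["time_s", "force_pN", "probe_nm", "target_nm"]


class SessionParseError(ValueError):
    """Raised when a session file is malformed; names the offending record."""


def _truth_to_dict(truth: GroundTruth) -> dict:
    d = {
        "bond_formed": truth.bond_formed,
        "outcome": truth.outcome,
        "lifetime": truth.lifetime,
        "rupture_force": truth.rupture_force,
        "lrrd_unfolded": truth.lrrd_unfolded,
        "msd_clamped_unfolded": truth.msd_clamped_unfolded,
        "calcium_type": truth.calcium_type,
        "start_time": getattr(truth, "start_time", None),
        "events": [dataclasses.asdict(e) for e in truth.events],
    }
    return d


def _truth_from_dict(d: dict) -> GroundTruth:
    truth = GroundTruth(
        bond_formed=d["bond_formed"], outcome=d["outcome"],
        lifetime=d["lifetime"], rupture_force=d["rupture_force"],
        lrrd_unfolded=d["lrrd_unfolded"],
        msd_clamped_unfolded=d["msd_clamped_unfolded"],
        calcium_type=d["calcium_type"],
        events=[UnfoldTruth(**e) for e in d["events"]],
    )
    if d.get("start_time") is not None:
        truth.start_time = d["start_time"]
    return truth


def write_session(path, cycles, calcium: CalciumTrace | None = None,
                  params: SimParams | None = None) -> Path:
    """Write a session (list of (trace, truth) pairs) to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": FORMAT_VERSION,
        "params": dataclasses.asdict(params) if params is not None else None,
        "cycles": [],
        "calcium": None,
    }
    for i, (trace, truth) in enumerate(cycles):
        rec = _truth_to_dict(truth)
        rec["trace_file"] = None
        if trace is not None:
            fname = f"cycle_{i:04d}.csv"
            df = pd.DataFrame({
                "time_s": trace.time, "force_pN": trace.force,
                "probe_nm": trace.probe_nm, "target_nm": trace.target_nm,
            })
            df.to_csv(path / fname, index=False, float_format="%.17g")
            rec["trace_file"] = fname
            rec["trace_meta"] = {
                "mode": trace.mode,
                "spring_constant": trace.spring_constant,
                "sample_rate": trace.sample_rate,
                "clamp_force": trace.clamp_force,
                "segments": trace.segments,
            }
        meta["cycles"].append(rec)
    if calcium is not None:
        meta["calcium"] = {
            "time": calcium.time.tolist(),
            "intensity": calcium.intensity.tolist(),
            "ca_type": calcium.ca_type,
            "onset_time": calcium.onset_time,
            "delta_i_max": calcium.delta_i_max,
        }
    with open(path / "session.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return path


def read_session(path):
    """Read a session directory; returns (cycles, calcium, params)."""
    path = Path(path)
    meta_file = path / "session.json"
    if not meta_file.exists():
        raise SessionParseError(f"missing session.json in {path}")
    with open(meta_file) as fh:
        meta = json.load(fh)
    if meta.get("format_version") != FORMAT_VERSION:
        raise SessionParseError(
            f"unsupported format version {meta.get('format_version')!r}")
    params = SimParams(**meta["params"]) if meta.get("params") else None
    cycles = []
    for i, rec in enumerate(meta["cycles"]):
        truth = _truth_from_dict(rec)
        trace = None
        if rec.get("trace_file"):
            fname = rec["trace_file"]
            df = pd.read_csv(path / fname, float_precision="round_trip")
            missing = [c for c in TRACE_COLUMNS if c not in df.columns]
            if missing:
                raise SessionParseError(
                    f"{fname}: missing column(s) {missing}")
            tm = rec.get("trace_meta", {})
            trace = ForceTrace(
                time=df["time_s"].to_numpy(),
                force=df["force_pN"].to_numpy(),
                probe_nm=df["probe_nm"].to_numpy(),
                target_nm=df["target_nm"].to_numpy(),
                mode=tm.get("mode", "clamp"),
                spring_constant=tm.get("spring_constant", 0.3),
                sample_rate=tm.get("sample_rate", 1000.0),
                clamp_force=tm.get("clamp_force"),
                segments={k: int(v) for k, v in tm.get("segments", {}).items()},
            )
        cycles.append((trace, truth))
    calcium = None
    if meta.get("calcium"):
        c = meta["calcium"]
        calcium = CalciumTrace(
            time=np.asarray(c["time"]), intensity=np.asarray(c["intensity"]),
            ca_type=c["ca_type"], onset_time=c["onset_time"],
            delta_i_max=c["delta_i_max"],
        )
    return cycles, calcium, params


def trace_checksum(csv_path, chunk_size: int = 10000) -> str:
    """SHA-256 of a trace CSV's numeric content, streamed in chunks.

    Reads the file incrementally so a full session at acquisition rate never
    has to be resident in memory; the digest is over the canonical repr of
    each chunk's values, so it is independent of chunking.
    """
    h = hashlib.sha256()
    for chunk in pd.read_csv(csv_path, chunksize=chunk_size,
                             float_precision="round_trip"):
        arr = np.ascontiguousarray(chunk.to_numpy(dtype=float))
        h.update(arr.tobytes())
    return h.hexdigest()
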