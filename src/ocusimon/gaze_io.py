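"""Session serialization: CSV recordings + YAML manifest with checksums.

A session bundle (designs, gaze recordings, optional ground truth) is
written as plain CSV files plus a YAML manifest listing each file's SHA-256
checksum, so downstream stages can be decoupled, replayed, and verified.
Two recording dialects are supported: one long CSV with a trial key, or one
CSV per trial.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .design_sim import TrialDesign, TrialRecording

__all__ = ["SessionBundle", "IntegrityError", "FormatError",
           "write_session", "read_session"]

_RECORDING_COLUMNS = ["t_ms", "x_deg", "y_deg"]
_KEY = ["participant_id", "block", "trial"]


class IntegrityError(RuntimeError):
    """Checksum mismatch between manifest and file contents."""


class FormatError(RuntimeError):
    """Structurally invalid session file."""


@dataclass
class SessionBundle:
    recordings: list[TrialRecording]
    designs: list[TrialDesign]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.recordings) != len(self.designs):
            raise ValueError("one design required per recording")
        rec_keys = {(r.design.participant_id, r.design.block, r.design.trial)
                    for r in self.recordings}
        des_keys = {(d.participant_id, d.block, d.trial) for d in self.designs}
        if rec_keys != des_keys:
            raise ValueError("recordings and designs keys do not match")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _designs_frame(designs: Sequence[TrialDesign]) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant_id": d.participant_id,
        "block": d.block,
        "trial": d.trial,
        "target_color": d.target_color,
        "target_side": d.target_side,
        "left_color": d.left_color,
        "fixation_duration_ms": d.fixation_duration_ms,
        "target_duration_ms": d.target_duration_ms,
        "iti_ms": d.iti_ms,
    } for d in designs])


def write_session(
    bundle: SessionBundle, directory: str | Path, layout: str = "long"
) -> Path:
    """Write all session CSVs plus a checksummed manifest; returns its path.

    ``layout='long'`` writes one recordings.csv keyed by trial;
    ``layout='per-trial'`` writes one file per trial under recordings/.
    """
    if layout not in ("long", "per-trial"):
        raise ValueError(f"unknown layout {layout!r}")
    if not bundle.provenance:
        raise ValueError("provenance must be non-empty on write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    files: dict[str, str] = {}

    designs_path = directory / "designs.csv"
    _designs_frame(bundle.designs).to_csv(designs_path, index=False)
    files["designs.csv"] = _sha256(designs_path)

    events_rows, gt_rows = [], []
    for rec in bundle.recordings:
        key = {"participant_id": rec.design.participant_id,
               "block": rec.design.block, "trial": rec.design.trial}
        for label, t in rec.events.items():
            events_rows.append({**key, "label": label, "t_ms": t})
        gt_rows.append({
            **key,
            "true_rt_ms": np.nan if rec.true_rt_ms is None else rec.true_rt_ms,
            "true_side": rec.true_side if rec.true_side else "none",
            "true_onset_index": (-1 if rec.true_onset_index is None
                                 else rec.true_onset_index),
        })

    if layout == "long":
        frames = []
        for rec in bundle.recordings:
            frames.append(pd.DataFrame({
                "participant_id": rec.design.participant_id,
                "block": rec.design.block,
                "trial": rec.design.trial,
                "t_ms": rec.t_ms, "x_deg": rec.x_deg, "y_deg": rec.y_deg,
            }))
        rec_path = directory / "recordings.csv"
        pd.concat(frames, ignore_index=True).to_csv(rec_path, index=False)
        files["recordings.csv"] = _sha256(rec_path)
    else:
        rec_dir = directory / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for rec in bundle.recordings:
            name = (f"recordings/{rec.design.participant_id}"
                    f"_b{rec.design.block}_t{rec.design.trial:03d}.csv")
            path = directory / name
            pd.DataFrame({
                "t_ms": rec.t_ms, "x_deg": rec.x_deg, "y_deg": rec.y_deg,
            }).to_csv(path, index=False)
            files[name] = _sha256(path)

    events_path = directory / "events.csv"
    pd.DataFrame(events_rows).to_csv(events_path, index=False)
    files["events.csv"] = _sha256(events_path)

    gt_path = directory / "ground_truth.csv"
    pd.DataFrame(gt_rows).to_csv(gt_path, index=False)
    files["ground_truth.csv"] = _sha256(gt_path)

    manifest = {
        "format": "ocusimon-session/1",
        "layout": layout,
        "n_trials": len(bundle.recordings),
        "provenance": bundle.provenance,
        "files": files,
    }
    manifest_path = directory / "manifest.yaml"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path


def _check_recording_frame(df: pd.DataFrame, name: str) -> None:
    for col in _RECORDING_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{name}: missing column {col!r}")
    t = df["t_ms"].to_numpy(dtype=float)
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise FormatError(f"{name}: t_ms not strictly increasing")


def read_session(manifest_path: str | Path) -> SessionBundle:
    """Read, checksum-verify, and validate a session written by write_session."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    for name, digest in manifest["files"].items():
        path = directory / name
        if not path.exists():
            raise IntegrityError(f"missing file {name}")
        if _sha256(path) != digest:
            raise IntegrityError(f"checksum mismatch for {name}")

    designs_df = pd.read_csv(directory / "designs.csv")
    designs = [
        TrialDesign(
            participant_id=str(r.participant_id), block=int(r.block),
            trial=int(r.trial), target_color=r.target_color,
            target_side=r.target_side, left_color=r.left_color,
            fixation_duration_ms=float(r.fixation_duration_ms),
            target_duration_ms=float(r.target_duration_ms),
            iti_ms=float(r.iti_ms),
        )
        for r in designs_df.itertuples()
    ]
    design_map = {(d.participant_id, d.block, d.trial): d for d in designs}

    events_df = pd.read_csv(directory / "events.csv")
    events_map: dict[tuple, dict[str, float]] = {}
    for r in events_df.itertuples():
        events_map.setdefault(
            (str(r.participant_id), int(r.block), int(r.trial)), {}
        )[r.label] = float(r.t_ms)

    gt_df = pd.read_csv(directory / "ground_truth.csv")
    gt_map = {(str(r.participant_id), int(r.block), int(r.trial)): r
              for r in gt_df.itertuples()}

    recordings: list[TrialRecording] = []
    if manifest["layout"] == "long":
        long_df = pd.read_csv(directory / "recordings.csv")
        for col in _KEY + _RECORDING_COLUMNS:
            if col not in long_df.columns:
                raise FormatError(f"recordings.csv: missing column {col!r}")
        groups = long_df.groupby(_KEY, sort=False)
        trial_frames = {
            (str(pid), int(blk), int(tr)): g
            for (pid, blk, tr), g in groups
        }
    else:
        trial_frames = {}
        for name in manifest["files"]:
            if not name.startswith("recordings/"):
                continue
            stem = Path(name).stem            # e.g. P01_b2_t013
            pid, b, t = stem.rsplit("_", 2)
            trial_frames[(pid, int(b[1:]), int(t[1:]))] = pd.read_csv(
                directory / name
            )

    for key, d in design_map.items():
        if key not in trial_frames:
            raise FormatError(f"missing recording for trial {key}")
        g = trial_frames[key]
        _check_recording_frame(g, f"recording {key}")
        ev = events_map.get(key, {})
        for required in ("fixation_onset", "target_onset", "target_offset"):
            if required not in ev:
                raise FormatError(f"trial {key}: missing event {required!r}")
        gt = gt_map.get(key)
        rt = None
        onset_idx = None
        side = "none"
        if gt is not None:
            rt = None if pd.isna(gt.true_rt_ms) else float(gt.true_rt_ms)
            side = str(gt.true_side)
            onset_idx = None if gt.true_onset_index < 0 else int(gt.true_onset_index)
        recordings.append(TrialRecording(
            design=d,
            t_ms=g["t_ms"].to_numpy(dtype=float),
            x_deg=g["x_deg"].to_numpy(dtype=float),
            y_deg=g["y_deg"].to_numpy(dtype=float),
            events=ev,
            true_rt_ms=rt, true_side=side, true_onset_index=onset_idx,
        ))

    return SessionBundle(
        recordings=recordings, designs=designs,
        provenance=manifest.get("provenance", {}),
    )
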