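"""Readers and writers: BIDS-style events, NIfTI volumes, tables, designs.

Events are serialized one TSV per scan (columns ``onset``, ``duration``,
``trial_type``) with a JSON sidecar holding TR, volume count, and the
generating seed, so a timeline round-trips exactly. NIfTI handling wraps
nibabel and passes world coordinates through untouched.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import ColumnInfo, DesignMatrix
from .exceptions import EventsParseError
from .paradigm import (
    CONDITIONS,
    DesignTimeline,
    ScanTimeline,
    TrialSpec,
)

__all__ = [
    "write_events",
    "read_events",
    "write_volume",
    "read_volume",
    "apply_mask",
    "write_design",
    "read_design",
    "read_roi_table",
    "write_roi_table",
]

_REINFORCER_KINDS = ("shock", "image", "audio", "benign")


def _events_frame(scan: ScanTimeline) -> pd.DataFrame:
    rows = []
    for t in scan.trials:
        rows.append(dict(onset=t.onset_s, duration=t.antic_dur_s,
                         trial_type=f"{t.condition}_antic"))
        for kind, onset, dur in t.reinforcer_events:
            rows.append(dict(onset=onset, duration=dur, trial_type=kind))
        rows.append(dict(onset=t.mask_onset_s, duration=t.mask_dur_s,
                         trial_type="mask"))
    return pd.DataFrame(rows).sort_values("onset", kind="stable").reset_index(drop=True)


def write_events(timeline: DesignTimeline, out_dir) -> list:
    """Write one events TSV per scan plus a JSON sidecar; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, scan in enumerate(timeline.scans):
        path = out_dir / f"scan-{i + 1}_events.tsv"
        _events_frame(scan).to_csv(path, sep="\t", index=False)
        paths.append(path)
    sidecar = out_dir / "events.json"
    sidecar.write_text(json.dumps(dict(
        seed=timeline.seed,
        tr_s=timeline.tr_s,
        n_volumes=timeline.n_volumes,
        n_scans=len(timeline.scans),
    ), indent=2))
    return paths


def _parse_scan_events(path, tr_s, n_volumes) -> ScanTimeline:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise EventsParseError(f"{path}: empty events file")
    for col in ("onset", "duration", "trial_type"):
        if col not in df.columns:
            raise EventsParseError(f"{path}: missing column {col!r}")
    if len(df) == 0:
        raise EventsParseError(f"{path}: no events")

    trials = []
    current = None
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            onset = float(row["onset"])
            dur = float(row["duration"])
        except (TypeError, ValueError):
            raise EventsParseError(
                f"{path}: non-numeric onset/duration", line=line
            )
        if not np.isfinite(onset) or not np.isfinite(dur):
            raise EventsParseError(f"{path}: non-finite timing", line=line)
        if dur < 0:
            raise EventsParseError(f"{path}: negative duration", line=line)
        ttype = str(row["trial_type"])
        if ttype.endswith("_antic"):
            cond = ttype[: -len("_antic")]
            if cond not in CONDITIONS:
                raise EventsParseError(
                    f"{path}: unknown condition {cond!r}", line=line
                )
            certainty, valence = cond.split("_")
            current = TrialSpec(
                valence=valence, certainty=certainty,
                onset_s=onset, antic_dur_s=dur,
                reinforcer_events=[], mask_onset_s=onset + dur,
            )
            trials.append(current)
        elif ttype in _REINFORCER_KINDS:
            if current is None:
                raise EventsParseError(
                    f"{path}: reinforcer before any trial", line=line
                )
            current.reinforcer_events.append((ttype, onset, dur))
        elif ttype == "mask":
            if current is None:
                raise EventsParseError(f"{path}: mask before any trial", line=line)
            current.mask_onset_s = onset
            current.mask_dur_s = dur
        elif ttype == "rating":
            if current is not None:
                current.rating_event = (onset, dur)
        else:
            raise EventsParseError(
                f"{path}: unknown trial_type {ttype!r}", line=line
            )
    for t in trials:
        t.validate()
    return ScanTimeline(tr_s=tr_s, n_volumes=n_volumes, trials=trials)


def read_events(in_dir) -> DesignTimeline:
    """Read a directory written by :func:`write_events`."""
    in_dir = Path(in_dir)
    sidecar = in_dir / "events.json"
    if not sidecar.exists():
        raise EventsParseError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    scans = []
    for i in range(int(meta["n_scans"])):
        path = in_dir / f"scan-{i + 1}_events.tsv"
        if not path.exists():
            raise EventsParseError(f"missing events file {path}")
        scans.append(_parse_scan_events(path, meta["tr_s"], meta["n_volumes"]))
    return DesignTimeline(scans=scans, seed=int(meta["seed"]))


# ---------------------------------------------------------------------------
# NIfTI volumes

def write_volume(data, path, affine=None):
    """Write a 3D/4D array as NIfTI-1."""
    affine = np.eye(4) if affine is None else np.asarray(affine)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_volume(path):
    """Read a NIfTI file; returns ``(data, affine)``."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def apply_mask(series4d, mask3d, series_affine=None, mask_affine=None):
    """Extract in-mask voxel time series from a 4D array.

    Returns (time x voxels) in stable C order of the mask. Affines, when
    both given, must match.
    """
    series4d = np.asarray(series4d)
    mask3d = np.asarray(mask3d).astype(bool)
    if series4d.shape[:3] != mask3d.shape:
        raise ValueError(
            f"mask shape {mask3d.shape} does not match series {series4d.shape[:3]}"
        )
    if series_affine is not None and mask_affine is not None:
        if not np.allclose(series_affine, mask_affine):
            raise ValueError("mask and series affines differ")
    return series4d[mask3d, :].T


# ---------------------------------------------------------------------------
# design matrices and ROI tables

def write_design(design: DesignMatrix, path):
    """Serialize a design matrix as TSV with a JSON header line."""
    path = Path(path)
    header = dict(
        model=design.model,
        tr_s=design.tr_s,
        scan_lengths=list(design.scan_lengths),
        labels=[[l.condition, l.component, l.scan] for l in design.labels],
        reference_record=[list(r) for r in design.reference_record],
    )
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        design.frame.to_csv(fh, sep="\t", index=False)


def read_design(path) -> DesignMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise EventsParseError(f"{path}: missing design header")
        header = json.loads(first[2:])
        df = pd.read_csv(fh, sep="\t")
    labels = [
        ColumnInfo(c, comp, scan=None if s is None else int(s))
        for c, comp, s in header["labels"]
    ]
    return DesignMatrix(
        X=df.to_numpy(dtype=float),
        labels=labels,
        reference_record=[tuple(r) for r in header["reference_record"]],
        tr_s=float(header["tr_s"]),
        scan_lengths=[int(v) for v in header["scan_lengths"]],
        model=header.get("model", ""),
    )


ROI_COLUMNS = ("subject", "region", "certainty", "block", "value")


def read_roi_table(path) -> pd.DataFrame:
    """Long-format ROI activation table (subject, region, certainty,
    block, value)."""
    df = pd.read_csv(path)
    missing = set(ROI_COLUMNS) - set(df.columns)
    if missing:
        raise EventsParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_roi_table(df: pd.DataFrame, path):
    df.to_csv(path, index=False, columns=list(ROI_COLUMNS))
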