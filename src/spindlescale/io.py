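"""CSV interchange for every record type, and JSON report helpers.

All tabular artifacts are RFC-4180 CSV with header rows; units are encoded
in the column names (``V_cell_um3``, ``rho_mg_per_ml``, ``frame_time_s``).
Readers validate row by row and report invariant violations with the
offending CSV line number rather than failing wholesale.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .records import (
    BlotDataset,
    CellRecord,
    CometTrack,
    FrapTrace,
    HalfSpindleProfile,
    Lineage,
    RIMeasurement,
)

CELL_COLUMNS = [
    "cell_id", "state_label", "time_bin_h", "V_cell_um3", "V_spindle_um3",
    "spindle_length_um", "spindle_width_um", "V_centrosome_um3",
    "rho_mg_per_ml", "mean_tubulin_signal_au", "n_astral_true",
]


def write_cell_records(records: Sequence[CellRecord], path) -> None:
    rows = [
        {
            "cell_id": r.cell_id,
            "state_label": r.state_label,
            "time_bin_h": r.time_bin_h,
            "V_cell_um3": r.V_cell,
            "V_spindle_um3": r.V_spindle,
            "spindle_length_um": r.spindle_length,
            "spindle_width_um": r.spindle_width,
            "V_centrosome_um3": r.V_centrosome,
            "rho_mg_per_ml": r.mass_density,
            "mean_tubulin_signal_au": r.mean_tubulin_signal,
            "n_astral_true": "" if r.n_astral_true is None else r.n_astral_true,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CELL_COLUMNS).to_csv(path, index=False)


def read_cell_records(path) -> list[CellRecord]:
    """Read and validate a cell-record CSV.

    Raises :class:`ValidationError` listing every offending row (1-based CSV
    line numbers, header = line 1) when any record violates its invariants;
    a missing mandatory column rejects the whole file.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing mandatory columns {missing}")
    records, problems = [], []
    for idx, row in df.iterrows():
        try:
            n_ast = row["n_astral_true"]
            records.append(CellRecord(
                cell_id=str(row["cell_id"]),
                state_label=str(row["state_label"]),
                time_bin_h=float(row["time_bin_h"]),
                V_cell=float(row["V_cell_um3"]),
                V_spindle=float(row["V_spindle_um3"]),
                spindle_length=float(row["spindle_length_um"]),
                spindle_width=float(row["spindle_width_um"]),
                V_centrosome=float(row["V_centrosome_um3"]),
                mass_density=float(row["rho_mg_per_ml"]),
                mean_tubulin_signal=float(row["mean_tubulin_signal_au"]),
                n_astral_true=None if pd.isna(n_ast) else int(n_ast),
            ))
        except (ValidationError, ValueError) as exc:
            problems.append(f"line {idx + 2}: {exc}")
    if problems:
        raise ValidationError(
            f"{path}: {len(problems)} invalid row(s):\n" + "\n".join(problems)
        )
    return records


def write_frap_traces(traces: Sequence[FrapTrace], path) -> None:
    rows = []
    for i, tr in enumerate(traces):
        for j, t in enumerate(tr.frame_times):
            rows.append({
                "trace_id": f"trace-{i:04d}",
                "frame_time_s": float(t),
                "bleach_roi": float(tr.bleach_roi[j]),
                "control_roi": float(tr.control_roi[j]),
                "phase": "pre" if j < tr.bleach_index else "post",
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_frap_traces(path) -> list[FrapTrace]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"trace_id", "frame_time_s", "bleach_roi", "control_roi", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing mandatory columns {sorted(missing)}")
    traces = []
    for _, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("frame_time_s")
        n_pre = int((grp["phase"] == "pre").sum())
        traces.append(FrapTrace(
            frame_times=grp["frame_time_s"].to_numpy(float),
            bleach_roi=grp["bleach_roi"].to_numpy(float),
            control_roi=grp["control_roi"].to_numpy(float),
            bleach_index=n_pre,
        ))
    return traces


def write_comet_tracks(tracks: Sequence[CometTrack], path) -> None:
    rows = []
    for tr in tracks:
        for j in range(tr.n_frames):
            rows.append({
                "cell_id": tr.cell_id,
                "track_id": tr.track_id,
                "frame": tr.start_frame + j,
                "x_um": float(tr.positions[j, 0]),
                "y_um": float(tr.positions[j, 1]),
                "quality": float(tr.quality[j]) if tr.quality is not None else "",
                "compartment": tr.compartment,
                "frame_interval_s": tr.frame_interval,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_comet_tracks(path) -> list[CometTrack]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"cell_id", "track_id", "frame", "x_um", "y_um",
                "compartment", "frame_interval_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing mandatory columns {sorted(missing)}")
    tracks = []
    for (_, track_id), grp in df.groupby(["cell_id", "track_id"], sort=True):
        grp = grp.sort_values("frame")
        quality = None
        if "quality" in grp.columns and grp["quality"].notna().all():
            quality = grp["quality"].to_numpy(float)
        tracks.append(CometTrack(
            cell_id=str(grp["cell_id"].iloc[0]),
            track_id=str(track_id),
            positions=grp[["x_um", "y_um"]].to_numpy(float),
            frame_interval=float(grp["frame_interval_s"].iloc[0]),
            quality=quality,
            compartment=str(grp["compartment"].iloc[0]),
            start_frame=int(grp["frame"].min()),
        ))
    return tracks


def write_profiles(profiles: Sequence[HalfSpindleProfile], path) -> None:
    rows = []
    for i, p in enumerate(profiles):
        for x, y in zip(p.distance, p.intensity):
            rows.append({
                "profile_id": f"profile-{i:04d}",
                "distance_norm": float(x),
                "intensity_norm": float(y),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles(path) -> list[HalfSpindleProfile]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"profile_id", "distance_norm", "intensity_norm"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing mandatory columns {sorted(missing)}")
    profiles = []
    for _, grp in df.groupby("profile_id", sort=True):
        grp = grp.sort_values("distance_norm")
        profiles.append(HalfSpindleProfile(
            distance=grp["distance_norm"].to_numpy(float),
            intensity=grp["intensity_norm"].to_numpy(float),
        ))
    return profiles


def write_blot(blot: BlotDataset, standards_path, lanes_path) -> None:
    pd.DataFrame(
        [{"loaded_tubulin_ng": m, "band_signal": s} for m, s in blot.standards]
    ).to_csv(standards_path, index=False)
    pd.DataFrame(
        [
            {"loaded_total_protein_ug": l, "band_signal": s,
             "coomassie_total_signal": c}
            for l, s, c in blot.lysate_lanes
        ]
    ).to_csv(lanes_path, index=False)


def read_blot(standards_path, lanes_path) -> BlotDataset:
    std = pd.read_csv(standards_path, float_precision="round_trip")
    lanes = pd.read_csv(lanes_path, float_precision="round_trip")
    return BlotDataset(
        standards=tuple(
            (float(r["loaded_tubulin_ng"]), float(r["band_signal"]))
            for _, r in std.iterrows()
        ),
        lysate_lanes=tuple(
            (float(r["loaded_total_protein_ug"]), float(r["band_signal"]),
             float(r["coomassie_total_signal"]))
            for _, r in lanes.iterrows()
        ),
    )


def write_lineages(lineages: Sequence[Lineage], path) -> None:
    rows = []
    for i, lin in enumerate(lineages):
        for t in lin.division_times:
            rows.append({"family_id": f"family-{i:04d}", "division_time_s": float(t)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_lineages(path) -> list[Lineage]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"family_id", "division_time_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing mandatory columns {sorted(missing)}")
    return [
        Lineage(division_times=np.sort(grp["division_time_s"].to_numpy(float)))
        for _, grp in df.groupby("family_id", sort=True)
    ]


def write_ri_measurements(measurements: Sequence[RIMeasurement], path) -> None:
    pd.DataFrame(
        [{"ri_raw": m.ri_raw, "ri_medium": m.ri_medium} for m in measurements]
    ).to_csv(path, index=False)


def read_ri_measurements(path) -> list[RIMeasurement]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"ri_raw", "ri_medium"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing mandatory columns {sorted(missing)}")
    return [
        RIMeasurement(ri_raw=float(r["ri_raw"]), ri_medium=float(r["ri_medium"]))
        for _, r in df.iterrows()
    ]


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     allow_nan=True) + "\n")


def read_json_report(path) -> dict:
    return json.loads(Path(path).read_text())
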