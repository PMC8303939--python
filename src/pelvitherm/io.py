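"""Session serialization: NIfTI volumes, CSV probe traces, JSON manifest.

Layout of a session directory::

    manifest.json                 geometry, constants, scan times, seed, ROIs
    phase_000.nii.gz ...          wrapped phase per scan
    magnitude_000.nii.gz ...      magnitude per scan
    mask_fat.nii.gz               fat label volume
    mask_air_s00.nii.gz           first-baseline air
    mask_air_s01.nii.gz           second-baseline air
    mask_roi.nii.gz               probe-ROI labels (1 bladder, 2 rectum, 3 vagina)
    probes.csv                    location, time_s, position_index, slice_offset_cm, temp_C
    truth_dt.nii.gz, truth.json   ground truth (synthetic sessions only)
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import PRFSConstants, PhaseScan, ProbeTrace, ScanGeometry
from .simulate import AnatomyModel, GroundTruthSeries, HeatingFocus, SessionDataset
from .thermometry import RoiSet, RoiTemperatureSeries

__all__ = ["write_session", "read_session", "write_roi_series", "read_probe_csv"]

_ROI_LABELS = {"bladder": 1, "rectum": 2, "vagina": 3}


def _affine(geometry: ScanGeometry) -> np.ndarray:
    v = geometry.voxel_inplane_cm * 10.0  # NIfTI spatial units are mm
    return np.diag([v, v, geometry.slice_thickness_cm * 10.0, 1.0])


def _save_nii(path: Path, data: np.ndarray, geometry: ScanGeometry) -> None:
    arr = data.astype(np.uint8) if data.dtype == bool else data.astype(np.float32)
    nib.save(nib.Nifti1Image(arr, _affine(geometry)), str(path))


def _load_nii(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def write_session(session: SessionDataset, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom, anat = session.geometry, session.anatomy

    for i, scan in enumerate(session.scans):
        _save_nii(out / f"phase_{i:03d}.nii.gz", scan.phase, geom)
        _save_nii(out / f"magnitude_{i:03d}.nii.gz", scan.magnitude, geom)

    _save_nii(out / "mask_fat.nii.gz", anat.fat_mask, geom)
    _save_nii(out / "mask_air_s00.nii.gz", anat.air_mask_s00, geom)
    _save_nii(out / "mask_air_s01.nii.gz", anat.air_mask_s01, geom)
    _save_nii(out / "mask_body.nii.gz", anat.body_mask, geom)

    roi_labels = np.zeros(geom.shape, dtype=np.uint8)
    rois = RoiSet.from_anatomy(anat)
    for loc, per_slice in rois.voxels.items():
        for z, coords in per_slice.items():
            roi_labels[coords[:, 0], coords[:, 1], z] = _ROI_LABELS[loc]
    _save_nii(out / "mask_roi.nii.gz", roi_labels, geom)

    rows = []
    for loc, trace in session.probe_traces.items():
        for i, t in enumerate(trace.cycle_times_s):
            for j in range(trace.readings.shape[1]):
                rows.append({
                    "location": loc,
                    "time_s": float(t),
                    "position_index": j,
                    "slice_offset_cm": float(trace.slice_offsets_cm[j]),
                    "temp_C": float(trace.readings[i, j]),
                })
    pd.DataFrame(rows).to_csv(out / "probes.csv", index=False)

    manifest = {
        "session_id": session.session_id,
        "seed": session.seed,
        "geometry": session.geometry.model_dump(),
        "constants": session.constants.model_dump(),
        "scan_times_s": [s.time_s for s in session.scans],
        "baseline_interval_s": session.baseline_interval_s,
        "scan_duration_s": session.scan_duration_s,
        "probe_tracks": {
            loc: np.asarray(t).tolist() for loc, t in anat.probe_tracks.items()
        },
        "roi_centers": {
            loc: {str(z): list(c) for z, c in per.items()}
            for loc, per in anat.roi_centers.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    if session.truth is not None:
        truth = session.truth
        nib.save(
            nib.Nifti1Image(
                np.moveaxis(truth.dt_true, 0, -1).astype(np.float32), _affine(geom)
            ),
            str(out / "truth_dt.nii.gz"),
        )
        h = truth.heating
        (out / "truth.json").write_text(json.dumps({
            "scan_times_s": truth.scan_times_s.tolist(),
            "heat_start_s": truth.heat_start_s,
            "heating": {
                "center_voxel": list(h.center_voxel),
                "sigma_cm": h.sigma_cm,
                "peak_c": h.peak_c,
                "ramp_min": h.ramp_min,
            },
        }, indent=2))
    return out


def read_probe_csv(path: str | Path, geometry: ScanGeometry,
                   probe_tracks: dict[str, np.ndarray]) -> dict[str, ProbeTrace]:
    df = pd.read_csv(path)
    traces: dict[str, ProbeTrace] = {}
    for loc, g in df.groupby("location"):
        piv = g.pivot_table(index="time_s", columns="position_index", values="temp_C")
        piv = piv.sort_index()
        offsets = (
            g.drop_duplicates("position_index")
            .sort_values("position_index")["slice_offset_cm"]
            .to_numpy()
        )
        traces[str(loc)] = ProbeTrace(
            location=str(loc),
            cycle_times_s=piv.index.to_numpy(dtype=float),
            positions=np.asarray(probe_tracks[str(loc)]),
            slice_offsets_cm=offsets,
            readings=piv.to_numpy(dtype=float),
        )
    return traces


def read_session(session_dir: str | Path) -> SessionDataset:
    d = Path(session_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    geom = ScanGeometry(**manifest["geometry"])
    constants = PRFSConstants(**manifest["constants"])

    scan_times = manifest["scan_times_s"]
    scans = []
    for i, t in enumerate(scan_times):
        scans.append(PhaseScan(
            phase=np.asarray(_load_nii(d / f"phase_{i:03d}.nii.gz"), dtype=float),
            magnitude=np.asarray(_load_nii(d / f"magnitude_{i:03d}.nii.gz"), dtype=float),
            time_s=float(t),
            is_baseline=i < 2,
        ))

    tracks = {loc: np.asarray(t) for loc, t in manifest["probe_tracks"].items()}
    roi_centers = {
        loc: {int(z): tuple(c) for z, c in per.items()}
        for loc, per in manifest["roi_centers"].items()
    }
    anatomy = AnatomyModel(
        geometry=geom,
        body_mask=_load_nii(d / "mask_body.nii.gz").astype(bool),
        fat_mask=_load_nii(d / "mask_fat.nii.gz").astype(bool),
        air_mask_s00=_load_nii(d / "mask_air_s00.nii.gz").astype(bool),
        air_mask_s01=_load_nii(d / "mask_air_s01.nii.gz").astype(bool),
        probe_tracks=tracks,
        roi_centers=roi_centers,
    )
    probes = read_probe_csv(d / "probes.csv", geom, tracks)

    truth = None
    if (d / "truth.json").exists():
        tj = json.loads((d / "truth.json").read_text())
        dt = np.moveaxis(
            np.asarray(_load_nii(d / "truth_dt.nii.gz"), dtype=float), -1, 0
        )
        h = HeatingFocus(
            center_voxel=tuple(tj["heating"]["center_voxel"]),
            sigma_cm=tj["heating"]["sigma_cm"],
            peak_c=tj["heating"]["peak_c"],
            ramp_min=tj["heating"]["ramp_min"],
        )
        # Rebuild the peak-normalized spatial profile from the stored truth.
        sat = dt[-1]
        denom = h.peak_c * (1.0 - np.exp(
            -(tj["scan_times_s"][-1] - tj["heat_start_s"]) / (h.ramp_min * 60.0)
        ))
        profile = sat / denom if denom > 0 else np.zeros_like(sat)
        truth = GroundTruthSeries(
            scan_times_s=np.asarray(tj["scan_times_s"], dtype=float),
            dt_true=dt,
            heating=h,
            heat_start_s=float(tj["heat_start_s"]),
            spatial_profile=profile,
        )

    return SessionDataset(
        geometry=geom,
        constants=constants,
        anatomy=anatomy,
        scans=scans,
        probe_traces=probes,
        truth=truth,
        seed=int(manifest["seed"]),
        baseline_interval_s=float(manifest["baseline_interval_s"]),
        scan_duration_s=float(manifest["scan_duration_s"]),
        session_id=str(manifest["session_id"]),
    )


def write_roi_series(series: RoiTemperatureSeries, path: str | Path) -> None:
    rows = []
    for loc, means in series.mean_c.items():
        frac = series.surviving_fraction(loc)
        for i, t in enumerate(series.scan_times_s):
            rows.append({
                "location": loc,
                "time_s": float(t),
                "mean_C": float(means[i]),
                "n_voxels": int(series.n_valid[loc][i]),
                "fraction_surviving": float(frac[i]),
            })
    pd.DataFrame(rows).to_csv(path, index=False)
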