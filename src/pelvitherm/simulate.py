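"""Synthetic treatment-session generator.

Emulates one MR-guided pelvic hyperthermia session end to end so that the
reconstruction, feature and selection stages can be exercised without any
clinical data:

* a pelvic cross-section with a subcutaneous fat ring (the B0-drift
  reference; fat shows no PRFS shift and stays thermally inert),
* gastrointestinal air pockets in the two baseline scans, whose overlap is
  controlled so that the Jaccard coefficient of the pair equals
  ``1 - air_motion_fraction``,
* three intraluminal probe tracks (bladder, rectum, vagina) spanning 2-8
  slices each, with circular ROI centers per slice,
* a Gaussian heating focus with a saturating-exponential temporal ramp,
* phase/magnitude scan series encoding the truth through the PRFS relation,
  corrupted by spatio-temporal B0 drift, phase noise and a dipole-like
  susceptibility perturbation near air whose strength scales with the
  inter-baseline air displacement,
* probe traces sampled from the ground-truth temperature field every 5 min
  with 1 cm steps along each catheter.

All randomness derives from a single seed through ``numpy.random.SeedSequence``
spawning, so identical seeds yield bit-identical sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    MAX_PROBE_RANGE_CM,
    PRFSConstants,
    PROBE_LOCATIONS,
    ROI_DIAMETER_CM,
    SCAN_DURATION_S,
    PhaseScan,
    ProbeTrace,
    ScanGeometry,
    wrap_phase,
)

__all__ = [
    "AnatomyModel",
    "HeatingFocus",
    "GroundTruthSeries",
    "SessionDataset",
    "generate_anatomy",
    "generate_truth",
    "encode_session",
    "sample_probe_readings",
    "random_drift_coefficients",
    "simulate_session",
]

#: Default interval between the starts of the two baseline scans, seconds.
BASELINE_INTERVAL_S = 97.0

#: Default interval between treatment scans, seconds (~9 scans over ~90 min).
TREATMENT_SCAN_INTERVAL_S = 560.0

#: Probe temperature-mapping interval, seconds (every 5 min).
PROBE_MAPPING_INTERVAL_S = 300.0

# In-plane body half-axes and track anchors as fractions of the matrix.
_BODY_HALF_AXES = (0.42, 0.30)
_TRACK_ANCHORS = {"bladder": (0.50, 0.40), "vagina": (0.50, 0.55), "rectum": (0.50, 0.66)}
_AIR_SEED_OFFSETS = {  # in-plane offsets (cm) of air-pocket seeds from track anchors
    "bladder": (-4.0, 0.5),
    "rectum": (4.0, -1.0),
    "vagina": (0.0, -6.5),
}
_FAT_THICKNESS_CM = 1.6


@dataclass
class AnatomyModel:
    """Static anatomy of one session: masks, probe tracks and ROI centers."""

    geometry: ScanGeometry
    body_mask: np.ndarray
    fat_mask: np.ndarray
    air_mask_s00: np.ndarray
    air_mask_s01: np.ndarray
    probe_tracks: dict[str, np.ndarray]  # location -> (n_positions, 3) voxel idx
    roi_centers: dict[str, dict[int, tuple[float, float]]]


@dataclass
class HeatingFocus:
    """Gaussian heating focus with a saturating-exponential temporal ramp."""

    center_voxel: tuple[float, float, float]
    sigma_cm: float = 4.0
    peak_c: float = 5.0
    ramp_min: float = 12.0


@dataclass
class GroundTruthSeries:
    """Simulation truth recorded at every scan time.

    ``dt_true`` holds one temperature-change volume per scan (baselines
    included, where it is identically zero); ``drift_true`` is filled in by
    :func:`encode_session` with the drift phase actually applied.  The
    heating parameters are retained so the continuous-time field can be
    evaluated at probe mapping times between scans.
    """

    scan_times_s: np.ndarray
    dt_true: np.ndarray  # (n_scans, x, y, slice)
    heating: HeatingFocus
    heat_start_s: float
    spatial_profile: np.ndarray  # peak-normalized Gaussian x thermal-inertness
    drift_true: np.ndarray | None = None

    def temporal_factor(self, t_s: float | np.ndarray) -> np.ndarray:
        dt = np.maximum(np.asarray(t_s, dtype=float) - self.heat_start_s, 0.0)
        tau = max(self.heating.ramp_min * 60.0, 1e-9)
        return 1.0 - np.exp(-dt / tau)

    def dt_at(self, t_s: float, voxels: np.ndarray) -> np.ndarray:
        """Truth at arbitrary time for the given ``(n, 3)`` voxel indices."""
        vx = np.asarray(voxels)
        prof = self.spatial_profile[vx[:, 0], vx[:, 1], vx[:, 2]]
        return self.heating.peak_c * prof * self.temporal_factor(t_s)


@dataclass
class SessionDataset:
    """One complete synthetic session: scans, anatomy, probes and truth."""

    geometry: ScanGeometry
    constants: PRFSConstants
    anatomy: AnatomyModel
    scans: list[PhaseScan]
    probe_traces: dict[str, ProbeTrace]
    truth: GroundTruthSeries | None
    seed: int
    baseline_interval_s: float = BASELINE_INTERVAL_S
    scan_duration_s: float = SCAN_DURATION_S
    session_id: str = ""

    @property
    def reference_scan(self) -> PhaseScan:
        return self.scans[0]

    @property
    def treatment_scans(self) -> list[PhaseScan]:
        return self.scans[1:]


def _ellipse_mask(matrix: int, half_axes: tuple[float, float]) -> np.ndarray:
    c = (matrix - 1) / 2.0
    x, y = np.meshgrid(np.arange(matrix), np.arange(matrix), indexing="ij")
    rx, ry = half_axes[0] * matrix, half_axes[1] * matrix
    return ((x - c) / rx) ** 2 + ((y - c) / ry) ** 2 <= 1.0


def _track_distance_sq(shape: tuple[int, int, int], tracks: dict[str, np.ndarray]) -> np.ndarray:
    """Per-voxel squared in-plane distance (voxels) to the nearest track axis."""
    x, y = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    d2 = np.full(shape[:2], np.inf)
    for track in tracks.values():
        tx, ty = float(track[0, 0]), float(track[0, 1])
        d2 = np.minimum(d2, (x - tx) ** 2 + (y - ty) ** 2)
    return np.broadcast_to(d2[:, :, None], shape)


def generate_anatomy(
    geometry: ScanGeometry,
    air_motion_fraction: float = 0.0,
    air_volume_ml: float = 200.0,
    seed: int = 0,
    fat_thickness_cm: float = _FAT_THICKNESS_CM,
) -> AnatomyModel:
    """Generate pelvic anatomy with controlled inter-baseline air motion.

    The second-baseline air mask ``B`` is produced from the first-baseline
    mask ``A`` by removing ``k`` trailing-edge voxels and appending ``k``
    fresh voxels on the leading edge, with ``k = |A| * f / (2 - f)`` for the
    requested motion fraction ``f`` — this makes the Jaccard coefficient
    ``J(A, B) = (|A|-k)/(|A|+k) = 1 - f`` up to integer rounding.

    Parameters
    ----------
    air_motion_fraction
        Requested ``1 - J(A, B)`` in [0, 1].
    air_volume_ml
        Total first-baseline air volume; realized to the nearest voxel.
    """
    if not 0.0 <= air_motion_fraction <= 1.0:
        raise ValueError("air_motion_fraction must lie in [0, 1]")
    if air_volume_ml < 0:
        raise ValueError("air_volume_ml must be non-negative")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0A17A]))
    m, nz = geometry.matrix, geometry.n_slices
    vox_cm = geometry.voxel_inplane_cm

    body2d = _ellipse_mask(m, _BODY_HALF_AXES)
    body = np.broadcast_to(body2d[:, :, None], geometry.shape).copy()

    fat_vox = max(1, round(fat_thickness_cm / vox_cm))
    inner2d = ndimage.binary_erosion(body2d, iterations=fat_vox)
    fat = body.copy()
    fat[inner2d[:, :, None] & body] = False

    interior2d = ndimage.binary_erosion(inner2d, iterations=2)
    interior = np.broadcast_to(interior2d[:, :, None], geometry.shape).copy()

    # Probe tracks: jittered in-plane anchors, 2-8 slices along the slice axis.
    tracks: dict[str, np.ndarray] = {}
    roi_centers: dict[str, dict[int, tuple[float, float]]] = {}
    for loc in PROBE_LOCATIONS:
        ax, ay = _TRACK_ANCHORS[loc]
        jitter = rng.integers(-2, 3, size=2)
        cx = int(round(ax * m)) + int(jitter[0])
        cy = int(round(ay * m)) + int(jitter[1])
        max_span = min(8, nz, int(MAX_PROBE_RANGE_CM / geometry.slice_thickness_cm))
        span = int(rng.integers(2, max_span + 1))
        z0 = max(0, (nz - span) // 2 + int(rng.integers(-1, 2)))
        z0 = min(z0, nz - span)
        zs = np.arange(z0, z0 + span)
        tracks[loc] = np.array([[cx, cy, z] for z in zs])
        roi_centers[loc] = {int(z): (float(cx), float(cy)) for z in zs}
        if not interior2d[cx, cy]:
            raise ValueError(f"probe track for {loc} fell outside the interior")

    # Keep air clear of the ROI cylinders so ROI voxels stay tissue.
    roi_r_vox = 0.5 * ROI_DIAMETER_CM / vox_cm
    clearance = _track_distance_sq(geometry.shape, tracks) > (roi_r_vox + 1.5) ** 2
    allowed = interior & clearance

    n_air = int(round(air_volume_ml / geometry.voxel_volume_ml))
    if n_air == 0:
        empty = np.zeros(geometry.shape, dtype=bool)
        return AnatomyModel(geometry, body, fat, empty, empty.copy(), tracks, roi_centers)
    if n_air > int(allowed.sum()):
        raise ValueError(
            f"requested air volume {air_volume_ml} mL exceeds available interior "
            f"({allowed.sum() * geometry.voxel_volume_ml:.1f} mL)"
        )

    # Seed pockets near the tracks, then take the n_air allowed voxels nearest
    # to the seed set (deterministic tie-break on coordinates).
    seeds = np.zeros(geometry.shape, dtype=bool)
    zmid = nz // 2
    for loc in PROBE_LOCATIONS:
        ox, oy = _AIR_SEED_OFFSETS[loc]
        sx = int(np.clip(tracks[loc][0, 0] + round(ox / vox_cm), 0, m - 1))
        sy = int(np.clip(tracks[loc][0, 1] + round(oy / vox_cm), 0, m - 1))
        seeds[sx, sy, zmid] = True
    dist = ndimage.distance_transform_edt(~seeds)
    air_a = _take_nearest(allowed, dist, n_air)

    f = air_motion_fraction
    k = int(round(n_air * f / (2.0 - f))) if f < 1.0 else n_air
    if k == 0:
        air_b = air_a.copy()
    else:
        order = _lex_order(np.argwhere(air_a))
        removed_idx = np.argwhere(air_a)[order[:k]]
        air_b = air_a.copy()
        air_b[removed_idx[:, 0], removed_idx[:, 1], removed_idx[:, 2]] = False
        cand_region = allowed & ~air_a
        dist_a = ndimage.distance_transform_edt(~air_a)
        added = _take_nearest(cand_region, dist_a, k, prefer_high_x=True)
        air_b |= added
    return AnatomyModel(geometry, body, fat, air_a, air_b, tracks, roi_centers)


def _lex_order(coords: np.ndarray) -> np.ndarray:
    """Order voxel coordinates by ascending x, then y, then z."""
    return np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))


def _take_nearest(
    region: np.ndarray, dist: np.ndarray, n: int, prefer_high_x: bool = False
) -> np.ndarray:
    """Pick the ``n`` voxels of ``region`` with the smallest ``dist``."""
    coords = np.argwhere(region)
    if len(coords) < n:
        raise ValueError("region too small for requested voxel count")
    d = dist[coords[:, 0], coords[:, 1], coords[:, 2]]
    x_key = -coords[:, 0] if prefer_high_x else coords[:, 0]
    order = np.lexsort((coords[:, 2], coords[:, 1], x_key, np.round(d, 6)))
    picked = coords[order[:n]]
    out = np.zeros(region.shape, dtype=bool)
    out[picked[:, 0], picked[:, 1], picked[:, 2]] = True
    return out


def default_scan_times(
    n_treatment_scans: int,
    baseline_interval_s: float = BASELINE_INTERVAL_S,
    scan_interval_s: float = TREATMENT_SCAN_INTERVAL_S,
    scan_duration_s: float = SCAN_DURATION_S,
) -> tuple[np.ndarray, float]:
    """Scan start times (two baselines + treatment scans) and heating onset."""
    heat_start = baseline_interval_s + scan_duration_s
    times = [0.0, baseline_interval_s]
    times += [heat_start + (k + 1) * scan_interval_s for k in range(n_treatment_scans)]
    return np.asarray(times), heat_start


def generate_truth(
    anatomy: AnatomyModel,
    heating: HeatingFocus | None = None,
    n_scans: int = 9,
    seed: int = 0,
    baseline_interval_s: float = BASELINE_INTERVAL_S,
    scan_interval_s: float = TREATMENT_SCAN_INTERVAL_S,
) -> GroundTruthSeries:
    """Ground-truth temperature evolution on the scan-time grid.

    A Gaussian spatial focus ramps up with a saturating exponential once RF
    power is on (after the second baseline scan).  Fat is kept thermally
    inert so the drift-correction reference assumption holds in the truth.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be at least 1")
    geom = anatomy.geometry
    if heating is None:
        centers = np.concatenate([t for t in anatomy.probe_tracks.values()])
        heating = HeatingFocus(center_voxel=tuple(centers.mean(axis=0)))
    if not 0.0 <= heating.peak_c <= 10.0:
        raise ValueError("peak_c must lie in [0, 10] deg C")
    cx, cy, cz = heating.center_voxel
    icx, icy, icz = int(round(cx)), int(round(cy)), int(round(cz))
    if not anatomy.body_mask[icx, icy, icz]:
        raise ValueError("heating focus center lies outside the body")

    x, y, z = np.meshgrid(
        np.arange(geom.matrix), np.arange(geom.matrix), np.arange(geom.n_slices),
        indexing="ij",
    )
    vx, vz = geom.voxel_inplane_cm, geom.slice_thickness_cm
    r2_cm = ((x - cx) * vx) ** 2 + ((y - cy) * vx) ** 2 + ((z - cz) * vz) ** 2
    profile = np.exp(-0.5 * r2_cm / heating.sigma_cm**2)
    profile *= anatomy.body_mask & ~anatomy.fat_mask  # fat thermally inert

    times, heat_start = default_scan_times(
        n_scans, baseline_interval_s=baseline_interval_s, scan_interval_s=scan_interval_s
    )
    truth = GroundTruthSeries(
        scan_times_s=times,
        dt_true=np.zeros((len(times),) + geom.shape),
        heating=heating,
        heat_start_s=heat_start,
        spatial_profile=profile,
    )
    for i, t in enumerate(times):
        truth.dt_true[i] = heating.peak_c * profile * truth.temporal_factor(t)
    return truth


# 2D polynomial basis used for drift fields: 1, X, Y, X^2, XY, Y^2 on [-1, 1].
DRIFT_BASIS_EXPONENTS = ((0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2))


def _drift_field(matrix: int, coeffs: np.ndarray) -> np.ndarray:
    u = np.linspace(-1.0, 1.0, matrix)
    xx, yy = np.meshgrid(u, u, indexing="ij")
    out = np.zeros((matrix, matrix))
    for c, (i, j) in zip(coeffs, DRIFT_BASIS_EXPONENTS):
        out += c * xx**i * yy**j
    return out


def random_drift_coefficients(
    n_scans_total: int,
    scan_times_s: np.ndarray,
    max_rad: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Smoothly growing quadratic drift: zero at the reference scan, ramping
    to coefficients of order ``max_rad`` by the session end."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD21F7]))
    direction = rng.uniform(-1.0, 1.0, size=len(DRIFT_BASIS_EXPONENTS))
    direction /= max(np.max(np.abs(direction)), 1e-12)
    t = np.asarray(scan_times_s)
    ramp = (t - t[0]) / max(t[-1] - t[0], 1.0)
    return max_rad * ramp[:, None] * direction[None, :]


def _susceptibility_pattern(anatomy: AnatomyModel, decay_cm: float = 1.5) -> np.ndarray:
    """Dipole-like unit pattern around the air pockets.

    Exponentially decaying with distance from the air boundary and modulated
    by cos(2*theta) around the per-slice air centroid — a stand-in for the
    field perturbation moving air induces, monotone in distance from air.
    """
    air = anatomy.air_mask_s00 | anatomy.air_mask_s01
    if not air.any():
        return np.zeros(air.shape)
    geom = anatomy.geometry
    lam_vox = max(decay_cm / geom.voxel_inplane_cm, 1.0)
    dist = ndimage.distance_transform_edt(~air)
    pattern = np.zeros(air.shape)
    x, y = np.meshgrid(np.arange(geom.matrix), np.arange(geom.matrix), indexing="ij")
    for z in range(geom.n_slices):
        sl = air[:, :, z]
        if not sl.any():
            continue
        cx, cy = np.argwhere(sl).mean(axis=0)
        theta = np.arctan2(y - cy, x - cx)
        pattern[:, :, z] = np.exp(-dist[:, :, z] / lam_vox) * np.cos(2.0 * theta)
    pattern[air] = 0.0
    return pattern


def encode_session(
    truth: GroundTruthSeries,
    anatomy: AnatomyModel,
    constants: PRFSConstants | None = None,
    drift: np.ndarray | None = None,
    noise_sd_rad: float = 0.0,
    air_artifact_rad: float = 0.0,
    seed: int = 0,
    probe_noise_sd_c: float = 0.1,
    baseline_interval_s: float = BASELINE_INTERVAL_S,
    session_id: str = "",
) -> SessionDataset:
    """Encode the truth into phase/magnitude scans plus probe traces.

    phi_n = wrap(phi_00 + gamma*alpha*B0*TE * dT_true(n) + drift(n)
                 + artifact(n) + noise), with the susceptibility artifact
    confined to a shell around air and scaled by the inter-baseline air
    displacement ``1 - J(A, B)``.
    """
    if noise_sd_rad < 0:
        raise ValueError("noise_sd_rad must be non-negative")
    constants = constants or PRFSConstants()
    geom = anatomy.geometry
    seq = np.random.SeedSequence([seed, 0xE9C0])
    rng_base, rng_noise, rng_art, rng_probe = (
        np.random.default_rng(s) for s in seq.spawn(4)
    )

    # Smooth anatomical baseline phase.
    base_coeffs = rng_base.uniform(-1.0, 1.0, size=len(DRIFT_BASIS_EXPONENTS))
    phi00_2d = _drift_field(geom.matrix, base_coeffs)
    phi00 = np.broadcast_to(phi00_2d[:, :, None], geom.shape).copy()

    times = truth.scan_times_s
    n_total = len(times)
    if drift is None:
        drift = np.zeros((n_total, len(DRIFT_BASIS_EXPONENTS)))
    drift = np.asarray(drift, dtype=float)
    if drift.shape != (n_total, len(DRIFT_BASIS_EXPONENTS)):
        raise ValueError("drift coefficients must have shape (n_scans, 6)")

    inter = anatomy.air_mask_s00 & anatomy.air_mask_s01
    union = anatomy.air_mask_s00 | anatomy.air_mask_s01
    displacement = 1.0 - (inter.sum() / union.sum() if union.any() else 1.0)
    pattern = (
        _susceptibility_pattern(anatomy)
        if air_artifact_rad != 0.0 and displacement > 0
        else None
    )

    truth.drift_true = np.zeros((n_total,) + geom.shape)
    scans: list[PhaseScan] = []
    for n, t in enumerate(times):
        dphi = constants.phase_rad_per_c * truth.dt_true[n]
        drift_vol = np.broadcast_to(
            _drift_field(geom.matrix, drift[n])[:, :, None], geom.shape
        )
        truth.drift_true[n] = drift_vol
        phi = phi00 + dphi + drift_vol
        if pattern is not None and n >= 2:
            g = rng_art.uniform(0.5, 1.5)
            phi = phi + air_artifact_rad * displacement * g * pattern
        if noise_sd_rad > 0:
            phi = phi + rng_noise.normal(0.0, noise_sd_rad, size=geom.shape)
        air = anatomy.air_mask_s01 if n == 1 else anatomy.air_mask_s00
        magnitude = np.where(anatomy.body_mask & ~air, 100.0, 8.0)
        magnitude = magnitude + rng_noise.normal(0.0, 1.0, size=geom.shape)
        scans.append(
            PhaseScan(
                phase=wrap_phase(phi),
                magnitude=magnitude,
                time_s=float(t),
                is_baseline=n < 2,
            )
        )

    probes = sample_probe_readings(
        truth, anatomy, noise_sd_c=probe_noise_sd_c,
        rng=rng_probe, session_end_s=float(times[-1]) + SCAN_DURATION_S,
    )
    return SessionDataset(
        geometry=geom,
        constants=constants,
        anatomy=anatomy,
        scans=scans,
        probe_traces=probes,
        truth=truth,
        seed=seed,
        baseline_interval_s=baseline_interval_s,
        session_id=session_id,
    )


def sample_probe_readings(
    truth: GroundTruthSeries,
    anatomy: AnatomyModel,
    mapping_interval_s: float = PROBE_MAPPING_INTERVAL_S,
    noise_sd_c: float = 0.1,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    session_end_s: float | None = None,
) -> dict[str, ProbeTrace]:
    """Sample intraluminal probe traces from the truth.

    One mapping cycle every ``mapping_interval_s`` (t = 0 inclusive); per
    cycle one reading per track position (1 cm steps along the slice axis,
    at most 14 positions).
    """
    if mapping_interval_s <= 0:
        raise ValueError("mapping_interval_s must be positive")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB073]))
    geom = anatomy.geometry
    end = session_end_s if session_end_s is not None else float(truth.scan_times_s[-1])
    n_cycles = int(np.floor(end / mapping_interval_s)) + 1
    cycle_times = np.arange(n_cycles) * mapping_interval_s

    traces: dict[str, ProbeTrace] = {}
    max_positions = int(MAX_PROBE_RANGE_CM / geom.slice_thickness_cm)
    for loc, track in anatomy.probe_tracks.items():
        track = np.asarray(track)[:max_positions]
        if (track < 0).any() or (track >= np.array(geom.shape)).any():
            raise ValueError(f"probe track for {loc} leaves the scan volume")
        readings = np.empty((n_cycles, len(track)))
        for i, t in enumerate(cycle_times):
            vals = truth.dt_at(float(t), track)
            if noise_sd_c > 0:
                vals = vals + rng.normal(0.0, noise_sd_c, size=len(track))
            readings[i] = vals
        offsets = np.array([geom.slice_offset_cm(int(z)) for z in track[:, 2]])
        traces[loc] = ProbeTrace(
            location=loc,
            cycle_times_s=cycle_times,
            positions=track,
            slice_offsets_cm=offsets,
            readings=readings,
        )
    return traces


def simulate_session(
    geometry: ScanGeometry | None = None,
    constants: PRFSConstants | None = None,
    air_motion_fraction: float = 0.0,
    air_volume_ml: float = 200.0,
    heating: HeatingFocus | None = None,
    heating_peak_c: float | None = None,
    n_treatment_scans: int = 9,
    drift_rad: float = 0.05,
    noise_sd_rad: float = 0.003,
    air_artifact_rad: float = 0.3,
    probe_noise_sd_c: float = 0.1,
    fat_thickness_cm: float = _FAT_THICKNESS_CM,
    seed: int = 0,
    session_id: str = "",
) -> SessionDataset:
    """Convenience wrapper: anatomy -> truth -> encoded session, one seed."""
    geometry = geometry or ScanGeometry(matrix=128, n_slices=15)
    seq = np.random.SeedSequence([seed, 0x5E55])
    s_anat, s_truth, s_drift, s_enc = (int(s.generate_state(1)[0] % 2**31) for s in seq.spawn(4))
    anatomy = generate_anatomy(
        geometry, air_motion_fraction=air_motion_fraction,
        air_volume_ml=air_volume_ml, seed=s_anat,
        fat_thickness_cm=fat_thickness_cm,
    )
    if heating is None and heating_peak_c is not None:
        centers = np.concatenate([t for t in anatomy.probe_tracks.values()])
        heating = HeatingFocus(center_voxel=tuple(centers.mean(axis=0)),
                               peak_c=heating_peak_c)
    truth = generate_truth(anatomy, heating=heating, n_scans=n_treatment_scans, seed=s_truth)
    drift = (
        random_drift_coefficients(len(truth.scan_times_s), truth.scan_times_s,
                                  max_rad=drift_rad, seed=s_drift)
        if drift_rad > 0 else None
    )
    return encode_session(
        truth, anatomy, constants=constants, drift=drift,
        noise_sd_rad=noise_sd_rad, air_artifact_rad=air_artifact_rad,
        seed=s_enc, probe_noise_sd_c=probe_noise_sd_c, session_id=session_id,
    )
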