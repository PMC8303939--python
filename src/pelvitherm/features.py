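"""Imaging-based session features predicting thermometry reliability.

Four per-session predictors computed from the baseline scans' masks:
Jaccard overlap of the two baseline air masks (inter-scan air motion),
gastrointestinal air volume (first baseline), fat volume, and the mean
minimum in-plane distance from air to the probe ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ScanGeometry
from .thermometry import RoiSet

__all__ = [
    "SessionFeatures",
    "jaccard_coefficient",
    "dice_coefficient",
    "mask_volume_ml",
    "min_air_roi_distance",
    "compute_session_features",
]


@dataclass
class SessionFeatures:
    session_id: str
    jaccard: float
    air_volume_ml: float
    fat_volume_ml: float
    min_distance_cm: float

    def as_dict(self) -> dict[str, float | str]:
        return {
            "session_id": self.session_id,
            "jaccard": self.jaccard,
            "air_volume_ml": self.air_volume_ml,
            "fat_volume_ml": self.fat_volume_ml,
            "min_distance_cm": self.min_distance_cm,
        }


def jaccard_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """J(A, B) = |A n B| / |A u B|; 1.0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must have congruent shapes")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); monotone companion of Jaccard."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must have congruent shapes")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def mask_volume_ml(mask: np.ndarray, geometry: ScanGeometry) -> float:
    """Mask volume in mL: voxel count times voxel volume."""
    return float(np.asarray(mask, dtype=bool).sum() * geometry.voxel_volume_ml)


def min_air_roi_distance(
    air_mask: np.ndarray,
    rois: RoiSet,
    geometry: ScanGeometry,
    cap_cm: float | None = None,
) -> float:
    """Mean over ROI-bearing slices of the minimum air-to-ROI distance.

    Per slice that carries any probe ROI, the minimum in-plane Euclidean
    distance between the ROI circle boundary and the nearest air-mask voxel
    center (clamped at zero for air on or inside the circle).  Slices
    without any air contribute ``cap_cm`` (default: the in-plane FOV
    diagonal) so air-free sessions score as "far" rather than missing.
    """
    if cap_cm is None:
        cap_cm = float(np.hypot(geometry.fov_cm, geometry.fov_cm))
    vox = geometry.voxel_inplane_cm
    r_cm = 0.5 * rois.diameter_cm

    roi_slices: dict[int, list[tuple[float, float]]] = {}
    for per_slice in rois.centers.values():
        for z, c in per_slice.items():
            roi_slices.setdefault(int(z), []).append(c)

    air = np.asarray(air_mask, dtype=bool)
    per_slice_min: list[float] = []
    for z, centers in sorted(roi_slices.items()):
        coords = np.argwhere(air[:, :, z])
        if len(coords) == 0:
            per_slice_min.append(cap_cm)
            continue
        best = np.inf
        for cx, cy in centers:
            d = np.hypot((coords[:, 0] - cx) * vox, (coords[:, 1] - cy) * vox)
            best = min(best, float(d.min()) - r_cm)
        per_slice_min.append(max(best, 0.0))
    return float(np.mean(per_slice_min))


def compute_session_features(session) -> SessionFeatures:
    """All four predictors for one (synthetic or loaded) session."""
    anat = session.anatomy
    rois = RoiSet.from_anatomy(anat)
    return SessionFeatures(
        session_id=session.session_id,
        jaccard=jaccard_coefficient(anat.air_mask_s00, anat.air_mask_s01),
        air_volume_ml=mask_volume_ml(anat.air_mask_s00, session.geometry),
        fat_volume_ml=mask_volume_ml(anat.fat_mask, session.geometry),
        min_distance_cm=min_air_roi_distance(anat.air_mask_s00, rois, session.geometry),
    )
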