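"""Three-stage region-of-interest determination for lung lesions.

Stage 1 aligns the scan by principal axes of the body and isolates the
chest with morphology + connected components; stage 2 segments the lungs
from air-like voxels inside the chest with parenchyma refinement; stage 3
turns a longest-axis annotation into a nodule mask by intensity clustering
(Otsu) around the annotation, using the left/right symmetry of the lungs
to suppress dense structures that have a mirrored counterpart (vessels,
hila) while always retaining the annotated component.

Lesions that cannot be delineated raise :class:`UndelineatableLesion` — an
explicit, countable outcome, mirroring how such patients are excluded from
a study rather than crashing a pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .volume import CTVolume

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class RoiError(RuntimeError):
    """A segmentation stage could not produce a valid result."""


class UndelineatableLesion(RoiError):
    """No dense component could be associated with the annotation."""


@dataclass(frozen=True)
class Annotation:
    """Longest-axis annotation: two 3-D endpoints in physical mm."""

    lesion_id: str
    p0_mm: tuple[float, float, float]
    p1_mm: tuple[float, float, float]
    annotator: str = ""

    def __post_init__(self) -> None:
        if np.allclose(self.p0_mm, self.p1_mm):
            raise ValueError("annotation endpoints must be distinct")

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.subtract(self.p1_mm, self.p0_mm)))

    @property
    def midpoint_mm(self) -> np.ndarray:
        return (np.asarray(self.p0_mm) + np.asarray(self.p1_mm)) / 2.0

    @property
    def radius_mm(self) -> float:
        return self.length_mm / 2.0

    @classmethod
    def from_json(cls, path: str | Path) -> "Annotation":
        d = json.loads(Path(path).read_text())
        return cls(
            lesion_id=d["lesion_id"],
            p0_mm=tuple(d["p0_mm"]),
            p1_mm=tuple(d["p1_mm"]),
            annotator=d.get("annotator", ""),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "lesion_id": self.lesion_id,
                    "p0_mm": list(self.p0_mm),
                    "p1_mm": list(self.p1_mm),
                    "annotator": self.annotator,
                }
            )
        )


@dataclass
class RigidTransform:
    """Rotation about a fixed physical center: p -> c + R (p - c)."""

    rotation: np.ndarray
    center_mm: np.ndarray

    def apply_points(self, pts_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts_mm, float))
        out = (pts - self.center_mm) @ self.rotation.T + self.center_mm
        return out[0] if np.asarray(pts_mm).ndim == 1 else out

    def angles_deg(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_euler("xyz", degrees=True)


@dataclass
class ROI:
    """A delineated lesion: mask, bounding box, annotation-derived radius."""

    mask: np.ndarray  # full-volume boolean
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # half-open
    lesion_radius_mm: float
    provenance: str = "otsu-symmetry"

    def __post_init__(self) -> None:
        if self.lesion_radius_mm <= 0:
            raise ValueError("lesion radius must be > 0")
        sub = np.zeros_like(self.mask)
        (x0, x1), (y0, y1), (z0, z1) = self.bbox
        sub[x0:x1, y0:y1, z0:z1] = True
        if np.any(self.mask & ~sub):
            raise ValueError("mask extends outside its bounding box")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def crop(self, arr: np.ndarray) -> np.ndarray:
        (x0, x1), (y0, y1), (z0, z1) = self.bbox
        return arr[x0:x1, y0:y1, z0:z1]


# ------------------------------------------------------------------ stages


def _ball_voxels(radius_mm: float, spacing: float) -> np.ndarray:
    r = max(1, int(round(radius_mm / spacing)))
    return ball(r)


def align_axes(
    v: CTVolume, body_threshold_hu: float = -200.0, max_angle_deg: float = 15.0
) -> tuple[CTVolume, RigidTransform]:
    """Rotate the scan so the body's principal axes match the grid axes.

    The principal axes of the above-threshold (body) voxel cloud are
    assigned to the nearest grid axes and the correcting rotation is
    applied about the volume's physical center; each Euler angle is
    clamped to ``max_angle_deg`` as a safety limit (scans are expected to
    be roughly aligned already).
    """
    body = v.values > body_threshold_hu
    if body.mean() < 0.01:
        raise RoiError("near-empty body mask; cannot align")
    idx = np.argwhere(body)
    pts = v.index_to_physical(idx)
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]  # descending variance
    evecs = evecs[:, order]

    # assign eigenvectors to grid axes: largest variance prefers z, the
    # rest go to whichever free axis they are most parallel to
    assigned: dict[int, np.ndarray] = {}
    free = [0, 1, 2]
    prefs = [2, 0, 1]
    for rank, pref in enumerate(prefs):
        vec = evecs[:, rank]
        if pref in free:
            axis = pref if abs(vec[pref]) >= 0.5 else max(free, key=lambda a: abs(vec[a]))
        else:
            axis = max(free, key=lambda a: abs(vec[a]))
        if vec[axis] < 0:
            vec = -vec
        assigned[axis] = vec
        free.remove(axis)
    A = np.stack([assigned[0], assigned[1], assigned[2]], axis=1)
    if np.linalg.det(A) < 0:
        A[:, 1] = -A[:, 1]
    R = A.T  # rotates each principal axis onto its grid axis

    angles = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
    angles = np.clip(angles, -max_angle_deg, max_angle_deg)
    R = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()

    vol_center = v.index_to_physical((np.array(v.shape) - 1) / 2.0)
    # resample: output physical p_out samples input at c + R^T (p_out - c)
    S = np.diag(v.spacing)
    Sinv = np.diag(1.0 / np.array(v.spacing))
    M = Sinv @ R.T @ S  # index-space matrix
    c_idx = (np.array(v.shape) - 1) / 2.0
    offset = c_idx - M @ c_idx
    out = ndimage.affine_transform(
        v.values, M, offset=offset, order=1, mode="constant", cval=-1000.0
    )
    aligned = CTVolume(out, v.spacing, v.origin, v.provenance)
    return aligned, RigidTransform(rotation=R, center_mm=vol_center)


def segment_chest(
    v: CTVolume,
    body_threshold_hu: float = -200.0,
    opening_mm: float = 3.0,
    closing_mm: float = 5.0,
    min_fraction: float = 0.05,
) -> np.ndarray:
    """Chest/body mask: threshold, open, largest component, close, fill."""
    if not v.is_isotropic(rtol=1e-3):
        raise RoiError("segment_chest expects an isotropic (resampled) volume")
    sp = v.spacing[0]
    raw = v.values > body_threshold_hu
    opened = ndimage.binary_opening(raw, structure=_ball_voxels(opening_mm, sp))
    labels, n = ndimage.label(opened, structure=STRUCT_26)
    if n == 0:
        raise RoiError("no connected body component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < min_fraction * labels.size:
        raise RoiError(
            f"largest component covers {sizes[biggest - 1] / labels.size:.1%} "
            f"< {min_fraction:.0%} of the volume"
        )
    mask = labels == biggest
    mask = ndimage.binary_closing(mask, structure=_ball_voxels(closing_mm, sp))
    mask = ndimage.binary_fill_holes(mask)
    return mask


def segment_lungs(
    v: CTVolume,
    chest_mask: np.ndarray,
    air_threshold_hu: float = -400.0,
    min_component_cm3: float = 5.0,
    min_total_cm3: float = 50.0,
    closing_mm: float = 3.0,
) -> np.ndarray:
    """Lungs: air-like voxels inside the chest, refined to re-include nodules.

    External (border-connected) air is discarded, small components are
    filtered out, and the result is closed with a 3-mm ball plus hole
    filling so dense nodules embedded in parenchyma stay inside the mask.
    """
    if chest_mask.sum() == 0:
        raise RoiError("empty chest mask")
    sp = v.spacing[0]
    # inclusive comparison: harmonized volumes clamp parenchyma exactly to
    # the lower truncation bound, which coincides with the default threshold
    air = (v.values <= air_threshold_hu) & chest_mask
    # drop candidates touching the volume border (external air leakage)
    labels, n = ndimage.label(air, structure=STRUCT_26)
    if n == 0:
        raise RoiError("no lung-candidate voxels inside the chest")
    border_labels = np.unique(
        np.concatenate(
            [
                labels[0].ravel(), labels[-1].ravel(),
                labels[:, 0].ravel(), labels[:, -1].ravel(),
                labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
            ]
        )
    )
    voxel_cm3 = np.prod(v.spacing) / 1000.0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = []
    for lab in range(1, n + 1):
        if lab in border_labels:
            continue
        if sizes[lab - 1] * voxel_cm3 >= min_component_cm3:
            keep.append(lab)
    if not keep:
        raise RoiError("no lung component survives the size filter")
    keep = sorted(keep, key=lambda lab: -sizes[lab - 1])[:2]
    if sum(sizes[lab - 1] for lab in keep) * voxel_cm3 < min_total_cm3:
        raise RoiError(
            f"lung candidate volume "
            f"{sum(sizes[lab - 1] for lab in keep) * voxel_cm3:.1f} cm^3 "
            f"< {min_total_cm3} cm^3"
        )
    # refinement per component: closing seals pleural partial-volume gaps,
    # hole filling re-includes dense nodules embedded in parenchyma
    mask = np.zeros_like(chest_mask)
    strut = _ball_voxels(closing_mm, sp)
    for lab in keep:
        comp = ndimage.binary_closing(labels == lab, structure=strut)
        mask |= ndimage.binary_fill_holes(comp)
    return mask


def detect_nodule_roi(
    v: CTVolume,
    lung_mask: np.ndarray,
    ann: Annotation,
    search_box_mm: float = 40.0,
    pleural_dilation_mm: float = 5.0,
    max_midpoint_gap_mm: float = 10.0,
    max_component_gap_mm: float = 20.0,
    mirror_x_mm: float | None = None,
    symmetry_overlap: float = 0.5,
) -> ROI:
    """Delineate the annotated nodule by clustering + lung symmetry.

    Otsu thresholding inside a ``search_box_mm`` cube around the annotation
    midpoint (restricted to the lung mask and its pleural dilation) labels
    dense voxels; dense components whose mirror image across the
    mid-sagittal plane is also dense are discarded as symmetric anatomy,
    except the component carrying the annotation, which is always kept.
    """
    if lung_mask.sum() == 0:
        raise RoiError("empty lung mask")
    sp = v.spacing[0]
    mid_idx = v.physical_to_index(ann.midpoint_mm)
    mid = np.round(mid_idx).astype(int)
    if np.any(mid < 0) or np.any(mid >= np.array(v.shape)):
        raise UndelineatableLesion("annotation midpoint outside the volume")

    dist_to_lung = ndimage.distance_transform_edt(~lung_mask, sampling=v.spacing)
    if dist_to_lung[tuple(mid)] > max_midpoint_gap_mm:
        raise UndelineatableLesion(
            f"annotation midpoint {dist_to_lung[tuple(mid)]:.1f} mm from lung"
        )

    region = ndimage.binary_dilation(
        lung_mask, structure=_ball_voxels(pleural_dilation_mm, sp)
    )
    half = int(round(search_box_mm / 2 / sp))
    lo = np.maximum(mid - half, 0)
    hi = np.minimum(mid + half + 1, np.array(v.shape))
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    box_region = np.zeros_like(region)
    box_region[box] = region[box]

    vals_in = v.values[box_region]
    if vals_in.size < 8 or np.ptp(vals_in) < 1e-6:
        raise UndelineatableLesion("no intensity contrast around the annotation")
    thresh = threshold_otsu(vals_in)
    dense_global = (v.values >= thresh) & region
    if not np.any(dense_global[box_region]):
        raise UndelineatableLesion("no dense voxels near the annotation")

    dense_box = dense_global & box_region
    labels, n = ndimage.label(dense_box, structure=STRUCT_26)

    if mirror_x_mm is None:
        xs = np.nonzero(lung_mask.any(axis=(1, 2)))[0]
        mirror_x_mm = v.index_to_physical(
            np.array([(xs[0] + xs[-1]) / 2.0, 0, 0])
        )[0]
    mirror_col = (mirror_x_mm - v.origin[0]) / v.spacing[0]

    def _has_mirror_twin(lab: int) -> bool:
        vox = np.argwhere(labels == lab)
        mirrored = vox.copy()
        mirrored[:, 0] = np.round(2 * mirror_col - vox[:, 0]).astype(int)
        valid = (mirrored[:, 0] >= 0) & (mirrored[:, 0] < v.shape[0])
        if valid.sum() == 0:
            return False
        m = mirrored[valid]
        return dense_global[m[:, 0], m[:, 1], m[:, 2]].mean() >= symmetry_overlap

    own = int(labels[tuple(mid)])
    # candidates: asymmetric dense components; the annotated one always stays
    candidates = [
        lab for lab in range(1, n + 1) if lab == own or not _has_mirror_twin(lab)
    ]
    if own == 0:
        if not candidates:
            raise UndelineatableLesion("no asymmetric dense component found")
        mid_mm = ann.midpoint_mm
        best, best_d = 0, np.inf
        for lab in candidates:
            pts = v.index_to_physical(np.argwhere(labels == lab))
            d = float(np.min(np.linalg.norm(pts - mid_mm, axis=1)))
            if d < best_d:
                best, best_d = lab, d
        if best_d > max_component_gap_mm:
            raise UndelineatableLesion(
                "no dense component within "
                f"{max_component_gap_mm} mm of the annotation midpoint"
            )
        own = best

    keep_mask = labels == own
    vox = np.argwhere(keep_mask)
    lo_b = np.maximum(vox.min(axis=0) - 2, 0)
    hi_b = np.minimum(vox.max(axis=0) + 3, np.array(v.shape))
    bbox = tuple((int(a), int(b)) for a, b in zip(lo_b, hi_b))
    return ROI(
        mask=keep_mask,
        bbox=bbox,  # type: ignore[arg-type]
        lesion_radius_mm=ann.radius_mm,
    )


def delineate(
    v: CTVolume, ann: Annotation, **kwargs
) -> tuple[ROI, np.ndarray, np.ndarray]:
    """Convenience: full ROI stack on an isotropic volume.

    Returns (roi, chest_mask, lung_mask).  Raises :class:`RoiError` /
    :class:`UndelineatableLesion` on the countable failure paths.
    """
    chest = segment_chest(v)
    lungs = segment_lungs(v, chest)
    roi = detect_nodule_roi(v, lungs, ann, **kwargs)
    return roi, chest, lungs
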