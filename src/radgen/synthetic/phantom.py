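"""Analytic thorax phantoms with ground-truth nodules.

The phantom is deliberately simple: an ellipsoidal soft-tissue body, two
mirror-symmetric ellipsoidal lungs filled with low-density parenchyma, and
spherical nodules of configurable radius, density and edge softness.  The
geometry is analytic, so every generated mask can be checked against exact
ellipsoid/sphere membership — the phantoms exist to make the segmentation
and feature pipeline testable, not to look like a patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..volume import CTVolume, HU_MAX, HU_MIN


@dataclass(frozen=True)
class Nodule:
    center_mm: tuple[float, float, float]
    radius_mm: float
    mean_hu: float = 20.0
    edge_softness_mm: float = 1.0
    #: sd of the intra-nodular texture field (correlated at ~texture_scale_mm);
    #: real lesions are heterogeneous, and texture features presume it
    texture_hu: float = 40.0
    texture_scale_mm: float = 2.5

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("nodule radius must be > 0")
        if self.edge_softness_mm < 0:
            raise ValueError("edge softness must be >= 0")
        if self.texture_hu < 0 or self.texture_scale_mm <= 0:
            raise ValueError("invalid nodule texture parameters")


@dataclass(frozen=True)
class Ellipsoid:
    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semiaxes_mm):
            raise ValueError("semi-axes must be > 0")

    def normalized_distance(self, pts_mm: np.ndarray) -> np.ndarray:
        """sqrt(sum(((p - c)/a)^2)); <= 1 inside."""
        d = (np.asarray(pts_mm, float) - np.asarray(self.center_mm)) / np.asarray(
            self.semiaxes_mm
        )
        return np.sqrt(np.sum(d * d, axis=-1))

    def contains_sphere(self, center_mm, radius_mm) -> bool:
        # conservative sufficient condition: the normalized-distance map is
        # 1/a_min-Lipschitz, so nd(c) + r/a_min <= 1 guarantees containment
        a_min = float(min(self.semiaxes_mm))
        if radius_mm >= a_min:
            return False
        nd = float(self.normalized_distance(np.asarray(center_mm, float)))
        return nd + radius_mm / a_min <= 1.0


@dataclass
class PhantomSpec:
    """Geometry and tissue parameters of a synthetic thorax."""

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 2.0)
    body: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((72.0, 72.0, 64.0), (66.0, 52.0, 62.0))
    )
    lungs: tuple[Ellipsoid, Ellipsoid] = field(
        default_factory=lambda: (
            Ellipsoid((44.0, 72.0, 64.0), (24.0, 32.0, 40.0)),
            Ellipsoid((100.0, 72.0, 64.0), (24.0, 32.0, 40.0)),
        )
    )
    nodules: list[Nodule] = field(default_factory=list)
    hu_air: float = -1000.0
    hu_lung: float = -850.0
    hu_soft: float = 40.0
    texture_noise_hu: float = 10.0

    @classmethod
    def small(cls) -> "PhantomSpec":
        """Compact phantom (96-mm cube scale) for replicate-heavy studies."""
        return cls(
            grid_shape=(64, 64, 48),
            spacing_mm=(1.5, 1.5, 2.0),
            body=Ellipsoid((48.0, 48.0, 48.0), (44.0, 36.0, 46.0)),
            lungs=(
                Ellipsoid((29.0, 48.0, 48.0), (16.0, 20.0, 28.0)),
                Ellipsoid((67.0, 48.0, 48.0), (16.0, 20.0, 28.0)),
            ),
        )

    def validate(self) -> None:
        if any(n < 2 for n in self.grid_shape):
            raise ValueError("grid_shape must be >= 2 per axis")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if not (self.hu_air < self.hu_lung < self.hu_soft):
            raise ValueError("expected hu_air < hu_lung < hu_soft")
        for lung in self.lungs:
            # lung must sit inside the body (sample the bounding sphere proxy)
            d = (
                np.abs(np.asarray(lung.center_mm) - np.asarray(self.body.center_mm))
                + np.asarray(lung.semiaxes_mm)
            ) / np.asarray(self.body.semiaxes_mm)
            if np.sum(d * d) > 3.0:  # loose containment screen
                raise ValueError("lung ellipsoid extends outside the body")
        for nod in self.nodules:
            if not any(l.contains_sphere(nod.center_mm, nod.radius_mm) for l in self.lungs):
                raise ValueError(
                    f"nodule at {nod.center_mm} (r={nod.radius_mm}) not inside a lung"
                )
        for i, a in enumerate(self.nodules):
            for b in self.nodules[i + 1 :]:
                gap = np.linalg.norm(
                    np.asarray(a.center_mm) - np.asarray(b.center_mm)
                )
                if gap < a.radius_mm + b.radius_mm and a.mean_hu != b.mean_hu:
                    raise ValueError("overlapping nodules with contradictory HU")


@dataclass
class PhantomMasks:
    body: np.ndarray
    lungs: list[np.ndarray]
    nodules: list[np.ndarray]


def _grid_points(spec: PhantomSpec) -> np.ndarray:
    axes = [
        np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing_mm)
    ]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return np.stack([X, Y, Z], axis=-1)


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> tuple[CTVolume, PhantomMasks]:
    """Voxelize a phantom spec into a CT volume plus ground-truth masks.

    Masks are exact analytic membership tests evaluated at voxel centers.
    Tissue interfaces in the intensity image are softened over
    ``edge_softness_mm`` (nodules) and ~2 mm (body/lung walls) so that the
    image is not pathologically band-limited; seeded Gaussian texture noise
    of ``texture_noise_hu`` is added everywhere inside the body.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    pts = _grid_points(spec)

    body_d = spec.body.normalized_distance(pts)
    body_mask = body_d <= 1.0

    # skin boundary is sharp at CT resolution: ~1 mm transition
    soft = 1.0 / float(np.mean(spec.body.semiaxes_mm))
    w_body = np.clip((1.0 + soft - body_d) / (2 * soft), 0.0, 1.0)
    hu = spec.hu_air + (spec.hu_soft - spec.hu_air) * w_body

    lung_masks = []
    for lung in spec.lungs:
        d = lung.normalized_distance(pts)
        lung_masks.append(d <= 1.0)
        soft_l = 2.0 / float(np.mean(lung.semiaxes_mm))
        w = np.clip((1.0 + soft_l - d) / (2 * soft_l), 0.0, 1.0)
        hu = hu + (spec.hu_lung - spec.hu_soft) * w

    from scipy import ndimage

    nodule_masks = []
    for nod in spec.nodules:
        r = np.linalg.norm(pts - np.asarray(nod.center_mm), axis=-1)
        nodule_masks.append(r <= nod.radius_mm)
        eps = max(nod.edge_softness_mm, 1e-6)
        w = np.clip((nod.radius_mm + eps / 2 - r) / eps, 0.0, 1.0)
        target = nod.mean_hu
        if nod.texture_hu > 0:
            sig_vox = nod.texture_scale_mm / np.asarray(spec.spacing_mm)
            field = ndimage.gaussian_filter(
                rng.normal(0.0, 1.0, hu.shape), sigma=sig_vox, mode="wrap"
            )
            fsd = field.std()
            if fsd > 0:
                target = target + nod.texture_hu * field / fsd
        hu = hu + (target - hu) * w

    if spec.texture_noise_hu > 0:
        hu = hu + rng.normal(0.0, spec.texture_noise_hu, hu.shape) * body_mask

    hu = np.clip(hu, HU_MIN, HU_MAX)
    vol = CTVolume(values=hu, spacing=spec.spacing_mm)
    return vol, PhantomMasks(body=body_mask, lungs=lung_masks, nodules=nodule_masks)


def sample_phantom_case(
    seed: int,
    radius_range_mm: tuple[float, float] = (5.0, 16.0),
    mean_hu_range: tuple[float, float] = (0.0, 50.0),
    spec: PhantomSpec | None = None,
):
    """Draw a single-nodule phantom with a longest-axis annotation.

    Returns ``(spec, annotation_endpoints_mm, nodule)`` where the endpoints
    span the nodule's diameter along a random direction — the voxel-level
    analogue of a radiologist's longest-axis annotation.
    """
    rng = np.random.default_rng(seed)
    base = spec if spec is not None else PhantomSpec()
    radius = float(rng.uniform(*radius_range_mm))
    mean_hu = float(rng.uniform(*mean_hu_range))
    lung = base.lungs[int(rng.integers(0, 2))]
    # rejection-sample a center whose sphere stays inside the lung with a
    # 2-mm parenchyma margin (partial-volume headroom)
    for _ in range(1000):
        u = rng.uniform(-1.0, 1.0, size=3)
        cand = np.asarray(lung.center_mm) + u * (
            np.asarray(lung.semiaxes_mm) - radius
        )
        if lung.contains_sphere(cand, radius + 2.0):
            break
    else:  # pragma: no cover - geometry guarantees success quickly
        cand = np.asarray(lung.center_mm)
    nod = Nodule(tuple(cand), radius, mean_hu=mean_hu, edge_softness_mm=1.5)
    full = PhantomSpec(
        grid_shape=base.grid_shape,
        spacing_mm=base.spacing_mm,
        body=base.body,
        lungs=base.lungs,
        nodules=[nod],
        hu_air=base.hu_air,
        hu_lung=base.hu_lung,
        hu_soft=base.hu_soft,
        texture_noise_hu=base.texture_noise_hu,
    )
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    p0 = cand - direction * radius
    p1 = cand + direction * radius
    return full, (tuple(p0), tuple(p1)), nod
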