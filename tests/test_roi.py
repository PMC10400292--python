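import numpy as np
import pytest
from scipy import ndimage

from radgen.harmonization import harmonize
from radgen.roi import (
    Annotation,
    RoiError,
    UndelineatableLesion,
    align_axes,
    detect_nodule_roi,
    segment_chest,
    segment_lungs,
)
from radgen.synthetic.phantom import (
    Nodule,
    PhantomSpec,
    generate_phantom,
)
from radgen.volume import CTVolume


@pytest.fixture(scope="module")
def iso_phantom():
    """Truth phantom (no acquisition noise path) harmonized to 1 mm."""
    spec = PhantomSpec(nodules=[Nodule((44.0, 72.0, 64.0), 8.0)])
    vol, masks = generate_phantom(spec, seed=2)
    ch = harmonize(vol)
    return spec, ch.original, masks


def _resampled_truth(mask, spacing=(1.5, 1.5, 2.0), out_shape=None):
    """Nearest-neighbour upsample of a truth mask to the 1-mm grid."""
    out_shape = out_shape or tuple(
        int(np.floor(n * s + 0.5)) for n, s in zip(mask.shape, spacing)
    )
    coords = np.meshgrid(
        *[np.arange(n) / s for n, s in zip(out_shape, spacing)], indexing="ij"
    )
    return (
        ndimage.map_coordinates(
            mask.astype(np.float32), np.stack(coords), order=0, mode="nearest"
        )
        > 0.5
    )


def _dice(a, b):
    return 2 * (a & b).sum() / (a.sum() + b.sum())


# -------------------------------------------------------------- alignment


def test_aligned_phantom_gives_near_identity_transform(iso_phantom):
    _, vol, _ = iso_phantom
    _, tf = align_axes(vol)
    assert np.all(np.abs(tf.angles_deg()) < 1.0)


def test_known_rotation_recovered_within_one_degree(iso_phantom):
    _, vol, _ = iso_phantom
    rotated = CTVolume(
        ndimage.rotate(
            vol.values, angle=10.0, axes=(0, 1), reshape=False,
            order=1, mode="constant", cval=-1000.0,
        ),
        vol.spacing,
    )
    _, tf = align_axes(rotated)
    # rotating back by -10 deg about z
    assert abs(abs(tf.angles_deg()[2]) - 10.0) < 1.0


def test_annotation_maps_consistently_through_transform(iso_phantom):
    _, vol, _ = iso_phantom
    aligned, tf = align_axes(vol)
    pt = np.array([44.0, 72.0, 64.0])
    moved = tf.apply_points(pt)
    # near-identity transform: the anatomical location barely moves and the
    # HU at the mapped point matches the original within interpolation noise
    orig_hu = vol.values[tuple(np.round(vol.physical_to_index(pt)).astype(int))]
    new_hu = aligned.values[
        tuple(np.round(aligned.physical_to_index(moved)).astype(int))
    ]
    assert abs(orig_hu - new_hu) < 50.0


def test_empty_volume_rejected():
    v = CTVolume(np.full((20, 20, 20), -1000.0), (1, 1, 1))
    with pytest.raises(RoiError, match="body"):
        align_axes(v)


# ------------------------------------------------------------------ chest


def test_chest_mask_matches_ground_truth_body(iso_phantom):
    spec, vol, masks = iso_phantom
    chest = segment_chest(vol)
    truth = _resampled_truth(masks.body, out_shape=vol.shape)
    assert _dice(chest, truth) >= 0.98


def test_disconnected_table_artifact_excluded(iso_phantom):
    _, vol, _ = iso_phantom
    v = vol.with_values(vol.values.copy())
    v.values[:, :4, :] = 500.0  # slab detached from the body
    chest = segment_chest(v)
    assert not chest[:, :3, :].any()


def test_all_air_volume_rejected():
    v = CTVolume(np.full((40, 40, 40), -1000.0), (1, 1, 1))
    with pytest.raises(RoiError):
        segment_chest(v)


# ------------------------------------------------------------------ lungs


def test_two_lungs_recovered_with_high_dice(iso_phantom):
    spec, vol, masks = iso_phantom
    chest = segment_chest(vol)
    lungs = segment_lungs(vol, chest)
    labels, n = ndimage.label(lungs, structure=np.ones((3, 3, 3), bool))
    assert n == 2
    for truth_mask in masks.lungs:
        truth = _resampled_truth(truth_mask, out_shape=vol.shape)
        best = max(
            _dice(labels == k, truth) for k in range(1, n + 1)
        )
        assert best >= 0.95


def test_solid_nodule_included_after_refinement():
    spec = PhantomSpec(nodules=[Nodule((44.0, 72.0, 64.0), 5.0, mean_hu=30.0)])
    vol, _ = generate_phantom(spec, seed=4)
    ch = harmonize(vol).original
    chest = segment_chest(ch)
    lungs = segment_lungs(ch, chest)
    center_idx = tuple(np.round(np.array([44.0, 72.0, 64.0])).astype(int))
    assert lungs[center_idx]


def test_solid_phantom_without_lungs_rejected():
    spec = PhantomSpec()
    vol, _ = generate_phantom(spec, seed=5)
    solid = vol.with_values(np.where(vol.values < -500, 40.0, vol.values))
    ch = harmonize(solid).original
    chest = segment_chest(ch)
    with pytest.raises(RoiError):
        segment_lungs(ch, chest)


# -------------------------------------------------------------------- ROI


def test_nodule_roi_recovers_sphere(phantom_case):
    roi = phantom_case["roi"]
    nod = phantom_case["nodule"]
    vol = phantom_case["channels"].original
    grid = np.indices(vol.shape).reshape(3, -1).T.astype(float)
    truth = (
        np.linalg.norm(grid - np.asarray(nod.center_mm), axis=1)
        <= nod.radius_mm
    ).reshape(vol.shape)
    assert _dice(roi.mask, truth) >= 0.6
    # the bounding box contains the true sphere
    (x0, x1), (y0, y1), (z0, z1) = roi.bbox
    inside = truth.copy()
    inside[x0:x1, y0:y1, z0:z1] = False
    assert inside.sum() / truth.sum() < 0.05


def test_roi_mask_single_26_connected_component(phantom_case):
    _, n = ndimage.label(
        phantom_case["roi"].mask, structure=np.ones((3, 3, 3), bool)
    )
    assert n == 1


def test_symmetric_twin_suppressed_annotated_component_kept():
    spec = PhantomSpec(
        nodules=[
            Nodule((44.0, 72.0, 64.0), 7.0, mean_hu=30.0, texture_hu=0.0),
            Nodule((100.0, 72.0, 64.0), 7.0, mean_hu=30.0, texture_hu=0.0),
        ]
    )
    vol, _ = generate_phantom(spec, seed=6)
    ch = harmonize(vol).original
    chest = segment_chest(ch)
    lungs = segment_lungs(ch, chest)
    ann = Annotation("left", (37.0, 72.0, 64.0), (51.0, 72.0, 64.0))
    roi = detect_nodule_roi(ch, lungs, ann)
    xs = np.nonzero(roi.mask.any(axis=(1, 2)))[0]
    assert xs.max() < 72  # left lung only; contralateral twin not included


def test_annotation_in_homogeneous_parenchyma_rejected(iso_phantom):
    _, vol, _ = iso_phantom
    chest = segment_chest(vol)
    lungs = segment_lungs(vol, chest)
    # right lung has no nodule
    ann = Annotation("empty", (95.0, 72.0, 64.0), (105.0, 72.0, 64.0))
    with pytest.raises(UndelineatableLesion):
        detect_nodule_roi(vol, lungs, ann)


def test_annotation_far_from_lung_rejected(iso_phantom):
    _, vol, _ = iso_phantom
    chest = segment_chest(vol)
    lungs = segment_lungs(vol, chest)
    # chest-wall point, > 10 mm from any lung voxel
    ann = Annotation("soft", (70.0, 24.0, 64.0), (74.0, 24.0, 64.0))
    with pytest.raises(UndelineatableLesion):
        detect_nodule_roi(vol, lungs, ann)


def test_annotation_endpoints_must_differ():
    with pytest.raises(ValueError):
        Annotation("x", (1.0, 2.0, 3.0), (1.0, 2.0, 3.0))


def test_annotation_json_roundtrip(tmp_path):
    ann = Annotation("lesion-1", (1.0, 2.0, 3.0), (4.0, 5.0, 6.0), "rad")
    path = tmp_path / "ann.json"
    ann.to_json(path)
    back = Annotation.from_json(path)
    assert back == ann
    assert back.radius_mm == pytest.approx(ann.length_mm / 2)
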