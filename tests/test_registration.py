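"""Landmark orientation and trimmed ICP: recovery of known rigid motions."""

import numpy as np
import pytest

from swell3d import (IcpParams, LandmarkSet, RigidTransform, add_swelling_bump,
                     apply_transform, icp_register, mesh_volume,
                     orient_by_landmarks)
from swell3d.errors import DegenerateLandmarksError, InvalidMeshError
from swell3d.registration import fit_rigid_points
from swell3d.synthetic import SwellingScenario, random_rigid_transform


def test_rigid_transform_group_laws():
    rng = np.random.default_rng(0)
    for _ in range(20):
        t = random_rigid_transform(rng, 180.0, 50.0)
        u = random_rigid_transform(rng, 180.0, 50.0)
        ident = t.compose(t.inverse())
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-8)
        assert np.allclose(ident.translation, 0, atol=1e-8)
        p = rng.normal(size=(5, 3))
        np.testing.assert_allclose(t.compose(u).apply(p), t.apply(u.apply(p)),
                                   atol=1e-9)


def test_orient_identity_for_canonical_landmarks(landmarks):
    t = orient_by_landmarks(landmarks)
    assert np.allclose(t.rotation, np.eye(3), atol=1e-9)
    assert np.allclose(t.translation, 0, atol=1e-9)


def test_orient_recovers_random_motions(landmarks):
    rng = np.random.default_rng(11)
    for _ in range(100):
        motion = random_rigid_transform(rng, 180.0, 100.0)
        moved = landmarks.transformed(motion)
        recovered = orient_by_landmarks(moved)
        total = recovered.compose(motion)
        assert np.allclose(total.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(total.translation, 0, atol=1e-6)


def test_orient_rejects_degenerate_landmarks(landmarks):
    pts = {k: v.copy() for k, v in landmarks.points.items()}
    pts["porion_right"] = pts["porion_left"]
    with pytest.raises(DegenerateLandmarksError):
        orient_by_landmarks(LandmarkSet(pts, side="left"))


def test_kabsch_fit_exact_on_noise_free_pairs():
    rng = np.random.default_rng(5)
    p = rng.normal(size=(40, 3))
    motion = random_rigid_transform(rng, 90.0, 20.0)
    fit = fit_rigid_points(p, motion.apply(p))
    assert np.allclose(fit.rotation, motion.rotation, atol=1e-10)
    assert np.allclose(fit.translation, motion.translation, atol=1e-10)


def test_icp_identity_on_identical_meshes(head):
    res = icp_register(head, head, IcpParams(seed=0))
    assert res.rms < 1e-6
    assert np.allclose(res.transform.rotation, np.eye(3), atol=1e-6)


def test_icp_recovers_seeded_motion(head):
    rng = np.random.default_rng(21)
    for i in range(3):
        motion = random_rigid_transform(rng, 10.0, 10.0)
        source = apply_transform(head, motion)
        res = icp_register(source, head, IcpParams(seed=i))
        recovered = apply_transform(source, res.transform)
        err = np.linalg.norm(recovered.vertices - head.vertices, axis=1).mean()
        assert err < 0.1


def test_icp_trimming_absorbs_swelling_bump(head):
    center = SwellingScenario().resolved_center()
    bumped, _ = add_swelling_bump(head, center, 3.0, 15.0)
    rng = np.random.default_rng(4)
    motion = random_rigid_transform(rng, 10.0, 10.0)
    source = apply_transform(bumped, motion)
    res = icp_register(source, head, IcpParams(seed=0))
    recovered = apply_transform(source, res.transform)
    unswollen = head.vertices[:, 0] < 0  # contralateral hemiface
    err = np.linalg.norm(recovered.vertices[unswollen]
                         - bumped.vertices[unswollen], axis=1).mean()
    assert err < 0.5


def test_icp_deterministic_given_seed(head):
    rng = np.random.default_rng(9)
    source = apply_transform(head, random_rigid_transform(rng, 8.0, 8.0))
    r1 = icp_register(source, head, IcpParams(seed=42))
    r2 = icp_register(source, head, IcpParams(seed=42))
    np.testing.assert_array_equal(r1.transform.rotation, r2.transform.rotation)
    np.testing.assert_array_equal(r1.transform.translation, r2.transform.translation)
    assert r1.rms == r2.rms


def test_icp_rejects_empty_mesh(head):
    from swell3d import TriangleMesh
    empty = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
    with pytest.raises(InvalidMeshError):
        icp_register(empty, head, IcpParams())
    with pytest.raises(InvalidMeshError):
        icp_register(head, empty, IcpParams())


def test_apply_transform_preserves_volume_and_rotates_vectors(head):
    rng = np.random.default_rng(2)
    head = head.copy()
    head.vertex_vectors["displacement_mm"] = rng.normal(size=(head.n_vertices, 3))
    motion = random_rigid_transform(rng, 45.0, 30.0)
    moved = apply_transform(head, motion)
    v0 = mesh_volume(head).volume
    v1 = mesh_volume(moved).volume
    assert abs(v1 - v0) / v0 < 1e-10
    np.testing.assert_allclose(
        moved.vertex_vectors["displacement_mm"],
        head.vertex_vectors["displacement_mm"] @ motion.rotation.T)
    # pure translation shifts the bbox
    shift = RigidTransform(np.eye(3), np.array([1.0, 2.0, 3.0]))
    np.testing.assert_allclose(apply_transform(head, shift).bounds,
                               head.bounds + np.array([1.0, 2.0, 3.0]))
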