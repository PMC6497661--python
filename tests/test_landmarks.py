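import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morphoshift import (gpa_align, procrustes_distance,
                         pairwise_procrustes_distances, read_landmarks,
                         resample_curve, simulate_landmark_dataset,
                         simulate_tree, species_consensus, write_landmarks)
from morphoshift.landmarks import (LandmarkDataset, _mirror_relabel,
                                   write_curve_spec)
from morphoshift.synthetic import make_template


# ------------------------------------------------------------------------ IO

def test_csv_round_trip_bit_equal(tmp_path, medium_tree):
    ds = simulate_landmark_dataset(medium_tree, missing_fraction=0.04, seed=5)
    path = tmp_path / "lm.csv"
    spec = tmp_path / "curves.json"
    write_landmarks(ds, path)
    write_curve_spec(ds, spec)
    back = read_landmarks(path, "csv", curve_spec_path=spec)
    assert back.specimen_ids == ds.specimen_ids
    np.testing.assert_array_equal(back.missing, ds.missing)
    np.testing.assert_array_equal(back.coordinates[~ds.missing],
                                  ds.coordinates[~ds.missing])
    assert back.bilateral_pairs == ds.bilateral_pairs
    assert back.midline == ds.midline


def test_csv_without_missing_has_empty_mask(tmp_path, medium_tree):
    ds = simulate_landmark_dataset(medium_tree, missing_fraction=0.0, seed=5)
    write_landmarks(ds, tmp_path / "lm.csv")
    back = read_landmarks(tmp_path / "lm.csv", "csv")
    assert not back.missing.any()


def test_tps_single_record(tmp_path):
    tps = tmp_path / "one.tps"
    tps.write_text("LM3=4\n0 0 0\n1 0 0\n0 1 0\n0 0 1\nID=spec_a\n")
    ds = read_landmarks(tps, "tps")
    assert ds.n_specimens == 1
    assert ds.n_landmarks == 4
    np.testing.assert_allclose(ds.coordinates[0, 3], [0, 0, 1])


def test_inconsistent_landmark_count_names_specimen(tmp_path):
    path = tmp_path / "bad.csv"
    rows = ["specimen,species,landmark,x,y,z",
            "s1,sp1,0,0,0,0", "s1,sp1,1,1,0,0",
            "s2,sp2,0,0,0,0"]
    path.write_text("\n".join(rows) + "\n")
    with pytest.raises(ValueError, match="s2"):
        read_landmarks(path, "csv")


# ---------------------------------------------------------- curve resampling

def test_resample_uniform_line():
    pts = np.linspace([0, 0, 0], [1, 0, 0], 11)
    out = resample_curve(pts, 5)
    np.testing.assert_allclose(out[:, 0], [0, 0.25, 0.5, 0.75, 1.0], atol=1e-12)
    np.testing.assert_allclose(out[:, 1:], 0.0, atol=1e-12)


def test_resample_right_angle_midpoint_at_corner():
    pts = np.array([[0, 0, 0.0], [1, 0, 0], [1, 1, 0]])
    out = resample_curve(pts, 3)
    np.testing.assert_allclose(out[1], [1, 0, 0], atol=1e-12)


def test_resample_idempotent_on_uniform_input():
    pts = np.linspace([0, 1, 2], [3, 1, -1], 7)
    np.testing.assert_allclose(resample_curve(pts, 7), pts, atol=1e-12)


def test_resample_equal_arclength_spacing():
    rng = np.random.default_rng(0)
    pts = np.cumsum(rng.standard_normal((20, 3)) * 0.3, axis=0)
    out = resample_curve(pts, 9)
    # locate each output point on the polyline and recover its arc position
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    arc = []
    for q in out:
        found = None
        for i in range(len(pts) - 1):
            d = pts[i + 1] - pts[i]
            t = np.clip((q - pts[i]) @ d / (d @ d), 0, 1)
            if np.linalg.norm(pts[i] + t * d - q) < 1e-9:
                found = s[i] + t * seg[i]
                break
        assert found is not None, "output point not on the polyline"
        arc.append(found)
    np.testing.assert_allclose(np.diff(arc), s[-1] / 8, atol=1e-9)
    np.testing.assert_allclose(out[0], pts[0], atol=1e-12)
    np.testing.assert_allclose(out[-1], pts[-1], atol=1e-12)


def test_resample_rejects_duplicates_and_bad_n():
    with pytest.raises(ValueError):
        resample_curve(np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0.0]]), 3)
    with pytest.raises(ValueError):
        resample_curve(np.array([[0, 0, 0], [1, 0, 0.0]]), 1)


# ------------------------------------------------------- Procrustes distance

def _grid_search_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Independent oracle for planar shapes: brute-force the in-plane rotation
    angle by iterated grid refinement."""
    def pre(x):
        c = x - x.mean(axis=0)
        return c / np.linalg.norm(c)
    pa, pb = pre(a), pre(b)
    lo, hi = 0.0, 2 * np.pi
    best = np.inf
    for _ in range(8):
        angles = np.linspace(lo, hi, 721)
        vals = []
        for th in angles:
            R = np.array([[np.cos(th), -np.sin(th), 0],
                          [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
            vals.append(np.linalg.norm(pa @ R - pb))
        i = int(np.argmin(vals))
        best = vals[i]
        span = (hi - lo) / 720
        lo, hi = angles[i] - span, angles[i] + span
    return float(best)


def _planar(points2d) -> np.ndarray:
    pts = np.asarray(points2d, dtype=float)
    return np.column_stack([pts, np.zeros(len(pts))])


def test_distance_rotation_invariance():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((8, 3))
    th = 1.1
    R = np.array([[np.cos(th), -np.sin(th), 0],
                  [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    assert procrustes_distance(X, 3.3 * X @ R + 5) < 1e-10


@pytest.mark.parametrize("tri_b", [
    [[0, 0], [1, 0], [0.5, 0.1]],        # near-degenerate isoceles
    [[0, 0], [2, 0], [0.3, 1.4]],
    [[0, 0], [1, 0], [1, 1]],
])
def test_distance_matches_rotation_grid_oracle(tri_b):
    tri_a = _planar([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])  # equilateral
    b = _planar(tri_b)
    assert procrustes_distance(tri_a, b) == pytest.approx(
        _grid_search_distance(tri_a, b), abs=1e-6)


def test_distance_symmetry_many_pairs():
    rng = np.random.default_rng(2)
    for _ in range(100):
        a, b = rng.standard_normal((2, 7, 3))
        assert procrustes_distance(a, b) == pytest.approx(
            procrustes_distance(b, a), abs=1e-12)


def test_distance_shape_mismatch():
    with pytest.raises(ValueError):
        procrustes_distance(np.zeros((4, 3)), np.zeros((5, 3)))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_distance_triangle_inequality_nearby_shapes(seed):
    """Partial Procrustes distance is a metric for nearby shapes."""
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((6, 3))
    shapes = [base + 0.05 * rng.standard_normal(base.shape) for _ in range(3)]
    d01 = procrustes_distance(shapes[0], shapes[1])
    d12 = procrustes_distance(shapes[1], shapes[2])
    d02 = procrustes_distance(shapes[0], shapes[2])
    assert max(d01, d12, d02) < 0.3
    assert d02 <= d01 + d12 + 1e-8


def test_pairwise_matches_scalar_distances():
    rng = np.random.default_rng(3)
    shapes = rng.standard_normal((5, 6, 3))
    D = pairwise_procrustes_distances(shapes)
    for i in range(5):
        for j in range(i + 1, 5):
            assert D[i, j] == pytest.approx(
                procrustes_distance(shapes[i], shapes[j]), abs=1e-10)


# ----------------------------------------------------------------------- GPA

def _dataset_from_shapes(shapes, curves=None, pairs=None, midline=None):
    ids = [f"s{i}" for i in range(len(shapes))]
    return LandmarkDataset(ids, {i: i for i in ids}, np.asarray(shapes, float),
                           np.zeros(np.asarray(shapes).shape[:2], dtype=bool),
                           curves=curves or [], bilateral_pairs=pairs or [],
                           midline=midline or [])


def test_gpa_removes_similarity_transforms():
    rng = np.random.default_rng(4)
    base = rng.standard_normal((7, 3))
    th = 0.7
    R = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0],
                  [-np.sin(th), 0, np.cos(th)]])
    ds = _dataset_from_shapes([base, 2.5 * base @ R + np.array([1, 2, 3])])
    out = gpa_align(ds)
    np.testing.assert_allclose(out.aligned[0], out.aligned[1], atol=1e-9)
    assert procrustes_distance(out.aligned[0], out.aligned[1]) < 1e-9


def test_gpa_invariants_center_and_unit_size():
    rng = np.random.default_rng(5)
    ds = _dataset_from_shapes(rng.standard_normal((6, 8, 3)))
    out = gpa_align(ds)
    for shape in out.aligned:
        assert np.linalg.norm(shape.mean(axis=0)) < 1e-10
        assert abs(np.linalg.norm(shape - shape.mean(axis=0)) - 1) < 1e-10
    np.testing.assert_allclose(out.consensus, out.aligned.mean(axis=0),
                               atol=1e-10)


def test_gpa_pairwise_distances_match_oracle():
    tris = [_planar([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]]),
            _planar([[0, 0], [1.5, 0], [0.2, 0.9]]),
            _planar([[0, 0], [1, 0], [0.9, 0.8]])]
    for i in range(3):
        for j in range(i + 1, 3):
            assert procrustes_distance(tris[i], tris[j]) == pytest.approx(
                _grid_search_distance(tris[i], tris[j]), abs=1e-6)


def test_gpa_sliding_reduces_procrustes_sum_of_squares(medium_tree):
    """Jittering semilandmarks along their curves is recoverable by sliding."""
    ds = simulate_landmark_dataset(medium_tree, seed=6)
    rng = np.random.default_rng(6)
    for c in ds.curves:
        ids = c["ids"]
        for j in range(1, len(ids) - 1):
            direction = ds.coordinates[:, ids[j + 1]] - ds.coordinates[:, ids[j - 1]]
            direction /= np.linalg.norm(direction, axis=1, keepdims=True)
            ds.coordinates[:, ids[j]] += \
                0.05 * rng.standard_normal((ds.n_specimens, 1)) * direction
    plain = gpa_align(ds, slide=False)
    slid = gpa_align(ds, slide=True)
    ss_plain = sum(procrustes_distance(s, plain.consensus) ** 2
                   for s in plain.aligned)
    ss_slid = sum(procrustes_distance(s, slid.consensus) ** 2
                  for s in slid.aligned)
    assert ss_slid <= ss_plain


def test_gpa_specimen_order_invariance():
    rng = np.random.default_rng(7)
    shapes = rng.standard_normal((6, 8, 3))
    a = gpa_align(_dataset_from_shapes(shapes))
    b = gpa_align(_dataset_from_shapes(shapes[::-1]))
    assert procrustes_distance(a.consensus, b.consensus) < 1e-8


def test_gpa_degenerate_specimen_named_in_error():
    shapes = np.zeros((3, 5, 3))
    shapes[0] = np.random.default_rng(0).standard_normal((5, 3))
    shapes[2] = np.random.default_rng(1).standard_normal((5, 3))
    with pytest.raises(ValueError, match="s1"):
        gpa_align(_dataset_from_shapes(shapes))


def test_gpa_requires_complete_data(medium_tree):
    ds = simulate_landmark_dataset(medium_tree, missing_fraction=0.05, seed=8)
    with pytest.raises(ValueError, match="missing"):
        gpa_align(ds)


# --------------------------------------------------------- species consensus

def test_consensus_single_specimen_is_itself():
    rng = np.random.default_rng(8)
    shapes = rng.standard_normal((2, 6, 3))
    ds = _dataset_from_shapes(shapes)
    out = gpa_align(ds)
    names, cons = species_consensus(out, {"s0": "spA", "s1": "spB"},
                                    do_symmetrize=False)
    assert names == ["spA", "spB"]
    np.testing.assert_allclose(cons[0], out.aligned[0], atol=1e-12)


def test_consensus_of_mirror_images_is_symmetric():
    template, curves, pairs, midline = make_template(n_semis=2)
    shape = template + 0.05 * np.random.default_rng(9).standard_normal(template.shape)
    M2, _ = _mirror_relabel(shape, np.ones(len(shape), bool), pairs, midline)
    names, cons = species_consensus(
        gpa_align(_dataset_from_shapes([shape, M2])),
        {"s0": "sp", "s1": "sp"}, bilateral_pairs=pairs, midline=midline)
    sym, _ = _mirror_relabel(cons[0], np.ones(len(shape), bool), pairs, midline)
    np.testing.assert_allclose(cons[0], sym, atol=1e-10)


def test_consensus_is_arithmetic_mean():
    rng = np.random.default_rng(10)
    base = rng.standard_normal((8, 3))
    shapes = [base + 0.01 * rng.standard_normal(base.shape) for _ in range(4)]
    out = gpa_align(_dataset_from_shapes(shapes))
    names, cons = species_consensus(out, {f"s{i}": "sp" for i in range(4)},
                                    do_symmetrize=False)
    np.testing.assert_allclose(cons[0], out.aligned.mean(axis=0), atol=1e-12)
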