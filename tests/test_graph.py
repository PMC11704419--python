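import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spotgae as sg
from spotgae.simulate import SimConfig, make_lattice


def hex_coords(rows=8, cols=8):
    return make_lattice(SimConfig(rows=rows, cols=cols, layout="hex"))


def deep_interior(coords, margin=2.5):
    """Indices at least `margin` from the bounding box.  Boundary spots have
    covering radii up to 2 lattice units (their 6th neighbor is farther than
    the unit ring), so union symmetrization can add edges up to 2 units
    inward; beyond that the 6-ring is exact."""
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    return np.flatnonzero(np.all((coords >= lo + margin) &
                                 (coords <= hi - margin), axis=1))


def test_radius_two_far_points_no_edge():
    g = sg.build_sng_radius(np.array([[0.0, 0], [2.0, 0]]), 1.0)
    assert g.n_edges == 0


def test_radius_grid_center_has_four_neighbors():
    coords = make_lattice(SimConfig(rows=3, cols=3, layout="grid"))
    g = sg.build_sng_radius(coords, 1.1)
    center = 4  # row 1, col 1
    assert sum(center in e for e in g.edges) == 4


def test_radius_duplicates_not_linked():
    g = sg.build_sng_radius(np.array([[0.0, 0], [0.0, 0]]), 1.0)
    assert g.n_edges == 0


def test_radius_strict_inequality():
    g = sg.build_sng_radius(np.array([[0.0, 0], [1.0, 0]]), 1.0)
    assert g.n_edges == 0  # distance == radius is excluded


def test_knn_hex_interior_degree_six():
    """On a hex lattice, k=6 covering-radius KNN gives exactly the 6-ring
    for spots away from the boundary, and <6 never occurs there."""
    coords = hex_coords(10, 10)
    g = sg.build_sng_knn(coords, 6)
    deg = g.degrees()
    interior = deep_interior(coords)
    assert len(interior) > 10
    assert np.all(deg[interior] == 6)
    # boundary spots list 6 neighbors themselves but can gain more via union
    corners = [0, 9]
    assert np.all(deg[corners] >= 6)


def test_knn_two_points():
    g = sg.build_sng_knn(np.array([[0.0, 0], [1.0, 0]]), 1)
    assert g.edges == {(0, 1)}


def test_knn_collinear_middle_point():
    coords = np.column_stack([np.arange(5.0), np.zeros(5)])
    g = sg.build_sng_knn(coords, 2)
    nbrs = g.neighbor_sets()
    assert {1, 3} <= nbrs[2]


def test_knn_k_out_of_range():
    with pytest.raises(ValueError):
        sg.build_sng_knn(np.zeros((3, 2)), 3)


def test_nonfinite_coords_fatal():
    with pytest.raises(ValueError):
        sg.build_sng_radius(np.array([[np.nan, 0], [0, 0]]), 1.0)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000), st.integers(2, 30), st.integers(1, 5))
def test_knn_symmetry_and_minimum_degree(seed, n, k):
    """Union symmetrization: A == A^T and every node has >= min(k, N-1)
    neighbors (covering radius includes at least k points, more under ties)."""
    rng = np.random.default_rng(seed)
    k = min(k, n - 1)
    coords = rng.random((n, 2)) * 10
    g = sg.build_sng_knn(coords, k)
    A = g.adjacency()
    assert (A != A.T).nnz == 0
    assert np.all(g.degrees() >= k)


def _stacked_slices(n_slices, rows=8, cols=8):
    cfg = sg.standard_small(rows=rows, cols=cols, n_genes=20, dropout_rate=0.0)
    ds, _ = sg.make_dataset(cfg)
    return [ds] * n_slices, ds.coords


def test_2dsng_far_apart_slices_equal_union_of_per_slice_graphs():
    cfg = sg.standard_small(rows=5, cols=5, n_genes=10)
    ds, _ = sg.make_dataset(cfg)
    import dataclasses
    far = dataclasses.replace(ds, coords=ds.coords + 1000.0)
    g = sg.build_2dsng([ds, far])
    per = sg.build_sng_knn(ds.coords, 6)
    expect = set(per.edges) | {(i + 25, j + 25) for i, j in per.edges}
    assert g.edges == expect


def test_2dsng_identical_slices_have_cross_edges():
    slices, _ = _stacked_slices(2)
    g = sg.build_2dsng(slices)
    n1 = slices[0].n_spots
    cross = [(i, j) for i, j in g.edges if (i < n1) != (j < n1)]
    assert len(cross) > 0


def test_2dsng_wrong_slice_count():
    slices, _ = _stacked_slices(3)
    with pytest.raises(ValueError, match="3dsng|3 slices|more than 2"):
        sg.build_2dsng(slices)
    with pytest.raises(ValueError):
        sg.build_2dsng(slices[:1])


def test_3dsng_neighbor_caps_on_perfect_stack():
    """4 perfectly stacked hex lattices: outer-slice interior spots have at
    most 6+7=13 neighbors, middle-slice interior spots at most 6+7+7=20 —
    and on a perfect stack those bounds are attained."""
    slices, coords = _stacked_slices(4)
    g = sg.build_3dsng(slices)
    n1 = slices[0].n_spots
    deg = g.degrees()
    interior = deep_interior(coords)
    assert len(interior) > 0
    assert np.all(deg[interior] == 13)          # slice 1 (outer)
    assert np.all(deg[interior + n1] == 20)     # slice 2 (middle)
    assert np.all(deg[interior + 2 * n1] == 20)  # slice 3 (middle)
    assert np.all(deg[interior + 3 * n1] == 13)  # slice 4 (outer)


def test_3dsng_nonadjacent_slices_never_linked():
    slices, _ = _stacked_slices(4)
    g = sg.build_3dsng(slices)
    n1 = slices[0].n_spots
    slice_of = np.repeat(np.arange(4), n1)
    for i, j in g.edges:
        assert abs(int(slice_of[i]) - int(slice_of[j])) <= 1


def test_3dsng_within_slice_equals_per_slice_knn():
    slices, _ = _stacked_slices(3)
    g = sg.build_3dsng(slices)
    n1 = slices[0].n_spots
    per = sg.build_sng_knn(slices[1].coords, 6)
    within_mid = {(i - n1, j - n1) for i, j in g.edges
                  if n1 <= i < 2 * n1 and n1 <= j < 2 * n1}
    assert within_mid == per.edges


def test_3dsng_too_few_slices():
    slices, _ = _stacked_slices(2)
    with pytest.raises(ValueError, match="2dsng|fewer than 3"):
        sg.build_3dsng(slices)


def test_no_self_loops_stored_anywhere():
    coords = hex_coords(5, 5)
    for g in (sg.build_sng_knn(coords, 6), sg.build_sng_radius(coords, 1.1)):
        assert all(i != j for i, j in g.edges)
        src, dst = g.directed_with_self()
        assert np.sum(src == dst) == g.n  # self-loops only at aggregation
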