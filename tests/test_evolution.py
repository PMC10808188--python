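"""Core hulls, nearest-medoid reassignment, transitions and radial summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import MultiPoint, Point

from tinnpheno import (
    DataValidationError,
    assign_t1,
    convex_hull,
    core_members,
    radial_summary,
    sankey_links,
    transition_table,
)

from conftest import make_table


def _coords(points, ids=None):
    pts = np.asarray(points, dtype=float)
    if ids is None:
        ids = [f"P{i:03d}" for i in range(len(pts))]
    return pd.DataFrame(pts, index=ids, columns=["x", "y"])


class TestCoreMembers:
    def test_five_members_at_graded_distances_keep_three(self):
        coords = _coords([[0, 0], [1, 0], [2, 0], [3, 0], [4, 0]])
        core = core_members(coords, list(coords.index), "P000")
        # distances {0,1,2,3,4}: median 2 -> members at distance <= 2
        assert core == ["P000", "P001", "P002"]

    def test_all_coincident_members_all_retained(self):
        coords = _coords([[1, 1]] * 4)
        core = core_members(coords, list(coords.index), "P000")
        assert len(core) == 4

    def test_two_members_keep_only_the_medoid(self):
        coords = _coords([[0, 0], [3, 4]])
        core = core_members(coords, list(coords.index), "P000")
        # distances {0, 5}: median 2.5 -> only the medoid survives
        assert core == ["P000"]

    def test_medoid_must_be_a_member(self):
        coords = _coords([[0, 0], [1, 1]])
        with pytest.raises(DataValidationError):
            core_members(coords, ["P000"], "P001")

    def test_empty_membership_raises(self):
        coords = _coords([[0, 0]])
        with pytest.raises(DataValidationError):
            core_members(coords, [], "P000")


class TestConvexHull:
    def test_unit_square(self):
        verts, area = convex_hull([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]])
        assert area == pytest.approx(1.0)
        assert len(verts) == 4

    def test_collinear_points_degenerate(self):
        verts, area = convex_hull([[0, 0], [1, 1], [2, 2]])
        assert area == 0.0
        assert len(verts) == 2

    def test_single_point(self):
        verts, area = convex_hull([[3, 4]])
        assert area == 0.0
        assert len(verts) == 1

    def test_triangle_shoelace(self):
        _, area = convex_hull([[0, 0], [2, 0], [0, 2]])
        assert area == pytest.approx(2.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        n=st.integers(min_value=3, max_value=20),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_matches_shapely_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2))
        verts, area = convex_hull(pts)
        oracle = MultiPoint([tuple(p) for p in pts]).convex_hull
        assert area == pytest.approx(oracle.area, abs=1e-9)
        # every input point lies inside or on the polygon
        if area > 0:
            poly = oracle.buffer(1e-9)
            assert all(poly.contains(Point(p)) for p in pts)
            assert all(poly.contains(Point(v)) for v in verts)

    def test_area_invariances(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(12, 2))
        _, area = convex_hull(pts)
        _, shifted = convex_hull(pts + [100.0, -40.0])
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        _, rotated = convex_hull(pts @ rot.T)
        _, scaled = convex_hull(pts * 3.0)
        assert shifted == pytest.approx(area)
        assert rotated == pytest.approx(area)
        assert scaled == pytest.approx(9.0 * area)


class TestAssignT1:
    def _medoids(self):
        return pd.DataFrame(
            [[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]],
            index=pd.Index([1, 2], name="phenotype"),
            columns=["v00", "v01", "v02"],
        )

    def test_exact_medoid_match(self):
        table = make_table(np.array([[10.0, 0.0, 0.0]]), timepoint="t1")
        labels = assign_t1(table, self._medoids())
        assert labels.iloc[0] == 2

    def test_equidistant_tie_goes_to_lowest_cluster_index(self):
        table = make_table(np.array([[5.0, 0.0, 0.0]]), timepoint="t1")
        assert assign_t1(table, self._medoids()).iloc[0] == 1

    def test_variable_mismatch_raises(self):
        table = make_table(np.zeros((2, 4)), timepoint="t1")
        with pytest.raises(DataValidationError):
            assign_t1(table, self._medoids())

    def test_reassigning_t0_reproduces_labels_when_medoid_separated(self):
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(0, 0.3, (15, 3)), rng.normal(8, 0.3, (15, 3))])
        table = make_table(X)
        from tinnpheno import cluster_baseline

        assignment = cluster_baseline(table, seed=0)
        medoids = pd.DataFrame(
            {c: table.data.loc[m] for c, m in assignment.medoid_ids.items()}
        ).T
        medoids.index.name = "phenotype"
        relabeled = assign_t1(table.with_data(table.data, timepoint="t1"), medoids)
        assert (relabeled.to_numpy() == assignment.labels.to_numpy()).all()


class TestTransitions:
    def _labels(self, values, ids=None):
        if ids is None:
            ids = [f"P{i:03d}" for i in range(len(values))]
        return pd.Series(values, index=ids)

    def test_unchanged_labels_are_diagonal(self):
        t0 = self._labels([1, 1, 2, 2, 3])
        table = transition_table(t0, t0)
        counts = table.counts.to_numpy()
        assert np.allclose(counts, np.diag(np.diag(counts)))
        assert sankey_links(table, min_share=0.0).shape[0] == 3  # self-links only

    def test_row_sums_equal_t0_cluster_sizes(self):
        rng = np.random.default_rng(13)
        t0 = self._labels(rng.integers(1, 5, size=200))
        t1 = self._labels(rng.integers(1, 5, size=200), ids=t0.index)
        table = transition_table(t0, t1)
        expected = t0.value_counts().sort_index()
        assert (table.counts.sum(axis=1).to_numpy() == expected.to_numpy()).all()
        assert table.n == 200

    def test_small_share_link_suppressed_at_default_threshold(self):
        values = [1] * 68 + [2] * 32
        t0 = self._labels(values)
        t1_values = list(values)
        t1_values[68] = 1  # two patients move 2 -> 1 (share 0.02)
        t1_values[69] = 1
        t1 = self._labels(t1_values, ids=t0.index)
        table = transition_table(t0, t1)
        assert table.counts.at[2, 1] == 2  # counts keep the movement
        links = sankey_links(table)  # default threshold 3%
        assert not (((links["from"] == 2) & (links["to"] == 1)).any())

    def test_share_exactly_at_threshold_is_suppressed(self):
        values = [1] * 97 + [2] * 3
        t0 = self._labels(values)
        t1 = self._labels([1] * 100, ids=t0.index)
        links = sankey_links(transition_table(t0, t1), min_share=0.03)
        assert not (((links["from"] == 2) & (links["to"] == 1)).any())

    def test_misaligned_labels_raise(self):
        t0 = self._labels([1, 2])
        t1 = self._labels([1, 2], ids=["a", "b"])
        with pytest.raises(DataValidationError):
            transition_table(t0, t1)


class TestRadialSummary:
    def _tables(self, m0, m1, n=20):
        rng = np.random.default_rng(14)
        base = rng.normal(0, 0.01, size=(n, 1))
        t0 = make_table(base + m0, "t0")
        t1 = make_table(base + m1, "t1")
        return t0, t1

    def test_drop_above_quarter_flags_improved(self):
        t0, t1 = self._tables(0.4, 0.0)
        labels = pd.Series(1, index=t0.patient_ids)
        out = radial_summary(t0, t1, labels)
        assert (out["flag"] == "improved").all()

    def test_rise_above_quarter_flags_worsened(self):
        t0, t1 = self._tables(0.0, 0.4)
        labels = pd.Series(1, index=t0.patient_ids)
        out = radial_summary(t0, t1, labels)
        assert (out["flag"] == "worsened").all()

    def test_small_change_flags_none(self):
        t0, t1 = self._tables(0.0, 0.1)
        labels = pd.Series(1, index=t0.patient_ids)
        assert (radial_summary(t0, t1, labels)["flag"] == "none").all()

    def test_stable_phenotype_delta_is_negative_population_change(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(30, 2))
        t0 = make_table(X, "t0")
        # phenotype 1 unchanged; phenotype 2 improves by 1
        shift = np.where(np.arange(30)[:, None] < 15, 0.0, -1.0)
        t1 = make_table(X + shift, "t1")
        labels = pd.Series([1] * 15 + [2] * 15, index=t0.patient_ids)
        out = radial_summary(t0, t1, labels)
        pop_change = (t1.data - t0.data).mean()
        one = out[out["phenotype"] == 1].set_index("variable")
        for var in t0.variable_names:
            assert one.loc[var, "delta_vs_population"] == pytest.approx(
                0.0 - pop_change[var]
            )
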