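"""Change-vector pathways: ordering, profiles, Spearman panel, association."""

import numpy as np
import pandas as pd
import pytest

from tinnpheno import (
    DataValidationError,
    bootstrap_spearman_ci,
    chi_square_association,
    compute_deltas,
    mosaic_counts,
    order_and_label,
    pathway_profile,
    share,
    spearman_with_pathways,
)
from tinnpheno.pathways import PATHWAY_NAMES_5, PathwayAssignment

from conftest import make_table


def _delta_frame(values, ids=None):
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = [f"P{i:03d}" for i in range(len(values))]
    return pd.DataFrame(values, index=pd.Index(ids, name="patient_id"),
                        columns=[f"v{j:02d}" for j in range(values.shape[1])])


class TestComputeDeltas:
    def test_identical_tables_give_zero(self):
        rng = np.random.default_rng(0)
        t0 = make_table(rng.normal(size=(10, 3)), "t0")
        t1 = make_table(t0.data.to_numpy(), "t1")
        assert (compute_deltas(t0, t1) == 0).all().all()

    def test_sign_convention_improvement_is_negative(self):
        t0 = make_table(np.array([[0.8]]), "t0")
        t1 = make_table(np.array([[0.3]]), "t1")
        assert compute_deltas(t0, t1).iloc[0, 0] == pytest.approx(-0.5)

    def test_misaligned_patients_raise(self):
        t0 = make_table(np.zeros((3, 2)), "t0")
        t1 = make_table(np.zeros((3, 2)), "t1", ids=["a", "b", "c"])
        with pytest.raises(DataValidationError):
            compute_deltas(t0, t1)


class TestOrderAndLabel:
    def _graded(self, means, per=6):
        rng = np.random.default_rng(1)
        blocks, raw = [], []
        for i, m in enumerate(means):
            blocks.append(rng.normal(m, 0.01, size=(per, 4)))
            raw += [i] * per
        return _delta_frame(np.vstack(blocks)), np.array(raw)

    def test_canonical_names_in_deterioration_order(self):
        deltas, raw = self._graded([+0.8, +0.2, -0.1, -0.4, -0.9])
        out = order_and_label(raw, deltas)
        assert out.m == 5
        assert [out.label_names[i] for i in range(1, 6)] == list(PATHWAY_NAMES_5)
        # cluster generated around +0.8 must be pathway 1, around -0.9 pathway 5
        assert (out.labels.iloc[:6] == 1).all()
        assert (out.labels.iloc[-6:] == 5).all()
        assert (out.order_stat.diff().dropna() < 0).all()

    def test_ordering_invariant_to_cluster_index_permutation(self):
        deltas, raw = self._graded([+0.5, 0.0, -0.5])
        perm = np.array([2, 0, 1])  # relabel raw clusters arbitrarily
        out_a = order_and_label(raw, deltas)
        out_b = order_and_label(perm[raw], deltas)
        pd.testing.assert_series_equal(out_a.labels, out_b.labels)

    def test_non_five_cluster_fallback_names(self):
        deltas, raw = self._graded([+0.5, 0.0, -0.5])
        out = order_and_label(raw, deltas)
        assert out.label_names == {1: "pathway 1/3", 2: "pathway 2/3", 3: "pathway 3/3"}

    def test_tie_keeps_original_cluster_order(self):
        deltas = _delta_frame(np.zeros((8, 3)))
        raw = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        out = order_and_label(raw, deltas)
        assert (out.labels.to_numpy() == raw + 1).all()


class TestPathwayProfile:
    def test_single_pathway_profile_is_population_mean(self):
        deltas = _delta_frame(np.random.default_rng(2).normal(size=(12, 4)))
        assignment = order_and_label(np.zeros(12, dtype=int), deltas)
        prof = pathway_profile(deltas, assignment)
        assert np.allclose(prof.loc[1], deltas.mean(), atol=1e-12)

    def test_size_weighted_profile_mean_is_population_mean(self):
        rng = np.random.default_rng(3)
        deltas = _delta_frame(rng.normal(size=(40, 5)))
        raw = rng.integers(0, 3, size=40)
        assignment = order_and_label(raw, deltas)
        prof = pathway_profile(deltas, assignment)
        weights = assignment.sizes / assignment.sizes.sum()
        assert np.allclose((prof.T @ weights), deltas.mean(), atol=1e-9)


class TestSpearmanPanel:
    def _assignment(self, labels, ids):
        labels = pd.Series(labels, index=ids, name="pathway")
        m = int(labels.max())
        stat = pd.Series(np.linspace(1, -1, m), index=range(1, m + 1))
        return PathwayAssignment(labels, stat, {i: f"pathway {i}/{m}" for i in range(1, m + 1)}, m)

    def test_feature_equal_to_indicator_has_r_one(self):
        rng = np.random.default_rng(4)
        labels = np.array([1] * 10 + [2] * 10)
        indicator = (labels == 1).astype(float)
        X = np.column_stack([indicator, rng.normal(size=20)])
        table = make_table(X)
        assignment = self._assignment(labels, table.patient_ids)
        panel = spearman_with_pathways(table, assignment, n_boot=50, seed=0)
        r = panel[(panel["variable"] == "v00") & (panel["pathway"] == 1)]["r"].iloc[0]
        assert r == pytest.approx(1.0)

    def test_same_seed_gives_identical_cis(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(1, 4, size=60)
        table = make_table(rng.normal(size=(60, 3)))
        assignment = self._assignment(labels, table.patient_ids)
        a = spearman_with_pathways(table, assignment, n_boot=200, seed=9)
        b = spearman_with_pathways(table, assignment, n_boot=200, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_independent_feature_ci_covers_zero(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(1, 3, size=2000)
        table = make_table(rng.normal(size=(2000, 1)))
        assignment = self._assignment(labels, table.patient_ids)
        panel = spearman_with_pathways(table, assignment, n_boot=400, seed=0)
        row = panel[(panel["variable"] == "v00") & (panel["pathway"] == 1)].iloc[0]
        assert row["ci_lo"] < 0 < row["ci_hi"]

    def test_tiny_pathway_reports_missing_ci(self):
        rng = np.random.default_rng(7)
        labels = np.array([1] * 18 + [2] * 2)
        table = make_table(rng.normal(size=(20, 2)))
        assignment = self._assignment(labels, table.patient_ids)
        panel = spearman_with_pathways(table, assignment, n_boot=50, seed=0)
        small = panel[panel["pathway"] == 2]
        assert small["ci_lo"].isna().all() and small["ci_hi"].isna().all()
        big = panel[panel["pathway"] == 1]
        assert big["ci_lo"].notna().all()

    def test_bootstrap_ci_helper_brackets_estimate(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=150)
        y = 0.6 * x + rng.normal(size=150)
        est, lo, hi = bootstrap_spearman_ci(x, y, n_boot=500, seed=1)
        assert lo <= est <= hi
        assert lo > 0  # clearly positive dependence


def _labels_from_table(counts: np.ndarray):
    """Expand a contingency table into aligned label vectors."""
    phenos, paths = [], []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            phenos += [i + 1] * counts[i, j]
            paths += [j + 1] * counts[i, j]
    ids = [f"P{i:05d}" for i in range(len(phenos))]
    return (pd.Series(phenos, index=ids), pd.Series(paths, index=ids))


class TestChiSquare:
    def test_closed_form_two_by_two(self):
        pheno, path = _labels_from_table(np.array([[10, 20], [20, 10]]))
        report = chi_square_association(pheno, path)
        assert report.chi2 == pytest.approx(20 / 3)
        assert report.df == 1

    def test_proportional_rows_give_zero(self):
        pheno, path = _labels_from_table(np.array([[10, 20], [20, 40]]))
        report = chi_square_association(pheno, path)
        assert report.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_four_by_five_has_df_twelve(self):
        rng = np.random.default_rng(9)
        pheno, path = _labels_from_table(rng.integers(1, 20, size=(4, 5)))
        assert chi_square_association(pheno, path).df == 12

    def test_matches_expected_count_oracle_on_random_tables(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            r = int(rng.integers(2, 7))
            c = int(rng.integers(2, 7))
            counts = rng.integers(1, 30, size=(r, c))
            pheno, path = _labels_from_table(counts)
            report = chi_square_association(pheno, path)
            # independent oracle: explicit expected-count double loop
            total = counts.sum()
            chi2 = 0.0
            for i in range(r):
                for j in range(c):
                    expected = counts[i].sum() * counts[:, j].sum() / total
                    chi2 += (counts[i, j] - expected) ** 2 / expected
            assert report.chi2 == pytest.approx(chi2)
            assert report.df == (r - 1) * (c - 1)


class TestShares:
    @pytest.mark.parametrize(
        "count,total,expected",
        [
            (697, 1228, 56.8),
            (173, 1228, 14.1),
            (187, 1228, 15.2),
            (171, 1228, 13.9),
            (45, 989, 4.6),
            (217, 989, 21.9),
            (341, 989, 34.5),
            (289, 989, 29.2),
            (97, 989, 9.8),
            (0, 10, 0.0),
        ],
    )
    def test_printed_subgroup_shares(self, count, total, expected):
        assert share(count, total) == expected

    def test_half_rounds_away_from_zero(self):
        assert share(45, 1000) == 4.5
        assert share(1, 16) == 6.3  # 6.25 -> 6.3 (banker's rounding would give 6.2)

    def test_zero_total_is_an_error(self):
        with pytest.raises(DataValidationError):
            share(1, 0)

    def test_mosaic_percentages_sum_to_hundred_within_rounding(self):
        rng = np.random.default_rng(11)
        pheno, path = _labels_from_table(rng.integers(1, 40, size=(4, 5)))
        counts, pct = mosaic_counts(pheno, path)
        assert (counts.to_numpy().sum()) == len(pheno)
        for _, row in pct.iterrows():
            assert abs(row.sum() - 100.0) <= 0.3
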