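import itertools
import math

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from scipy import stats

from fibermeta import (
    SampleMetadata, bray_curtis, averaged_bray_curtis, permanova_sequential,
    permdisp,
)
from fibermeta.io import ValidationError


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        X = np.array([[3, 3], [1, 1], [4, 4]])
        assert bray_curtis(X).data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_one(self):
        X = np.array([[3, 0], [0, 5]])
        assert bray_curtis(X).data[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_example(self):
        X = np.array([[1, 1], [0, 2], [3, 0]])
        assert bray_curtis(X).data[0, 1] == pytest.approx(5 / 7, abs=1e-9)

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(np.array([[1, 0], [2, 0]]))


class TestAveragedBrayCurtis:
    def test_even_table_equals_single_shot(self, tiny_table):
        # all columns share one total: rarefaction at that depth is identity
        counts = np.array([[5, 3, 2], [1, 4, 5], [4, 3, 3]])
        from fibermeta import CountTable
        t = CountTable(("a", "b", "c"), ("x", "y", "z"), counts)
        dm = averaged_bray_curtis(t, 10, n_iter=5, seed=0)
        direct = bray_curtis(np.sqrt(counts), t.sample_ids)
        assert np.allclose(dm.data, direct.data, atol=1e-12)

    def test_two_iterations_are_the_mean(self, small_study):
        table, _, _, _ = small_study
        depth = int(table.sample_totals().min())
        both = averaged_bray_curtis(table, depth, n_iter=2, seed=9)
        # replaying the same seeded stream reproduces the two draws
        rng = np.random.default_rng(9)
        from fibermeta import rarefy
        parts = []
        for _ in range(2):
            rt = rarefy(table, depth, rng)
            parts.append(bray_curtis(np.sqrt(rt.counts), rt.sample_ids).data)
        assert np.allclose(both.data, (parts[0] + parts[1]) / 2, atol=1e-12)

    def test_iteration_noise_shrinks(self, small_study):
        table, _, _, _ = small_study
        depth = int(table.sample_totals().min() * 0.5)
        def spread(n_iter, seeds):
            ms = [averaged_bray_curtis(table, depth, n_iter, seed=s).data
                  for s in seeds]
            return np.var(np.stack(ms), axis=0).mean()
        v1 = spread(1, range(8))
        v16 = spread(16, range(8))
        assert v16 < v1 / 4  # expect roughly 1/16


def _brute_force_one_way_permanova_p(dist, labels):
    """Independent oracle via the within/between sums-of-squares identity,
    enumerated over all relabelings."""
    n = len(labels)

    def f_stat(lbl):
        ss_total = (dist ** 2)[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        groups = set(lbl)
        for g in groups:
            idx = np.flatnonzero(np.asarray(lbl) == g)
            sub = dist[np.ix_(idx, idx)]
            ss_within += (sub ** 2)[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_between = ss_total - ss_within
        df_b, df_w = len(groups) - 1, n - len(groups)
        return (ss_between / df_b) / (ss_within / df_w)

    f_obs = f_stat(labels)
    count = exceed = 0
    for perm in itertools.permutations(range(n)):
        lbl = [labels[i] for i in perm]
        if f_stat(lbl) >= f_obs - 1e-12:
            exceed += 1
        count += 1
    return f_obs, exceed / count


def _one_factor_meta(labels, ids):
    rows = [
        {"sample_id": s, "subject_id": g, "study_id": "st",
         "timepoint": "before" if g == "A" else "after", "order": i}
        for i, (s, g) in enumerate(zip(ids, labels))
    ]
    return SampleMetadata(pd.DataFrame(rows))


class TestPermanova:
    def test_exhaustive_p_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 2))
        X[:3] += 1.5
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(6)]
        labels = ["A", "A", "A", "B", "B", "B"]
        dm = DistanceMatrix(d, ids=ids)
        meta = _one_factor_meta(labels, ids)
        res = permanova_sequential(dm, meta, terms=("timepoint",),
                                   n_perm="exact")
        f_oracle, p_oracle = _brute_force_one_way_permanova_p(d, labels)
        assert res.term("timepoint").pseudo_f == pytest.approx(f_oracle, rel=1e-9)
        assert res.term("timepoint").p == pytest.approx(p_oracle, abs=1e-12)

    def test_r2_partition_sums_to_one(self, small_study):
        table, meta, _, _ = small_study
        depth = int(table.sample_totals().min())
        dm = averaged_bray_curtis(table, depth, n_iter=3, seed=0)
        res = permanova_sequential(dm, meta.subset(dm.ids), n_perm=19, seed=0)
        total_r2 = sum(t.r2 for t in res.terms) + res.residual.r2
        assert total_r2 == pytest.approx(1.0, abs=1e-10)
        assert sum(t.df for t in res.terms) + res.residual.df == res.total.df

    def test_coincident_group_centroids_give_zero_ss(self):
        # both groups have mean 0 in the Euclidean embedding, so the group
        # term explains exactly nothing
        x = np.array([-1.0, 1.0, -2.0, 2.0, -3.0, 3.0])
        d = np.abs(x[:, None] - x[None, :])
        ids = [f"s{i}" for i in range(6)]
        meta = _one_factor_meta(["A", "A", "B", "B", "B", "B"], ids)
        res = permanova_sequential(DistanceMatrix(d, ids=ids), meta,
                                   terms=("timepoint",), n_perm=9, seed=0)
        assert res.term("timepoint").r2 == pytest.approx(0.0, abs=1e-10)

    def test_euclidean_one_factor_equals_classical_anova(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0, 1, 5), rng.normal(2, 1, 7)])
        labels = ["A"] * 5 + ["B"] * 7
        ids = [f"s{i}" for i in range(12)]
        d = np.abs(x[:, None] - x[None, :])
        res = permanova_sequential(
            DistanceMatrix(d, ids=ids), _one_factor_meta(labels, ids),
            terms=("timepoint",), n_perm=9, seed=0,
        )
        f_classic = stats.f_oneway(x[:5], x[5:]).statistic
        assert res.term("timepoint").pseudo_f == pytest.approx(f_classic, abs=1e-8)

    def test_matches_skbio_single_factor(self):
        """Cross-check pseudo-F against the independent scikit-bio PERMANOVA."""
        from skbio.stats.distance import permanova as skbio_permanova
        rng = np.random.default_rng(21)
        X = rng.normal(size=(10, 3))
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(10)]
        labels = ["A"] * 5 + ["B"] * 5
        dm = DistanceMatrix(d, ids=ids)
        ours = permanova_sequential(dm, _one_factor_meta(labels, ids),
                                    terms=("timepoint",), n_perm=9, seed=0)
        theirs = skbio_permanova(dm, grouping=labels, permutations=9)
        assert ours.term("timepoint").pseudo_f == pytest.approx(
            theirs["test statistic"], rel=1e-9
        )

    def test_single_level_term_errors(self):
        ids = ["a", "b", "c", "d"]
        d = np.ones((4, 4)) - np.eye(4)
        meta = _one_factor_meta(["A", "A", "A", "A"], ids)
        with pytest.raises(ValidationError, match="single level"):
            permanova_sequential(DistanceMatrix(d, ids=ids), meta,
                                 terms=("timepoint",), n_perm=9)


class TestPermdisp:
    def test_zero_dispersion_group(self):
        # group A: mutually identical points; group B: spread out
        d = np.array([
            [0, 0, 1, 1],
            [0, 0, 1, 1],
            [1, 1, 0, 0.8],
            [1, 1, 0.8, 0],
        ])
        dm = DistanceMatrix(d, ids=list("abcd"))
        res = permdisp(dm, {"a": "A", "b": "A", "c": "B", "d": "B"},
                       n_perm=19, seed=0)
        assert res.group_means["A"] == pytest.approx(0.0, abs=1e-10)
        assert res.group_means["B"] > 0

    def test_group_exchange_symmetric_f(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 2))
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(8)])
        g1 = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        g2 = {f"s{i}": ("B" if i < 4 else "A") for i in range(8)}
        f1 = permdisp(dm, g1, n_perm=9, seed=0).f
        f2 = permdisp(dm, g2, n_perm=9, seed=0).f
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_points_on_a_line_match_direct_geometry(self):
        x = np.array([0.0, 1.0, 4.0, 9.0])
        d = np.abs(x[:, None] - x[None, :])
        dm = DistanceMatrix(d, ids=list("abcd"))
        res = permdisp(dm, {"a": "A", "b": "A", "c": "B", "d": "B"},
                       n_perm=19, seed=0)
        # centroids at 0.5 and 6.5; all four distances-to-centroid direct
        assert res.group_means["A"] == pytest.approx(0.5, abs=1e-8)
        assert res.group_means["B"] == pytest.approx(2.5, abs=1e-8)

    def test_singleton_group_errors(self):
        d = np.ones((3, 3)) - np.eye(3)
        dm = DistanceMatrix(d, ids=list("abc"))
        with pytest.raises(ValidationError, match="fewer than 2"):
            permdisp(dm, {"a": "A", "b": "B", "c": "B"}, n_perm=9)
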