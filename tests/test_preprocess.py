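"""Control subtraction, batch adjustment, PCA, variance ranking, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from toxclass.datatypes import (
    CLASS_A,
    CONTROL,
    ContrastMatrix,
    ExpressionMatrix,
    PairingError,
    SampleMetadata,
    ValidationError,
)
from toxclass.preprocess import (
    combat_adjust,
    hierarchical_cluster,
    pca,
    subtract_controls,
    top_variance_features,
)
from toxclass.simulate import CompoundSpec, SyntheticConfig, generate_dataset


class TestSubtractControls:
    def test_identical_treated_and_control_gives_zero(self, tiny_paired):
        expr, meta = tiny_paired
        con = subtract_controls(expr, meta)
        # t2 is an exact copy of its single control c3
        assert np.allclose(con.data["t2"], 0.0)

    def test_two_controls_are_averaged(self, tiny_paired):
        expr, meta = tiny_paired
        con = subtract_controls(expr, meta)
        # P1: treated 6.0, controls 3.0 and 5.0 -> 6 - 4 = 2
        assert con.data.loc["P1", "t1"] == pytest.approx(2.0)

    def test_controls_dropped_and_order_preserved(self, tiny_paired):
        expr, meta = tiny_paired
        con = subtract_controls(expr, meta)
        assert con.sample_ids == ["t1", "t2"]
        assert con.probe_ids == expr.probe_ids

    def test_matches_per_cell_loop_oracle(self, mini_dataset):
        expr, meta, *_ = mini_dataset
        con = subtract_controls(expr, meta)
        rng = np.random.default_rng(0)
        probes = rng.choice(expr.probe_ids, size=20, replace=False)
        for sid in meta.treated_ids[:6]:
            ctrls = meta.controls_of(sid)
            for p in probes:
                expected = expr.data.loc[p, sid] - np.mean(
                    [expr.data.loc[p, c] for c in ctrls]
                )
                assert con.data.loc[p, sid] == pytest.approx(expected)

    def test_linear_in_constant_control_shift(self, tiny_paired):
        """Adding a per-probe constant to every sample leaves contrasts fixed."""
        expr, meta = tiny_paired
        shift = pd.Series([1.5, -2.0, 0.25], index=expr.probe_ids)
        shifted = ExpressionMatrix(expr.data.add(shift, axis=0))
        a = subtract_controls(expr, meta)
        b = subtract_controls(shifted, meta)
        assert np.allclose(a.values, b.values)

    def test_unpaired_sample_raises(self, tiny_paired):
        expr, meta = tiny_paired
        with pytest.raises(ValidationError):
            subtract_controls(expr.subset_samples(["t1", "c1"]), meta)


def _batched_dataset(shift=0.0, seed=0, n_probes=400, residual_sd=0.4):
    comps = tuple(CompoundSpec(f"a{i}", CLASS_A, 4, 0, 0.0) for i in range(2)) + tuple(
        CompoundSpec(f"b{i}", "CLASS_B", 4, 0, 0.0) for i in range(2)
    )
    cfg = SyntheticConfig(
        n_probesets=n_probes,
        n_genes=300,
        compounds=comps,
        n_controls=16,
        n_shared_per_class=0,
        batch_location_sd=0.0,
        batch_scale_range=(1.0, 1.0),
        residual_sd=residual_sd,
        seed=seed,
    )
    expr, meta, *_ = generate_dataset(cfg)
    if shift:
        b2 = [s for s in expr.sample_ids if meta.batch_ids[s] == "B2"]
        data = expr.data.copy()
        data[b2] += shift
        expr = ExpressionMatrix(data)
    return expr, meta


class TestCombatAdjust:
    def test_no_batch_effect_leaves_data_nearly_unchanged(self):
        expr, meta = _batched_dataset(shift=0.0, seed=1)
        adj, model = combat_adjust(expr, meta)
        assert np.abs(adj.values - expr.values).mean() < 0.05

    def test_additive_shift_removed(self):
        # low replicate noise so the residual batch-mean gap reflects the
        # correction, not sampling error of the 16-sample batch means
        expr, meta = _batched_dataset(shift=1.0, seed=2, residual_sd=0.15)
        adj, model = combat_adjust(expr, meta)
        batch = meta.batch_ids
        b1 = [s for s in expr.sample_ids if batch[s] == "B1"]
        b2 = [s for s in expr.sample_ids if batch[s] == "B2"]
        gap = (adj.data[b2].mean(axis=1) - adj.data[b1].mean(axis=1)).abs().mean()
        assert gap < 0.05

    def test_unshrunken_equals_direct_standardization_oracle(self):
        expr, meta = _batched_dataset(shift=0.7, seed=3, n_probes=60)
        adj, model = combat_adjust(expr, meta, parametric=False, covariate_treatment=False)
        # oracle: per probe, standardize by grand mean / pooled sd, then
        # remove each batch's observed location and scale on that scale
        batch = meta.batch_ids
        batches = ["B1", "B2"]
        Y = expr.data
        n = Y.shape[1]
        for p in expr.probe_ids[:30]:
            y = Y.loc[p]
            b_means = {b: y[[s for s in Y.columns if batch[s] == b]].mean() for b in batches}
            n_b = {b: sum(batch[s] == b for s in Y.columns) for b in batches}
            grand = sum(b_means[b] * n_b[b] for b in batches) / n
            resid = np.array([y[s] - b_means[batch[s]] for s in Y.columns])
            pooled_sd = np.sqrt((resid**2).sum() / n)
            for s in Y.columns:
                z = (y[s] - grand) / pooled_sd
                zb = [(y[t] - grand) / pooled_sd for t in Y.columns if batch[t] == batch[s]]
                g = np.mean(zb)
                d = np.var(zb, ddof=1)
                expected = (z - g) / np.sqrt(d) * pooled_sd + grand
                assert adj.data.loc[p, s] == pytest.approx(expected, abs=1e-8)

    def test_grand_mean_preserved_and_batch_variance_not_increased(self):
        expr, meta = _batched_dataset(shift=1.0, seed=4)
        adj, _ = combat_adjust(expr, meta)
        assert np.abs(adj.data.mean(axis=1) - expr.data.mean(axis=1)).mean() < 0.05
        batch = meta.batch_ids
        b1 = [s for s in expr.sample_ids if batch[s] == "B1"]
        b2 = [s for s in expr.sample_ids if batch[s] == "B2"]

        def between_batch_var(m):
            return ((m[b1].mean(axis=1) - m[b2].mean(axis=1)) ** 2).mean()

        assert between_batch_var(adj.data) <= between_batch_var(expr.data)

    def test_single_sample_batch_rejected(self, tiny_paired):
        expr, meta = tiny_paired  # batch B2 holds only samples c3/t2
        table = meta.table.copy()
        table.loc[table["sample_id"] == "t2", "batch_id"] = "B1"
        with pytest.raises(ValidationError):
            combat_adjust(expr, SampleMetadata(table))


class TestPCA:
    def _two_cluster_matrix(self):
        rng = np.random.default_rng(8)
        left = rng.normal(0, 0.1, size=(30, 5))
        right = rng.normal(0, 0.1, size=(30, 5))
        left[0] -= 4
        right[0] += 4
        data = np.hstack([left, right])
        return ExpressionMatrix(
            pd.DataFrame(
                data,
                index=[f"P{i}" for i in range(30)],
                columns=[f"s{j}" for j in range(10)],
            )
        )

    def test_pc1_separates_planted_clusters(self):
        res = pca(self._two_cluster_matrix(), n_components=2)
        signs = np.sign(res.scores["PC1"].to_numpy())
        assert len(set(signs[:5])) == 1 and len(set(signs[5:])) == 1
        assert signs[0] != signs[5]
        assert res.explained_variance_ratio[0] > res.explained_variance_ratio[1]

    def test_full_rank_scores_preserve_pairwise_distances(self):
        m = self._two_cluster_matrix()
        res = pca(m, n_components=9)
        X = m.values.T
        Xc = X - X.mean(axis=0)
        S = res.scores.to_numpy()
        for i, j in [(0, 1), (2, 7), (4, 9)]:
            assert np.linalg.norm(S[i] - S[j]) == pytest.approx(
                np.linalg.norm(Xc[i] - Xc[j]), rel=1e-9
            )

    def test_explained_variance_matches_eigendecomposition_oracle(self):
        m = self._two_cluster_matrix()
        res = pca(m, n_components=5)
        X = m.values.T
        Xc = X - X.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        expected = eigvals[:5] / eigvals[eigvals > -1].sum()
        assert np.allclose(res.explained_variance_ratio, expected[:5], atol=1e-12)

    def test_scores_covariance_is_diagonal(self):
        res = pca(self._two_cluster_matrix(), n_components=4)
        S = res.scores.to_numpy()
        cov = (S - S.mean(0)).T @ (S - S.mean(0))
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_too_many_components_rejected(self):
        with pytest.raises(ValidationError):
            pca(self._two_cluster_matrix(), n_components=11)


class TestTopVariance:
    def test_constant_probe_ranked_last(self):
        df = pd.DataFrame(
            {"s1": [1.0, 5.0, 2.0], "s2": [1.0, -5.0, 4.0]},
            index=["flat", "wild", "mid"],
        )
        ranked = top_variance_features(ContrastMatrix(df), 3)
        assert list(ranked.index) == ["wild", "mid", "flat"]
        assert ranked["flat"] == 0.0

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(17)
        df = pd.DataFrame(
            rng.normal(size=(50, 8)),
            index=[f"P{i:02d}" for i in range(50)],
            columns=[f"s{j}" for j in range(8)],
        )
        ranked = top_variance_features(ContrastMatrix(df), 50)
        oracle = sorted(df.index, key=lambda p: (-df.loc[p].var(ddof=1), p))
        assert list(ranked.index) == oracle

    def test_ties_broken_lexicographically(self):
        df = pd.DataFrame(
            {"s1": [0.0, 0.0, 1.0], "s2": [2.0, 2.0, 3.0]},
            index=["zz", "aa", "mm"],
        )
        ranked = top_variance_features(ContrastMatrix(df), 3)
        assert list(ranked.index) == ["aa", "mm", "zz"]

    def test_n_larger_than_probes_rejected(self):
        df = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["P1"])
        with pytest.raises(ValidationError):
            top_variance_features(ContrastMatrix(df), 2)


def _brute_force_agglomerate(points, method):
    """Naive agglomeration oracle over sample points; returns merge heights
    and leaf partitions at each step."""
    clusters = {i: [i] for i in range(len(points))}
    merges = []
    next_id = len(points)
    dist = lambda a, b: np.linalg.norm(points[a] - points[b])
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            ds = [dist(a, b) for a in clusters[i] for b in clusters[j]]
            d = max(ds) if method == "complete" else np.mean(ds)
            if best is None or d < best[0] - 1e-12:
                best = (d, i, j)
        d, i, j = best
        merges.append((frozenset(clusters[i]), frozenset(clusters[j]), d))
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return merges


class TestHierarchicalCluster:
    def _matrix(self, points):
        arr = np.asarray(points, dtype=float).T
        return ContrastMatrix(
            pd.DataFrame(
                arr,
                index=[f"P{i}" for i in range(arr.shape[0])],
                columns=[f"s{j}" for j in range(arr.shape[1])],
            )
        )

    def test_coincident_pair_merges_first_at_zero(self):
        m = self._matrix([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        dend = hierarchical_cluster(m)
        a, b, h, size = dend.merges[0]
        assert {a, b} == {0, 1} and h == 0.0 and size == 2

    @pytest.mark.parametrize("method", ["complete", "average"])
    def test_merge_sequence_matches_brute_force_oracle(self, method):
        rng = np.random.default_rng(23)
        points = rng.normal(size=(4, 3))
        m = self._matrix(points)
        dend = hierarchical_cluster(m, method=method)
        oracle = _brute_force_agglomerate(points, method)
        # compare leaf partitions and heights in merge order
        groups = {i: frozenset([i]) for i in range(4)}
        for k, (a, b, h, size) in enumerate(dend.merges):
            left, right = groups[a], groups[b]
            groups[4 + k] = left | right
            oa, ob, oh = oracle[k]
            assert {left, right} == {oa, ob}
            assert h == pytest.approx(oh)

    def test_planted_groups_split_at_top(self, mini_contrasts):
        con, meta = mini_contrasts
        top = con.subset_probes(list(top_variance_features(con, 50).index))
        dend = hierarchical_cluster(top)
        labels = dend.cut(2)
        classes = {s: meta.class_of(meta.table.set_index("sample_id").loc[s, "compound"]) for s in top.sample_ids}
        # the two top-level clusters should be strongly class-enriched
        import collections

        purity = 0
        for cid in set(labels.values()):
            members = [s for s, c in labels.items() if c == cid]
            counts = collections.Counter(classes[s] for s in members)
            purity += counts.most_common(1)[0][1]
        assert purity / len(labels) >= 0.9

    def test_nan_rejected(self):
        df = pd.DataFrame({"s1": [np.nan], "s2": [1.0]}, index=["P1"])
        con = ContrastMatrix.__new__(ContrastMatrix)
        con.data = df  # bypass constructor to test the clustering guard
        with pytest.raises(ValidationError):
            hierarchical_cluster(con)
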