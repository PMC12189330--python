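"""Canonical discriminant analysis: screen, fit, tests, LOOCV, distances."""

import numpy as np
import pandas as pd
import pytest

from pedloop.cda import (
    CDAError,
    alpha_from_coancestry,
    assemble_ancestor_features,
    collinearity_screen,
    discriminant_significance_tests,
    distance_dendrogram,
    eigenvalues_from_shares,
    fit_canonical_discriminant,
    loocv_classification,
    mahalanobis_centroid_distances,
    pillai_trace,
    resubstitution_hit_ratio,
    stepwise_variable_selection,
    univariate_equality_tests,
    variance_inflation_factors,
    wilks_lambda,
)


def _gaussian_groups(rng, means, n_per_group, p=2, sd=1.0, labels=None):
    X, y = [], []
    labels = labels or [f"g{i}" for i in range(len(means))]
    for lab, mu in zip(labels, means):
        X.append(rng.normal(mu, sd, size=(n_per_group, p)))
        y += [lab] * n_per_group
    return (
        pd.DataFrame(np.concatenate(X), columns=[f"v{j}" for j in range(p)]),
        np.array(y),
    )


class TestAlphaIdentity:
    def test_printed_extremes(self):
        assert alpha_from_coancestry(0.022355) == pytest.approx(-0.022867, abs=1e-6)
        assert alpha_from_coancestry(0.000058) == pytest.approx(-0.000058, abs=1e-6)

    def test_zero_maps_to_zero(self):
        assert alpha_from_coancestry(0.0) == 0.0


class TestFeatureAssembly:
    def test_identities_and_filtering(self, fixtures):
        from pedloop.decompose import founder_contributions, nca_contributions_group
        from pedloop.relationship import compute_inbreeding

        ped = fixtures["chain"]
        F = compute_inbreeding(ped)
        # mean-F target over {X}: loops close only at M, founders A and B
        uf = nca_contributions_group(ped, ["X"], target="mean_F", F=F)
        vf = founder_contributions(ped, uf)
        table = assemble_ancestor_features(ped, uf, vf, vf)
        # scale identity and per-row alpha identity hold on every row
        np.testing.assert_allclose(
            table["loop_contribution"], 2.0 * table["coancestry_C"], atol=1e-12
        )
        np.testing.assert_allclose(
            table["alpha"],
            1.0 - 1.0 / (1.0 - table["coancestry_C"]),
            atol=1e-12,
        )
        # zero-everywhere ancestors are absent (C and E never contribute)
        assert "C" not in table.index and "E" not in table.index


class TestCollinearityScreen:
    def test_identical_columns_infinite_vif_one_removed(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50)})
        df["b"] = df["a"]
        df["c"] = rng.normal(size=50)
        vifs = variance_inflation_factors(df)
        assert np.isinf(vifs["a"]) and np.isinf(vifs["b"])
        reduced, report = collinearity_screen(df)
        assert list(reduced.columns) == ["a", "c"]  # first of the pair survives
        assert any(r["column"] == "b" and r["action"] == "removed" for r in report)

    def test_independent_columns_untouched(self, rng):
        df = pd.DataFrame(rng.normal(size=(1000, 4)), columns=list("abcd"))
        vifs = variance_inflation_factors(df)
        assert (vifs < 1.2).all()
        reduced, _ = collinearity_screen(df)
        assert list(reduced.columns) == list("abcd")

    def test_invariant_feature_table_is_reduced_to_nonredundant_pair(self, rng):
        # a table honoring the built-in identities: loop = 2C and
        # alpha = 1 - 1/(1-C) make {loop, C, alpha} mutually redundant
        c = np.abs(rng.normal(0.005, 0.004, size=200))
        df = pd.DataFrame(
            {
                "loop_contribution": 2 * c,
                "founder_to_meanF": np.abs(rng.normal(0.001, 0.001, 200)),
                "founder_to_meanC": np.abs(rng.normal(0.0005, 0.0005, 200)),
                "coancestry_C": c,
                "alpha": 1.0 - 1.0 / (1.0 - c),
            }
        )
        reduced, report = collinearity_screen(df, threshold=5.0)
        kept = set(reduced.columns)
        # at most one survivor of the exactly/near-exactly dependent trio
        assert len(kept & {"loop_contribution", "coancestry_C", "alpha"}) <= 1
        final_vifs = variance_inflation_factors(reduced)
        assert (final_vifs <= 5.0).all() or len(kept) == 2

    def test_single_column_errors(self, rng):
        with pytest.raises(CDAError):
            collinearity_screen(pd.DataFrame({"a": rng.normal(size=10)}))


class TestStepwiseSelection:
    def test_planted_signal_selected_first(self, rng):
        n = 150
        y = np.array(["a"] * 75 + ["b"] * 75)
        df = pd.DataFrame(
            {
                "noise1": rng.normal(size=n),
                "signal": np.where(y == "a", 0.0, 3.0) + rng.normal(size=n),
                "noise2": rng.normal(size=n),
            }
        )
        selected, trace = stepwise_variable_selection(df, y)
        assert selected and trace[1]["added"] == "signal"

    def test_pure_noise_rarely_selects(self, rng):
        import warnings

        picks = 0
        for _ in range(30):
            n = 80
            y = np.array(["a"] * 40 + ["b"] * 40)
            df = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("uvw"))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                selected, _ = stepwise_variable_selection(df, y)
            picks += len(selected) > 0
        assert picks <= 6  # BIC keeps the spurious-selection rate low

    def test_collinear_partner_not_added(self, rng):
        n = 120
        y = np.array(["a"] * 60 + ["b"] * 60)
        signal = np.where(y == "a", 0.0, 4.0) + rng.normal(size=n)
        df = pd.DataFrame({"s1": signal, "s2": signal * 2.0})
        selected, _ = stepwise_variable_selection(df, y)
        assert selected == ["s1"]


class TestFitCanonicalDiscriminant:
    def test_one_variable_closed_form(self, rng):
        X, y = _gaussian_groups(rng, [0.0, 2.0], 40, p=1)
        model = fit_canonical_discriminant(X, y)
        x = X.to_numpy().ravel()
        grand = x.mean()
        ssb = sum(
            (x[y == lab].mean() - grand) ** 2 * (y == lab).sum()
            for lab in np.unique(y)
        )
        ssw = sum(
            ((x[y == lab] - x[y == lab].mean()) ** 2).sum() for lab in np.unique(y)
        )
        assert len(model.eigenvalues) == 1
        assert model.eigenvalues[0] == pytest.approx(ssb / ssw, rel=1e-10)

    def test_label_permutation_collapses_leading_eigenvalue(self, rng):
        X, y = _gaussian_groups(rng, [0.0, 5.0], 100, p=2)
        lam_sep = fit_canonical_discriminant(X, y).eigenvalues[0]
        lam_perm = fit_canonical_discriminant(X, rng.permutation(y)).eigenvalues[0]
        assert lam_perm < 0.1 * lam_sep

    def test_eigen_identities(self, rng):
        X, y = _gaussian_groups(rng, [0.0, 1.0, 2.5], 50, p=3)
        model = fit_canonical_discriminant(X, y)
        lam = model.eigenvalues
        assert wilks_lambda(lam) * np.prod(1.0 + lam) == pytest.approx(1.0, abs=1e-12)
        assert model.percent_discrimination.sum() == pytest.approx(100.0)
        np.testing.assert_allclose(
            model.canonical_correlations, np.sqrt(lam / (1 + lam)), atol=1e-12
        )
        assert len(lam) == min(3, 3 - 1)

    def test_small_group_errors(self, rng):
        X = pd.DataFrame({"v": rng.normal(size=3)})
        with pytest.raises(CDAError, match="two rows"):
            fit_canonical_discriminant(X, np.array(["a", "a", "b"]))

    def test_matches_statsmodels_manova(self, rng):
        sm_manova = pytest.importorskip("statsmodels.multivariate.manova")
        X, y = _gaussian_groups(rng, [0.0, 0.5, 1.5], 60, p=3)
        model = fit_canonical_discriminant(X, y)
        tests = discriminant_significance_tests(
            model.eigenvalues, n=model.n, p=model.p, g=model.g
        )
        df = X.copy()
        df["grp"] = y
        mv = sm_manova.MANOVA.from_formula("v0 + v1 + v2 ~ grp", data=df)
        res = mv.mv_test().results["grp"]["stat"]
        assert tests["wilks"]["lambda"] == pytest.approx(
            float(res.loc["Wilks' lambda", "Value"]), abs=1e-8
        )
        assert tests["pillai"]["V"] == pytest.approx(
            float(res.loc["Pillai's trace", "Value"]), abs=1e-8
        )


class TestSignificanceTests:
    def test_printed_table_reconstruction(self):
        lam = eigenvalues_from_shares(0.0157, [79.72, 19.04, 1.25])
        assert round(wilks_lambda(lam), 4) == 0.9806
        assert round(pillai_trace(lam), 4) == 0.0194
        # leading canonical correlation below the 0.30 emphasis threshold
        assert np.sqrt(0.0157 / 1.0157) == pytest.approx(0.1243, abs=1e-4)

    def test_null_eigenvalues(self):
        out = discriminant_significance_tests([0.0], n=100, p=1, g=2)
        assert out["wilks"]["lambda"] == 1.0
        assert out["pillai"]["V"] == 0.0
        assert out["wilks"]["p_value"] == pytest.approx(1.0)

    def test_insufficient_df_errors(self):
        with pytest.raises(CDAError, match="residual"):
            discriminant_significance_tests([0.1], n=5, p=3, g=2)

    def test_univariate_wilks_is_ssw_over_sst(self, rng):
        X, y = _gaussian_groups(rng, [0.0, 1.0], 30, p=2)
        table = univariate_equality_tests(X, y)
        x = X["v0"].to_numpy()
        grand = x.mean()
        ssw = sum(
            ((x[y == lab] - x[y == lab].mean()) ** 2).sum() for lab in np.unique(y)
        )
        sst = ((x - grand) ** 2).sum()
        assert table.loc["v0", "wilks_lambda"] == pytest.approx(ssw / sst, rel=1e-10)


class TestLOOCV:
    def test_planted_separation(self, rng):
        X, y = _gaussian_groups(rng, [0.0, 10.0], 50, p=2)
        report = loocv_classification(X, y)
        assert report.overall_hit >= 0.98
        assert report.press_q > 6.63

    def test_shuffled_labels_near_chance(self, rng):
        X, y = _gaussian_groups(rng, [0.0, 10.0], 50, p=2)
        report = loocv_classification(X, rng.permutation(y))
        assert abs(report.overall_hit - report.max_chance) < 0.15

    def test_press_q_hand_value(self, rng):
        X, y = _gaussian_groups(rng, [0.0, 50.0], 50, p=1)
        report = loocv_classification(X, y)
        assert report.overall_hit == 1.0
        # N = 100, K = 2, all correct: (100 - 200)^2 / 100 = 100
        assert report.press_q == pytest.approx(100.0)

    def test_confusion_rows_sum_to_group_sizes(self, rng):
        X, y = _gaussian_groups(rng, [0.0, 1.0, 2.0], 20, p=2)
        report = loocv_classification(X, y)
        assert (report.confusion.sum(axis=1) == 20).all()
        assert report.overall_hit == pytest.approx(
            np.trace(report.confusion.to_numpy()) / 60
        )

    def test_hit_ratio_affine_invariant(self, rng):
        X, y = _gaussian_groups(rng, [0.0, 1.5], 40, p=2)
        base = loocv_classification(X, y).overall_hit
        scaled = X * np.array([100.0, 0.01]) + np.array([5.0, -3.0])
        assert loocv_classification(scaled, y).overall_hit == base

    def test_loocv_not_above_resubstitution_on_average(self, rng):
        diffs = []
        for _ in range(10):
            X, y = _gaussian_groups(rng, [0.0, 1.0], 30, p=2)
            diffs.append(
                resubstitution_hit_ratio(X, y) - loocv_classification(X, y).overall_hit
            )
        assert np.mean(diffs) >= 0.0

    def test_singleton_group_warns(self, rng):
        X = pd.DataFrame({"v": rng.normal(size=5), "w": rng.normal(size=5)})
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.warns(UserWarning, match="single row"):
            report = loocv_classification(X, y)
        assert report.per_group_hit["b"] == 0.0


class TestMahalanobisDistances:
    def test_zero_diagonal_symmetry_nonnegative(self, rng):
        X, y = _gaussian_groups(rng, [0.0, 1.0, 3.0], 30, p=2)
        D = mahalanobis_centroid_distances(X, y)
        assert np.all(np.diag(D.to_numpy()) == 0.0)
        np.testing.assert_allclose(D.to_numpy(), D.to_numpy().T)
        assert (D.to_numpy() >= 0).all()

    def test_duplicated_group_distance_zero(self, rng):
        Xa = rng.normal(size=(30, 2))
        X = pd.DataFrame(np.concatenate([Xa, Xa]), columns=["u", "v"])
        y = np.array(["a"] * 30 + ["b"] * 30)
        D = mahalanobis_centroid_distances(X, y)
        assert D.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_univariate_closed_form(self, rng):
        x1 = rng.normal(0.0, 1.0, size=200)
        x2 = rng.normal(4.0, 1.0, size=200)
        X = pd.DataFrame({"v": np.concatenate([x1, x2])})
        y = np.array(["a"] * 200 + ["b"] * 200)
        gap = abs(x1.mean() - x2.mean())
        pooled_var = (
            ((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()
        ) / (400 - 2)
        D = mahalanobis_centroid_distances(X, y)
        assert D.loc["a", "b"] == pytest.approx(gap / np.sqrt(pooled_var), rel=1e-10)


class TestDendrogram:
    def test_closest_pair_merges_first(self):
        D = pd.DataFrame(
            [[0, 1, 10], [1, 0, 10], [10, 10, 0]],
            index=list("ABC"),
            columns=list("ABC"),
            dtype=float,
        )
        Z, newick = distance_dendrogram(D)
        assert set(Z[0, :2].astype(int)) == {0, 1}  # A and B first
        assert "A" in newick and newick.endswith(";")

    def test_zero_matrix_collapses_at_height_zero(self):
        D = pd.DataFrame(np.zeros((4, 4)), index=list("ABCD"), columns=list("ABCD"))
        Z, _ = distance_dendrogram(D)
        assert np.all(Z[:, 2] == 0.0)

    def test_upgma_heights_match_naive_agglomeration(self, rng):
        n = 8
        M = np.abs(rng.normal(size=(n, n)))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        labels = [f"L{i}" for i in range(n)]
        D = pd.DataFrame(M, index=labels, columns=labels)
        Z, _ = distance_dendrogram(D, linkage="upgma")

        # brute-force UPGMA: merge closest clusters, size-weighted averages
        clusters = {i: [i] for i in range(n)}
        dist = {
            frozenset((i, j)): M[i, j] for i in range(n) for j in range(i + 1, n)
        }
        heights = []
        next_id = n
        while len(clusters) > 1:
            (a, b), h = min(
                (
                    (tuple(sorted(k)), v)
                    for k, v in dist.items()
                    if all(x in clusters for x in k)
                ),
                key=lambda t: t[1],
            )
            heights.append(h)
            merged = clusters.pop(a) + clusters.pop(b)
            for c in list(clusters):
                d_new = np.mean([M[x, y] for x in merged for y in clusters[c]])
                dist[frozenset((next_id, c))] = d_new
            clusters[next_id] = merged
            next_id += 1
        np.testing.assert_allclose(sorted(Z[:, 2]), sorted(heights), atol=1e-10)

    def test_newick_leaves_parse_to_group_labels(self, rng):
        dendropy = pytest.importorskip("dendropy")
        X, y = _gaussian_groups(rng, [0.0, 1.0, 3.0, 6.0], 25, p=2)
        D = mahalanobis_centroid_distances(X, y)
        _, newick = distance_dendrogram(D)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == set(D.index)

    def test_single_group_errors(self):
        D = pd.DataFrame([[0.0]], index=["A"], columns=["A"])
        with pytest.raises(CDAError):
            distance_dendrogram(D)
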