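"""Phylogenetic covariance, signal statistics, HSD, PCA and (p)FDA."""

import numpy as np
import pandas as pd
import pytest

from trophotax import synthetic
from trophotax.comparative import (
    blomberg_k,
    compact_letters,
    fda_fit_predict,
    kmult,
    pca_transform,
    pfda_fit_predict,
    phylo_cov,
    phylo_pairwise_hsd,
)
from trophotax.trees import Phylogeny, PhylogenyError


class TestPhyloCov:
    def test_star_tree_is_diagonal(self):
        star = Phylogeny.from_newick("(A:2,B:2,C:2,D:2);")
        C = phylo_cov(star).matrix.to_numpy()
        assert np.allclose(C, 2 * np.eye(4))

    def test_cherry_shares_root_path(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        C = phylo_cov(tree).matrix
        assert C.loc["A", "B"] == pytest.approx(1.0)
        assert C.loc["A", "A"] == pytest.approx(2.0)
        assert C.loc["A", "C"] == pytest.approx(0.0)

    def test_lambda_zero_removes_structure(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        C0 = phylo_cov(tree, lam=0.0).matrix.to_numpy()
        assert np.allclose(C0, np.diag(np.diag(C0)))
        with pytest.raises(PhylogenyError):
            phylo_cov(tree, lam=1.5)


def brute_force_k(tree, y):
    """Explicit-inverse evaluation of the K ratio (independent oracle)."""
    C = tree.vcv(labels=list(y.index)).to_numpy()
    Ci = np.linalg.inv(C)
    n = len(y)
    one = np.ones(n)
    yv = y.to_numpy(dtype=float)
    ahat = (one @ Ci @ yv) / (one @ Ci @ one)
    r = yv - ahat
    mse0 = r @ r
    mse = r @ Ci @ r
    expected = (np.trace(C) - n / (one @ Ci @ one)) / (n - 1)
    return (mse0 / mse) / expected


class TestPhylogeneticSignal:
    def test_matches_explicit_gls_oracle_on_small_trees(self, eight_tip_tree):
        for seed in range(5):
            y = synthetic.simulate_bm_traits(
                eight_tip_tree, 1.0, 0.0, seed=seed
            ).data["trait"]
            got = blomberg_k(eight_tip_tree, y, n_perm=9, seed=0).K
            assert got == pytest.approx(brute_force_k(eight_tip_tree, y), abs=1e-10)

    def test_bm_simulations_centre_near_one(self, yule100):
        ks = [
            blomberg_k(
                yule100,
                synthetic.simulate_bm_traits(yule100, 1.0, 0.0, seed=s).data["trait"],
                n_perm=0,
                seed=0,
            ).K
            for s in range(100)
        ]
        assert 0.9 <= np.mean(ks) <= 1.1

    def test_shuffled_data_loses_signal(self, yule100):
        nonsig, klow = 0, 0
        reps = 100
        for r in range(reps):
            tr = synthetic.simulate_bm_traits(yule100, 1.0, 0.0, seed=500 + r)
            y = tr.data["trait"].sample(frac=1, random_state=r)
            y.index = tr.data.index
            res = blomberg_k(yule100, y, n_perm=99, seed=r)
            nonsig += res.p_value > 0.05
            klow += res.K < 0.5
        assert nonsig / reps >= 0.9
        assert klow / reps >= 0.9

    def test_constant_trait_rejected(self, eight_tip_tree):
        y = pd.Series(1.0, index=eight_tip_tree.tip_labels)
        with pytest.raises(ValueError, match="variance"):
            blomberg_k(eight_tip_tree, y, n_perm=9, seed=0)

    def test_kmult_reduces_to_univariate(self, eight_tip_tree):
        y = synthetic.simulate_bm_traits(eight_tip_tree, 1.0, 0.0, seed=3).data
        k1 = blomberg_k(eight_tip_tree, y["trait"], n_perm=19, seed=5)
        km = kmult(eight_tip_tree, y, n_perm=19, seed=5)
        assert km.K == pytest.approx(k1.K, abs=1e-10)
        assert km.p_value == k1.p_value

    def test_kmult_bm_mean_near_one_and_p_floor(self):
        tree = synthetic.simulate_yule_tree(60, 1.0, seed=9)
        kms = []
        for r in range(40):
            X = pd.concat(
                [
                    synthetic.simulate_bm_traits(
                        tree, 1.0, 0.0, seed=3000 + 3 * r + j
                    ).data.rename(columns={"trait": f"x{j}"})
                    for j in range(3)
                ],
                axis=1,
            )
            kms.append(kmult(tree, X, n_perm=0, seed=0).K)
        assert 0.85 <= np.mean(kms) <= 1.15
        res = kmult(tree, X, n_perm=49, seed=0)
        assert res.p_value >= 1 / 50


@pytest.fixture(scope="module")
def hsd_setup():
    tree = synthetic.simulate_yule_tree(45, 1.0, seed=11)
    groups = pd.Series(
        ["g1"] * 15 + ["g2"] * 15 + ["g3"] * 15, index=tree.tip_labels
    )
    return tree, groups


class TestPairwiseHSD:
    def test_null_type_one_error_near_alpha(self, hsd_setup):
        tree, groups = hsd_setup
        sig, tot = 0, 0
        for rep in range(200):
            tr = synthetic.simulate_bm_traits(tree, 1.0, 0.0, seed=1000 + rep)
            pmat, _ = phylo_pairwise_hsd(
                tree, tr.data["trait"], groups, n_perm=199, seed=rep
            )
            iu = np.triu_indices(3, 1)
            ps = pmat.to_numpy()[iu]
            sig += (ps <= 0.05).sum()
            tot += ps.size
        assert 0.03 <= sig / tot <= 0.07

    def test_shifted_group_hits_permutation_floor(self, hsd_setup):
        tree, groups = hsd_setup
        tr = synthetic.simulate_bm_traits(tree, 1.0, 0.0, seed=5)
        x = tr.data["trait"].copy()
        x[groups == "g3"] += 5 * x.std()
        pmat, letters = phylo_pairwise_hsd(tree, x, groups, n_perm=199, seed=0)
        assert pmat.loc["g1", "g3"] == pytest.approx(1 / 200)
        assert pmat.loc["g2", "g3"] == pytest.approx(1 / 200)
        assert letters["g3"] not in (letters["g1"], letters["g2"])
        assert set(letters["g1"]) & set(letters["g2"])

    def test_group_absent_from_tree_rejected(self, hsd_setup):
        tree, groups = hsd_setup
        x = pd.Series(
            np.arange(45, dtype=float), index=[f"z{i}" for i in range(45)]
        )
        g = pd.Series(groups.to_numpy(), index=x.index)
        with pytest.raises(PhylogenyError, match="not in tree"):
            phylo_pairwise_hsd(tree, x, g, n_perm=9, seed=0)

    def test_small_group_rejected(self, hsd_setup):
        tree, _ = hsd_setup
        tips = tree.tip_labels
        groups = pd.Series(["g1"] + ["g2"] * 44, index=tips)
        x = pd.Series(np.arange(45, dtype=float), index=tips)
        with pytest.raises(ValueError, match="fewer than 2"):
            phylo_pairwise_hsd(tree, x, groups, n_perm=9, seed=0)


class TestCompactLetters:
    def test_four_separated_groups_get_four_letters(self):
        levels = ["nect", "gran", "inv", "frug", "gen", "fol", "tetra"]
        means = pd.Series([1, 2, 2.1, 3, 3.1, 4, 4.1], index=levels)
        p = pd.DataFrame(0.001, index=levels, columns=levels)
        for a, b in [("gran", "inv"), ("frug", "gen"), ("fol", "tetra")]:
            p.loc[a, b] = p.loc[b, a] = 0.8
        np.fill_diagonal(p.to_numpy(), 1.0)
        letters = compact_letters(p, means)
        assert letters["nect"] == "a"
        assert letters["gran"] == letters["inv"] == "b"
        assert letters["frug"] == letters["gen"] == "c"
        assert letters["fol"] == letters["tetra"] == "d"


class TestPCA:
    def test_pc1_follows_major_axis(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=500)
        X = pd.DataFrame({"a": 3 * z + 0.1 * rng.normal(size=500),
                          "b": 3 * z + 0.1 * rng.normal(size=500)})
        res = pca_transform(X)
        v = res.loadings["PC1"].to_numpy()
        assert abs(abs(v @ [1, 1] / np.sqrt(2)) - 1) < 1e-3
        assert res.variance_explained_pct[0] > 99

    def test_variance_sums_and_orthonormal_loadings(self, star_traits):
        res = pca_transform(star_traits, standardize=True)
        assert res.variance_explained_pct.sum() == pytest.approx(100.0)
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_sign_convention_deterministic(self, star_traits):
        L = pca_transform(star_traits).loadings.to_numpy()
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_constant_column_with_standardize_rejected(self):
        X = pd.DataFrame({"a": [1, 2, 3], "b": [5, 5, 5]})
        with pytest.raises(ValueError, match="constant"):
            pca_transform(X, standardize=True)


class TestFDA:
    def test_separated_classes_classified_confidently(self, star_traits):
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=star_traits.index)
        X = star_traits.copy()
        X.loc[labels == "B", "x"] += 10
        model, pred = fda_fit_predict(X, labels, X_new=X)
        assert model.train_misclassification == 0.0
        top = pred.posterior.max(axis=1)
        assert (top > 0.999).all()
        assert (pred.predicted == labels).all()

    def test_posterior_rows_sum_to_one_and_order_invariant(self, star_traits):
        labels = pd.Series(["A"] * 14 + ["B"] * 13 + ["C"] * 13, index=star_traits.index)
        X = star_traits.copy()
        X.loc[labels == "B", "x"] += 2
        X.loc[labels == "C", "y"] += 2
        _, pred = fda_fit_predict(X, labels, X_new=X)
        assert np.allclose(pred.posterior.sum(axis=1), 1.0, atol=1e-9)
        flipped = X.iloc[::-1]
        _, pred2 = fda_fit_predict(X, labels, X_new=flipped)
        assert np.allclose(
            pred2.posterior.loc[X.index], pred.posterior, atol=1e-12
        )

    def test_priors_modes(self, star_traits):
        labels = pd.Series(["A"] * 30 + ["B"] * 10, index=star_traits.index)
        X = star_traits.copy()
        X.loc[labels == "B", "x"] += 3
        prop, _ = fda_fit_predict(X, labels, priors="proportional")
        eq, _ = fda_fit_predict(X, labels, priors="equal")
        assert prop.priors["A"] == pytest.approx(0.75)
        assert eq.priors["A"] == pytest.approx(0.5)

    def test_collinear_features_warn_and_still_fit(self, star_traits):
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=star_traits.index)
        X = star_traits.copy()
        X["dup"] = X["x"]
        X.loc[labels == "B", ["x", "dup"]] += 5
        with pytest.warns(UserWarning, match="singular"):
            model, _ = fda_fit_predict(X, labels)
        assert model.train_misclassification <= 0.05


@pytest.fixture(scope="module")
def pfda_setup():
    tree = synthetic.simulate_yule_tree(44, 1.0, seed=3)
    tips = tree.tip_labels
    train, new = tips[:40], tips[40:]
    labels = pd.Series(["A"] * 20 + ["B"] * 20, index=train)
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.normal(size=(40, 3)), index=train)
    X.loc[labels == "B", 0] += 3
    Xn = pd.DataFrame(rng.normal(size=(4, 3)), index=new)
    Xn.iloc[2:, 0] += 3
    return tree, X, labels, Xn


class TestPFDA:

    def test_lambda_zero_reduces_to_fda(self, pfda_setup):
        tree, X, labels, Xn = pfda_setup
        _, p_fda = fda_fit_predict(X, labels, X_new=Xn)
        _, p0 = pfda_fit_predict(tree, X, labels, X_new=Xn, lambda_grid=[0.0])
        assert (p0.predicted == p_fda.predicted).all()
        assert np.allclose(p0.posterior, p_fda.posterior, atol=1e-12)

    def test_lambda_selected_by_loo_with_ties_to_smaller(self, pfda_setup):
        tree, X, labels, _ = pfda_setup
        model, _ = pfda_fit_predict(
            tree, X, labels, lambda_grid=[0.0, 0.5, 1.0]
        )
        errs = model.loo_errors
        best = min(errs.values())
        assert model.lam == min(l for l, e in errs.items() if e == best)

    def test_phylogenetic_clustering_not_hurt_by_pfda(self):
        # with lambda 0 on the grid, the selected LOO error can never
        # exceed plain FDA's; verify on trait data with phylogenetic
        # class clustering
        wins = 0
        reps = 15
        for r in range(reps):
            tree = synthetic.simulate_yule_tree(30, 1.0, seed=100 + r)
            tips = tree.tip_labels
            labels = pd.Series(["A" if i < 15 else "B" for i in range(30)], index=tips)
            cols = {}
            for j in range(2):
                tt = synthetic.simulate_bm_traits(
                    tree, 1.0, 0.0,
                    group_map=labels.to_dict(), offsets={"A": 0.0, "B": 2.0},
                    seed=200 + 2 * r + j,
                )
                cols[f"x{j}"] = tt.data["trait"]
            X = pd.DataFrame(cols)
            model, _ = pfda_fit_predict(
                tree, X, labels, lambda_grid=[0.0, 0.5, 1.0]
            )
            fda_err = model.loo_errors[0.0]
            wins += min(model.loo_errors.values()) <= fda_err
        assert wins / reps >= 0.8

    def test_overlapping_new_taxa_rejected_in_combined_mode(self, pfda_setup):
        tree, X, labels, _ = pfda_setup
        with pytest.raises(ValueError, match="distinct"):
            pfda_fit_predict(tree, X, labels, X_new=X, lambda_grid=[0.0])

    def test_extant_only_mode_predicts(self, pfda_setup):
        tree, X, labels, Xn = pfda_setup
        _, pred = pfda_fit_predict(
            tree, X, labels, X_new=Xn, lambda_grid=[0.0, 1.0], mode="extant_only"
        )
        assert np.allclose(pred.posterior.sum(axis=1), 1.0, atol=1e-9)
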