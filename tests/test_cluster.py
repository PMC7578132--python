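"""Divisive and fuzzy clustering on dissimilarities, and the FC matrix."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from mosscoda import (
    DivisiveClustering,
    FuzzyClustering,
    GeneratorConfig,
    aitchison_distance_matrix,
    fc_matrix,
    generate,
)


def euclidean(pts):
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return d


@pytest.fixture
def two_clouds(rng):
    pts = np.vstack([rng.normal(0, 0.3, (6, 2)), rng.normal(5, 0.3, (6, 2))])
    return pts, euclidean(pts)


class TestDivisiveClustering:
    def test_first_split_recovers_separated_clouds(self, two_clouds):
        _, d = two_clouds
        labels = DivisiveClustering(n_clusters=2).fit(d).labels_
        assert set(labels[:6]) != set(labels[6:])
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1

    def test_two_points_base_case(self):
        d = np.array([[0.0, 1.5], [1.5, 0.0]])
        diana = DivisiveClustering().fit(d)
        assert diana.dendrogram_.root.height == pytest.approx(1.5)
        assert diana.heights_.tolist() == [1.5]

    def test_sample_order_invariance(self, rng, two_clouds):
        pts, d = two_clouds
        diana1 = DivisiveClustering().fit(d)
        perm = rng.permutation(len(pts))
        d2 = d[np.ix_(perm, perm)]
        diana2 = DivisiveClustering().fit(d2)
        np.testing.assert_allclose(
            sorted(diana1.heights_), sorted(diana2.heights_), rtol=1e-12
        )
        # the K=2 partition must be the same up to relabeling
        cut1 = diana1.dendrogram_.cut(2)[perm]
        cut2 = diana2.dendrogram_.cut(2)
        assert (
            np.array_equal(cut1, cut2) or np.array_equal(cut1, 1 - cut2)
        )

    def test_heights_monotone_from_root(self, rng):
        d = euclidean(rng.normal(size=(15, 3)))
        dend = DivisiveClustering().fit(d).dendrogram_

        def check(node):
            if node.children is None:
                return
            for child in node.children:
                assert child.height <= node.height + 1e-12
                check(child)

        check(dend.root)
        assert dend.root.height == pytest.approx(d.max())

    def test_newick_export_parses(self, two_clouds):
        dendropy = pytest.importorskip("dendropy")
        _, d = two_clouds
        dist = pd.DataFrame(d, index=[f"s{i}" for i in range(12)], columns=[f"s{i}" for i in range(12)])
        nwk = DivisiveClustering().fit(dist).dendrogram_.to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 12

    def test_invalid_distance_rejected(self):
        with pytest.raises(ValueError):
            DivisiveClustering().fit(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DivisiveClustering().fit(np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestFuzzyClustering:
    def test_clear_groups_get_confident_memberships(self, two_clouds):
        _, d = two_clouds
        fanny = FuzzyClustering(n_clusters=2, random_state=0).fit(d)
        own = np.take_along_axis(
            fanny.membership_, fanny.labels_[:, None], axis=1
        ).ravel()
        assert fanny.converged_
        assert np.all(own >= 0.8)
        assert set(fanny.labels_[:6]) != set(fanny.labels_[6:])

    def test_equidistant_points_stay_uniform(self):
        d = np.ones((6, 6)) - np.eye(6)
        fanny = FuzzyClustering(n_clusters=2, random_state=1).fit(d)
        np.testing.assert_allclose(fanny.membership_, 0.5, atol=1e-3)

    def test_rows_sum_to_one_and_reproducible(self, two_clouds):
        _, d = two_clouds
        f1 = FuzzyClustering(random_state=7).fit(d)
        f2 = FuzzyClustering(random_state=7).fit(d)
        np.testing.assert_allclose(f1.membership_.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_array_equal(f1.membership_, f2.membership_)

    def test_objective_non_increasing(self, two_clouds):
        _, d = two_clouds
        path = FuzzyClustering(random_state=0).fit(d).objective_path_
        assert np.all(np.diff(path) <= 1e-12)

    def test_non_convergence_is_reported(self, two_clouds):
        _, d = two_clouds
        with pytest.warns(UserWarning, match="did not converge"):
            fanny = FuzzyClustering(max_iter=1, tol=1e-300, random_state=0).fit(d)
        assert not fanny.converged_

    def test_parameter_validation(self, two_clouds):
        _, d = two_clouds
        with pytest.raises(ValueError):
            FuzzyClustering(n_clusters=1).fit(d)
        with pytest.raises(ValueError):
            FuzzyClustering(membership_exponent=1.0).fit(d)


@pytest.fixture(scope="module")
def r_results(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("rcluster")
    rng = np.random.default_rng(5)
    pts = np.vstack([rng.normal(0, 0.4, (5, 2)), rng.normal(4, 0.4, (5, 2))])
    np.savetxt(tmp / "pts.csv", pts, delimiter=",")
    script = tmp / "cmp.R"
    script.write_text(
        f'x <- as.matrix(read.csv("{tmp}/pts.csv", header=FALSE))\n'
        "d <- dist(x)\n"
        "library(cluster)\n"
        "dv <- diana(d, diss=TRUE)\n"
        f'write.csv(data.frame(h=sort(dv$height, decreasing=TRUE)), "{tmp}/rheights.csv", row.names=FALSE)\n'
        f'write.csv(data.frame(k=cutree(as.hclust(dv), k=2)), "{tmp}/rcut.csv", row.names=FALSE)\n'
        "fn <- fanny(d, k=2, diss=TRUE, memb.exp=2)\n"
        f'write.table(fn$membership, "{tmp}/rmemb.csv", sep=",", row.names=FALSE, col.names=FALSE)\n'
    )
    proc = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, timeout=120
    )
    if proc.returncode != 0:
        pytest.fail(f"Rscript failed: {proc.stderr}")
    return {
        "pts": pts,
        "heights": pd.read_csv(tmp / "rheights.csv")["h"].to_numpy(),
        "cut": pd.read_csv(tmp / "rcut.csv")["k"].to_numpy() - 1,
        "memb": np.loadtxt(tmp / "rmemb.csv", delimiter=","),
    }


class TestAgainstRClusterPackage:
    """Independent oracle: the classical divisive/fuzzy implementations in R."""

    def test_diana_matches_r(self, r_results):
        d = euclidean(r_results["pts"])
        diana = DivisiveClustering(n_clusters=2).fit(d)
        np.testing.assert_allclose(
            sorted(diana.heights_, reverse=True), r_results["heights"], rtol=1e-6
        )
        cut = diana.labels_
        rcut = r_results["cut"]
        assert np.array_equal(cut, rcut) or np.array_equal(cut, 1 - rcut)

    def test_fanny_matches_r(self, r_results):
        d = euclidean(r_results["pts"])
        mine = FuzzyClustering(n_clusters=2, random_state=0).fit(d).membership_
        theirs = r_results["memb"]
        direct = np.abs(mine - theirs).max()
        swapped = np.abs(mine - theirs[:, ::-1]).max()
        assert min(direct, swapped) < 0.01


class TestFCMatrix:
    def test_hard_memberships_reduce_to_cluster_sums(self, rng):
        C = pd.DataFrame(rng.lognormal(size=(6, 3)), columns=list("abc"))
        u = np.zeros((6, 2))
        u[:3, 0] = 1.0
        u[3:, 1] = 1.0
        fc = fc_matrix(u, C)
        np.testing.assert_allclose(fc.fc.iloc[0], C.iloc[:3].sum())
        np.testing.assert_allclose(fc.fc.iloc[1], C.iloc[3:].sum())

    def test_uniform_memberships_give_unit_ratio(self, rng):
        C = pd.DataFrame(rng.lognormal(size=(8, 4)))
        u = np.full((8, 2), 0.5)
        fc = fc_matrix(u, C)
        np.testing.assert_allclose(fc.component_ratio, 1.0)
        np.testing.assert_allclose(fc.cluster_ratio, 1.0)

    def test_concentrated_element_flags_dominant_cluster(self):
        C = pd.DataFrame({"x": [10.0, 10.0, 1.0, 1.0], "y": [1.0, 1.0, 1.0, 1.0]})
        u = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        fc = fc_matrix(u, C)
        assert fc.component_ratio["x"] < 1.0
        assert fc.dominant_cluster["x"] == "cluster_1"

    def test_linearity_in_concentrations(self, rng):
        C1 = pd.DataFrame(rng.lognormal(size=(5, 3)))
        C2 = pd.DataFrame(rng.lognormal(size=(5, 3)))
        u = rng.dirichlet(np.ones(2), size=5)
        total = fc_matrix(u, C1 + C2).fc
        np.testing.assert_allclose(
            total, fc_matrix(u, C1).fc + fc_matrix(u, C2).fc, rtol=1e-12
        )

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            fc_matrix(np.ones((4, 2)) / 2, pd.DataFrame(rng.lognormal(size=(5, 3))))


class TestOnSyntheticSurvey:
    def test_crisp_and_fuzzy_views_agree_when_groups_separate(self):
        """With a strong site-class contrast the dendrogram cut and the
        fuzzy argmax recover the same two-group structure."""
        config = GeneratorConfig(
            n_per_group=12, default_shift=4.0, noise_sigma=0.08,
            factor_loading=0.15, outlier_rate=0.0, seed=2,
        )
        table, _ = generate(config)
        dist = aitchison_distance_matrix(table.values)
        crisp = DivisiveClustering(n_clusters=2).fit(dist).labels_
        fuzzy = FuzzyClustering(n_clusters=2, random_state=0).fit(dist).labels_
        agreement = max(np.mean(crisp == fuzzy), np.mean(crisp != fuzzy))
        assert agreement >= 0.8
        site = (table.meta["site_class"] == "mountain").to_numpy().astype(int)
        site_match = max(np.mean(crisp == site), np.mean(crisp != site))
        assert site_match >= 0.8
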