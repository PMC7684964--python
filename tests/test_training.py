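import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from cstkit import (
    BrayCurtisWardClusterer,
    CommunityStateTyper,
    NameCollisionError,
    ValidationError,
    bootstrap_centroid_se,
    build_centroids,
    generate_cohort,
    name_clusters,
    subcluster_diverse_group,
    three_group_spec,
    to_relative_abundance,
)
from cstkit import phylotypes as pt
from cstkit.synthetic import default_cohort_spec


@pytest.fixture(scope="module")
def three_blobs():
    cohort = generate_cohort(three_group_spec(), 60, seed=3)
    props, _ = to_relative_abundance(cohort.table)
    return props, cohort.true_labels


class TestBrayCurtisWardClusterer:
    def test_davies_bouldin_selects_three_blobs(self, three_blobs):
        props, truth = three_blobs
        model = BrayCurtisWardClusterer(k_min=2, k_max=20).fit(props)
        assert model.chosen_k_ == 3
        assert adjusted_rand_score(truth, model.labels_) == 1.0

    def test_validity_scores_recorded_over_full_range(self, three_blobs):
        props, _ = three_blobs
        model = BrayCurtisWardClusterer(k_min=2, k_max=20).fit(props)
        assert len(model.davies_bouldin_) == 19
        assert list(model.davies_bouldin_.index) == list(range(2, 21))
        assert set(model.silhouette_.columns) == {"euclidean", "braycurtis"}

    def test_manual_k_override(self, three_blobs):
        props, _ = three_blobs
        model = BrayCurtisWardClusterer(k=2).fit(props)
        assert model.chosen_k_ == 2
        assert len(np.unique(model.labels_)) == 2

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame(np.full((5, 2), 0.5))
        with pytest.raises(ValidationError, match="k_max"):
            BrayCurtisWardClusterer(k_max=20).fit(X)

    def test_identical_samples_error_or_fallback(self):
        X = pd.DataFrame(np.full((25, 2), 0.5))
        with pytest.raises(ValidationError, match="identical"):
            BrayCurtisWardClusterer().fit(X)
        model = BrayCurtisWardClusterer(allow_degenerate=True).fit(X)
        assert model.chosen_k_ == 1
        assert set(model.labels_) == {1}

    def test_sklearn_clone_compatible(self):
        est = BrayCurtisWardClusterer(k_min=3, k_max=7)
        assert clone(est).get_params() == est.get_params()


class TestSubclusterDiverseGroup:
    def test_recovers_five_ivc_subtypes(self):
        spec = default_cohort_spec(concentration=200)
        ivc = [l for l in spec.labels if l.startswith("IV-C")]
        weights = pd.Series(0.0, index=spec.profiles.index)
        weights[ivc] = 1 / len(ivc)
        spec.weights = weights
        cohort = generate_cohort(spec, 120, seed=9)
        props, _ = to_relative_abundance(cohort.table)
        labels = subcluster_diverse_group(props, k=5)
        assert adjusted_rand_score(cohort.true_labels, labels) == 1.0

    def test_k_below_two_rejected(self):
        X = pd.DataFrame(np.eye(4))
        with pytest.raises(ValidationError, match="k >= 2"):
            subcluster_diverse_group(X, k=1)

    def test_subset_smaller_than_k_rejected(self):
        X = pd.DataFrame(np.eye(3))
        with pytest.raises(ValidationError, match="3 samples into 5"):
            subcluster_diverse_group(X, k=5)


def mean_cluster(core: dict, taxa=None) -> pd.DataFrame:
    taxa = taxa or sorted(set(core) | {"g_Filler"})
    row = pd.Series(0.0, index=taxa)
    for t, v in core.items():
        row[t] = v
    row["g_Filler"] = 1.0 - row.sum() + row.get("g_Filler", 0.0)
    return row.to_frame().T


class TestNameClusters:
    @pytest.mark.parametrize(
        "core,expected",
        [
            ({pt.L_CRISPATUS: 0.90}, "I-A"),
            ({pt.L_CRISPATUS: 0.55, pt.L_INERS: 0.10}, "I-B"),
            ({pt.L_INERS: 0.92}, "III-A"),
            ({pt.L_INERS: 0.50, pt.G_VAGINALIS: 0.20}, "III-B"),
            ({pt.L_GASSERI: 0.80}, "II"),
            ({pt.L_JENSENII: 0.60, pt.L_INERS: 0.20}, "V"),
            ({pt.CA_L_VAGINAE: 0.45, pt.G_VAGINALIS: 0.25}, "IV-A"),
            ({pt.G_VAGINALIS: 0.60, pt.CA_L_VAGINAE: 0.02}, "IV-B"),
            ({pt.STREPTOCOCCUS: 0.70, pt.L_INERS: 0.05}, "IV-C1"),
            ({pt.ENTEROCOCCUS: 0.65}, "IV-C2"),
            ({pt.BIFIDOBACTERIUM: 0.75}, "IV-C3"),
            ({pt.STAPHYLOCOCCUS: 0.70}, "IV-C4"),
            ({pt.PREVOTELLA: 0.20, pt.STREPTOCOCCUS: 0.10}, "IV-C0"),
        ],
    )
    def test_naming_rules(self, core, expected):
        X = mean_cluster(core)
        names = name_clusters(np.array([1]), X)
        assert names[1] == expected

    def test_collision_error_and_merge(self):
        X = pd.concat(
            [mean_cluster({pt.L_CRISPATUS: 0.90}), mean_cluster({pt.L_CRISPATUS: 0.95})]
        ).fillna(0.0)
        X = X.div(X.sum(axis=1), axis=0)
        labels = np.array([1, 2])
        with pytest.raises(NameCollisionError, match="I-A"):
            name_clusters(labels, X)
        names = name_clusters(labels, X, collision="merge")
        assert names == {1: "I-A", 2: "I-A"}

    def test_coarse_mode_names_plain_ivc(self):
        X = mean_cluster({pt.STREPTOCOCCUS: 0.70})
        names = name_clusters(np.array([1]), X, ivc_subtypes=False)
        assert names[1] == "IV-C"


class TestBuildCentroids:
    def test_mean_of_two_members(self):
        X = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], columns=["g_A", "g_B"])
        cs = build_centroids(X, pd.Series(["x", "x"]))
        np.testing.assert_allclose(cs.centroids.loc["x"], [0.5, 0.5])
        assert cs.n_samples["x"] == 2

    def test_single_member_group_identity(self):
        X = pd.DataFrame([[0.3, 0.7]], columns=["g_A", "g_B"])
        cs = build_centroids(X, pd.Series(["solo"]))
        np.testing.assert_allclose(cs.centroids.loc["solo"], [0.3, 0.7])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.dirichlet(np.ones(5), size=30))
        y = pd.Series(rng.choice(["a", "b", "c"], size=30))
        perm = rng.permutation(30)
        cs1 = build_centroids(X, y)
        cs2 = build_centroids(X.iloc[perm].reset_index(drop=True), y.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(
            cs1.centroids.to_numpy(), cs2.centroids.to_numpy(), atol=1e-12
        )

    def test_dirichlet_group_centroid_near_target_mean(self):
        rng = np.random.default_rng(6)
        m = np.array([0.6, 0.3, 0.1])
        conc = 50.0
        n = 400
        X = pd.DataFrame(rng.dirichlet(conc * m, size=n))
        cs = build_centroids(X, pd.Series(["g"] * n))
        se = np.sqrt(m * (1 - m) / (conc + 1) / n)
        assert (np.abs(cs.centroids.loc["g"].to_numpy() - m) < 3 * se).all()

    def test_missing_label_group_rejected(self):
        X = pd.DataFrame([[1.0]], columns=["g_A"])
        with pytest.raises(ValidationError, match="empty"):
            build_centroids(X, pd.Series(["a"]), label_order=["a", "b"])


@pytest.fixture(scope="module")
def groups():
    rng = np.random.default_rng(8)
    X = pd.DataFrame(
        np.vstack(
            [rng.dirichlet([30, 10, 5], size=150), rng.dirichlet([5, 10, 30], size=150)]
        ),
        columns=["g_A", "g_B", "g_C"],
    )
    y = pd.Series(["p"] * 150 + ["q"] * 150)
    return X, y


class TestBootstrapCentroidSE:
    def test_bit_identical_under_fixed_seed(self, groups):
        X, y = groups
        se1, n1 = bootstrap_centroid_se(X, y, n_boot=100, frac=0.10, random_state=42)
        se2, n2 = bootstrap_centroid_se(X, y, n_boot=100, frac=0.10, random_state=42)
        pd.testing.assert_frame_equal(se1, se2)
        pd.testing.assert_series_equal(n1, n2)

    def test_zero_within_group_variance_gives_zero_se(self):
        X = pd.DataFrame(np.tile([0.25, 0.75], (40, 1)), columns=["g_A", "g_B"])
        y = pd.Series(["same"] * 40)
        se, _ = bootstrap_centroid_se(X, y, n_boot=50, frac=1.0, random_state=0)
        np.testing.assert_allclose(se.loc["same"], 0.0, atol=1e-15)

    def test_se_shrinks_with_group_size(self):
        rng = np.random.default_rng(10)
        ses = []
        for n in (60, 240, 960):
            X = pd.DataFrame(rng.dirichlet([20, 10, 5], size=n))
            y = pd.Series(["g"] * n)
            se, _ = bootstrap_centroid_se(X, y, n_boot=80, frac=0.5, random_state=1)
            ses.append(se.loc["g"].mean())
        # roughly 1/sqrt(n): quadrupling n should at least halve-ish the SE
        assert ses[1] < ses[0] * 0.7
        assert ses[2] < ses[1] * 0.7

    def test_sparse_label_warns(self, groups):
        X, y = groups
        y = y.copy()
        y.iloc[0] = "rare"
        with pytest.warns(UserWarning, match="fewer than half"):
            bootstrap_centroid_se(X, y, n_boot=20, frac=0.05, random_state=2)

    def test_parameter_validation(self, groups):
        X, y = groups
        with pytest.raises(ValueError):
            bootstrap_centroid_se(X, y, n_boot=1)
        with pytest.raises(ValueError):
            bootstrap_centroid_se(X, y, frac=0.0)


class TestCommunityStateTyper:
    def test_recovers_generating_sub_csts(self, tight_cohort):
        """Unsupervised training on a 13-type cohort recovers the generating
        labels for nearly all samples (name-matched, not just partitioned)."""
        _, cohort, props = tight_cohort
        typer = CommunityStateTyper(random_state=0).fit(props)
        agreement = (typer.labels_.to_numpy() == cohort.true_labels.to_numpy()).mean()
        assert agreement >= 0.90

    def test_moderate_spread_recovery(self):
        # concentration 50 (the defaults): still >= 90% after optimal naming
        spec = default_cohort_spec()
        cohort = generate_cohort(spec, 500, seed=13)
        props, _ = to_relative_abundance(cohort.table)
        typer = CommunityStateTyper(random_state=0).fit(props)
        agreement = (typer.labels_.to_numpy() == cohort.true_labels.to_numpy()).mean()
        assert agreement >= 0.90

    def test_centroids_on_simplex_with_bootstrap_se(self, tight_cohort):
        _, _, props = tight_cohort
        typer = CommunityStateTyper(n_boot=20, random_state=0, k_max=16).fit(props.iloc[:400])
        cs = typer.centroid_set_
        np.testing.assert_allclose(cs.centroids.sum(axis=1), 1.0, atol=1e-9)
        assert cs.bootstrap_se is not None
        assert (cs.bootstrap_se.fillna(0.0).to_numpy() >= 0).all()

    def test_report_contains_validity_scores(self, tight_cohort):
        _, _, props = tight_cohort
        typer = CommunityStateTyper(random_state=0).fit(props)
        assert set(typer.report_["davies_bouldin"]) == set(range(2, 21))
        assert typer.report_["chosen_k_stage1"] >= 2
        assert typer.report_["naming_evidence"]
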