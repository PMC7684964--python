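"""Define sub-CSTs from a cohort and build reference centroids.

The training procedure mirrors how vaginal community state types are
defined from a cohort of taxonomic profiles:

1. Agglomerative (Ward) clustering of the pairwise Bray-Curtis distances
   between samples; the tree is cut at every candidate number of clusters
   k in 2..20 and each cut is scored with the Davies-Bouldin index (lower
   is better) and the silhouette coefficient. The cut minimizing
   Davies-Bouldin wins (smallest k on ties), with a manual override.
2. The diverse, Lactobacillus-deficient communities (CST IV-C) are pooled
   and clustered a second time (same algorithm) into five subtypes.
3. Clusters are named deterministically from their mean composition
   (I/II/III/V by the dominant Lactobacillus species, with A/B splits by a
   dominance threshold; IV-A by Ca. Lachnocurva vaginae; IV-B by
   G. vaginalis; IV-C0..C4 by the marker anaerobe).
4. Each sub-CST's reference centroid is the arithmetic mean of the
   relative abundances of its member samples, with bootstrap standard
   errors from repeated resampling of a fraction of the cohort.

Bray-Curtis is not Euclidean, so Ward linkage on it is a heuristic; it is
used here because it is the established practice for these data.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.exceptions import NotFittedError
from sklearn.metrics import davies_bouldin_score, silhouette_score

from . import phylotypes as pt
from .errors import NameCollisionError, ValidationError
from .taxa_io import CentroidSet

_SIMPLEX_ATOL = 1e-9


def _as_profile_frame(X) -> pd.DataFrame:
    """Validate a samples-by-taxa relative abundance frame (rows sum to 1)."""
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.atleast_2d(np.asarray(X, dtype=float)))
    arr = X.to_numpy(dtype=float)
    if len(arr) and (arr < 0).any():
        raise ValidationError("relative abundances must be non-negative")
    if len(arr):
        sums = arr.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-6
        if bad.any():
            raise ValidationError(
                f"rows {np.flatnonzero(bad).tolist()} do not sum to 1; "
                "convert counts with to_relative_abundance first"
            )
    return X


class BrayCurtisWardClusterer(BaseEstimator, ClusterMixin):
    """Ward hierarchical clustering on Bray-Curtis distances with
    Davies-Bouldin cluster-number selection.

    Parameters
    ----------
    k_min, k_max : int, default 2 and 20
        Candidate numbers of clusters at which the dendrogram is cut.
    k : int or None
        Manual override; when set, validity scores are still computed over
        the full range but ``chosen_k_`` is forced to this value.
    allow_degenerate : bool, default False
        If all pairwise distances are zero (identical samples), fall back
        to a single cluster instead of raising.

    Attributes
    ----------
    linkage_ : ndarray
        scipy condensed linkage matrix (Ward on Bray-Curtis).
    labels_per_k_ : dict[int, ndarray]
        Flat cluster labels for every candidate k.
    davies_bouldin_ : pandas.Series
        Davies-Bouldin score per k (Euclidean, on the abundance vectors).
    silhouette_ : pandas.DataFrame
        Silhouette per k, in both Euclidean and Bray-Curtis space.
    chosen_k_ : int
        argmin of Davies-Bouldin (smallest k on ties) or the override.
    labels_ : ndarray
        Cluster labels (1..chosen_k_) at the chosen cut.
    """

    def __init__(
        self,
        k_min: int = 2,
        k_max: int = 20,
        k: int | None = None,
        allow_degenerate: bool = False,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.k = k
        self.allow_degenerate = allow_degenerate

    def fit(self, X, y=None) -> "BrayCurtisWardClusterer":
        X = _as_profile_frame(X)
        n = len(X)
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")
        if n < self.k_max and self.k is None:
            raise ValidationError(
                f"need at least k_max={self.k_max} samples, got {n}"
            )
        if self.k is not None and n < self.k:
            raise ValidationError(f"need at least k={self.k} samples, got {n}")

        arr = X.to_numpy(dtype=float)
        dist = pdist(arr, metric="braycurtis")
        if not np.any(dist > 0):
            if not self.allow_degenerate:
                raise ValidationError(
                    "all pairwise distances are zero (identical samples); "
                    "set allow_degenerate=True for a single-cluster fallback"
                )
            self.linkage_ = linkage(dist, method="ward")
            self.labels_per_k_ = {}
            self.davies_bouldin_ = pd.Series(dtype=float)
            self.silhouette_ = pd.DataFrame(columns=["euclidean", "braycurtis"])
            self.chosen_k_ = 1
            self.labels_ = np.ones(n, dtype=int)
            return self

        # Ward.D2-style update on the Bray-Curtis distance matrix; merges of
        # identical samples tie-break by input order inside scipy.
        self.linkage_ = linkage(dist, method="ward")
        sq = squareform(dist)

        ks = [k for k in range(self.k_min, self.k_max + 1) if k <= n]
        self.labels_per_k_ = {}
        db, sil_e, sil_bc = {}, {}, {}
        for k in ks:
            labels = fcluster(self.linkage_, t=k, criterion="maxclust")
            self.labels_per_k_[k] = labels
            if len(np.unique(labels)) < 2 or len(np.unique(labels)) >= n:
                db[k] = np.nan
                sil_e[k] = np.nan
                sil_bc[k] = np.nan
                continue
            db[k] = davies_bouldin_score(arr, labels)
            sil_e[k] = silhouette_score(arr, labels)
            sil_bc[k] = silhouette_score(sq, labels, metric="precomputed")
        self.davies_bouldin_ = pd.Series(db, name="davies_bouldin")
        self.silhouette_ = pd.DataFrame({"euclidean": sil_e, "braycurtis": sil_bc})

        if self.k is not None:
            self.chosen_k_ = int(self.k)
            self.labels_ = fcluster(self.linkage_, t=self.chosen_k_, criterion="maxclust")
        else:
            valid = self.davies_bouldin_.dropna()
            if valid.empty:
                raise ValidationError("no valid cluster cut in the requested k range")
            # idxmin returns the first (smallest) k on exact ties
            self.chosen_k_ = int(valid.idxmin())
            self.labels_ = self.labels_per_k_[self.chosen_k_]
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def cluster_samples(
    compositions: pd.DataFrame,
    k_range: tuple[int, int] = (2, 20),
    k: int | None = None,
) -> BrayCurtisWardClusterer:
    """Thin wrapper: fit a :class:`BrayCurtisWardClusterer` on *compositions*."""
    return BrayCurtisWardClusterer(k_min=k_range[0], k_max=k_range[1], k=k).fit(compositions)


def subcluster_diverse_group(compositions: pd.DataFrame, k: int = 5) -> np.ndarray:
    """Second-round Ward/Bray-Curtis clustering of the diverse (IV-C) pool.

    Returns flat cluster labels 1..k. Raises if k < 2 or the pool is
    smaller than k.
    """
    if k < 2:
        raise ValidationError("subclustering needs k >= 2")
    compositions = _as_profile_frame(compositions)
    if len(compositions) < k:
        raise ValidationError(
            f"cannot split {len(compositions)} samples into {k} subclusters"
        )
    dist = pdist(compositions.to_numpy(dtype=float), metric="braycurtis")
    Z = linkage(dist, method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


# ---------------------------------------------------------------------------
# cluster naming
# ---------------------------------------------------------------------------

def _name_from_mean(
    mean: pd.Series,
    dominance_threshold: float,
    iva_threshold: float,
    ivb_threshold: float,
    ivc_marker_threshold: float,
    ivc_subtypes: bool,
) -> str:
    top = str(mean.idxmax())
    focal = {
        pt.L_CRISPATUS: ("I-A", "I-B"),
        pt.L_INERS: ("III-A", "III-B"),
    }
    if top in focal:
        a, b = focal[top]
        return a if mean[top] >= dominance_threshold else b
    if top == pt.L_GASSERI:
        return "II"
    if top == pt.L_JENSENII:
        return "V"
    if mean.get(pt.CA_L_VAGINAE, 0.0) >= iva_threshold:
        return "IV-A"
    if mean.get(pt.G_VAGINALIS, 0.0) >= ivb_threshold:
        return "IV-B"
    if not ivc_subtypes:
        return "IV-C"
    if top in pt.IVC_MARKERS and mean[top] >= ivc_marker_threshold:
        return pt.IVC_MARKERS[top]
    return "IV-C0"


def name_clusters(
    labels,
    compositions: pd.DataFrame,
    dominance_threshold: float = 0.75,
    iva_threshold: float = 0.15,
    ivb_threshold: float = 0.30,
    ivc_marker_threshold: float = 0.25,
    ivc_subtypes: bool = True,
    collision: str = "error",
) -> dict:
    """Name each cluster from its mean composition.

    Rules (applied in order to the cluster's mean relative abundances):

    * top taxon *L. crispatus* -> I-A if its mean abundance is at least
      ``dominance_threshold`` (the focal species clearly dominates), else
      I-B; likewise *L. iners* -> III-A / III-B.
    * top taxon *L. gasseri* -> II; *L. jensenii* -> V.
    * *Ca. Lachnocurva vaginae* at >= ``iva_threshold`` -> IV-A.
    * otherwise *G. vaginalis* at >= ``ivb_threshold`` -> IV-B.
    * remainder -> IV-C: the marker genus (Streptococcus/Enterococcus/
      Bifidobacterium/Staphylococcus), when it is the top taxon at
      >= ``ivc_marker_threshold``, selects IV-C1..C4; an even community
      (often with notable Prevotella) falls back to IV-C0. With
      ``ivc_subtypes=False`` the remainder is named plain "IV-C".

    *collision* controls what happens when two clusters derive the same
    name: ``"error"`` raises :class:`NameCollisionError` (adjust k or the
    thresholds); ``"merge"`` lets them share the name.
    """
    if collision not in ("error", "merge"):
        raise ValueError("collision must be 'error' or 'merge'")
    labels = np.asarray(labels)
    compositions = _as_profile_frame(compositions)
    if len(labels) != len(compositions):
        raise ValidationError("labels and compositions are misaligned")
    names: dict = {}
    for cid in np.unique(labels):
        members = compositions.loc[np.asarray(labels == cid)]
        if len(members) == 0:
            raise ValidationError(f"cluster {cid} is empty")
        names[cid] = _name_from_mean(
            members.mean(axis=0),
            dominance_threshold,
            iva_threshold,
            ivb_threshold,
            ivc_marker_threshold,
            ivc_subtypes,
        )
    if collision == "error":
        seen: dict[str, object] = {}
        for cid, name in names.items():
            if name in seen:
                raise NameCollisionError(
                    f"clusters {seen[name]} and {cid} both map to {name!r}; "
                    "adjust k or the naming thresholds"
                )
            seen[name] = cid
    return names


# ---------------------------------------------------------------------------
# centroids
# ---------------------------------------------------------------------------

def build_centroids(
    compositions: pd.DataFrame,
    final_labels: pd.Series,
    label_order: list[str] | None = None,
) -> CentroidSet:
    """Average the relative abundances of each sub-CST's member samples.

    Means of simplex vectors already sum to 1; the result is renormalized
    anyway to guard floating-point rounding. Output is permutation-
    invariant to sample order.
    """
    compositions = _as_profile_frame(compositions)
    final_labels = pd.Series(np.asarray(final_labels), index=compositions.index)
    if final_labels.isna().any():
        raise ValidationError("every sample must carry a label")
    means = compositions.groupby(final_labels, sort=True).mean()
    counts = final_labels.value_counts()
    if label_order is not None:
        missing = [l for l in label_order if l not in means.index]
        if missing:
            raise ValidationError(f"empty label groups: {missing}")
        means = means.loc[label_order]
    means = means.div(means.sum(axis=1), axis=0)
    return CentroidSet(centroids=means, n_samples=counts.reindex(means.index))


def bootstrap_centroid_se(
    compositions: pd.DataFrame,
    final_labels: pd.Series,
    n_boot: int = 100,
    frac: float = 0.10,
    random_state: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Bootstrap standard errors of the centroid means.

    For each of *n_boot* replicates, ``ceil(frac * N)`` samples are drawn
    with replacement from the full training table and each label's centroid
    is recomputed from the replicate's members of that label. The SE of a
    taxon's mean is the standard deviation of that mean across the
    replicates in which the label appeared; labels absent from a replicate
    contribute nothing for it. The default (100 replicates of 10% of the
    cohort) matches how the reference centroids' error bars are defined.

    Returns
    -------
    (se, n_present)
        ``se`` is labels x taxa; ``n_present`` counts the replicates in
        which each label appeared. Labels present in fewer than half the
        replicates trigger a warning (their SE rests on few replicates).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must be in (0, 1]")
    compositions = _as_profile_frame(compositions)
    final_labels = pd.Series(np.asarray(final_labels), index=compositions.index)
    rng = np.random.default_rng(random_state)
    N = len(compositions)
    m = math.ceil(frac * N)
    arr = compositions.to_numpy(dtype=float)
    lab = final_labels.to_numpy()
    unique_labels = sorted(pd.unique(lab))

    replicate_means: dict = {l: [] for l in unique_labels}
    for _ in range(n_boot):
        idx = rng.choice(N, size=m, replace=True)
        rep_lab = lab[idx]
        rep_arr = arr[idx]
        for l in unique_labels:
            mask = rep_lab == l
            if mask.any():
                replicate_means[l].append(rep_arr[mask].mean(axis=0))

    se_rows, present = {}, {}
    for l in unique_labels:
        reps = replicate_means[l]
        present[l] = len(reps)
        if len(reps) >= 2:
            se_rows[l] = np.std(np.vstack(reps), axis=0, ddof=1)
        else:
            se_rows[l] = np.full(arr.shape[1], np.nan)
    n_present = pd.Series(present, name="n_replicates_present")
    sparse = n_present[n_present < n_boot / 2]
    if len(sparse):
        warnings.warn(
            f"labels present in fewer than half the replicates: {dict(sparse)}; "
            "their SEs rest on few replicates",
            UserWarning,
            stacklevel=2,
        )
    se = pd.DataFrame(se_rows, index=compositions.columns).T
    return se, n_present


# ---------------------------------------------------------------------------
# full pipeline estimator
# ---------------------------------------------------------------------------

class CommunityStateTyper(BaseEstimator):
    """End-to-end sub-CST trainer: cluster, name, build centroids, classify.

    ``fit`` runs the two-stage clustering and centroid construction on a
    cohort of relative-abundance profiles; ``predict`` then assigns
    profiles (the training cohort or new samples) by nearest centroid
    under Yue-Clayton theta.

    Parameters
    ----------
    k_min, k_max : int
        Stage-1 candidate cluster numbers (Davies-Bouldin selects).
    k_stage1 : int or None
        Manual override of the stage-1 cut.
    ivc_k : int, default 5
        Number of IV-C subtypes cut in the second round.
    dominance_threshold : float, default 0.75
        Focal-species mean abundance separating the A from the B subtype
        of CSTs I and III.
    iva_threshold, ivb_threshold, ivc_marker_threshold : float
        Naming thresholds (see :func:`name_clusters`).
    collision : {"merge", "error"}, default "merge"
        Same-name cluster policy; the pipeline default merges because the
        Davies-Bouldin-chosen k need not match the canonical names 1:1.
    n_boot, boot_frac : bootstrap SE settings (0 boots disables).
    random_state : seed for the bootstrap.

    Attributes
    ----------
    stage1_ : BrayCurtisWardClusterer
    cluster_names_ : dict mapping stage-1 cluster id -> coarse name
    labels_ : pandas.Series of final sub-CST names per training sample
    centroid_set_ : CentroidSet (with bootstrap SEs when requested)
    report_ : dict of validity scores, chosen k and naming evidence
    """

    def __init__(
        self,
        k_min: int = 2,
        k_max: int = 20,
        k_stage1: int | None = None,
        ivc_k: int = 5,
        dominance_threshold: float = 0.75,
        iva_threshold: float = 0.15,
        ivb_threshold: float = 0.30,
        ivc_marker_threshold: float = 0.25,
        collision: str = "merge",
        n_boot: int = 0,
        boot_frac: float = 0.10,
        low_conf_threshold: float = 0.5,
        margin: float = 0.1,
        random_state: int | None = None,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.k_stage1 = k_stage1
        self.ivc_k = ivc_k
        self.dominance_threshold = dominance_threshold
        self.iva_threshold = iva_threshold
        self.ivb_threshold = ivb_threshold
        self.ivc_marker_threshold = ivc_marker_threshold
        self.collision = collision
        self.n_boot = n_boot
        self.boot_frac = boot_frac
        self.low_conf_threshold = low_conf_threshold
        self.margin = margin
        self.random_state = random_state

    def fit(self, X, y=None) -> "CommunityStateTyper":
        X = _as_profile_frame(X)
        naming_kwargs = dict(
            dominance_threshold=self.dominance_threshold,
            iva_threshold=self.iva_threshold,
            ivb_threshold=self.ivb_threshold,
            ivc_marker_threshold=self.ivc_marker_threshold,
            collision=self.collision,
        )

        self.stage1_ = BrayCurtisWardClusterer(
            k_min=self.k_min, k_max=self.k_max, k=self.k_stage1
        ).fit(X)
        stage1_labels = self.stage1_.labels_
        # coarse names: the whole diverse pool is provisionally "IV-C"
        self.cluster_names_ = name_clusters(
            stage1_labels, X, ivc_subtypes=False, **naming_kwargs
        )

        final = pd.Series(
            [self.cluster_names_[c] for c in stage1_labels], index=X.index, dtype=object
        )
        ivc_mask = (final == "IV-C").to_numpy()
        self.ivc_sub_labels_ = None
        if ivc_mask.any():
            pool = X.loc[ivc_mask]
            if len(pool) >= self.ivc_k and self.ivc_k >= 2:
                sub = subcluster_diverse_group(pool, k=self.ivc_k)
                sub_names = name_clusters(sub, pool, ivc_subtypes=True, **naming_kwargs)
                final.loc[ivc_mask] = [sub_names[s] for s in sub]
                self.ivc_sub_labels_ = pd.Series(sub, index=pool.index)
            else:
                # pool too small for a second cut: name it as one group
                name = _name_from_mean(
                    pool.mean(axis=0),
                    self.dominance_threshold,
                    self.iva_threshold,
                    self.ivb_threshold,
                    self.ivc_marker_threshold,
                    ivc_subtypes=True,
                )
                final.loc[ivc_mask] = name

        self.labels_ = final
        from .classify import SUB_CST_LABELS

        order = [l for l in SUB_CST_LABELS if l in set(final)]
        order += [l for l in pd.unique(final) if l not in order]
        self.centroid_set_ = build_centroids(X, final, label_order=order)

        if self.n_boot > 0:
            se, n_present = bootstrap_centroid_se(
                X,
                final,
                n_boot=self.n_boot,
                frac=self.boot_frac,
                random_state=self.random_state,
            )
            self.centroid_set_.bootstrap_se = se.reindex(order)
            self.bootstrap_present_ = n_present

        key = [t for t in pt.KEY_TAXA if t in X.columns]
        self.report_ = {
            "chosen_k_stage1": int(self.stage1_.chosen_k_),
            "davies_bouldin": {int(k): float(v) for k, v in self.stage1_.davies_bouldin_.items()},
            "silhouette_euclidean": {
                int(k): float(v) for k, v in self.stage1_.silhouette_["euclidean"].items()
            },
            "silhouette_braycurtis": {
                int(k): float(v) for k, v in self.stage1_.silhouette_["braycurtis"].items()
            },
            "stage1_cluster_names": {int(c): n for c, n in self.cluster_names_.items()},
            "sub_cst_sizes": {str(k): int(v) for k, v in final.value_counts().items()},
            "naming_evidence": {
                label: {
                    t: float(v)
                    for t, v in self.centroid_set_.centroids.loc[label, key].items()
                }
                for label in self.centroid_set_.labels
            },
        }
        return self

    def _classifier(self):
        from .classify import YueClaytonNearestCentroid

        if not hasattr(self, "centroid_set_"):
            raise NotFittedError("this CommunityStateTyper instance is not fitted yet")
        return YueClaytonNearestCentroid.from_centroid_set(
            self.centroid_set_,
            low_conf_threshold=self.low_conf_threshold,
            margin=self.margin,
        )

    def predict(self, X) -> np.ndarray:
        """Nearest-centroid sub-CST assignment under the learned centroids."""
        return self._classifier().predict(X)

    def predict_similarity(self, X) -> pd.DataFrame:
        return self._classifier().predict_similarity(X)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)
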