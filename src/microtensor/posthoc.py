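"""Interpretation of fitted PARAFAC models.

Covers the downstream steps that turn a fitted model into biology:

* per-feature fit metrics (variance explained over the feature's
  subject x time slab, and the congruence between the observed and fitted
  slab) and a selection rule keeping only well-modelled features;
* a linear transformation of the feature loadings such that Euclidean
  geometry among the transformed rows equals the geometry of the features'
  fitted trajectories — required before plotting or clustering components
  that are not orthogonal;
* K-medoids clustering of the transformed loadings with
  within-cluster-sum-of-squares, silhouette, and gap-statistic guidance for
  the number of clusters;
* a permutation test comparing, per time point, the summed relative
  abundance of each cluster between two subject groups;
* rank-sum / correlation tests of subject loadings against subject metadata,
  Benjamini-Hochberg corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import sqrtm
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .cube import DataCube
from .parafac import ParafacModel, reconstruct

__all__ = [
    "FeatureFitMetrics",
    "ClusterResult",
    "feature_fit_metrics",
    "select_features",
    "transform_feature_loadings",
    "kmedoids",
    "cluster_features",
    "cluster_abundance_test",
    "associate_loadings",
]


@dataclass
class FeatureFitMetrics:
    """Per-feature model fit: slab variance explained (%) and observed-vs-
    fitted congruence, NaN where undefined (zero-variance slab)."""

    table: pd.DataFrame  # index: feature id; columns: variance_explained, congruence


def feature_fit_metrics(model: ParafacModel, cube: DataCube) -> FeatureFitMetrics:
    """Score how well the model reproduces each feature's full trajectory."""
    recon = reconstruct(model)
    rows = []
    for j, fid in enumerate(cube.feature_ids):
        m = cube.observed_mask[:, j, :]
        obs = cube.values[:, j, :][m]
        fit = recon[:, j, :][m]
        ssx = float(np.sum(obs**2))
        if ssx == 0 or np.linalg.norm(fit) == 0:
            rows.append({"feature": fid, "variance_explained": np.nan,
                         "congruence": np.nan})
            continue
        sse = float(np.sum((obs - fit) ** 2))
        phi = float(np.dot(obs, fit) / (np.linalg.norm(obs) * np.linalg.norm(fit)))
        rows.append({"feature": fid,
                     "variance_explained": 100.0 * (1.0 - sse / ssx),
                     "congruence": phi})
    return FeatureFitMetrics(pd.DataFrame(rows).set_index("feature"))


def select_features(
    metrics: FeatureFitMetrics, congruence_min: float = 0.4
) -> list:
    """Keep features whose slab variance explained is at least the average
    over features AND whose congruence is at least ``congruence_min``."""
    t = metrics.table
    mean_ve = t["variance_explained"].mean(skipna=True)
    keep = (t["variance_explained"] >= mean_ve) & (t["congruence"] >= congruence_min)
    selected = list(t.index[keep.fillna(False)])
    if not selected:
        import warnings

        warnings.warn("no feature passes the fit-metric selection", stacklevel=2)
    return selected


def transform_feature_loadings(model: ParafacModel) -> np.ndarray:
    """Feature loadings mapped so Euclidean geometry matches fitted trajectories.

    With non-orthogonal components, raw feature loadings cannot be compared
    by Euclidean distance.  The map B~ = B diag(lambda) M^(1/2), with
    M = (A^T A) ∘ (C^T C) the Hadamard product of the subject- and time-mode
    Gram matrices, makes <B~_j, B~_j'> equal the inner product of features
    j and j' fitted subject x time trajectories.
    """
    M = (model.A.T @ model.A) * (model.C.T @ model.C)
    eigvals = np.linalg.eigvalsh(M)
    if eigvals.min() < -1e-8 * max(1.0, abs(eigvals.max())):
        raise ValueError("congruence Gram matrix is not positive semidefinite")
    root = np.real(sqrtm(M))
    return (model.B * model.weights) @ root


def kmedoids(
    points: np.ndarray,
    k: int,
    n_starts: int = 50,
    rng: np.random.Generator | None = None,
    max_iter: int = 100,
):
    """Best-of-``n_starts`` K-medoids (PAM-style alternation, Euclidean).

    Each start draws k distinct random medoids, then alternates assignment
    and medoid update (the member minimising the summed distance to its
    cluster) until stable.  Returns ``(medoid_indices, labels, objective)``
    with the objective the total within-cluster distance; ties between starts
    go to the earliest start.
    """
    rng = rng or np.random.default_rng(0)
    n = len(points)
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n} points")
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    best = None
    for _ in range(n_starts):
        medoids = rng.choice(n, size=k, replace=False)
        for _ in range(max_iter):
            labels = np.argmin(d[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.where(labels == c)[0]
                if len(members) == 0:
                    continue
                within = d[np.ix_(members, members)].sum(axis=0)
                new_medoids[c] = members[np.argmin(within)]
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                break
            medoids = new_medoids
        labels = np.argmin(d[:, medoids], axis=1)
        objective = float(d[np.arange(n), medoids[labels]].sum())
        if best is None or objective < best[2] - 1e-12:
            best = (np.array(medoids), labels, objective)
    return best


@dataclass
class ClusterResult:
    """Outcome of :func:`cluster_features`."""

    selected_features: list
    transformed_loadings: pd.DataFrame  # J' x F, indexed by feature id
    metrics: pd.DataFrame  # index k; columns wss, silhouette, gap
    chosen_k: int
    medoids: list  # feature ids
    assignments: pd.Series  # feature id -> cluster label (1-based)
    tests: pd.DataFrame | None = None


def _wss(points: np.ndarray, medoids: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squared distances to the medoid."""
    return float(
        np.sum(np.linalg.norm(points - points[medoids[labels]], axis=1) ** 2)
    )


def cluster_features(
    transformed: pd.DataFrame | np.ndarray,
    k_range=range(2, 9),
    n_starts: int = 50,
    seed: int = 0,
    chosen_k: int | None = None,
    feature_ids=None,
    n_gap_refs: int = 50,
) -> ClusterResult:
    """Cluster transformed feature loadings with K-medoids.

    For each k in ``k_range`` (clipped to [2, J'-1]): best-of-``n_starts``
    K-medoids, plus WSS, mean silhouette width, and the gap statistic
    (uniform reference draws over the bounding box).  ``chosen_k`` defaults
    to the silhouette argmax; pass it explicitly to override after manual
    inspection.
    """
    if isinstance(transformed, pd.DataFrame):
        feature_ids = list(transformed.index)
        points = transformed.to_numpy(dtype=float)
    else:
        points = np.asarray(transformed, dtype=float)
        if feature_ids is None:
            feature_ids = list(range(len(points)))
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 features to cluster")
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("k_range empty after clipping to [2, n-1]")

    rng = np.random.default_rng(seed)
    lo, hi = points.min(axis=0), points.max(axis=0)
    refs = [
        rng.uniform(lo, hi, size=points.shape) for _ in range(n_gap_refs)
    ]

    rows, solutions = [], {}
    for k in k_range:
        medoids, labels, _ = kmedoids(points, k, n_starts=n_starts,
                                      rng=np.random.default_rng(seed + k))
        solutions[k] = (medoids, labels)
        wss = _wss(points, medoids, labels)
        sil = (
            float(silhouette_score(points, labels))
            if len(np.unique(labels)) > 1
            else np.nan
        )
        ref_log_wss = []
        for r, ref in enumerate(refs):
            rm, rl, _ = kmedoids(ref, k, n_starts=5,
                                 rng=np.random.default_rng(seed * 1000 + k * 100 + r))
            ref_log_wss.append(np.log(max(_wss(ref, rm, rl), 1e-300)))
        gap = float(np.mean(ref_log_wss) - np.log(max(wss, 1e-300)))
        rows.append({"k": k, "wss": wss, "silhouette": sil, "gap": gap})
    metrics = pd.DataFrame(rows).set_index("k")

    if chosen_k is None:
        chosen_k = int(metrics["silhouette"].idxmax())
    if chosen_k not in solutions:
        raise ValueError(f"chosen_k={chosen_k} not in evaluated k_range {k_range}")
    medoids, labels = solutions[chosen_k]
    return ClusterResult(
        selected_features=feature_ids,
        transformed_loadings=pd.DataFrame(
            points, index=feature_ids,
            columns=[f"component_{f + 1}" for f in range(points.shape[1])],
        ),
        metrics=metrics,
        chosen_k=chosen_k,
        medoids=[feature_ids[m] for m in medoids],
        assignments=pd.Series(labels + 1, index=feature_ids, name="cluster"),
    )


def cluster_abundance_test(
    cube: DataCube,
    assignments: pd.Series,
    group_column: str,
    groups: tuple = None,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test of cluster relative-abundance sums between two groups.

    Per (cluster, time point): each sample's statistic is the sum of the
    cluster's feature counts divided by the sample's total counts (over all
    features of the raw cube); the test statistic is the difference of group
    means, its null built by permuting subject group labels ``n_perm`` times.
    Two-sided add-one p-values, BH-corrected across time points within each
    cluster.
    """
    if cube.raw_counts is None and cube.has_transform("clr"):
        raise ValueError("relative abundances require raw counts on the cube")
    counts = cube.raw_counts if cube.raw_counts is not None else cube.values
    labels = cube.group_labels(group_column)
    if groups is None:
        uniq = list(pd.unique(labels))
        if len(uniq) != 2:
            raise ValueError(
                f"group column has {len(uniq)} levels; pass groups=(g1, g2)"
            )
        groups = tuple(uniq)
    g1, g2 = groups
    in1, in2 = labels == g1, labels == g2
    if not in1.any() or not in2.any():
        raise ValueError("both contrast groups must be non-empty")
    sel = in1 | in2

    fidx = {f: j for j, f in enumerate(cube.feature_ids)}
    rng = np.random.default_rng(seed)
    rows = []
    totals = np.nansum(np.where(cube.observed_mask, counts, np.nan), axis=1)  # I x K
    for cluster in sorted(assignments.unique()):
        members = [fidx[f] for f in assignments.index[assignments == cluster]]
        csum = np.nansum(
            np.where(cube.observed_mask[:, members, :], counts[:, members, :], np.nan),
            axis=1,
        )  # I x K
        with np.errstate(invalid="ignore", divide="ignore"):
            relsum = np.where(totals > 0, csum / totals, np.nan)
        observed_fiber = cube.observed_mask.any(axis=1)  # I x K
        relsum = np.where(observed_fiber, relsum, np.nan)
        for k, t in enumerate(cube.time_points):
            x = relsum[:, k]
            ok = ~np.isnan(x) & sel
            l1, l2 = ok & in1, ok & in2
            if not l1.any() or not l2.any():
                rows.append({"cluster": cluster, "time": t, "statistic": np.nan,
                             "p_value": np.nan, "testable": False})
                continue
            obs_stat = float(x[l1].mean() - x[l2].mean())
            pool = np.where(ok)[0]
            lab_pool = in1[pool]
            null = np.empty(n_perm)
            for p in range(n_perm):
                perm = rng.permutation(lab_pool)
                null[p] = x[pool][perm].mean() - x[pool][~perm].mean()
            p_val = (1 + np.sum(np.abs(null) >= abs(obs_stat))) / (n_perm + 1)
            rows.append({"cluster": cluster, "time": t, "statistic": obs_stat,
                         "p_value": float(p_val), "testable": True})
    df = pd.DataFrame(rows)
    df["p_adjusted"] = np.nan
    for cluster in df["cluster"].unique():
        m = (df["cluster"] == cluster) & df["testable"]
        if m.any():
            df.loc[m, "p_adjusted"] = multipletests(
                df.loc[m, "p_value"], method="fdr_bh"
            )[1]
    return df


def associate_loadings(
    model: ParafacModel,
    cube: DataCube,
    variables: dict,
) -> pd.DataFrame:
    """Test subject loadings against subject metadata.

    ``variables`` maps metadata column names to ``"binary"`` (two-sided
    Wilcoxon rank-sum on the loadings split by the two levels) or
    ``"continuous"`` (two-sided Pearson correlation test).  BH correction is
    applied across all (component, variable) pairs tested in this call.
    Variables with a single level are skipped with a note in the table.
    """
    if cube.subject_metadata is None:
        raise ValueError("cube carries no subject metadata")
    rows = []
    for var, kind in variables.items():
        values = cube.subject_metadata.loc[cube.subject_ids, var]
        for f in range(model.n_components):
            load = model.A[:, f]
            ok = values.notna().to_numpy()
            if kind == "binary":
                levels = pd.unique(values[ok])
                if len(levels) < 2:
                    rows.append({"component": f + 1, "variable": var,
                                 "kind": kind, "statistic": np.nan,
                                 "p_value": np.nan, "note": "single level"})
                    continue
                if len(levels) > 2:
                    raise ValueError(f"variable {var!r} has >2 levels")
                x = load[ok & (values == levels[0]).to_numpy()]
                y = load[ok & (values == levels[1]).to_numpy()]
                stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            elif kind == "continuous":
                v = pd.to_numeric(values, errors="coerce").to_numpy()
                ok = ok & ~np.isnan(v)
                if ok.sum() < 3 or np.std(v[ok]) == 0:
                    rows.append({"component": f + 1, "variable": var,
                                 "kind": kind, "statistic": np.nan,
                                 "p_value": np.nan, "note": "degenerate"})
                    continue
                stat, p = stats.pearsonr(load[ok], v[ok])
            else:
                raise ValueError(f"unknown variable kind {kind!r}")
            rows.append({"component": f + 1, "variable": var, "kind": kind,
                         "statistic": float(stat), "p_value": float(p),
                         "note": ""})
    df = pd.DataFrame(rows)
    tested = df["p_value"].notna()
    df["p_adjusted"] = np.nan
    if tested.any():
        df.loc[tested, "p_adjusted"] = multipletests(
            df.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    return df
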