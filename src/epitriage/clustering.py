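"""Resampling consensus clustering of tumour methylomes, with k selection,
assignment of new samples and PCA diagnostics.

For each of ``n_resamples`` rounds a random subset of samples (default 80%,
without replacement) is clustered by the base clusterer (hierarchical,
average linkage on Euclidean distance, by default; k-means optional).  The
consensus value for a pair of samples is the fraction of rounds in which they
were clustered together among the rounds in which both were drawn:

    c_ij = (# co-clustered) / (# co-sampled)

Final class assignments come from hierarchical clustering (average linkage) of
the dissimilarity ``1 - c`` cut into k groups.  With subsample fraction 1 and
a deterministic base clusterer the consensus matrix degenerates to the 0/1
co-membership matrix of a single clustering run — a useful small-n oracle.

k is chosen from the area under the consensus CDF: the chosen k is the
smallest beyond which the relative area gain falls below a tolerance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "ConsensusResult",
    "KChoice",
    "PcaEmbedding",
    "consensus_cluster",
    "choose_k",
    "assign_new_samples",
    "pca_project",
    "consensus_cdf_area",
]


@dataclass
class ConsensusResult:
    k: int
    sample_ids: list[str]
    consensus_matrix: np.ndarray  # n x n, entries in [0, 1], diagonal 1
    cosample_counts: np.ndarray  # n x n integer co-draw counts
    assignments: pd.Series  # sample_id -> cluster label (1..k)
    resample_params: dict = field(default_factory=dict)


@dataclass
class KChoice:
    k: int
    areas: dict[int, float]  # k -> area under consensus CDF
    delta_areas: dict[int, float]  # k -> relative gain over previous k
    pac: dict[int, float] = field(default_factory=dict)  # k -> ambiguity share
    method: str = "delta_area"
    degenerate: bool = False
    low_confidence: bool = False


@dataclass
class PcaEmbedding:
    coordinates: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray


def _base_labels(X: np.ndarray, k: int, method: str, linkage_method: str, seed: int) -> np.ndarray:
    if method == "hierarchical":
        Z = linkage(X, method=linkage_method, metric="euclidean")
        return fcluster(Z, t=k, criterion="maxclust")
    if method == "kmeans":
        return KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
    raise ValueError(f"unknown base clusterer {method!r}")


def _renumber(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance (deterministic)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def consensus_cluster(
    data: pd.DataFrame,
    k_values,
    n_resamples: int = 1000,
    item_fraction: float = 0.8,
    feature_fraction: float = 1.0,
    base_clusterer: str = "hierarchical",
    linkage_method: str = "average",
    seed: int | None = None,
) -> dict[int, ConsensusResult]:
    """Run resampling consensus clustering over the given k values.

    ``data`` is features x samples (the orientation of a beta/M matrix); the
    same subsample is reused for every k within a round, so consensus matrices
    across k share the co-sampling counts.  ``seed`` is required: all
    resampling comes from one documented NumPy generator stream.
    """
    if seed is None:
        raise ValueError("seed is required (resampling must be reproducible)")
    k_values = sorted(set(int(k) for k in k_values))
    n = data.shape[1]
    if n < max(k_values):
        raise ValueError(f"n={n} samples < largest k={max(k_values)}")
    if not 0 < item_fraction <= 1 or not 0 < feature_fraction <= 1:
        raise ValueError("subsample fractions must be in (0, 1]")
    sample_ids = data.columns.tolist()
    X = np.ascontiguousarray(data.to_numpy(dtype=float).T)  # samples x features
    p = X.shape[1]
    m = n if item_fraction == 1.0 else max(2, int(math.ceil(item_fraction * n)))
    q = p if feature_fraction == 1.0 else max(1, int(math.ceil(feature_fraction * p)))
    rng = np.random.default_rng(seed)

    cocluster = {k: np.zeros((n, n)) for k in k_values}
    cosample = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False)) if m < n else np.arange(n)
        cols = np.sort(rng.choice(p, size=q, replace=False)) if q < p else slice(None)
        sub = X[np.ix_(idx, cols)] if q < p else X[idx]
        cosample[np.ix_(idx, idx)] += 1
        for k in k_values:
            labels = _base_labels(sub, k, base_clusterer, linkage_method, int(rng.integers(2**31)))
            same = labels[:, None] == labels[None, :]
            cocluster[k][np.ix_(idx, idx)] += same

    off = cosample.copy()
    np.fill_diagonal(off, 1)
    never = [sample_ids[i] for i in range(n) if n > 1 and cosample[i].sum() - cosample[i, i] == 0]
    if never:
        raise RuntimeError(
            f"samples never co-sampled with any other: {never}; increase n_resamples"
        )

    params = {
        "n_resamples": n_resamples,
        "item_subsample_fraction": item_fraction,
        "feature_subsample_fraction": feature_fraction,
        "base_clusterer": base_clusterer,
        "linkage_method": linkage_method,
        "seed": seed,
    }
    results: dict[int, ConsensusResult] = {}
    for k in k_values:
        with np.errstate(invalid="ignore"):
            consensus = np.where(cosample > 0, cocluster[k] / np.maximum(cosample, 1), 0.0)
        np.fill_diagonal(consensus, 1.0)
        consensus = (consensus + consensus.T) / 2
        d = 1.0 - consensus
        np.fill_diagonal(d, 0.0)
        Z = linkage(squareform(d, checks=False), method="average")
        labels = _renumber(fcluster(Z, t=k, criterion="maxclust"))
        results[k] = ConsensusResult(
            k=k,
            sample_ids=sample_ids,
            consensus_matrix=consensus,
            cosample_counts=cosample.astype(int),
            assignments=pd.Series(labels, index=sample_ids, name="cluster"),
            resample_params=params,
        )
    return results


def consensus_cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus values.

    For values supported on [0, 1] the integral of the step CDF equals
    ``1 - mean(c)``; the area grows as pairwise consensus values polarise
    toward zero, which is what adding genuine clusters achieves.
    """
    iu = np.triu_indices_from(consensus, k=1)
    vals = consensus[iu]
    if vals.size == 0:
        return 0.0
    return float(1.0 - vals.mean())


def consensus_pac(consensus: np.ndarray, band: tuple[float, float] = (0.1, 0.9)) -> float:
    """Proportion of ambiguous clustering: the share of off-diagonal consensus
    values falling strictly inside ``band`` (neither clearly together nor
    clearly apart)."""
    iu = np.triu_indices_from(consensus, k=1)
    vals = consensus[iu]
    if vals.size == 0:
        return 0.0
    return float(((vals > band[0]) & (vals < band[1])).mean())


def choose_k(
    results: dict[int, ConsensusResult],
    tol: float = 0.1,
    method: str = "delta_area",
    pac_tol: float = 0.02,
) -> KChoice:
    """Pick k from the consensus matrices over the evaluated k values.

    ``method="delta_area"`` (default) returns the smallest k beyond which
    every relative gain in the consensus-CDF area falls below ``tol``.

    ``method="pac"`` returns the largest k whose proportion of ambiguous
    clustering stays at or below ``pac_tol`` — every pair of samples is still
    decisively co-clustered or separated.  This resolves small genuine
    clusters (a few samples out of dozens) whose area gain is indistinguishable
    from the forced-split noise the elbow rule sees at k above the truth.

    Both report the full area, gain and PAC curves.  Degenerate data
    (consensus ~ all ones at the smallest k: indistinguishable samples)
    returns k=1 with a warning flag; data where the rule never resolves
    (no elbow / no crisp k) returns the largest k flagged low-confidence.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 k values to choose k")
    ks = sorted(results)
    areas = {k: consensus_cdf_area(results[k].consensus_matrix) for k in ks}
    pac = {k: consensus_pac(results[k].consensus_matrix) for k in ks}
    delta: dict[int, float] = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        base = areas[prev] if areas[prev] > 0 else 1.0
        delta[k] = (areas[k] - areas[prev]) / base

    first = results[ks[0]].consensus_matrix
    iu = np.triu_indices_from(first, k=1)
    if iu[0].size and first[iu].min() > 0.999:
        return KChoice(k=1, areas=areas, delta_areas=delta, pac=pac,
                       method=method, degenerate=True)

    if method == "pac":
        crisp = [k for k in ks if pac[k] <= pac_tol]
        if not crisp:
            return KChoice(k=ks[-1], areas=areas, delta_areas=delta, pac=pac,
                           method=method, low_confidence=True)
        return KChoice(k=max(crisp), areas=areas, delta_areas=delta, pac=pac, method=method)
    if method != "delta_area":
        raise ValueError(f"unknown method {method!r}")

    chosen = None
    for i, k in enumerate(ks):
        if all(delta[k2] < tol for k2 in ks[i + 1 :]):
            chosen = k
            break
    if chosen is None or chosen == ks[-1]:
        return KChoice(k=ks[-1], areas=areas, delta_areas=delta, pac=pac,
                       method=method, low_confidence=True)
    return KChoice(k=chosen, areas=areas, delta_areas=delta, pac=pac, method=method)


def assign_new_samples(
    reference: ConsensusResult,
    combined_data: pd.DataFrame,
    seed: int,
    n_resamples: int | None = None,
):
    """Assign new samples by re-running consensus clustering on the combined
    cohort at the reference k and mapping clusters back by majority overlap.

    Returns ``(labels, report)`` where ``labels`` maps each new sample to the
    reference cluster label it inherits ("novel" for an unmappable cluster)
    and ``report`` records the cluster mapping plus any reference samples
    whose mapped label disagrees with their reference assignment.
    """
    ref_ids = set(reference.sample_ids)
    missing = ref_ids - set(combined_data.columns)
    if missing:
        raise ValueError(f"combined data lacks reference samples: {sorted(missing)[:5]}")
    params = reference.resample_params
    res = consensus_cluster(
        combined_data,
        [reference.k],
        n_resamples=n_resamples or params.get("n_resamples", 1000),
        item_fraction=params.get("item_subsample_fraction", 0.8),
        feature_fraction=params.get("feature_subsample_fraction", 1.0),
        base_clusterer=params.get("base_clusterer", "hierarchical"),
        linkage_method=params.get("linkage_method", "average"),
        seed=seed,
    )[reference.k]
    new_assign = res.assignments
    mapping: dict[int, object] = {}
    for c in sorted(new_assign.unique()):
        members = new_assign.index[new_assign == c]
        ref_members = [s for s in members if s in ref_ids]
        if not ref_members:
            mapping[c] = "novel"
        else:
            ref_labels = reference.assignments.loc[ref_members]
            mapping[c] = int(ref_labels.value_counts().sort_index().idxmax())
    moved = [
        s
        for s in reference.sample_ids
        if mapping[new_assign.loc[s]] != int(reference.assignments.loc[s])
    ]
    new_ids = [s for s in combined_data.columns if s not in ref_ids]
    labels = pd.Series({s: mapping[new_assign.loc[s]] for s in new_ids}, name="cluster")
    report = {"cluster_mapping": mapping, "reference_samples_moved": moved, "rerun": res}
    return labels, report


def pca_project(data: pd.DataFrame, n_components: int = 2) -> PcaEmbedding:
    """Centered PCA of samples (columns of ``data``); deterministic up to sign."""
    n_samples = data.shape[1]
    limit = min(n_samples - 1, data.shape[0])
    if n_components > limit:
        raise ValueError(f"n_components {n_components} > min(n_samples-1, n_features) = {limit}")
    X = data.to_numpy(dtype=float).T
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PcaEmbedding(
        coordinates=pd.DataFrame(coords, index=data.columns, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
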