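"""Conformer-ensemble clustering: t-SNE embedding followed by k-means.

Disordered-peptide conformers are featurized as vectors of all pairwise
Calpha distances (rotation/translation invariant), embedded into two
dimensions by t-distributed stochastic neighbor embedding at a chosen
perplexity, and partitioned by k-means on the embedding.  Homogeneity is
reported as the silhouette score on the embedding.  One representative per
cluster is the medoid: the member minimizing the summed feature-space
distance to all other members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .structures import Ensemble

__all__ = ["ClusterResult", "featurize", "cluster", "representatives", "perplexity_scan"]

log = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    labels: np.ndarray           # cluster id per conformer
    k: int
    silhouette: float            # on the 2-D embedding; 0 when degenerate
    representatives: list[int]   # conformer index per cluster, cluster order
    perplexity: float
    embedding: np.ndarray        # (n, 2)


def featurize(ens: Ensemble, atom_name: str = "CA") -> np.ndarray:
    """Conformer x pairwise-distance feature matrix (Angstrom).

    Rows have length n(n-1)/2 for n residues; invariant under rigid motion of
    any conformer.
    """
    topo = ens.topology
    idx = [i for i, a in enumerate(topo.atoms) if a.name == atom_name]
    n = len(idx)
    if n < 3:
        raise ValueError(f"need at least 3 {atom_name} atoms per conformer, found {n}")
    feats = np.empty((ens.frame_count, n * (n - 1) // 2))
    for f in range(ens.frame_count):
        feats[f] = pdist(ens.coords[f][idx])
    return feats


def cluster(
    features: np.ndarray,
    k: int = 50,
    perplexity: float = 30.0,
    seed: int = 0,
) -> ClusterResult:
    """Embed with t-SNE, partition with k-means, report embedding silhouette.

    Deterministic under a fixed seed.  Requires at least k rows and more rows
    than the perplexity.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} conformers")
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} must be below the number of conformers {n}")
    if np.allclose(features, features[0]):
        # degenerate input: no variance to embed (and Barnes-Hut t-SNE
        # cannot handle it); a single all-points cluster with silhouette 0
        if k != 1:
            raise ValueError("identical conformers cannot form more than one cluster")
        log.warning("all conformers identical; silhouette reported as 0")
        labels = np.zeros(n, dtype=int)
        return ClusterResult(labels, 1, 0.0, [0], perplexity, np.zeros((n, 2)))
    tsne = TSNE(
        n_components=2, perplexity=perplexity, init="pca", random_state=seed,
        max_iter=1000,
    )
    emb = tsne.fit_transform(features)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(emb)

    if k == 1 or len(np.unique(labels)) < 2 or np.allclose(emb, emb[0]):
        log.warning("degenerate clustering (single cluster or identical points); silhouette = 0")
        sil = 0.0
    else:
        sil = float(silhouette_score(emb, labels))

    reps = _medoids(features, labels, k)
    return ClusterResult(labels, k, sil, reps, perplexity, emb)


def _medoids(features: np.ndarray, labels: np.ndarray, k: int) -> list[int]:
    reps: list[int] = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            raise ValueError(f"cluster {c} is empty")
        if members.size == 1:
            reps.append(int(members[0]))
            continue
        sub = squareform(pdist(features[members]))
        reps.append(int(members[np.argmin(sub.sum(axis=1))]))
    return reps


def representatives(ens: Ensemble, result: ClusterResult) -> Ensemble:
    """One frame per cluster: the feature-space medoid of each cluster."""
    if len(result.labels) != ens.frame_count:
        raise ValueError("cluster result does not match ensemble frame count")
    return Ensemble(ens.topology, ens.coords[result.representatives].copy())


def perplexity_scan(
    features: np.ndarray,
    k: int,
    perplexities: list[float],
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Silhouette score versus perplexity over a list of candidate values."""
    out = []
    for p in perplexities:
        res = cluster(features, k=k, perplexity=p, seed=seed)
        out.append((p, res.silhouette))
    return out
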