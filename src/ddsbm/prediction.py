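"""Held-out link prediction and posterior clustering summaries.

Link-prediction accuracy is estimated by k-fold cross-validation over
the observable pairs of a relation: each fold's pairs are marked
unobserved (they contribute nothing to the likelihood during fitting),
the model is refit, and the posterior mean connection probability of
each held-out pair is scored against its true presence/absence by ROC
AUC.  The posterior over partitions is summarized by the coassignment
matrix — the fraction of pooled samples in which two entities share a
type.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import roc_auc_score, roc_curve

from .core import Relation, SampleSet
from .likelihoods import Dataset, get_obs_model
from .inference import InferenceConfig, run_chains


def _observable_pairs(relation: Relation) -> np.ndarray:
    """(n_pairs, 2) array of off-diagonal observable pairs.

    Ordered pairs for directed relations, unordered (i < j) otherwise.
    """
    n = relation.n
    sel = relation.mask & ~np.eye(n, dtype=bool)
    if not relation.directed:
        sel = sel & np.triu(np.ones((n, n), dtype=bool), k=1)
    return np.argwhere(sel)


def make_cv_folds(relation: Relation, k: int = 10, rng=None) -> list[np.ndarray]:
    """Partition observable pairs into k folds; return per-fold training masks.

    Fold j's mask equals the relation's mask with fold-j pairs switched
    off (held out).  Undirected relations hold out unordered pairs, so
    both ordered copies are masked together.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(rng)
    pairs = _observable_pairs(relation)
    if pairs.shape[0] < k:
        raise ValueError(f"only {pairs.shape[0]} observable pairs for {k} folds")
    perm = rng.permutation(pairs.shape[0])
    masks = []
    for fold in np.array_split(perm, k):
        m = relation.mask.copy()
        held = pairs[fold]
        m[held[:, 0], held[:, 1]] = False
        if not relation.directed:
            m[held[:, 1], held[:, 0]] = False
        masks.append(m)
    return masks


def predictive_link_prob(samples: SampleSet, pairs, data: Dataset, q: int = 0):
    """Posterior-mean connection probability for the given pairs.

    Averages, over pooled samples, the link function's probability of a
    present edge given that sample's assignment and parameters; Poisson
    relations use P(count >= 1) = 1 - exp(-rate).
    """
    pairs = np.atleast_2d(np.asarray(pairs))
    i, j = pairs[:, 0], pairs[:, 1]
    om = get_obs_model(data.models[q])
    d = data.geometry.distances[i, j]
    probs = np.zeros(pairs.shape[0])
    for state in samples.samples:
        c = state.assignment.labels
        tabs = state.component_params[q].tables
        pij = {name: t[c[i], c[j]] for name, t in tabs.items()}
        probs += om.link_prob(d, pij, state.hyper[q])
    return probs / len(samples.samples)


def roc_points(scores, labels):
    """(false-positive-rate, true-positive-rate) pairs over score thresholds."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr])


def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann–Whitney; ties get half credit)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def cross_validated_auc(data: Dataset, config: InferenceConfig, k: int = 10,
                        q: int = 0, rng=None):
    """k-fold held-out link prediction on relation ``q``.

    Returns (per-fold AUC list, pooled AUC over all folds' held-out
    pairs concatenated, per-pair scores, per-pair labels).
    """
    rel = data.relations[q]
    rng = np.random.default_rng(config.seed if rng is None else rng)
    masks = make_cv_folds(rel, k=k, rng=rng)
    fold_aucs, all_scores, all_labels = [], [], []
    for fi, mask in enumerate(masks):
        train_rel = replace(rel, mask=mask)
        rels = list(data.relations)
        rels[q] = train_rel
        fold_data = Dataset(rels, data.geometry, models=list(data.models),
                            soma=data.soma, synapse_profiles=data.synapse_profiles)
        fold_cfg = replace(config, seed=config.seed + 1000 * (fi + 1))
        samples = run_chains(fold_data, fold_cfg)
        held = np.argwhere(rel.mask & ~mask)
        if not rel.directed:
            held = held[held[:, 0] < held[:, 1]]
        scores = predictive_link_prob(samples, held, fold_data, q=q)
        labels = (rel.matrix[held[:, 0], held[:, 1]] > 0).astype(int)
        all_scores.append(scores)
        all_labels.append(labels)
        if np.unique(labels).size == 2:
            fold_aucs.append(auc(scores, labels))
    all_scores = np.concatenate(all_scores)
    all_labels = np.concatenate(all_labels)
    pooled = auc(all_scores, all_labels)
    return fold_aucs, pooled, all_scores, all_labels


def coassignment_matrix(samples: SampleSet) -> np.ndarray:
    """P(same type) per entity pair: mean over samples of 1[c_i == c_j]."""
    if not samples.samples:
        raise ValueError("empty sample set")
    n = samples.samples[0].assignment.n
    co = np.zeros((n, n))
    for state in samples.samples:
        c = state.assignment.labels
        co += (c[:, None] == c[None, :])
    return co / len(samples.samples)


def sort_for_blocks(coassign: np.ndarray) -> np.ndarray:
    """Deterministic entity ordering that groups high-coassignment blocks.

    Average-linkage agglomerative clustering of the dissimilarity
    1 - coassignment; returns the dendrogram leaf order.
    """
    co = np.asarray(coassign, dtype=float)
    n = co.shape[0]
    if n <= 2:
        return np.arange(n)
    dis = 1.0 - co
    np.fill_diagonal(dis, 0.0)
    dis = (dis + dis.T) / 2.0
    z = linkage(squareform(dis, checks=False), method="average")
    return np.asarray(leaves_list(z))


__all__ = [
    "make_cv_folds",
    "predictive_link_prob",
    "roc_points",
    "auc",
    "cross_validated_auc",
    "coassignment_matrix",
    "sort_for_blocks",
]
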