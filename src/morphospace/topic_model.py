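"""Topic summaries of a term vocabulary: tf-idf, PPMI co-occurrence, Ward.

The pipeline condenses a term-document occurrence table into macro-categories:
term-document counts are tf-idf weighted, turned into a positive pointwise
mutual information (PPMI) term-term co-occurrence matrix, and clustered with
agglomerative Ward linkage on the PPMI rows.  The conventional resolutions
are 12 (broad), 25 (medium) and 55 (fine) clusters, but any K is accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import ClusterWarning, fcluster, linkage

PRESET_LEVELS = (12, 25, 55)


def tfidf(counts: pd.DataFrame) -> pd.DataFrame:
    """tf-idf weighting of a terms x documents count table.

    ``weight(t, d) = tf(t, d) * ln(N_docs / df(t))`` with raw counts as tf.
    Terms occurring in every document get zero weight; a term occurring in no
    document has undefined idf and raises.
    """
    if counts.shape[1] < 1:
        raise ValueError("need at least one document")
    C = counts.to_numpy(dtype=float)
    if (C < 0).any():
        raise ValueError("counts must be nonnegative")
    df_t = (C > 0).sum(axis=1)
    dead = counts.index[df_t == 0].tolist()
    if dead:
        raise ValueError(f"terms with zero document frequency: {dead[:10]}")
    idf = np.log(counts.shape[1] / df_t)
    return pd.DataFrame(C * idf[:, None], index=counts.index, columns=counts.columns)


@dataclass
class PPMIMatrix:
    """Symmetric nonnegative terms x terms positive-PMI matrix."""

    data: pd.DataFrame

    def __post_init__(self):
        A = self.data.to_numpy(dtype=float)
        if not np.allclose(A, A.T):
            raise ValueError("PPMI matrix must be symmetric")
        if (A < -1e-12).any():
            raise ValueError("PPMI matrix must be nonnegative")

    @property
    def terms(self) -> list:
        return list(self.data.index)


def ppmi(weighted: pd.DataFrame) -> PPMIMatrix:
    """Positive PMI term-term matrix from a (weighted) term-document table.

    Co-occurrence is the weighted table times its transpose; joint and
    marginal probabilities come from normalizing it to unit mass.  PMI is the
    natural log of joint over product of marginals; pairs that never co-occur
    are set to zero before the log (no -inf), and negative PMI is clipped to
    zero.
    """
    if weighted.shape[0] < 1:
        raise ValueError("empty vocabulary")
    W = weighted.to_numpy(dtype=float)
    if (W < 0).any():
        raise ValueError("weights must be nonnegative")
    C = W @ W.T
    total = C.sum()
    if total <= 0:
        raise ValueError("co-occurrence matrix has zero mass")
    P = C / total
    pi = P.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(P / np.outer(pi, pi))
    pmi[C == 0] = 0.0
    pmi[~np.isfinite(pmi)] = 0.0
    out = np.maximum(pmi, 0.0)
    out = (out + out.T) / 2.0  # exact symmetry against float asymmetry
    return PPMIMatrix(pd.DataFrame(out, index=weighted.index, columns=weighted.index))


@dataclass
class TopicClustering:
    """Ward clustering of PPMI rows into K topics.

    ``assignment`` maps every term to a cluster label in 1..K (labels are
    renumbered by order of first appearance, so the output is stable under
    identical input).
    """

    k: int
    assignment: pd.Series
    linkage_matrix: np.ndarray

    def __post_init__(self):
        labels = set(self.assignment)
        if len(labels) != self.k:
            raise ValueError(f"expected {self.k} nonempty clusters, got {len(labels)}")

    def members(self, label: int) -> list:
        return self.assignment.index[self.assignment == label].tolist()


def cluster_terms(matrix: PPMIMatrix, k: int) -> TopicClustering:
    """Agglomerative Ward clustering of terms on their PPMI rows.

    Ward linkage minimizes the within-cluster squared-Euclidean variance
    increase at each merge; scipy's implementation resolves merge-cost ties
    deterministically by cluster index, so results are reproducible.
    """
    n = matrix.data.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"K must lie in 1..{n}, got {k}")
    X = matrix.data.to_numpy(dtype=float)
    with warnings.catch_warnings():
        # the PPMI matrix is square/symmetric by nature; rows are features,
        # not a condensed distance matrix
        warnings.simplefilter("ignore", ClusterWarning)
        if k == n:
            labels = np.arange(1, n + 1)
            Z = linkage(X, method="ward") if n > 1 else np.empty((0, 4))
        else:
            Z = linkage(X, method="ward")
            raw = fcluster(Z, t=k, criterion="maxclust")
            # renumber by first appearance for determinism of the public labels
            remap: Dict[int, int] = {}
            labels = np.empty_like(raw)
            for i, lab in enumerate(raw):
                if lab not in remap:
                    remap[lab] = len(remap) + 1
                labels[i] = remap[lab]
    return TopicClustering(k=k,
                           assignment=pd.Series(labels, index=matrix.data.index,
                                                name="cluster"),
                           linkage_matrix=Z)


def top_terms(clustering: TopicClustering, weighted: pd.DataFrame,
              k: int = 10) -> Dict[int, List[str]]:
    """Per-cluster term ranking by total tf-idf mass (ties lexicographic)."""
    mass = weighted.sum(axis=1)
    out: Dict[int, List[str]] = {}
    for label in sorted(set(clustering.assignment)):
        terms = clustering.members(label)
        ranked = sorted(terms, key=lambda t: (-mass.get(t, 0.0), t))
        out[int(label)] = ranked[:k]
    return out
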