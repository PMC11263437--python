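"""Discriminant analysis of principal components on spectra.

PCA on centered spectra, optional k-means group inference (k chosen by
BIC over a candidate range), then linear discriminant analysis on the
retained principal components.  A repeated stratified hold-out CV picks
the number of retained components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import ConfigError, DegenerateModelError


@dataclass
class DAPCResult:
    n_pcs: int
    ld_coordinates: np.ndarray        # rows x (n_groups - 1)
    ld_variance_pct: np.ndarray       # per-LD % of discriminant variance
    assignments: np.ndarray           # predicted group per row
    labels: np.ndarray                # the grouping used for the DA
    cv_accuracy: float
    inferred_k: Optional[int] = None  # set when groups were inferred
    kmeans_bic: Optional[dict] = None


def _pca_scores(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA via SVD; returns (scores, explained variances)."""
    X = values - values.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U * s
    var = s ** 2 / max(1, X.shape[0] - 1)
    return scores, var


def _kmeans_bic(scores: np.ndarray, k_range: Sequence[int], seed: int
                ) -> tuple[int, np.ndarray, dict]:
    """k-means over a range of k; BIC = n log(WSS/n) + k log(n)."""
    n = scores.shape[0]
    bics, fits = {}, {}
    for k in k_range:
        if k < 1 or k > n:
            continue
        km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(scores)
        wss = float(km.inertia_)
        bics[k] = n * np.log(max(wss, 1e-300) / n) + k * np.log(n)
        fits[k] = km.labels_
    if not bics:
        raise ConfigError("empty k range")
    k_best = min(bics, key=lambda k: (bics[k], k))
    return k_best, fits[k_best], bics


def _holdout_accuracy(scores: np.ndarray, labels: np.ndarray, n_pcs: int,
                      reps: int, seed: int, test_frac: float = 0.1) -> float:
    """Repeated stratified 90/10 split accuracy of LDA on n_pcs scores."""
    rng = np.random.default_rng(seed)
    uniq = np.unique(labels)
    accs = []
    for _ in range(reps):
        test_idx = []
        for g in uniq:
            members = np.flatnonzero(labels == g)
            n_test = max(1, int(round(test_frac * len(members))))
            if n_test >= len(members):  # keep at least one for training
                n_test = len(members) - 1
            if n_test < 1:
                continue
            test_idx.extend(rng.permutation(members)[:n_test])
        test_idx = np.asarray(test_idx)
        mask = np.ones(len(labels), dtype=bool)
        mask[test_idx] = False
        if len(np.unique(labels[mask])) < 2:
            continue
        lda = LinearDiscriminantAnalysis()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lda.fit(scores[mask, :n_pcs], labels[mask])
        accs.append(float(np.mean(lda.predict(scores[test_idx, :n_pcs])
                                  == labels[test_idx])))
    return float(np.mean(accs)) if accs else float("nan")


def cv_select_npcs(values: np.ndarray, labels, candidates: Sequence[int],
                   reps: int = 100, seed: int = 0) -> int:
    """Candidate PC count maximising mean held-out assignment accuracy;
    ties go to the smaller count.  Candidates above the data rank are
    skipped with a warning."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ConfigError("need at least 2 groups")
    scores, var = _pca_scores(values)
    rank = int(np.sum(var > 1e-12 * max(var.max(), 1e-300)))
    best_n, best_acc = None, -np.inf
    for n_pcs in sorted(set(int(c) for c in candidates)):
        if n_pcs < 1 or n_pcs > rank:
            warnings.warn(f"candidate {n_pcs} exceeds rank {rank}; skipped")
            continue
        acc = _holdout_accuracy(scores, labels, n_pcs, reps, seed)
        if acc > best_acc + 1e-12:
            best_n, best_acc = n_pcs, acc
    if best_n is None:
        raise ConfigError("no usable PC-count candidate")
    return best_n


def dapc_fit(values: np.ndarray, labels=None, n_pcs: Optional[int] = None,
             k_range: Sequence[int] = range(2, 7), seed: int = 0,
             cv_reps: int = 50) -> DAPCResult:
    """Fit the DAPC: PCA, (k-means when no labels), then LDA.

    With ``labels=None``, groups are inferred by k-means on all PCs and
    ``k`` picked by BIC over ``k_range``.  ``n_pcs=None`` selects the
    retained component count by repeated stratified hold-out accuracy.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 3:
        raise ConfigError("need at least 3 rows")
    scores, var = _pca_scores(values)
    rank = int(np.sum(var > 1e-12 * max(var.max(), 1e-300)))
    if rank < 1:
        raise DegenerateModelError("spectra matrix has zero variance")

    inferred_k = None
    bics = None
    if labels is None:
        k_best, lab, bics = _kmeans_bic(scores[:, :rank], k_range, seed)
        if k_best == 1:
            raise DegenerateModelError("a single cluster was inferred; "
                                       "no discriminant axis exists")
        labels = lab
        inferred_k = k_best
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ConfigError("need at least 2 distinct groups")
    if (counts < 2).any():
        raise ConfigError("every group needs at least 2 members")

    if n_pcs is None:
        candidates = sorted({c for c in
                             (2, 5, 10, 20, 40, rank) if 1 <= c <= rank})
        n_pcs = cv_select_npcs(values, labels, candidates, reps=cv_reps,
                               seed=seed)
    if n_pcs > rank:
        warnings.warn(f"n_pcs {n_pcs} exceeds rank {rank}; truncated")
        n_pcs = rank

    lda = LinearDiscriminantAnalysis()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ld = lda.fit_transform(scores[:, :n_pcs], labels)
    evr = getattr(lda, "explained_variance_ratio_", None)
    if evr is None or len(evr) == 0:
        evr = np.ones(ld.shape[1]) / ld.shape[1]
    pct = 100.0 * np.asarray(evr) / np.sum(evr)
    assignments = lda.predict(scores[:, :n_pcs])
    acc = _holdout_accuracy(scores, labels, n_pcs, cv_reps, seed)
    return DAPCResult(int(n_pcs), ld, pct, assignments, labels, acc,
                      inferred_k, bics)
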