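"""Eye-fixation features: K-means areas of interest (AOI) and per-subject
AOI distribution frequencies.

Fixation points pooled over the *training* subjects are clustered into K
AOIs with Lloyd's algorithm; each subject's feature vector is the fraction
of that subject's fixations falling in each AOI (a probability vector of
length K).  The clustering is written out explicitly — alternating nearest-
center assignment and centroid update of the within-cluster sum of squares

    J = sum_n sum_k r_nk * ||x_n - mu_k||^2

with k-means++-style seeded restarts — because the loss trajectory and the
assignment rule are part of the method's contract (J is non-increasing
across iterations; ties go to the lowest cluster index).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import FixationSet

__all__ = ["KMeansState", "kmeans_fit", "aoi_frequencies",
           "gaze_feature_table"]


@dataclass
class KMeansState:
    """A fitted AOI clustering."""

    K: int
    centers: np.ndarray          # (K, 2)
    assignments: np.ndarray      # (n,) cluster index per training point
    loss: float                  # final J
    n_iter: int
    converged: bool
    loss_history: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "K": self.K,
            "centers": self.centers.tolist(),
            "loss": self.loss,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "KMeansState":
        d = json.loads(text)
        centers = np.asarray(d["centers"], dtype=float)
        return cls(K=d["K"], centers=centers,
                   assignments=np.empty(0, dtype=int), loss=d["loss"],
                   n_iter=d["n_iter"], converged=d["converged"])


def _assign(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # squared distances (n, K); argmin breaks ties toward the lowest index
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def _loss(points: np.ndarray, centers: np.ndarray,
          assign: np.ndarray) -> float:
    return float(((points - centers[assign]) ** 2).sum())


def _plusplus_init(points: np.ndarray, K: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Greedy k-means++ seeding: each subsequent center is the best of a
    few candidates sampled with probability proportional to squared
    distance from the nearest chosen center (the candidate minimising the
    resulting potential is kept)."""
    n = len(points)
    n_candidates = 2 + int(np.log(max(K, 2)))
    centers = np.empty((K, 2))
    centers[0] = points[rng.integers(n)]
    d2 = ((points - centers[0]) ** 2).sum(axis=1)
    for k in range(1, K):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a center
            centers[k] = points[rng.integers(n)]
            continue
        cand = rng.choice(n, size=n_candidates, p=d2 / total)
        cand_d2 = np.minimum(
            d2, ((points[None, :, :] - points[cand, None, :]) ** 2)
            .sum(axis=2))
        best = int(np.argmin(cand_d2.sum(axis=1)))
        centers[k] = points[cand[best]]
        d2 = cand_d2[best]
    return centers


def _improve_single_moves(points: np.ndarray, assign: np.ndarray, K: int,
                          max_moves: int = 100) -> bool:
    """Hartigan-style polish: greedily move single points between clusters
    while the move strictly lowers J (accounting for the centroid shift).

    Lloyd convergence only guarantees a fixed point of the assign/update
    alternation; a point can still lower J by switching cluster once the
    centroid displacement is taken into account.  Returns True if any move
    was applied (``assign`` is modified in place).
    """
    moved = False
    for _ in range(max_moves):
        counts = np.bincount(assign, minlength=K)
        sums = np.zeros((K, points.shape[1]))
        np.add.at(sums, assign, points)
        centers = sums / np.maximum(counts, 1)[:, None]
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        n_own = counts[assign]
        # removal gain n/(n-1)*d2_own; insertion cost m/(m+1)*d2_target
        remove = n_own / np.maximum(n_own - 1, 1) * \
            d2[np.arange(len(points)), assign]
        insert = counts[None, :] / (counts[None, :] + 1) * d2
        delta = insert - remove[:, None]
        delta[n_own == 1, :] = np.inf  # never empty a cluster
        delta[np.arange(len(points)), assign] = 0.0
        i, k = np.unravel_index(np.argmin(delta), delta.shape)
        if delta[i, k] >= -1e-12:
            break
        assign[i] = k
        moved = True
    return moved


def _lloyd(points: np.ndarray, K: int, rng: np.random.Generator,
           max_iter: int, tol: float) -> KMeansState:
    centers = _plusplus_init(points, K, rng)
    assign = _assign(points, centers)
    history = [_loss(points, centers, assign)]
    converged = False
    total_iter = 0
    for _round in range(3):  # Lloyd passes interleaved with polish moves
        for _ in range(1, max_iter + 1 - total_iter):
            total_iter += 1
            new_centers = centers.copy()
            for k in range(K):
                mask = assign == k
                if mask.any():
                    new_centers[k] = points[mask].mean(axis=0)
                else:
                    # empty cluster: reseed at the point farthest from its
                    # current assigned center
                    far = np.argmax(
                        ((points - centers[assign]) ** 2).sum(axis=1))
                    new_centers[k] = points[far]
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            assign = _assign(points, centers)
            history.append(_loss(points, centers, assign))
            if shift < tol:
                converged = True
                break
        if not (converged and _improve_single_moves(points, assign, K)):
            break
        # a polish move strictly lowered J: recompute centers and let
        # Lloyd settle again from the improved assignment
        centers = np.array([points[assign == k].mean(axis=0)
                            if (assign == k).any() else centers[k]
                            for k in range(K)])
        assign = _assign(points, centers)
        history.append(_loss(points, centers, assign))
    return KMeansState(K=K, centers=centers, assignments=assign,
                       loss=history[-1], n_iter=total_iter,
                       converged=converged, loss_history=history)


def kmeans_fit(points: np.ndarray, K: int, seed: int = 0, n_init: int = 10,
               max_iter: int = 100, tol: float = 1e-6) -> KMeansState:
    """Cluster 2-D points into K AOIs; best of ``n_init`` seeded restarts.

    Parameters
    ----------
    points
        (n, 2) array of fixation coordinates.
    K
        Number of areas of interest; must not exceed the number of distinct
        points.
    seed, n_init, max_iter, tol
        Restart seeding, restart count, per-run iteration cap, and the
        center-shift convergence threshold (max-norm, pixels).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError(f"points: expected (n, 2), got {points.shape}")
    if len(points) == 0:
        raise ValueError("points: empty input")
    if K < 1:
        raise ValueError(f"K: must be >= 1, got {K}")
    n_distinct = len(np.unique(points, axis=0))
    if K > n_distinct:
        raise ValueError(f"K: {K} clusters requested but only {n_distinct} "
                         f"distinct points")
    rng = np.random.default_rng(seed)
    best: KMeansState | None = None
    for _ in range(max(1, n_init)):
        state = _lloyd(points, K, rng, max_iter, tol)
        if best is None or state.loss < best.loss:
            best = state
    return best


def aoi_frequencies(model: KMeansState, subject_points: FixationSet
                    ) -> np.ndarray:
    """Fraction of a subject's fixations in each fitted AOI.

    Each point goes to its nearest center (lowest index on ties); the
    returned length-K vector is nonnegative and sums to 1.
    """
    if model.centers.size == 0:
        raise ValueError("model: not fitted (no centers)")
    assign = _assign(subject_points.points, model.centers)
    counts = np.bincount(assign, minlength=model.K).astype(float)
    return counts / counts.sum()


def gaze_feature_table(fixations: list[FixationSet], K: int = 8,
                       seed: int = 0, n_init: int = 10,
                       train_ids: set[str] | None = None,
                       ) -> tuple[pd.DataFrame, KMeansState]:
    """AOI-frequency feature matrix for a list of subjects.

    K-means is fitted on the pooled fixation points of the training
    subjects only (``train_ids``; all subjects when None) and every subject
    — training or held-out — is projected onto the fitted centers.  Returns
    the subjects x K frequency table (columns ``f1..fK``) and the fitted
    model.
    """
    if train_ids is None:
        train = fixations
    else:
        train = [f for f in fixations if f.subject_id in train_ids]
        if not train:
            raise ValueError("train_ids: no training subjects matched")
    pooled = np.vstack([f.points for f in train])
    model = kmeans_fit(pooled, K=K, seed=seed, n_init=n_init)
    rows = [aoi_frequencies(model, f) for f in fixations]
    df = pd.DataFrame(rows, index=[f.subject_id for f in fixations],
                      columns=[f"f{k + 1}" for k in range(K)])
    df.index.name = "subject_id"
    return df, model
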