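"""Similarity-preserving spherical embedding of a pathway collection.

Pathways are placed on the unit sphere so that the geodesic (great-
circle) distance between two pathways tracks their gene-component
dissimilarity: the target distance is ``(1 - s) * max_arc`` where ``s``
is the similarity score — identical pathways coincide, fully disjoint
ones sit ``max_arc`` apart (antipodal by default).

The layout is fitted by projected gradient descent on a normalized
Kruskal-type stress

    stress = sum_{i<j} (g_ij - d_ij)^2 / sum_{i<j} d_ij^2

with ``g`` the realized geodesic and ``d`` the target distance. Steps
that would increase stress are halved until they do not (monotone
descent), and the seeded uniform initialization makes a layout
bit-reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientInputError
from .model import PathwayCollection
from .similarity import similarity


def target_distances(
    collection: PathwayCollection, max_arc: float = math.pi
) -> dict[tuple[str, str], float]:
    """Target geodesic distance for every unordered pathway pair."""
    if len(collection) < 2:
        raise InsufficientInputError("target distances need at least 2 pathways")
    out: dict[tuple[str, str], float] = {}
    paths = collection.pathways
    for i, a in enumerate(paths):
        for b in paths[i + 1 :]:
            out[(a.id, b.id)] = (1.0 - similarity(a, b)) * max_arc
    return out


@dataclass(frozen=True)
class SphereLayout:
    """A fitted spherical layout.

    ``coordinates`` maps pathway id to a unit 3-vector; ``stress_history``
    records the stress after initialization and after every accepted
    step (non-increasing).
    """

    coordinates: dict[str, np.ndarray]
    target_d: dict[tuple[str, str], float]
    stress: float
    stress_history: tuple[float, ...]
    seed: int
    n_iterations: int

    def latlon_degrees(self) -> dict[str, tuple[float, float]]:
        """(latitude, longitude) in degrees for each pathway."""
        out = {}
        for pid, v in self.coordinates.items():
            lat = math.degrees(math.asin(max(-1.0, min(1.0, float(v[2])))))
            lon = math.degrees(math.atan2(float(v[1]), float(v[0])))
            out[pid] = (lat, lon)
        return out


def _stress(X: np.ndarray, D: np.ndarray, denom: float) -> float:
    G = np.arccos(np.clip(X @ X.T, -1.0, 1.0))
    iu = np.triu_indices(len(X), k=1)
    return float(((G[iu] - D[iu]) ** 2).sum() / denom)


def _gradient(X: np.ndarray, D: np.ndarray, denom: float) -> np.ndarray:
    U = np.clip(X @ X.T, -1.0 + 1e-9, 1.0 - 1e-9)
    G = np.arccos(U)
    R = G - D
    np.fill_diagonal(R, 0.0)
    # d g_ij / d x_i = -x_j / sqrt(1 - u_ij^2)
    W = -2.0 * R / np.sqrt(1.0 - U**2)
    np.fill_diagonal(W, 0.0)
    return (W @ X) / denom


def embed_sphere(
    collection: PathwayCollection,
    seed: int = 0,
    n_iterations: int = 500,
    *,
    max_arc: float = math.pi,
    initial_step: float = 0.5,
) -> SphereLayout:
    """Fit a spherical layout by monotone projected gradient descent.

    ``n_iterations`` bounds the number of accepted descent steps; the
    optimizer stops early when step halving can no longer reduce the
    stress. With ``n_iterations=0`` the seeded initial layout and its
    stress are returned unchanged. Identical seed and input give
    bit-identical coordinates.
    """
    if len(collection) < 3:
        raise InsufficientInputError("a non-degenerate layout needs at least 3 pathways")
    ids = collection.ids
    n = len(ids)
    targets = target_distances(collection, max_arc=max_arc)
    D = np.zeros((n, n))
    pos = {pid: i for i, pid in enumerate(ids)}
    for (a, b), d in targets.items():
        D[pos[a], pos[b]] = D[pos[b], pos[a]] = d
    iu = np.triu_indices(n, k=1)
    denom = float((D[iu] ** 2).sum())
    if denom == 0.0:  # all pathways identical: any single point is optimal
        denom = 1.0

    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 3))
    X /= np.linalg.norm(X, axis=1, keepdims=True)

    stress = _stress(X, D, denom)
    history = [stress]
    step = initial_step
    accepted = 0
    while accepted < n_iterations:
        grad = _gradient(X, D, denom)
        improved = False
        trial_step = step
        for _ in range(40):
            Y = X - trial_step * grad
            Y /= np.linalg.norm(Y, axis=1, keepdims=True)
            new = _stress(Y, D, denom)
            if new < stress:
                X, stress = Y, new
                step = trial_step * 1.2
                improved = True
                break
            trial_step *= 0.5
        if not improved:
            break
        history.append(stress)
        accepted += 1

    return SphereLayout(
        coordinates={pid: X[i].copy() for pid, i in pos.items()},
        target_d=targets,
        stress=stress,
        stress_history=tuple(history),
        seed=seed,
        n_iterations=accepted,
    )


def geodesic(u: np.ndarray, v: np.ndarray) -> float:
    """Great-circle distance between two unit vectors."""
    return float(np.arccos(np.clip(float(np.dot(u, v)), -1.0, 1.0)))
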