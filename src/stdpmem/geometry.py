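"""Memory-plane geometry and retrieval-quality metrics.

The harmonic storage input b(t) = sum_i sin(omega t - xi_i) m_i expands as
sin(omega t) u - cos(omega t) v with

    u = sum_i cos(xi_i) m_i,      v = sum_i sin(xi_i) m_i,

so the input trajectory is a closed orbit in the 2-D *memory plane*
S = span{u, v}.  Retrieval quality is measured by the scaled cosine
similarity s_i(t) = f_i^T g_i(t) / ||f_i||^2 between each original datum
f_i and its decoded counterpart g_i(t) = decode(x(t), r_i), averaged over
items into p(t) and over time into p-bar; and, for the semantic task, by
the cumulative role-fitness integrals
P^i_j(t) = int_{t0}^{t} |f_i^T decode(x(s), r_j)| ds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .dynamics import Trajectory
from .encoding import TagSet, decode_trajectory

__all__ = [
    "MemoryPlane",
    "RetrievalMetrics",
    "RoleFitness",
    "memory_plane",
    "plane_distance",
    "intersection_time",
    "retrieval_quality",
    "role_fitness",
    "dominance",
]


@dataclass
class MemoryPlane:
    """The plane S spanned by u and v, with an orthonormal basis.

    Degenerate inputs (u, v parallel or one zero) yield a 1-D "plane"
    with a single basis vector and ``degenerate = True``.
    """

    u: np.ndarray
    v: np.ndarray
    basis: np.ndarray            # (rank, N), orthonormal rows
    degenerate: bool = False

    @property
    def N(self) -> int:
        return self.u.size

    def project(self, x: np.ndarray) -> np.ndarray:
        coeffs = self.basis @ x
        return coeffs @ self.basis


def memory_plane(memories: np.ndarray, phases: np.ndarray) -> MemoryPlane:
    """Generators and orthonormal basis of the memory plane.

    u = sum cos(xi_i) m_i and v = sum sin(xi_i) m_i; the basis is obtained
    by an SVD of [u, v] with a rank tolerance, flagging the degenerate
    1-D case.
    """
    memories = np.atleast_2d(np.asarray(memories, dtype=float))
    phases = np.asarray(phases, dtype=float).ravel()
    if not np.any(np.linalg.norm(memories, axis=1) > 0):
        raise ValueError("all memories are zero; no plane is defined")
    u = np.cos(phases) @ memories
    v = np.sin(phases) @ memories
    G = np.vstack([u, v])
    U, s, Vt = np.linalg.svd(G, full_matrices=False)
    tol = max(s[0], 1.0) * 1e-12
    rank = int(np.sum(s > tol))
    rank = max(rank, 1)
    return MemoryPlane(u=u, v=v, basis=Vt[:rank], degenerate=(rank < 2))


def plane_distance(x: np.ndarray, plane: MemoryPlane) -> float:
    """Euclidean distance from x to its orthogonal projection onto S."""
    x = np.asarray(x, dtype=float).ravel()
    return float(np.linalg.norm(x - plane.project(x)))


def intersection_time(omega: float, k: int = 0) -> float:
    """Analytic plane-crossing time t-dagger = (arctan(omega) + k pi) / omega.

    The forced component of the retrieval orbit along the cue direction
    vanishes at these times, so the orbit meets the memory plane there;
    consecutive crossings are pi/omega apart.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    return (math.atan(omega) + k * math.pi) / omega


def last_intersection_time(omega: float, T: float) -> float:
    """The largest t-dagger not exceeding T (transients maximally decayed)."""
    k = int(math.floor((T * omega - math.atan(omega)) / math.pi))
    return intersection_time(omega, max(k, 0))


@dataclass
class RetrievalMetrics:
    """p(t) series, temporal average p-bar, and per-item similarities.

    ``similarities`` holds the signed per-item scaled cosine similarities
    s_i(t), shape (n_items, M).  ``p_series`` averages them over items
    (absolute values first in "absolute" mode); ``p_bar`` is the
    trapezoidal time-average of p(t).
    """

    times: np.ndarray
    p_series: np.ndarray
    p_bar: float
    similarities: np.ndarray
    mode: str = "absolute"
    P_curves: object | None = None

    def p_at(self, t: float) -> float:
        i = int(round((t - self.times[0]) / (self.times[1] - self.times[0])))
        i = min(max(i, 0), len(self.times) - 1)
        return float(self.p_series[i])


def retrieval_quality(traj: Trajectory, originals, tags: TagSet,
                      mode: str = "absolute") -> RetrievalMetrics:
    """Scaled-cosine retrieval metrics for a trajectory.

    For each item i, g_i(t) = decode(x(t), r_i) and
    s_i(t) = f_i^T g_i(t) / ||f_i||^2.  In the default "absolute" mode
    p(t) = mean_i |s_i(t)| (the retrieved items oscillate between positive
    and negative copies, so a signed time-average would cancel); "signed"
    averages the raw s_i(t).
    """
    if mode not in ("absolute", "signed"):
        raise ValueError("mode must be 'absolute' or 'signed'")
    originals = [np.asarray(f, dtype=float).ravel() for f in originals]
    sims = []
    for i, f in enumerate(originals):
        nf2 = float(f @ f)
        if nf2 == 0.0:
            raise ValueError(f"original vector {i} has zero norm")
        G = decode_trajectory(traj.states, tags[i])     # (M, D)
        sims.append(G @ f / nf2)
    S = np.vstack(sims)                                 # (n, M)
    p = np.mean(np.abs(S), axis=0) if mode == "absolute" else np.mean(S, axis=0)
    span = traj.times[-1] - traj.times[0]
    p_bar = float(np.trapezoid(p, traj.times) / span)
    return RetrievalMetrics(times=traj.times, p_series=p, p_bar=p_bar,
                            similarities=S, mode=mode)


@dataclass
class RoleFitness:
    """Cumulative role-fitness curves P^i_j(t), shape (n_words, n_roles, M)."""

    times: np.ndarray
    values: np.ndarray
    word_labels: list = field(default_factory=list)
    role_labels: list = field(default_factory=list)

    def curve(self, word, role) -> np.ndarray:
        i = self.word_labels.index(word) if isinstance(word, str) else word
        j = self.role_labels.index(role) if isinstance(role, str) else role
        return self.values[i, j]

    def final_slope(self, window_fraction: float = 0.5) -> np.ndarray:
        """Least-squares slope of each curve over the trailing window."""
        M = len(self.times)
        start = max(0, int(math.floor(M * (1.0 - window_fraction))))
        t = self.times[start:]
        tc = t - t.mean()
        denom = float(tc @ tc)
        Y = self.values[:, :, start:]
        return (Y - Y.mean(axis=2, keepdims=True)) @ tc / denom


def role_fitness(traj: Trajectory, words, roles: TagSet,
                 t0: float = 0.0,
                 word_labels: list | None = None) -> RoleFitness:
    """Cumulative integrals P^i_j(t) = int_{t0}^t |f_i^T decode(x, r_j)| ds.

    Trapezoidal quadrature on the trajectory grid; each curve is
    non-decreasing by construction.
    """
    if not (traj.times[0] <= t0 <= traj.times[-1]):
        raise ValueError("t0 outside the trajectory span")
    words = [np.asarray(f, dtype=float).ravel() for f in words]
    i0 = traj.index_of(t0)
    t = traj.times[i0:]
    curves = np.zeros((len(words), roles.m, len(t)))
    for j in range(roles.m):
        G = decode_trajectory(traj.states[i0:], roles[j])   # (M, D)
        for i, f in enumerate(words):
            integrand = np.abs(G @ f)
            curves[i, j, 1:] = cumulative_trapezoid(integrand, t)
    labels = list(word_labels) if word_labels else [str(i) for i in range(len(words))]
    return RoleFitness(times=t, values=curves, word_labels=labels,
                       role_labels=list(roles.labels))


def dominance(P_curves: RoleFitness, window_fraction: float = 0.5,
              threshold_fraction: float = 0.5) -> set:
    """Identify dominantly retrieved (word, role) components.

    A component is dominant within its role iff the least-squares slope of
    its P-curve over the trailing ``window_fraction`` of the grid is at
    least ``threshold_fraction`` times the largest slope in that role.
    """
    if P_curves.values.size == 0:
        raise ValueError("empty P-curve family")
    slopes = P_curves.final_slope(window_fraction)
    out = set()
    for j, role in enumerate(P_curves.role_labels):
        top = float(np.max(slopes[:, j]))
        if top <= 0.0:
            continue
        for i, word in enumerate(P_curves.word_labels):
            if slopes[i, j] >= threshold_fraction * top:
                out.add((word, role))
    return out
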