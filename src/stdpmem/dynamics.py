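"""Storage and retrieval dynamics of the STDP associative memory.

Storage integrates the coupled state/plasticity delay system

    x'(t) = -x + W x + b(t)
    W'(t) = -gamma W + rho (x x_tau^T - x_tau x^T),      x_tau = x(t - tau),

driven by the sequential harmonic memory input
``b(t) = sum_i sin(omega t - xi_i) m_i``.  The plasticity update is
antisymmetric by construction, so an antisymmetric W(0) (e.g. zero) stays
antisymmetric for all time; with suitable parameters W converges to a
near-rank-2 fixed point ``W* = alpha (v u^T - u v^T)`` whose generators
span the memory plane.

Retrieval freezes plasticity (gamma = rho = 0) and integrates the linear
forced system ``x' = -x + W* x + b_c(t)`` under a (possibly composite,
possibly noisy) cue.  Because this system is linear with sinusoidal
forcing, its unique periodic solution is available in closed form
(:func:`phasor_steady_state`) and serves as an independent oracle for the
numerical integrator.

Both phases use Heun's predictor-corrector (a modified Euler scheme,
second order); the delayed state is linearly interpolated on the stored
trajectory grid, with the constant pre-history x(s) = x(0) for s <= 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg.blas import dger

__all__ = [
    "ModelParams",
    "StorageInputSpec",
    "CueSpec",
    "Trajectory",
    "DenseConnectivity",
    "FactoredConnectivity",
    "StorageResult",
    "ConvergenceReport",
    "storage_input",
    "cue_input",
    "integrate_storage",
    "integrate_retrieval",
    "phasor_steady_state",
    "check_convergence",
    "random_antisymmetric",
]

ANTISYM_TOL = 1e-10


@dataclass
class ModelParams:
    """Parameters of the storage dynamics.

    omega : forcing frequency (rad / time unit), default 1.5
    gamma : homeostatic decay rate of W (1 / time unit), default 0.5
    rho   : learning rate (1 / time unit), default 0.5
    tau   : synaptic delay (time units), default pi / (2 omega) = pi / 3
    dt    : integration step (time units), default 0.1
    T     : storage duration (time units), default 40
    """

    omega: float = 1.5
    gamma: float = 0.5
    rho: float = 0.5
    tau: float = math.pi / 3.0
    dt: float = 0.1
    T: float = 40.0

    def __post_init__(self) -> None:
        for name in ("omega", "tau", "dt", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gamma", "rho"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tau >= self.T:
            raise ValueError("tau must be smaller than the duration T")

    @property
    def period(self) -> float:
        return 2.0 * math.pi / self.omega


@dataclass
class StorageInputSpec:
    """The harmonic memory input b(t) = sum_i sin(omega t - xi_i) m_i."""

    memories: np.ndarray          # (n, N)
    phases: np.ndarray            # (n,) sampling phases xi_i in [0, pi)
    omega: float = 1.5

    def __post_init__(self) -> None:
        self.memories = np.atleast_2d(np.asarray(self.memories, dtype=float))
        self.phases = np.asarray(self.phases, dtype=float).ravel()
        if len(self.phases) != len(self.memories):
            raise ValueError("one phase per memory required")
        if len(self.phases) > 1 and np.any(np.diff(self.phases) <= 0):
            raise ValueError("phases must be strictly increasing")

    @property
    def n(self) -> int:
        return self.memories.shape[0]

    @property
    def N(self) -> int:
        return self.memories.shape[1]

    def __call__(self, t: float) -> np.ndarray:
        return storage_input(self, t)


@dataclass
class CueSpec:
    """A retrieval cue b_c(t) = sum_c sin(omega t - xi_c) m_c.

    A single-component cue uses xi = 0, reducing to sin(omega t) m_c.
    """

    components: list              # list of (m, xi) pairs
    omega: float = 1.5

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("cue must have at least one component")
        comps = []
        N = None
        for m, xi in self.components:
            m = np.asarray(m, dtype=float).ravel()
            if N is None:
                N = m.size
            elif m.size != N:
                raise ValueError("cue components must share length")
            comps.append((m, float(xi)))
        self.components = comps

    @classmethod
    def single(cls, m: np.ndarray, omega: float = 1.5) -> "CueSpec":
        return cls(components=[(m, 0.0)], omega=omega)

    @property
    def N(self) -> int:
        return self.components[0][0].size

    def __call__(self, t: float) -> np.ndarray:
        return cue_input(self, t)


def storage_input(spec: StorageInputSpec, t: float) -> np.ndarray:
    """Evaluate b(t) = sum_i sin(omega t - xi_i) m_i."""
    coeff = np.sin(spec.omega * t - spec.phases)
    return coeff @ spec.memories


def cue_input(spec: CueSpec, t: float) -> np.ndarray:
    """Evaluate the (possibly multi-component) cue input at time t."""
    out = np.zeros(spec.N)
    for m, xi in spec.components:
        out += math.sin(spec.omega * t - xi) * m
    return out


# ---------------------------------------------------------------------------
# Connectivity representations
# ---------------------------------------------------------------------------

class DenseConnectivity:
    """An explicit N x N connectivity matrix."""

    def __init__(self, W: np.ndarray):
        self.W = np.asarray(W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")

    @property
    def N(self) -> int:
        return self.W.shape[0]

    def matvec(self, x: np.ndarray) -> np.ndarray:
        return self.W @ x

    def to_dense(self) -> np.ndarray:
        return self.W

    def copy(self) -> "DenseConnectivity":
        return DenseConnectivity(self.W.copy())

    def frob(self) -> float:
        return float(np.linalg.norm(self.W))

    def inner(self, other: "DenseConnectivity") -> float:
        return float(np.tensordot(self.W, other.to_dense(), axes=2))

    def antisymmetry_defect(self) -> float:
        return float(np.linalg.norm(self.W + self.W.T) / max(1.0, self.frob()))

    def singular_values(self, k: int | None = None) -> np.ndarray:
        sv = np.linalg.svd(self.W, compute_uv=False)
        return sv if k is None else sv[:k]

    def solve_shifted(self, a: complex, m: np.ndarray) -> np.ndarray:
        """Solve (a I - W) z = m."""
        A = a * np.eye(self.N) - self.W
        return np.linalg.solve(A, m.astype(complex))

    def __add__(self, other):
        return DenseConnectivity(self.W + other.to_dense())


class FactoredConnectivity:
    """Antisymmetric connectivity in compressed form W = Q B Q^T.

    Q is N x r with orthonormal columns and B is a small antisymmetric
    r x r core.  Outer-product plasticity increments
    ``a (p q^T - q p^T)`` are buffered and folded into the core by
    :meth:`consolidate` (QR of the enlarged basis followed by spectral
    truncation of the core at ``trunc_tol`` relative), so storage at large
    N never materializes an N x N array.  Agrees with the dense
    representation to near machine precision on small problems.
    """

    def __init__(self, N: int, trunc_tol: float = 1e-13):
        self.N_ = int(N)
        self.trunc_tol = float(trunc_tol)
        self.Q = np.zeros((self.N_, 0))
        self.B = np.zeros((0, 0))
        self._pend: list = []        # (p, q, coeff) with W += c (p q^T - q p^T)

    @property
    def N(self) -> int:
        return self.N_

    @property
    def rank(self) -> int:
        return self.B.shape[0]

    def scale_by(self, c: float) -> None:
        if self.B.size:
            self.B *= c
        if self._pend:
            self._pend = [(p, q, a * c) for p, q, a in self._pend]

    def add_pair(self, p: np.ndarray, q: np.ndarray, coeff: float) -> None:
        self._pend.append((p.copy(), q.copy(), float(coeff)))

    def matvec(self, x: np.ndarray) -> np.ndarray:
        y = self.Q @ (self.B @ (self.Q.T @ x)) if self.B.size else np.zeros(self.N_)
        for p, q, a in self._pend:
            y += a * (p * (q @ x) - q * (p @ x))
        return y

    def consolidate(self) -> None:
        if not self._pend:
            return
        k = len(self._pend)
        V = np.empty((self.N_, self.rank + 2 * k))
        V[:, : self.rank] = self.Q
        A = np.zeros((self.rank + 2 * k, self.rank + 2 * k))
        A[: self.rank, : self.rank] = self.B
        for j, (p, q, a) in enumerate(self._pend):
            c0 = self.rank + 2 * j
            V[:, c0] = p
            V[:, c0 + 1] = q
            A[c0, c0 + 1] = a
            A[c0 + 1, c0] = -a
        self._pend = []
        Qn, R = np.linalg.qr(V)
        Bn = R @ A @ R.T
        Bn = 0.5 * (Bn - Bn.T)
        # spectral truncation via the PSD square (eigenpairs of antisym core)
        C = Bn @ Bn.T
        w, E = np.linalg.eigh(C)
        smax = math.sqrt(max(w[-1], 0.0))
        if smax == 0.0:
            self.Q = np.zeros((self.N_, 0))
            self.B = np.zeros((0, 0))
            return
        keep = np.sqrt(np.maximum(w, 0.0)) > self.trunc_tol * smax
        E = E[:, keep]
        self.Q = Qn @ E
        self.B = E.T @ Bn @ E

    def to_dense(self) -> np.ndarray:
        self.consolidate()
        return self.Q @ self.B @ self.Q.T

    def copy(self) -> "FactoredConnectivity":
        self.consolidate()
        out = FactoredConnectivity(self.N_, self.trunc_tol)
        out.Q = self.Q.copy()
        out.B = self.B.copy()
        return out

    def frob(self) -> float:
        self.consolidate()
        return float(np.linalg.norm(self.B))

    def inner(self, other) -> float:
        self.consolidate()
        if isinstance(other, FactoredConnectivity):
            other.consolidate()
            M = self.Q.T @ other.Q
            return float(np.trace(self.B.T @ M @ other.B @ M.T))
        return float(np.tensordot(self.to_dense(), other.to_dense(), axes=2))

    def antisymmetry_defect(self) -> float:
        self.consolidate()
        if not self.B.size:
            return 0.0
        return float(np.linalg.norm(self.B + self.B.T)
                     / max(1.0, np.linalg.norm(self.B)))

    def singular_values(self, k: int | None = None) -> np.ndarray:
        self.consolidate()
        sv = np.sort(np.linalg.svd(self.B, compute_uv=False))[::-1] \
            if self.B.size else np.zeros(0)
        full = np.zeros(self.N_)
        full[: sv.size] = sv
        return full if k is None else full[:k]

    def solve_shifted(self, a: complex, m: np.ndarray) -> np.ndarray:
        """Solve (a I - W) z = m via the low-rank (Woodbury) identity."""
        self.consolidate()
        m = np.asarray(m, dtype=complex)
        if not self.B.size:
            return m / a
        r = self.rank
        C = np.linalg.solve(a * np.eye(r) - self.B.astype(complex), self.B.astype(complex))
        return (m + self.Q @ (C @ (self.Q.T @ m))) / a


def random_antisymmetric(N: int, seed: int, scale: float | None = None) -> DenseConnectivity:
    """A seeded random antisymmetric matrix with O(1) spectral norm."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((N, N))
    W = (A - A.T) / (2.0 * math.sqrt(N))
    if scale is not None:
        sv = np.linalg.svd(W, compute_uv=False)[0]
        if sv > 0:
            W *= scale / sv
    return DenseConnectivity(W)


# ---------------------------------------------------------------------------
# Trajectories and integration
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """A uniformly-sampled trajectory: times (M+1,), states (M+1, N)."""

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if len(self.times) != len(self.states):
            raise ValueError("times and states length mismatch")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def index_of(self, t: float) -> int:
        """Nearest grid index to time t (clipped to the grid)."""
        i = int(round((t - self.times[0]) / self.dt))
        return min(max(i, 0), len(self.times) - 1)

    def at(self, t: float) -> np.ndarray:
        return self.states[self.index_of(t)]


@dataclass
class StorageResult:
    trajectory: Trajectory
    snapshots: list
    snapshot_times: list


@dataclass
class ConvergenceReport:
    converged: bool
    Wstar: object
    rel_change: float
    message: str = ""


def _delayed_state(states: np.ndarray, x0: np.ndarray, n_done: int,
                   s: float, dt: float) -> np.ndarray:
    """x(s) by linear interpolation on the grid; constant history for s<=0."""
    if s <= 0.0:
        return x0
    pos = s / dt
    j = int(pos)
    theta = pos - j
    if j >= n_done:
        return states[n_done]
    if theta == 0.0:
        return states[j]
    return (1.0 - theta) * states[j] + theta * states[j + 1]


def _check_finite(x: np.ndarray, step: int, t: float) -> None:
    if not np.all(np.isfinite(x)):
        raise FloatingPointError(
            f"state became non-finite at step {step} (t={t:.4f}); "
            "the integration blew up"
        )


def default_initial_state(spec: StorageInputSpec, seed: int = 0) -> np.ndarray:
    """An 'appropriately small' random initial state: i.i.d. normal entries
    with std 1e-3 * max(1, max_i ||m_i||_inf)."""
    rng = np.random.default_rng(seed)
    scale = 1e-3 * max(1.0, float(np.max(np.abs(spec.memories))))
    return scale * rng.standard_normal(spec.N)


def integrate_storage(params: ModelParams, spec: StorageInputSpec,
                      x0: np.ndarray | None = None,
                      W0=None, seed: int = 0,
                      mode: str = "auto",
                      snapshot_every: float | None = None) -> StorageResult:
    """Integrate the coupled state/plasticity delay system (Heun scheme).

    Returns the full state trajectory and connectivity snapshots taken once
    per forcing period (plus the final time).  ``mode`` selects the dense
    N x N representation of W or the low-memory factored one ("dense",
    "factored", or "auto": factored for N > 10_000).
    """
    N = spec.N
    dt, tau = params.dt, params.tau
    if tau < dt:
        raise ValueError("tau must be at least one integration step dt")
    if x0 is None:
        x0 = default_initial_state(spec, seed=seed)
    x0 = np.asarray(x0, dtype=float).ravel()
    if x0.size != N:
        raise ValueError("x0 length mismatch")

    if mode == "auto":
        mode = "factored" if N > 10_000 else "dense"
    if mode == "dense":
        W = DenseConnectivity(np.zeros((N, N)) if W0 is None
                              else np.array(W0.to_dense() if hasattr(W0, "to_dense")
                                            else W0, dtype=float))
    elif mode == "factored":
        if W0 is not None and getattr(W0, "frob", lambda: 0.0)() != 0.0:
            raise ValueError("factored mode starts from W(0) = 0")
        W = FactoredConnectivity(N)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    steps = int(round(params.T / dt))
    times = np.arange(steps + 1) * dt
    states = np.empty((steps + 1, N))
    states[0] = x0

    gdt = params.gamma * dt
    c_decay = 1.0 - gdt + 0.5 * gdt * gdt       # Heun decay factor for W
    a1 = 0.5 * params.rho * dt * (1.0 - gdt)    # weight of the stage-1 update
    a2 = 0.5 * params.rho * dt                  # weight of the stage-2 update

    snap_dt = snapshot_every if snapshot_every is not None else params.period
    snap_step = max(1, int(round(snap_dt / dt)))
    snapshots, snap_times = [], []

    for n in range(steps):
        t0, t1 = times[n], times[n + 1]
        x = states[n]
        xt0 = _delayed_state(states, x0, n, t0 - tau, dt)
        xt1 = _delayed_state(states, x0, n, t1 - tau, dt)
        b0, b1 = spec(t0), spec(t1)

        k1 = -x + W.matvec(x) + b0
        xp = x + dt * k1                         # predictor state

        if mode == "dense":
            Wt_xp = (1.0 - gdt) * (W.W @ xp) + params.rho * dt * (
                x * (xt0 @ xp) - xt0 * (x @ xp))
            k2 = -xp + Wt_xp + b1
            # in-place rank-1 plasticity updates (W += a (p q^T - q p^T))
            W.W *= c_decay
            WT = W.W.T            # F-contiguous view; dger(a, q, p, WT) does W += a p q^T
            dger(a1, xt0, x, a=WT, overwrite_a=1)
            dger(-a1, x, xt0, a=WT, overwrite_a=1)
            dger(a2, xt1, xp, a=WT, overwrite_a=1)
            dger(-a2, xp, xt1, a=WT, overwrite_a=1)
        else:
            Wxp = W.matvec(xp)
            Wt_xp = (1.0 - gdt) * Wxp + params.rho * dt * (
                x * (xt0 @ xp) - xt0 * (x @ xp))
            k2 = -xp + Wt_xp + b1
            W.scale_by(c_decay)
            W.add_pair(x, xt0, a1)
            W.add_pair(xp, xt1, a2)

        states[n + 1] = x + 0.5 * dt * (k1 + k2)
        _check_finite(states[n + 1], n + 1, t1)

        if (n + 1) % snap_step == 0:
            snapshots.append(W.copy())
            snap_times.append(float(t1))

    if not snap_times or snap_times[-1] != float(times[-1]):
        snapshots.append(W.copy())
        snap_times.append(float(times[-1]))

    return StorageResult(Trajectory(times, states), snapshots, snap_times)


def integrate_retrieval(Wstar, cue: CueSpec,
                        x0: np.ndarray | None = None,
                        dt: float = 0.01, T: float = 15.0,
                        seed: int = 0) -> Trajectory:
    """Integrate the linear retrieval system x' = -x + W* x + b_c(t).

    Plasticity is frozen; no delay term remains.  ``Wstar`` may be dense or
    factored (anything with a ``matvec``).
    """
    N = cue.N
    if x0 is None:
        rng = np.random.default_rng(seed)
        scale = 1e-3 * max(1.0, float(max(np.max(np.abs(m))
                                          for m, _ in cue.components)))
        x0 = scale * rng.standard_normal(N)
    x0 = np.asarray(x0, dtype=float).ravel()
    if x0.size != N:
        raise ValueError("x0 length mismatch")

    steps = int(round(T / dt))
    times = np.arange(steps + 1) * dt
    states = np.empty((steps + 1, N))
    states[0] = x0
    b_prev = cue(times[0])
    for n in range(steps):
        x = states[n]
        b1 = cue(times[n + 1])
        k1 = -x + Wstar.matvec(x) + b_prev
        xp = x + dt * k1
        k2 = -xp + Wstar.matvec(xp) + b1
        states[n + 1] = x + 0.5 * dt * (k1 + k2)
        _check_finite(states[n + 1], n + 1, times[n + 1])
        b_prev = b1
    return Trajectory(times, states)


class PhasorSolution:
    """The unique periodic solution of the linear retrieval system.

    For each cue component sin(omega t - xi) m the complex amplitude z
    solves ((1 + i omega) I - W*) z = m, and the solution is
    x_c(t) = sum Im(exp(i (omega t - xi)) z).  Callable on scalar times or
    1-D time arrays.
    """

    def __init__(self, omega: float, parts: list):
        self.omega = omega
        self.parts = parts              # list of (z complex (N,), xi)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        tt = np.atleast_1d(t)
        out = np.zeros((tt.size, self.parts[0][0].size))
        for z, xi in self.parts:
            phase = self.omega * tt - xi
            out += (np.sin(phase)[:, None] * z.real[None, :]
                    + np.cos(phase)[:, None] * z.imag[None, :])
        return out[0] if scalar else out


def phasor_steady_state(Wstar, cue: CueSpec) -> PhasorSolution:
    """Closed-form periodic solution of x' = -x + W* x + b_c(t).

    Exists and is unique because W* is antisymmetric: its eigenvalues are
    purely imaginary, so (1 + i omega) I - W* is nonsingular.
    """
    a = 1.0 + 1j * cue.omega
    parts = []
    for m, xi in cue.components:
        z = Wstar.solve_shifted(a, m)
        parts.append((z, xi))
    return PhasorSolution(cue.omega, parts)


def check_convergence(snapshots: list, omega: float,
                      tol: float = 1e-2,
                      times: list | None = None) -> ConvergenceReport:
    """Per-period Frobenius convergence test on connectivity snapshots.

    Converged iff ||W(t_end) - W(t_end - 2 pi / omega)||_F / ||W(t_end)||_F
    < tol.  When snapshot ``times`` are given, the comparison snapshot is
    the one closest to a full forcing period before the end; otherwise the
    snapshots are assumed period-spaced and the last two are compared.
    Returns the last snapshot as W*.
    """
    if len(snapshots) < 2:
        raise ValueError("need at least two snapshots spanning two periods")
    W_end = snapshots[-1]
    if times is not None:
        if len(times) != len(snapshots):
            raise ValueError("times and snapshots length mismatch")
        target = times[-1] - 2.0 * math.pi / omega
        j = int(np.argmin(np.abs(np.asarray(times[:-1]) - target)))
        W_prev = snapshots[j]
    else:
        W_prev = snapshots[-2]
    n_end = W_end.frob()
    if n_end == 0.0:
        return ConvergenceReport(False, W_end, float("inf"),
                                 "all-zero connectivity: nothing was stored")
    diff = math.sqrt(max(W_end.frob() ** 2 + W_prev.frob() ** 2
                         - 2.0 * W_end.inner(W_prev), 0.0))
    rel = diff / n_end
    return ConvergenceReport(rel < tol, W_end, rel,
                             f"relative per-period change {rel:.3e}")
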