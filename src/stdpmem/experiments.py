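"""End-to-end storage/retrieval experiments on synthetic fixtures.

Two task families:

* **Grouped images** — n synthetic grayscale images are vectorized
  (brightness mapped to [-sigma, sigma]), bound to orthonormal placeholder
  tags, streamed into the plasticity dynamics as a harmonic pulse train,
  and retrieved from exact, noisy, occluded, or irrelevant cues.  Quality
  is measured by the scaled cosine similarity p(t), its time average
  p-bar, and p at the analytic plane-crossing time t-dagger.

* **Semantic sentences** — 8 orthonormal word vectors and 4 orthonormal
  role vectors (subject / predicate / object / modifier) encode three
  sentences; each sentence is stored separately and the converged
  connectivities are summed.  Cues are word-role bindings (possibly
  composite); the retrieved content is read off the cumulative
  role-fitness curves P^i_j(t) and their dominance pattern.

A capacity sweep with random unit patterns (D=200, K=20) measures how
p-bar decays with the number n of simultaneously stored memories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (CueSpec, ModelParams, StorageInputSpec, Trajectory,
                       check_convergence, integrate_retrieval,
                       integrate_storage)
from .encoding import (ImageSpec, TagSet, encode, image_to_vector,
                       make_tag_set, synth_image, vector_to_image)
from .geometry import (MemoryPlane, RetrievalMetrics, RoleFitness, dominance,
                       last_intersection_time, memory_plane, plane_distance,
                       retrieval_quality, role_fitness)

__all__ = [
    "NoiseSpec",
    "SentenceSpec",
    "ImageTaskReport",
    "CapacityResult",
    "SemanticTaskReport",
    "make_noisy_cue",
    "occlude",
    "run_image_task",
    "run_capacity_sweep",
    "build_sentences",
    "run_semantic_task",
    "store_group",
    "WORDS",
    "ROLES",
]


@dataclass
class NoiseSpec:
    """Cue contamination levels: data noise alpha, tag noise beta, both in
    [0, 1], plus the seed for the noise draws."""

    alpha: float = 0.25
    beta: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("alpha and beta must lie in [0, 1]")


def make_noisy_cue(f: np.ndarray, r: np.ndarray, noise: NoiseSpec,
                   renormalize_tag: bool = False) -> np.ndarray:
    """Contaminated cue  m_c = f~ (x) r~  with

        f~ = sqrt(1 - alpha^2) f + alpha zeta,    ||zeta|| = ||f||,
        r~ = sqrt(1 - beta^2) r + beta eta,       ||eta|| = 1,

    zeta and eta isotropic random directions.  With the noise scaled to the
    signal norm, ||f~|| stays close to ||f|| for every alpha.  The tag is
    not re-normalized by default (matching the construction as printed);
    pass ``renormalize_tag=True`` to force a unit tag.
    """
    f = np.asarray(f, dtype=float).ravel()
    r = np.asarray(r, dtype=float).ravel()
    rng = np.random.default_rng(noise.seed)
    zeta = rng.standard_normal(f.size)
    zeta *= np.linalg.norm(f) / np.linalg.norm(zeta)
    eta = rng.standard_normal(r.size)
    eta /= np.linalg.norm(eta)
    f_t = math.sqrt(1.0 - noise.alpha ** 2) * f + noise.alpha * zeta
    r_t = math.sqrt(1.0 - noise.beta ** 2) * r + noise.beta * eta
    if renormalize_tag:
        r_t /= np.linalg.norm(r_t)
    return encode(f_t, r_t, check=False)


def noisy_tag(r: np.ndarray, beta: float, seed: int) -> np.ndarray:
    """The tag-noise half of :func:`make_noisy_cue` on its own."""
    r = np.asarray(r, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    eta = rng.standard_normal(r.size)
    eta /= np.linalg.norm(eta)
    return math.sqrt(1.0 - beta ** 2) * r + beta * eta


def occlude(img: ImageSpec, box: tuple) -> ImageSpec:
    """Obstruct a rectangular region: pixels set to mid-gray 0.5, which
    maps to 0 in vector space.  ``box`` is (row, col, height, width)."""
    row, col, h, w = box
    H, W = img.pixels.shape
    if row < 0 or col < 0 or h < 0 or w < 0 or row + h > H or col + w > W:
        raise ValueError(f"box {box} outside image bounds {(H, W)}")
    pixels = img.pixels.copy()
    pixels[row:row + h, col:col + w] = 0.5
    return ImageSpec(pixels=pixels, sigma=img.sigma)


def _child_seeds(seed: int, n: int) -> list:
    """Deterministic independent integer seeds derived from one seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1, dtype=np.uint32)[0]) for c in ss.spawn(n)]


def store_group(memories: np.ndarray, phases: np.ndarray,
                params: ModelParams, seed: int = 0, mode: str = "auto"):
    """Store one memory group; returns (ConvergenceReport, StorageResult)."""
    spec = StorageInputSpec(memories=memories, phases=phases,
                            omega=params.omega)
    result = integrate_storage(params, spec, seed=seed, mode=mode)
    report = check_convergence(result.snapshots, params.omega,
                               times=result.snapshot_times)
    return report, result


@dataclass
class ImageTaskReport:
    images: list
    originals: list
    tags: TagSet
    plane: MemoryPlane
    Wstar: object
    converged: bool
    conv_rel_change: float
    trajectory: Trajectory
    metrics: RetrievalMetrics
    t_dagger: float
    p_at_t_dagger: float
    cosines_at_t_dagger: np.ndarray
    t_farthest: float
    snapshots_intersection: list
    snapshots_farthest: list
    cue_mode: str
    provenance: dict = field(default_factory=dict)


def run_image_task(n_images: int = 5, image_size: tuple = (16, 16),
                   params: ModelParams | None = None,
                   cue_mode: str = "noisy",
                   noise: NoiseSpec | None = None,
                   seed: int = 0, sigma: float = 0.02,
                   style: str = "blobs",
                   retrieval_T: float = 15.0, retrieval_dt: float = 0.01,
                   sigma_display: float = 0.002,
                   occlusion_box: tuple | None = None,
                   mode: str = "auto") -> ImageTaskReport:
    """The grouped-image experiment end to end.

    Cue modes: ``exact`` (the stored representation m_1), ``noisy``
    (contaminated data and tag), ``occluded`` (first image partially
    obstructed, noisy tag), ``irrelevant`` (an independently generated
    image never stored, noisy tag).
    """
    if cue_mode not in ("exact", "noisy", "occluded", "irrelevant"):
        raise ValueError(f"unknown cue_mode {cue_mode!r}")
    params = params or ModelParams()
    H, W = image_size
    seeds = _child_seeds(seed, 5)
    img_seeds = _child_seeds(seeds[0], n_images)
    noise = noise or NoiseSpec(seed=seeds[3])

    images = [synth_image(s, H, W, style=style, sigma=sigma)
              for s in img_seeds]
    fs = [image_to_vector(img) for img in images]
    tags = make_tag_set(n_images, n_images, seed=seeds[1])
    memories = np.array([encode(f, tags[i]) for i, f in enumerate(fs)])
    phases = np.pi * np.arange(n_images) / n_images

    report, storage = store_group(memories, phases, params,
                                  seed=seeds[2], mode=mode)
    Wstar = report.Wstar
    plane = memory_plane(memories, phases)

    if cue_mode == "exact":
        m_c = memories[0]
    elif cue_mode == "noisy":
        m_c = make_noisy_cue(fs[0], tags[0], noise)
    elif cue_mode == "occluded":
        box = occlusion_box or (0, 0, H, W // 2)
        f_occ = image_to_vector(occlude(images[0], box))
        m_c = encode(f_occ, noisy_tag(tags[0], noise.beta, noise.seed),
                     check=False)
    else:  # irrelevant: an image the system never saw
        img_irr = synth_image(_child_seeds(seeds[4], 1)[0], H, W,
                              style=style, sigma=sigma)
        m_c = encode(image_to_vector(img_irr),
                     noisy_tag(tags[0], noise.beta, noise.seed), check=False)

    cue = CueSpec.single(m_c, omega=params.omega)
    traj = integrate_retrieval(Wstar, cue, dt=retrieval_dt, T=retrieval_T,
                               seed=seeds[2])
    metrics = retrieval_quality(traj, fs, tags, mode="absolute")

    t_dag = last_intersection_time(params.omega, retrieval_T)
    i_dag = traj.index_of(t_dag)
    x_dag = traj.states[i_dag]

    cosines = np.empty(n_images)
    decoded_dag = []
    for i, f in enumerate(fs):
        g = x_dag.reshape(len(f), n_images) @ tags[i]
        ng = np.linalg.norm(g)
        cosines[i] = abs(f @ g) / (np.linalg.norm(f) * ng) if ng > 0 else 0.0
        decoded_dag.append(g)

    # farthest-from-plane grid time within the final forcing period
    period = params.period
    i_lo = traj.index_of(retrieval_T - period)
    dists = [plane_distance(traj.states[i], plane)
             for i in range(i_lo, len(traj.times))]
    i_far = i_lo + int(np.argmax(dists))
    t_far = float(traj.times[i_far])
    x_far = traj.states[i_far]

    snaps_dag = [vector_to_image(g, H, W, sigma_display) for g in decoded_dag]
    snaps_far = [vector_to_image(x_far.reshape(len(fs[i]), n_images) @ tags[i],
                                 H, W, sigma_display)
                 for i in range(n_images)]

    return ImageTaskReport(
        images=images, originals=fs, tags=tags, plane=plane, Wstar=Wstar,
        converged=report.converged, conv_rel_change=report.rel_change,
        trajectory=traj, metrics=metrics,
        t_dagger=float(traj.times[i_dag]),
        p_at_t_dagger=metrics.p_at(t_dag),
        cosines_at_t_dagger=cosines,
        t_farthest=t_far,
        snapshots_intersection=snaps_dag, snapshots_farthest=snaps_far,
        cue_mode=cue_mode,
        provenance={"seed": seed, "n_images": n_images,
                    "image_size": list(image_size), "sigma": sigma,
                    "style": style, "cue_mode": cue_mode,
                    "alpha": noise.alpha, "beta": noise.beta,
                    "noise_seed": noise.seed,
                    "params": vars(params).copy()},
    )


@dataclass
class CapacityResult:
    table: pd.DataFrame          # columns: n, mean_pbar, std_pbar
    slope: float                 # log-log slope of mean p-bar vs n
    pbar_values: dict            # n -> list of per-rep p-bar


def run_capacity_sweep(n_values=(2, 4, 8, 16), D: int = 200, K: int = 20,
                       reps: int = 5, seed: int = 0,
                       params: ModelParams | None = None,
                       retrieval_T: float = 15.0,
                       retrieval_dt: float = 0.01,
                       mode: str = "factored") -> CapacityResult:
    """Memory capacity: mean p-bar versus the number of stored patterns.

    Patterns are seeded random unit vectors in R^D with orthonormal tags in
    R^K; the cue is the first stored representation (clean).  The factored
    connectivity keeps the N = D*K = 4000 default tractable.
    """
    n_values = sorted(int(n) for n in n_values)
    if max(n_values) > K:
        raise ValueError("cannot store more patterns than tag dimensions")
    params = params or ModelParams()
    pbar_values: dict = {n: [] for n in n_values}
    rep_seeds = _child_seeds(seed, reps)
    for rep in range(reps):
        sub = _child_seeds(rep_seeds[rep], 2 * len(n_values))
        for k, n in enumerate(n_values):
            rng = np.random.default_rng(sub[2 * k])
            F = rng.standard_normal((n, D))
            F /= np.linalg.norm(F, axis=1, keepdims=True)
            tags = make_tag_set(n, K, seed=sub[2 * k + 1])
            memories = np.array([encode(F[i], tags[i]) for i in range(n)])
            phases = np.pi * np.arange(n) / n
            report, _ = store_group(memories, phases, params,
                                    seed=sub[2 * k], mode=mode)
            cue = CueSpec.single(memories[0], omega=params.omega)
            traj = integrate_retrieval(report.Wstar, cue, dt=retrieval_dt,
                                       T=retrieval_T, seed=sub[2 * k])
            metrics = retrieval_quality(traj, list(F), tags)
            pbar_values[n].append(metrics.p_bar)
    rows = [(n, float(np.mean(v)), float(np.std(v)))
            for n, v in pbar_values.items()]
    table = pd.DataFrame(rows, columns=["n", "mean_pbar", "std_pbar"])
    slope = float(np.polyfit(np.log(table["n"]),
                             np.log(table["mean_pbar"]), 1)[0])
    return CapacityResult(table=table, slope=slope, pbar_values=pbar_values)


# ---------------------------------------------------------------------------
# Semantic sentences
# ---------------------------------------------------------------------------

WORDS = ["Mary", "John", "calling", "livingroom",
         "chasing", "dog", "looking", "garden"]
ROLES = ["S", "P", "O", "M"]

# (word, role) bindings per sentence:
#   S1: Mary is calling John in the living room
#   S2: John is chasing the dog in the garden
#   S3: John is looking at Mary in the garden
_SENTENCES = [
    [("Mary", "S"), ("calling", "P"), ("John", "O"), ("livingroom", "M")],
    [("John", "S"), ("chasing", "P"), ("dog", "O"), ("garden", "M")],
    [("John", "S"), ("looking", "P"), ("Mary", "O"), ("garden", "M")],
]


@dataclass
class SentenceSpec:
    """Ordered (word index, role index) bindings of one sentence; roles
    within a sentence are distinct."""

    bindings: list
    label: str = ""

    def __post_init__(self) -> None:
        roles = [j for _, j in self.bindings]
        if len(set(roles)) != len(roles):
            raise ValueError("roles within one sentence must be distinct")


def build_sentences(D: int = 8, K: int = 4, seed: int = 7):
    """The three-sentence vocabulary: 8 orthonormal word vectors, 4
    orthonormal role vectors, and the sentence bindings.

    John occurs once as an object (S1) and twice as a subject (S2, S3);
    Mary and garden also recur across sentences.
    """
    if D < len(WORDS) or K < len(ROLES):
        raise ValueError("need D >= 8 and K >= 4 for orthonormal sets")
    word_seeds, role_seed = _child_seeds(seed, 2)
    words = make_tag_set(len(WORDS), D, seed=word_seeds, labels=WORDS)
    roles = make_tag_set(len(ROLES), K, seed=role_seed, labels=ROLES)
    sentences = [
        SentenceSpec(bindings=[(WORDS.index(w), ROLES.index(r))
                               for w, r in bindings], label=f"S{k + 1}")
        for k, bindings in enumerate(_SENTENCES)
    ]
    return words, roles, sentences


@dataclass
class SemanticTaskReport:
    words: TagSet
    roles: TagSet
    sentences: list
    Wstar: object
    converged: list
    trajectory: Trajectory
    P_curves: RoleFitness
    dominant: set
    cue_description: list
    provenance: dict = field(default_factory=dict)


def run_semantic_task(cue_components: list,
                      params: ModelParams | None = None,
                      retrieval_T: float = 30.0, retrieval_dt: float = 0.01,
                      seed: int = 7, t0: float = 0.0,
                      window_fraction: float = 0.5,
                      threshold_fraction: float = 0.5) -> SemanticTaskReport:
    """Store the three sentences, combine the connectivities, retrieve.

    ``cue_components`` is a list of (word, role) label pairs, e.g.
    ``[("John", "S"), ("Mary", "O")]``.  Each component is driven at the
    storage phase of its role, xi_j = pi (j - 1) / 4, so a composite cue
    addresses each binding at its original sampling time.
    """
    params = params or ModelParams()
    words, roles, sentences = build_sentences(seed=seed)
    role_phases = np.pi * np.arange(roles.m) / roles.m

    Wstar = None
    converged = []
    store_seeds = _child_seeds(seed, len(sentences) + 1)
    for k, sent in enumerate(sentences):
        mems, phases = [], []
        for i, j in sent.bindings:
            mems.append(encode(words[i], roles[j]))
            phases.append(role_phases[j])
        order = np.argsort(phases)
        mems = np.array(mems)[order]
        phases = np.array(phases)[order]
        report, _ = store_group(mems, phases, params, seed=store_seeds[k],
                                mode="dense")
        converged.append(report.converged)
        Wstar = report.Wstar if Wstar is None else Wstar + report.Wstar

    comps = []
    for w, r in cue_components:
        if w not in WORDS:
            raise ValueError(f"unknown word {w!r}")
        if r not in ROLES:
            raise ValueError(f"unknown role {r!r}")
        comps.append((encode(words[w], roles[r]), role_phases[ROLES.index(r)]))
    cue = CueSpec(components=comps, omega=params.omega)

    traj = integrate_retrieval(Wstar, cue, dt=retrieval_dt, T=retrieval_T,
                               seed=store_seeds[-1])
    curves = role_fitness(traj, [words[i] for i in range(words.m)], roles,
                          t0=t0, word_labels=WORDS)
    dom = dominance(curves, window_fraction, threshold_fraction)
    return SemanticTaskReport(
        words=words, roles=roles, sentences=sentences, Wstar=Wstar,
        converged=converged, trajectory=traj, P_curves=curves, dominant=dom,
        cue_description=list(cue_components),
        provenance={"seed": seed, "retrieval_T": retrieval_T,
                    "retrieval_dt": retrieval_dt,
                    "params": vars(params).copy()},
    )
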