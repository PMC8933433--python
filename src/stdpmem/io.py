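"""HDF5 archives, CSV metric export, and provenance records.

A storage archive holds the converged connectivity W*, the parameter set,
the encoded inputs needed to build cues and metrics later (tags, original
data vectors, fixture images), and convergence diagnostics.  Archives
produced from separate groups can be summed (``combine_archives``) for
multi-group retrieval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .dynamics import DenseConnectivity
from .encoding import TagSet
from .geometry import RetrievalMetrics, RoleFitness

__all__ = [
    "Archive",
    "save_archive",
    "load_archive",
    "combine_archives",
    "save_metrics_csv",
    "save_pcurves_csv",
    "save_tagset",
    "load_tagset",
]


@dataclass
class Archive:
    Wstar: DenseConnectivity
    params: dict
    meta: dict = field(default_factory=dict)
    tags: TagSet | None = None
    originals: np.ndarray | None = None
    images: np.ndarray | None = None
    convergence: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return self.Wstar.N


def save_archive(path, Wstar, params: dict, meta: dict | None = None,
                 tags: TagSet | None = None,
                 originals: np.ndarray | None = None,
                 images: np.ndarray | None = None,
                 convergence: dict | None = None) -> Path:
    """Write a storage archive.  ``Wstar`` may be dense or factored (it is
    densified on write)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("W", data=np.asarray(Wstar.to_dense()))
        g = h5.create_group("params")
        for k, v in params.items():
            g.attrs[k] = v
        h5.attrs["package_version"] = __version__
        for k, v in (meta or {}).items():
            h5.attrs[k] = v
        if tags is not None:
            d = h5.create_dataset("tags", data=tags.vectors)
            d.attrs["labels"] = json.dumps(list(tags.labels))
        if originals is not None:
            h5.create_dataset("originals", data=np.asarray(originals))
        if images is not None:
            h5.create_dataset("images", data=np.asarray(images))
        if convergence:
            c = h5.create_group("convergence")
            for k, v in convergence.items():
                c.attrs[k] = v
    return path


def load_archive(path) -> Archive:
    with h5py.File(path, "r") as h5:
        W = DenseConnectivity(h5["W"][...])
        params = dict(h5["params"].attrs)
        meta = {k: v for k, v in h5.attrs.items()}
        tags = None
        if "tags" in h5:
            labels = json.loads(h5["tags"].attrs["labels"])
            tags = TagSet(vectors=h5["tags"][...], labels=labels)
        originals = h5["originals"][...] if "originals" in h5 else None
        images = h5["images"][...] if "images" in h5 else None
        conv = dict(h5["convergence"].attrs) if "convergence" in h5 else {}
    return Archive(Wstar=W, params=params, meta=meta, tags=tags,
                   originals=originals, images=images, convergence=conv)


def combine_archives(paths, out) -> Path:
    """Sum the connectivities of several archives: W* = sum_k W*_k.

    Antisymmetry is preserved (a sum of antisymmetric matrices).  The first
    archive supplies parameters and encoding metadata.
    """
    if not paths:
        raise ValueError("no archives to combine")
    archives = [load_archive(p) for p in paths]
    N = archives[0].N
    for p, a in zip(paths, archives):
        if a.N != N:
            raise ValueError(f"archive {p} has N={a.N}, expected {N}")
    W = archives[0].Wstar.to_dense().copy()
    for a in archives[1:]:
        W += a.Wstar.to_dense()
    first = archives[0]
    return save_archive(out, DenseConnectivity(W), first.params,
                        meta={**first.meta, "combined_from": len(archives)},
                        tags=first.tags, originals=first.originals)


def save_metrics_csv(metrics: RetrievalMetrics, path) -> Path:
    """One row per time point: t, p(t), and the per-item similarities."""
    path = Path(path)
    cols = {"t": metrics.times, "p": metrics.p_series}
    for i, s in enumerate(metrics.similarities):
        cols[f"s_{i}"] = s
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")
    return path


def save_pcurves_csv(curves: RoleFitness, path) -> Path:
    """Long-format export: (time, word, role, value) rows."""
    path = Path(path)
    frames = []
    for i, w in enumerate(curves.word_labels):
        for j, r in enumerate(curves.role_labels):
            frames.append(pd.DataFrame({
                "t": curves.times, "word": w, "role": r,
                "value": curves.values[i, j],
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.10g")
    return path


def save_tagset(path, tags: TagSet, data: dict | None = None) -> Path:
    """Serialize a TagSet (and optional labeled data vectors) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        d = h5.create_dataset("tags", data=tags.vectors)
        d.attrs["labels"] = json.dumps(list(tags.labels))
        for name, vec in (data or {}).items():
            h5.create_dataset(f"data/{name}", data=np.asarray(vec))
    return path


def load_tagset(path) -> tuple:
    with h5py.File(path, "r") as h5:
        labels = json.loads(h5["tags"].attrs["labels"])
        tags = TagSet(vectors=h5["tags"][...], labels=labels)
        data = {}
        if "data" in h5:
            for name in h5["data"]:
                data[name] = h5[f"data/{name}"][...]
    return tags, data
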