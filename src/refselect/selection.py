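"""Reference sample-set selection strategies.

For read-depth CNV calling every query sample needs a panel of other
samples ("reference set") from which its expected, CNV-free coverage is
modelled.  Four strategies are provided:

``all``
    every other sample in the cohort (the no-selection baseline);
``random``
    a per-sample uniform draw without replacement of a fixed size;
``knn``
    the k samples whose depth profiles are most Pearson-correlated
    with the query;
``kmeans``
    partition the cohort into k groups by Lloyd's k-means on a classical
    multidimensional-scaling embedding of the correlation distance
    d = 1 - r; each sample's panel is its own group minus itself.

With k = 1 the k-means strategy degenerates to ``all``, as does kNN with
k = S - 1; these equivalences are part of the contract and exercised by
the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .depthio import DepthMatrix

__all__ = [
    "CorrelationMatrix",
    "MDSEmbedding",
    "ReferenceAssignment",
    "correlation_matrix",
    "mds_embed",
    "select_all",
    "select_random",
    "select_knn",
    "select_kmeans",
]


class SelectionError(ValueError):
    pass


@dataclass
class CorrelationMatrix:
    """Pearson correlation of per-target depth profiles between samples."""

    samples: list[str]
    values: np.ndarray  # S x S, symmetric, unit diagonal

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        S = len(self.samples)
        if self.values.shape != (S, S):
            raise SelectionError(f"correlation shape {self.values.shape} != ({S},{S})")

    def distance(self) -> np.ndarray:
        """Correlation distance d = 1 - r (0 for identical profiles)."""
        return 1.0 - self.values


@dataclass
class MDSEmbedding:
    """Classical MDS (principal coordinates) of the correlation distance."""

    samples: list[str]
    coordinates: np.ndarray  # S x m
    eigenvalues: np.ndarray  # length m, descending, non-negative


@dataclass
class ReferenceAssignment:
    """Per-sample reference panels produced by one selection strategy.

    ``references[s]`` never contains ``s`` itself.  For k-means the
    cluster label of each sample is recorded; samples in the same cluster
    share the same panel modulo self-exclusion.
    """

    method: str
    samples: list[str]
    references: dict[str, list[str]]
    labels: dict[str, int] | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cohort = set(self.samples)
        for s, refs in self.references.items():
            if s in refs:
                raise SelectionError(f"sample {s} appears in its own reference set")
            unknown = set(refs) - cohort
            if unknown:
                raise SelectionError(
                    f"reference set of {s} names unknown samples: {sorted(unknown)}"
                )
            if len(set(refs)) != len(refs):
                raise SelectionError(f"reference set of {s} contains duplicates")

    def reference_sets(self) -> dict[str, frozenset[str]]:
        return {s: frozenset(r) for s, r in self.references.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.samples,
                "method": self.method,
                "cluster": [
                    self.labels[s] if self.labels is not None else -1
                    for s in self.samples
                ],
                "ref_samples": [",".join(self.references[s]) for s in self.samples],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "ReferenceAssignment":
        df = pd.read_csv(path, sep="\t", dtype={"sample": str})
        samples = [str(s) for s in df["sample"]]
        refs = {
            s: ([] if pd.isna(r) or r == "" else str(r).split(","))
            for s, r in zip(samples, df["ref_samples"].fillna(""))
        }
        labels = {s: int(c) for s, c in zip(samples, df["cluster"])}
        method = str(df["method"].iloc[0]) if len(df) else "unknown"
        if all(v == -1 for v in labels.values()):
            labels = None
        return cls(method=method, samples=samples, references=refs, labels=labels)


def correlation_matrix(
    matrix: DepthMatrix, median_scale: bool = False
) -> CorrelationMatrix:
    """Pearson correlation between the depth profiles of every sample pair.

    Computed on raw QC-passed counts by default.  ``median_scale`` first
    divides every target row by its median depth across samples, putting
    all targets on a comparable scale so a few very deep targets cannot
    dominate the correlation (per-sample scaling would be a no-op, as
    Pearson correlation is scale-invariant per profile).  Requires >= 2
    targets; a sample with zero variance across targets has no defined
    correlation and raises an error naming it.
    """
    if matrix.n_targets < 2:
        raise SelectionError("need at least 2 targets to correlate profiles")
    counts = matrix.counts
    if median_scale:
        med = np.median(counts, axis=1)
        if np.any(med <= 0):
            bad = matrix.targets[int(np.nonzero(med <= 0)[0][0])]
            raise SelectionError(
                "median scaling impossible: target with non-positive "
                f"median depth: {bad.key()}"
            )
        counts = counts / med[:, None]
    stds = counts.std(axis=0)
    flat = np.nonzero(stds == 0)[0]
    if flat.size:
        raise SelectionError(
            "zero-variance depth profile for sample(s): "
            + ", ".join(matrix.samples[j] for j in flat)
        )
    r = np.corrcoef(counts, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(samples=list(matrix.samples), values=r)


def mds_embed(corr: CorrelationMatrix, m: int | None = None) -> MDSEmbedding:
    """Classical (Torgerson) MDS on the correlation distance d = 1 - r.

    Double-centers -D^2/2, eigendecomposes, and keeps the top ``m``
    strictly positive eigenpairs; coordinates are eigenvectors scaled by
    sqrt(eigenvalue), hence centered.  If fewer than ``m`` positive
    eigenvalues exist the embedding is truncated with a warning.
    """
    S = len(corr.samples)
    if m is None:
        m = min(10, S - 1)
    if not 1 <= m <= S - 1:
        raise SelectionError(f"embedding dimension m={m} outside [1, {S - 1}]")
    D = corr.distance()
    J = np.eye(S) - np.ones((S, S)) / S
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-9 * max(abs(evals[0]), 1.0))
    n_pos = int(np.sum(evals > tol))
    if n_pos < m:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating embedding from "
            f"{m} to {n_pos} dimensions",
            stacklevel=2,
        )
        m = max(n_pos, 1)
    kept = evals[:m].clip(min=0.0)
    coords = evecs[:, :m] * np.sqrt(kept)
    return MDSEmbedding(samples=list(corr.samples), coordinates=coords, eigenvalues=kept)


def select_all(matrix: DepthMatrix) -> ReferenceAssignment:
    """Every other cohort sample, in cohort order (the baseline)."""
    samples = list(matrix.samples)
    if len(samples) < 2:
        raise SelectionError("need at least 2 samples")
    refs = {s: [t for t in samples if t != s] for s in samples}
    return ReferenceAssignment(method="all", samples=samples, references=refs)


def select_random(matrix: DepthMatrix, size: int, seed: int) -> ReferenceAssignment:
    """Per-sample uniform draw without replacement of ``size`` other samples."""
    samples = list(matrix.samples)
    S = len(samples)
    if not 1 <= size <= S - 1:
        raise SelectionError(f"size={size} outside [1, {S - 1}]")
    rng = np.random.default_rng(seed)
    refs: dict[str, list[str]] = {}
    for s in samples:
        others = [t for t in samples if t != s]
        picked = rng.choice(len(others), size=size, replace=False)
        chosen = {others[i] for i in picked}
        refs[s] = [t for t in others if t in chosen]  # cohort order
    return ReferenceAssignment(
        method="random",
        samples=samples,
        references=refs,
        params={"size": size, "seed": seed},
    )


def select_knn(corr: CorrelationMatrix, k: int) -> ReferenceAssignment:
    """The k most-correlated other samples per query.

    Panels are ordered by descending correlation; equal correlations are
    broken by ascending sample ID so the result is deterministic and the
    k-panel is always a subset of the (k+1)-panel.
    """
    samples = list(corr.samples)
    S = len(samples)
    if not 1 <= k <= S - 1:
        raise SelectionError(f"k={k} outside [1, {S - 1}]")
    refs: dict[str, list[str]] = {}
    for i, s in enumerate(samples):
        ranked = sorted(
            (t for t in range(S) if t != i),
            key=lambda t: (-corr.values[i, t], samples[t]),
        )
        refs[s] = [samples[t] for t in ranked[:k]]
    return ReferenceAssignment(
        method="knn", samples=samples, references=refs, params={"k": k}
    )


def kmeans_labels(
    embedding: MDSEmbedding, k: int, seed: int, n_init: int = 10
) -> np.ndarray:
    """Lloyd's k-means with k-means++ starts on the MDS coordinates.

    ``n_init`` restarts; the one with the lowest within-cluster sum of
    squares wins.  Deterministic given identical inputs and seed.
    """
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        algorithm="lloyd",
        random_state=int(seed) % (2**31),
    )
    return km.fit_predict(embedding.coordinates)


def select_kmeans(
    matrix: DepthMatrix,
    k: int,
    seed: int = 0,
    m: int | None = None,
    corr: CorrelationMatrix | None = None,
    embedding: MDSEmbedding | None = None,
) -> ReferenceAssignment:
    """Cluster the cohort into k groups; each sample's panel is its group.

    Precomputed ``corr``/``embedding`` may be passed to share work across
    repeated calls (e.g. a sweep over k).  A singleton cluster leaves its
    sample with an empty panel, which downstream calling must reject; a
    warning is emitted.
    """
    samples = list(matrix.samples)
    S = len(samples)
    if not 1 <= k <= S:
        raise SelectionError(f"k={k} outside [1, {S}]")
    if embedding is None:
        if corr is None:
            corr = correlation_matrix(matrix)
        embedding = mds_embed(corr, m=min(m or 10, S - 1))
    labels = kmeans_labels(embedding, k, seed)
    members: dict[int, list[str]] = {}
    for s, lab in zip(samples, labels):
        members.setdefault(int(lab), []).append(s)
    singletons = [c for c, mem in members.items() if len(mem) == 1]
    if singletons:
        warnings.warn(
            f"{len(singletons)} singleton cluster(s) (labels {sorted(singletons)}): "
            "their samples have empty reference sets",
            stacklevel=2,
        )
    refs = {
        s: [t for t in members[int(lab)] if t != s]
        for s, lab in zip(samples, labels)
    }
    return ReferenceAssignment(
        method="kmeans",
        samples=samples,
        references=refs,
        labels={s: int(lab) for s, lab in zip(samples, labels)},
        params={"k": k, "seed": seed, "m": embedding.coordinates.shape[1]},
    )
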