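"""Fork-join CNV-calling workflow over a chosen reference strategy.

Each sample is processed independently — select its reference panel,
normalize, segment, call — and the per-sample call lists are unioned
into the cohort call set.  Results do not depend on processing order, so
the per-sample work is trivially parallelizable; here it runs serially.

The expensive stage in real pipelines is normalization (building the
expected-depth model), so the workflow accounts for how many distinct
normalization contexts each strategy needs: one shared context for
``all``, one per sample for ``knn`` and ``random`` (every sample has its
own panel), and one per non-singleton cluster for ``kmeans``.  This count
is the strategy's cost model: with S samples and k clusters the k-means
route performs S/k times fewer normalizations than kNN.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .depthio import DepthMatrix, TargetRegion
from .evalcnv import EvaluationReport, GoldVariant, evaluate
from .mincall import (
    CallerParams,
    CNVCall,
    normalize,
    reference_profile,
    segment_and_call,
)
from .selection import (
    ReferenceAssignment,
    correlation_matrix,
    select_all,
    select_knn,
    select_kmeans,
    select_random,
)

__all__ = ["RunManifest", "run_pipeline", "compare_methods", "parse_method_spec"]

logger = logging.getLogger("refselect")

METHODS = ("all", "random", "knn", "kmeans")


class WorkflowError(ValueError):
    pass


@dataclass
class RunManifest:
    """Provenance and cost accounting for one pipeline run."""

    method: str
    params: dict
    n_samples: int
    ref_set_sizes: dict[str, int]
    n_normalizations: int
    calls_per_sample: dict[str, int]
    skipped_samples: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    seed: int | None = None
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _build_assignment(
    matrix: DepthMatrix, method: str, k: int | None, size: int | None, seed: int
) -> ReferenceAssignment:
    if method == "all":
        return select_all(matrix)
    if method == "random":
        if size is None:
            raise WorkflowError("random selection needs --size")
        return select_random(matrix, size=size, seed=seed)
    if method == "knn":
        if k is None:
            raise WorkflowError("knn selection needs -k")
        return select_knn(correlation_matrix(matrix), k=k)
    if method == "kmeans":
        if k is None:
            raise WorkflowError("kmeans selection needs -k")
        return select_kmeans(matrix, k=k, seed=seed)
    raise WorkflowError(f"unknown method {method!r}; expected one of {METHODS}")


def run_pipeline(
    matrix: DepthMatrix,
    method: str,
    k: int | None = None,
    size: int | None = None,
    seed: int = 0,
    caller_params: CallerParams | None = None,
    assignment: ReferenceAssignment | None = None,
) -> tuple[list[CNVCall], RunManifest]:
    """Select references, normalize, call and union over all samples.

    ``all`` shares one cohort-median expected profile; ``kmeans`` shares
    one median profile per cluster (computed over the whole cluster —
    with several members the median is robust to including the query);
    ``knn`` and ``random`` build one profile per sample from its own
    panel.  Samples left in a singleton k-means cluster have no panel and
    are skipped with a recorded warning.
    """
    params = caller_params or CallerParams()
    if assignment is None:
        assignment = _build_assignment(matrix, method, k, size, seed)
    method = assignment.method

    n_norm = 0
    calls: list[CNVCall] = []
    per_sample: dict[str, int] = {}
    skipped: list[str] = []
    warns: list[str] = []

    if method == "all":
        shared = np.median(matrix.counts, axis=1)
        n_norm = 1
        profiles = {s: shared for s in matrix.samples}
    elif method == "kmeans":
        assert assignment.labels is not None
        members: dict[int, list[str]] = {}
        for s in matrix.samples:
            members.setdefault(assignment.labels[s], []).append(s)
        cluster_profile: dict[int, np.ndarray] = {}
        for lab, mem in sorted(members.items()):
            if len(mem) < 2:
                warns.append(
                    f"cluster {lab} is a singleton ({mem[0]}); sample skipped"
                )
                continue
            cluster_profile[lab] = reference_profile(matrix, mem)
            n_norm += 1
        profiles = {}
        for s in matrix.samples:
            lab = assignment.labels[s]
            if lab in cluster_profile:
                profiles[s] = cluster_profile[lab]
    else:  # knn / random: one context per sample
        profiles = {}
        for s in matrix.samples:
            refs = assignment.references[s]
            if not refs:
                warns.append(f"sample {s} has an empty reference set; skipped")
                continue
            profiles[s] = reference_profile(matrix, refs)
            n_norm += 1

    for s in matrix.samples:
        if s not in profiles:
            skipped.append(s)
            per_sample[s] = 0
            continue
        prof = normalize(s, assignment.references[s], matrix, profile=profiles[s], params=params)
        sample_calls = segment_and_call(prof, params)
        per_sample[s] = len(sample_calls)
        calls.extend(sample_calls)
        logger.debug("sample %s: %d call(s)", s, len(sample_calls))

    calls.sort(key=lambda c: (c.sample, c.chrom, c.start))
    manifest = RunManifest(
        method=method,
        params={**assignment.params, "k": k, "size": size},
        n_samples=matrix.n_samples,
        ref_set_sizes={s: len(assignment.references[s]) for s in matrix.samples},
        n_normalizations=n_norm,
        calls_per_sample=per_sample,
        skipped_samples=skipped,
        warnings=warns,
        seed=seed,
        timestamp=datetime.datetime.now().isoformat(timespec="seconds"),
    )
    logger.info(
        "method=%s: %d calls, %d normalization context(s)", method, len(calls), n_norm
    )
    return calls, manifest


def parse_method_spec(spec: str) -> tuple[str, dict]:
    """Parse ``name[:param]`` strings such as ``kmeans:4`` or ``random:20``."""
    name, _, arg = spec.partition(":")
    name = name.strip()
    if name not in METHODS:
        raise WorkflowError(f"unknown method {name!r}")
    params: dict = {}
    if arg:
        value = int(arg)
        params["size" if name == "random" else "k"] = value
    return name, params


def compare_methods(
    matrix: DepthMatrix,
    gold: Sequence[GoldVariant],
    methods: Sequence[str | tuple[str, dict]],
    seed: int = 0,
    caller_params: CallerParams | None = None,
    min_recip_overlap: float = 0.5,
) -> dict[str, tuple[EvaluationReport, RunManifest]]:
    """Run each strategy on the same cohort and score it against the gold set.

    ``methods`` entries are either spec strings (``"kmeans:3"``) or
    ``(name, params)`` pairs.  Returns the stratified evaluation and the
    manifest per method, keyed by the spec string.
    """
    out: dict[str, tuple[EvaluationReport, RunManifest]] = {}
    for entry in methods:
        if isinstance(entry, str):
            name, params = parse_method_spec(entry)
            key = entry
        else:
            name, params = entry
            key = name + (
                ":" + str(params.get("k", params.get("size"))) if params else ""
            )
        calls, manifest = run_pipeline(
            matrix,
            name,
            k=params.get("k"),
            size=params.get("size"),
            seed=seed,
            caller_params=caller_params,
        )
        report = evaluate(
            calls,
            list(gold),
            matrix.targets,
            n_samples=matrix.n_samples,
            min_recip_overlap=min_recip_overlap,
        )
        out[key] = (report, manifest)
    return out
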