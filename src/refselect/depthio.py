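"""Depth-matrix I/O and target-level quality control.

An exome read-depth cohort is stored as a targets x samples count matrix
together with per-target annotations (GC fraction, mappability).  All
coordinates are 0-based half-open, BED style.  Quality control removes
targets that are poorly covered, extreme in length, repetitive
(low mappability) or extreme in GC content; thresholds follow the common
exome-caller defaults (median depth in [20, 4000], length in [20, 2000] bp,
mappability >= 0.9, GC in [0.20, 0.80]) with *strict* inequalities, so a
target sitting exactly on a bound is retained.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TargetRegion",
    "DepthMatrix",
    "QCThresholds",
    "QCReport",
    "read_depth_matrix",
    "write_depth_matrix",
    "apply_qc",
]

ANNOT_COLUMNS = ("chrom", "start", "end", "gc", "mappability")


class DepthMatrixError(ValueError):
    """Raised on malformed or invariant-violating depth-matrix input."""


@dataclass(frozen=True)
class TargetRegion:
    """A capture target (exon) with GC and mappability annotation.

    Coordinates are 0-based half-open; ``end > start``.
    """

    chrom: str
    start: int
    end: int
    gc: float
    mappability: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DepthMatrixError(
                f"target {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )
        if not 0.0 <= self.gc <= 1.0:
            raise DepthMatrixError(f"target {self.key()}: gc {self.gc} outside [0, 1]")
        if not 0.0 <= self.mappability <= 1.0:
            raise DepthMatrixError(
                f"target {self.key()}: mappability {self.mappability} outside [0, 1]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """>=1 bp overlap with a half-open interval on ``chrom``."""
        return self.chrom == chrom and self.start < end and self.end > start


@dataclass
class DepthMatrix:
    """Targets x samples read-depth counts with annotations.

    ``counts[i, j]`` is the depth of sample ``samples[j]`` on
    ``targets[i]``.  Counts are non-negative; sample IDs are unique;
    targets are sorted by (chrom, start) and non-overlapping within a
    chromosome.
    """

    targets: list[TargetRegion]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.validate()

    def validate(self) -> None:
        T, S = len(self.targets), len(self.samples)
        if self.counts.shape != (T, S):
            raise DepthMatrixError(
                f"counts shape {self.counts.shape} != (targets={T}, samples={S})"
            )
        if len(set(self.samples)) != S:
            dupes = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise DepthMatrixError(f"duplicate sample IDs: {', '.join(dupes)}")
        if T and np.min(self.counts) < 0:
            i, j = np.argwhere(self.counts < 0)[0]
            raise DepthMatrixError(
                f"negative count for sample {self.samples[j]} on target "
                f"{self.targets[i].key()}"
            )
        prev: TargetRegion | None = None
        for t in self.targets:
            if prev is not None and prev.chrom == t.chrom:
                if t.start < prev.start:
                    raise DepthMatrixError(
                        f"targets not sorted at {t.key()} (after {prev.key()})"
                    )
                if t.start < prev.end:
                    raise DepthMatrixError(
                        f"overlapping targets {prev.key()} and {t.key()}"
                    )
            prev = t

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def column(self, sample: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample)]

    def subset_targets(self, keep: Sequence[int]) -> "DepthMatrix":
        keep = list(keep)
        return DepthMatrix(
            targets=[self.targets[i] for i in keep],
            samples=list(self.samples),
            counts=self.counts[keep, :].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepthMatrix):
            return NotImplemented
        return (
            self.targets == other.targets
            and self.samples == other.samples
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True)
class QCThresholds:
    """Target-level QC bounds.  All comparisons are strict: a target is
    removed only when its value lies *beyond* a bound, never on it."""

    min_median_depth: float = 20.0
    max_median_depth: float = 4000.0
    min_length_bp: int = 20
    max_length_bp: int = 2000
    min_mappability: float = 0.9
    min_gc: float = 0.20
    max_gc: float = 0.80

    def __post_init__(self) -> None:
        if self.min_median_depth >= self.max_median_depth:
            raise ValueError("min_median_depth must be < max_median_depth")
        if self.min_length_bp >= self.max_length_bp:
            raise ValueError("min_length_bp must be < max_length_bp")
        if self.min_gc >= self.max_gc:
            raise ValueError("min_gc must be < max_gc")


@dataclass
class QCReport:
    """Removed targets with the first rule each one failed."""

    removed: list[tuple[TargetRegion, str]] = field(default_factory=list)
    n_input: int = 0

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"chrom": t.chrom, "start": t.start, "end": t.end, "rule": rule}
                for t, rule in self.removed
            ],
            columns=["chrom", "start", "end", "rule"],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _first_failing_rule(
    target: TargetRegion, median_depth: float, thr: QCThresholds
) -> str | None:
    # Rules checked in a fixed order; the first violated one is reported.
    if median_depth < thr.min_median_depth:
        return "median_depth_low"
    if median_depth > thr.max_median_depth:
        return "median_depth_high"
    if target.length < thr.min_length_bp:
        return "length_short"
    if target.length > thr.max_length_bp:
        return "length_long"
    if target.mappability < thr.min_mappability:
        return "mappability_low"
    if target.gc < thr.min_gc:
        return "gc_low"
    if target.gc > thr.max_gc:
        return "gc_high"
    return None


def apply_qc(
    matrix: DepthMatrix, thresholds: QCThresholds | None = None
) -> tuple[DepthMatrix, QCReport]:
    """Remove targets failing any QC rule; samples are never touched.

    The median depth of a target is taken across *all* samples of the raw
    matrix.  Idempotent: re-applying QC to its own output removes nothing.
    """
    thr = thresholds or QCThresholds()
    medians = np.median(matrix.counts, axis=1) if matrix.n_targets else np.array([])
    keep: list[int] = []
    report = QCReport(n_input=matrix.n_targets)
    for i, target in enumerate(matrix.targets):
        rule = _first_failing_rule(target, float(medians[i]), thr)
        if rule is None:
            keep.append(i)
        else:
            report.removed.append((target, rule))
    if matrix.n_targets and not keep:
        raise DepthMatrixError(
            "QC removed every target; review thresholds against this cohort"
        )
    return matrix.subset_targets(keep), report


def read_depth_matrix(path: str | Path | io.TextIOBase) -> DepthMatrix:
    """Read a depth matrix from TSV.

    Expected layout: a ``#``-prefixed header ``chrom start end gc
    mappability <sample...>`` followed by one row per target.  Malformed
    rows raise an error naming the 1-based file line.
    """
    if isinstance(path, (str, Path)):
        with open(path) as fh:
            return _parse_depth_matrix(fh)
    return _parse_depth_matrix(path)


def _parse_depth_matrix(fh: Iterable[str]) -> DepthMatrix:
    header: list[str] | None = None
    targets: list[TargetRegion] = []
    rows: list[list[float]] = []
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.lstrip("#").split("\t")
        if header is None:
            if list(fields[: len(ANNOT_COLUMNS)]) != list(ANNOT_COLUMNS):
                raise DepthMatrixError(
                    f"line {lineno}: header must start with "
                    + "\t".join(ANNOT_COLUMNS)
                )
            header = fields
            continue
        if len(fields) != len(header):
            raise DepthMatrixError(
                f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        try:
            target = TargetRegion(
                chrom=fields[0],
                start=int(fields[1]),
                end=int(fields[2]),
                gc=float(fields[3]),
                mappability=float(fields[4]),
            )
            counts = [float(x) for x in fields[5:]]
        except (ValueError, DepthMatrixError) as exc:
            raise DepthMatrixError(f"line {lineno}: {exc}") from exc
        if counts and min(counts) < 0:
            raise DepthMatrixError(f"line {lineno}: negative read count")
        targets.append(target)
        rows.append(counts)
    if header is None:
        raise DepthMatrixError("empty file: no header found")
    samples = header[len(ANNOT_COLUMNS):]
    counts = np.array(rows, dtype=float) if rows else np.empty((0, len(samples)))
    return DepthMatrix(targets=targets, samples=samples, counts=counts)


def write_depth_matrix(matrix: DepthMatrix, path: str | Path) -> None:
    """Write the TSV layout accepted by :func:`read_depth_matrix`."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(list(ANNOT_COLUMNS) + matrix.samples) + "\n")
        for i, t in enumerate(matrix.targets):
            row = matrix.counts[i, :]
            vals = "\t".join(_fmt_count(v) for v in row)
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.gc:g}\t{t.mappability:g}"
                + ("\t" + vals if matrix.samples else "")
                + "\n"
            )


def _fmt_count(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:g}"


def read_targets(path: str | Path) -> list[TargetRegion]:
    """Read a targets-only TSV (``chrom start end gc mappability``)."""
    df = pd.read_csv(path, sep="\t", comment=None)
    df.columns = [c.lstrip("#") for c in df.columns]
    return [
        TargetRegion(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            gc=float(r.gc),
            mappability=float(r.mappability),
        )
        for r in df.itertuples()
    ]


def write_targets(targets: Sequence[TargetRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(ANNOT_COLUMNS) + "\n")
        for t in targets:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.gc:g}\t{t.mappability:g}\n")
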