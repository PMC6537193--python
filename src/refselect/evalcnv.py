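"""Benchmarking call sets against a gold standard.

Calls are matched 1-to-1 to gold variants of the same sample and type by
reciprocal overlap (default >= 0.5, greedy in descending overlap), and
the resulting TP/FP/FN counts are stratified by cohort frequency
(rare: <= 5%, common: > 5%) and by event span in exome targets
(short: 1-2 exons, long: >= 3 exons).  Matched and missed gold variants
carry their own frequency and span; an unmatched call (FP) is assigned
the fraction of cohort samples sharing an overlapping same-type call and
its own exon span.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .depthio import TargetRegion
from .mincall import CNVCall

__all__ = [
    "GoldVariant",
    "StratumCounts",
    "EvaluationReport",
    "MatchResult",
    "count_exons",
    "categorize",
    "match_calls",
    "evaluate",
    "read_gold",
    "write_gold",
]

RARE_MAX_FREQ = 0.05  # inclusive bound: frequency <= 5% is rare
SHORT_MAX_EXONS = 2  # 1-2 exons short, >= 3 long

STRATA = ("rare_short", "rare_long", "common_short", "common_long")


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class GoldVariant:
    """A trusted CNV with its cohort carrier frequency."""

    sample: str
    chrom: str
    start: int
    end: int
    type: str
    frequency: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise EvaluationError("gold variant end must exceed start")
        if self.type not in ("DEL", "DUP"):
            raise EvaluationError(f"bad variant type {self.type!r}")
        if not 0.0 <= self.frequency <= 1.0:
            raise EvaluationError("frequency outside [0, 1]")


def count_exons(
    chrom: str, start: int, end: int, targets: Sequence[TargetRegion]
) -> int:
    """Number of targets overlapping the half-open interval by >= 1 bp."""
    n = 0
    for t in targets:
        if t.chrom == chrom and t.start < end and t.end > start:
            n += 1
    return n


def categorize(
    variant: GoldVariant, targets: Sequence[TargetRegion]
) -> tuple[str, str | None]:
    """(rare|common, short|long) stratum of a variant.

    Rare iff frequency <= 0.05 (boundary inclusive).  Span classes
    partition the events: 1-2 exons short, >= 3 long.  A variant touching
    zero QC-passed exons cannot be span-classified; it is flagged with a
    warning and excluded from the stratified counts.
    """
    freq_class = "rare" if variant.frequency <= RARE_MAX_FREQ else "common"
    n = count_exons(variant.chrom, variant.start, variant.end, targets)
    if n == 0:
        warnings.warn(
            f"variant {variant.chrom}:{variant.start}-{variant.end} in "
            f"{variant.sample} overlaps no target; excluded from strata",
            stacklevel=2,
        )
        return freq_class, None
    return freq_class, "short" if n <= SHORT_MAX_EXONS else "long"


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def reciprocal_overlap(call: CNVCall, gold: GoldVariant) -> float:
    """min(overlap/len(call), overlap/len(gold)); 0 on different chroms."""
    if call.chrom != gold.chrom:
        return 0.0
    ov = _overlap(call.start, call.end, gold.start, gold.end)
    return min(ov / (call.end - call.start), ov / (gold.end - gold.start))


@dataclass
class MatchResult:
    pairs: list[tuple[CNVCall, GoldVariant]]
    tp_gold: list[GoldVariant]
    fn_gold: list[GoldVariant]
    fp_calls: list[CNVCall]

    @property
    def tp(self) -> int:
        return len(self.tp_gold)

    @property
    def fp(self) -> int:
        return len(self.fp_calls)

    @property
    def fn(self) -> int:
        return len(self.fn_gold)


def match_calls(
    calls: Sequence[CNVCall],
    gold: Sequence[GoldVariant],
    min_recip_overlap: float = 0.5,
    any_overlap: bool = False,
) -> MatchResult:
    """Greedy 1-to-1 matching of calls to gold variants.

    A call is eligible for a gold variant iff same sample, same type and
    reciprocal overlap >= ``min_recip_overlap`` (or any positive overlap
    with ``any_overlap``).  Eligible pairs are consumed in descending
    reciprocal overlap (ties by input order), each call and each variant
    at most once.  TP = matched gold variants, FN = unmatched gold,
    FP = unmatched calls.
    """
    edges: list[tuple[float, int, int]] = []
    for ci, c in enumerate(calls):
        for gi, g in enumerate(gold):
            if c.sample != g.sample or c.type != g.type:
                continue
            ro = reciprocal_overlap(c, g)
            ok = ro > 0.0 if any_overlap else ro >= min_recip_overlap
            if ok:
                edges.append((ro, ci, gi))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    used_c: set[int] = set()
    used_g: set[int] = set()
    pairs: list[tuple[CNVCall, GoldVariant]] = []
    for _, ci, gi in edges:
        if ci in used_c or gi in used_g:
            continue
        used_c.add(ci)
        used_g.add(gi)
        pairs.append((calls[ci], gold[gi]))
    return MatchResult(
        pairs=pairs,
        tp_gold=[gold[gi] for gi in sorted(used_g)],
        fn_gold=[g for gi, g in enumerate(gold) if gi not in used_g],
        fp_calls=[c for ci, c in enumerate(calls) if ci not in used_c],
    )


@dataclass
class StratumCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp > 0 else math.nan

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else math.nan

    @property
    def f1(self) -> float:
        p, r = self.precision, self.sensitivity
        if math.isnan(p) or math.isnan(r) or p + r == 0:
            return math.nan
        return 2 * p * r / (p + r)


@dataclass
class EvaluationReport:
    """TP/FP/FN and derived metrics, overall and per stratum."""

    overall: StratumCounts
    strata: dict[str, StratumCounts]
    n_unclassified: int = 0  # zero-exon events excluded from strata

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, c in [("overall", self.overall)] + [
            (s, self.strata[s]) for s in STRATA
        ]:
            rows.append(
                {
                    "stratum": name,
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "precision": c.precision,
                    "sensitivity": c.sensitivity,
                    "f1": c.f1,
                }
            )
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def call_cohort_frequency(
    call: CNVCall, calls: Sequence[CNVCall], n_samples: int
) -> float:
    """Fraction of cohort samples carrying an overlapping same-type call."""
    carriers = {
        c.sample
        for c in calls
        if c.type == call.type
        and c.chrom == call.chrom
        and _overlap(c.start, c.end, call.start, call.end) > 0
    }
    carriers.add(call.sample)
    return len(carriers) / n_samples


def evaluate(
    calls: Sequence[CNVCall],
    gold: Sequence[GoldVariant],
    targets: Sequence[TargetRegion],
    n_samples: int,
    min_recip_overlap: float = 0.5,
    any_overlap: bool = False,
) -> EvaluationReport:
    """Match, count and stratify.

    TP and FN strata come from the gold variant (its frequency and span);
    FP strata come from the call itself, using the cohort frequency of
    overlapping same-type calls.  Order of inputs does not affect the
    counts.  With an empty gold set sensitivity is undefined (NaN) and a
    warning is emitted.
    """
    if not gold:
        warnings.warn("empty gold set: sensitivity is undefined", stacklevel=2)
    res = match_calls(calls, gold, min_recip_overlap, any_overlap)
    strata = {s: StratumCounts() for s in STRATA}
    n_uncls = 0

    def bump(freq_class: str, len_class: str | None, attr: str) -> None:
        nonlocal n_uncls
        if len_class is None:
            n_uncls += 1
            return
        c = strata[f"{freq_class}_{len_class}"]
        setattr(c, attr, getattr(c, attr) + 1)

    for g in res.tp_gold:
        bump(*categorize(g, targets), "tp")
    for g in res.fn_gold:
        bump(*categorize(g, targets), "fn")
    for c in res.fp_calls:
        freq = call_cohort_frequency(c, calls, n_samples)
        pseudo = GoldVariant(
            sample=c.sample,
            chrom=c.chrom,
            start=c.start,
            end=c.end,
            type=c.type,
            frequency=freq,
        )
        bump(*categorize(pseudo, targets), "fp")
    overall = StratumCounts(tp=res.tp, fp=res.fp, fn=res.fn)
    return EvaluationReport(overall=overall, strata=strata, n_unclassified=n_uncls)


# ---------------------------------------------------------------------------
# gold-set I/O: `sample chrom start end type frequency`

GOLD_COLUMNS = ["sample", "chrom", "start", "end", "type", "frequency"]


def write_gold(gold: Iterable[GoldVariant], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample": g.sample,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "type": g.type,
                "frequency": g.frequency,
            }
            for g in gold
        ],
        columns=GOLD_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gold(path: str | Path) -> list[GoldVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    return [
        GoldVariant(
            sample=str(r.sample),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            type=str(r.type),
            frequency=float(r.frequency),
        )
        for r in df.itertuples()
    ]
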