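"""Minimal reference-panel CNV caller.

This caller exists so the selection workflow can be exercised end to end;
it deliberately stays simple and fully parameterised rather than
replicating any production caller.  Per query sample:

1. the expected depth of each target is the median depth over the
   reference panel, rescaled by the query's median observed/expected
   ratio (absorbing library size);
2. the per-target signal is the log2 ratio of observed to expected depth
   (pseudocount 0.5 on both sides);
3. a 3-state Gaussian HMM (copy 1 / 2 / 3, means -1, 0, +log2(3/2))
   is Viterbi-decoded per chromosome; maximal runs of non-neutral states
   become DEL/DUP calls.

The shared emission standard deviation is estimated robustly as
1.4826 x the median absolute deviation of the profile, floored for
numerical sanity, and optionally capped: a caller whose noise model is
tied to sequencing depth does not silently widen its tolerance when the
reference panel is a poor match, and the cap reproduces that behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .depthio import DepthMatrix, TargetRegion

__all__ = [
    "CallerParams",
    "NormalizedProfile",
    "CNVCall",
    "reference_profile",
    "normalize",
    "segment_and_call",
    "viterbi_path",
    "read_calls",
    "write_calls",
    "write_calls_vcf",
]

LOG2_DUP = math.log2(3.0 / 2.0)  # single-copy gain on a diploid background


class CallerError(ValueError):
    pass


@dataclass(frozen=True)
class CallerParams:
    """Tunables of the plumbing caller.

    state_means: expected log2 ratios for copy 1 / 2 / 3.
    switch_prob: per-step probability of moving to each other state.
    sd_floor / sd_cap: bounds on the MAD-based emission sd (the floor
    keeps noise-free profiles decodable; the cap bounds how much panel
    mismatch the emission model may absorb, None to disable).
    """

    del_mean: float = -1.0
    neutral_mean: float = 0.0
    dup_mean: float = LOG2_DUP
    switch_prob: float = 1e-4
    sd_floor: float = 0.05
    sd_cap: float | None = 0.25
    pseudocount: float = 0.5

    @property
    def state_means(self) -> tuple[float, float, float]:
        return (self.del_mean, self.neutral_mean, self.dup_mean)


@dataclass
class NormalizedProfile:
    """Observed vs expected depth for one query sample."""

    sample: str
    targets: list[TargetRegion]
    observed: np.ndarray
    expected: np.ndarray
    log2_ratio: np.ndarray

    def __post_init__(self) -> None:
        for name in ("observed", "expected", "log2_ratio"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.all(np.isfinite(self.log2_ratio)):
            raise CallerError(f"non-finite log2 ratio for sample {self.sample}")


@dataclass(frozen=True)
class CNVCall:
    """A deletion or duplication call on one sample (0-based half-open)."""

    sample: str
    chrom: str
    start: int
    end: int
    type: str  # "DEL" | "DUP"
    n_targets: int
    mean_log2: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CallerError("call end must exceed start")
        if self.type not in ("DEL", "DUP"):
            raise CallerError(f"bad call type {self.type!r}")
        if self.n_targets < 1:
            raise CallerError("call must cover at least one target")


def reference_profile(matrix: DepthMatrix, ref_samples: Sequence[str]) -> np.ndarray:
    """Per-target median depth over a reference panel."""
    if not ref_samples:
        raise CallerError("empty reference panel")
    idx = [matrix.sample_index(s) for s in ref_samples]
    return np.median(matrix.counts[:, idx], axis=1)


def normalize(
    sample: str,
    refset: Sequence[str],
    matrix: DepthMatrix,
    profile: np.ndarray | None = None,
    params: CallerParams | None = None,
) -> NormalizedProfile:
    """Normalize a query against a reference panel (or a prebuilt profile).

    The scale s = median over targets of observed/reference absorbs
    library size, so e_j = s * m_j and r_j = log2((x_j + c) / (e_j + c)).
    An explicit ``profile`` (e.g. a per-cluster median shared by many
    queries) bypasses the panel median; otherwise the panel must be
    non-empty and must not contain the query itself.
    """
    p = params or CallerParams()
    if profile is None:
        if not refset:
            raise CallerError(
                f"sample {sample}: empty reference set (singleton cluster?)"
            )
        if sample in refset:
            raise CallerError(f"sample {sample} is inside its own reference set")
        profile = reference_profile(matrix, refset)
    profile = np.asarray(profile, dtype=float)
    x = matrix.column(sample)
    pos = profile > 0
    if not np.any(pos):
        raise CallerError(f"sample {sample}: reference profile is zero everywhere")
    s = float(np.median(x[pos] / profile[pos]))
    expected = s * profile
    ratio = np.log2((x + p.pseudocount) / (expected + p.pseudocount))
    return NormalizedProfile(
        sample=sample,
        targets=list(matrix.targets),
        observed=x.copy(),
        expected=expected,
        log2_ratio=ratio,
    )


def viterbi_path(
    obs: np.ndarray, means: Sequence[float], sd: float, switch_prob: float
) -> np.ndarray:
    """Most probable state sequence of the 3-state Gaussian chain.

    Transition matrix: stay with 1 - 2p, switch to each other state with
    p; the initial distribution equals a transition row from the neutral
    state.  Returns state indices (0 = loss, 1 = neutral, 2 = gain).
    """
    obs = np.asarray(obs, dtype=float)
    n_states = len(means)
    log_stay = math.log1p(-(n_states - 1) * switch_prob)
    log_switch = math.log(switch_prob)
    trans = np.full((n_states, n_states), log_switch)
    np.fill_diagonal(trans, log_stay)
    start = trans[1].copy()  # entering the chain from the neutral state
    # Gaussian log density up to a shared constant
    ll = -0.5 * ((obs[:, None] - np.asarray(means)[None, :]) / sd) ** 2
    T = len(obs)
    score = start + ll[0]
    back = np.zeros((T, n_states), dtype=int)
    for t in range(1, T):
        cand = score[:, None] + trans
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(n_states)] + ll[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(score))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def estimate_sd(ratios: np.ndarray, params: CallerParams) -> float:
    """Robust emission sd: 1.4826 x MAD, floored and optionally capped."""
    mad = float(np.median(np.abs(ratios - np.median(ratios))))
    sd = max(1.4826 * mad, params.sd_floor)
    if params.sd_cap is not None:
        sd = min(sd, params.sd_cap)
    return sd


def segment_and_call(
    profile: NormalizedProfile, params: CallerParams | None = None
) -> list[CNVCall]:
    """Viterbi-decode the log2-ratio profile and emit DEL/DUP calls.

    Decoding runs independently per chromosome in target order; each
    maximal run of a non-neutral state becomes one call spanning from the
    first to the last target of the run.  Calls within a sample are
    non-overlapping and sorted by construction.
    """
    p = params or CallerParams()
    ratios = profile.log2_ratio
    if not np.all(np.isfinite(ratios)):
        raise CallerError(f"non-finite ratios for sample {profile.sample}")
    sd = estimate_sd(ratios, p)
    calls: list[CNVCall] = []
    chroms: dict[str, list[int]] = {}
    for i, t in enumerate(profile.targets):
        chroms.setdefault(t.chrom, []).append(i)
    for chrom, idx in chroms.items():
        sub = ratios[idx]
        path = viterbi_path(sub, p.state_means, sd, p.switch_prob)
        i = 0
        while i < len(path):
            if path[i] == 1:
                i += 1
                continue
            j = i
            while j + 1 < len(path) and path[j + 1] == path[i]:
                j += 1
            first, last = profile.targets[idx[i]], profile.targets[idx[j]]
            calls.append(
                CNVCall(
                    sample=profile.sample,
                    chrom=chrom,
                    start=first.start,
                    end=last.end,
                    type="DEL" if path[i] == 0 else "DUP",
                    n_targets=j - i + 1,
                    mean_log2=float(sub[i : j + 1].mean()),
                )
            )
            i = j + 1
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


# ---------------------------------------------------------------------------
# call-set I/O

CALL_COLUMNS = ["sample", "chrom", "start", "end", "type", "n_targets", "mean_log2"]


def calls_to_frame(calls: Sequence[CNVCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "type": c.type,
                "n_targets": c.n_targets,
                "mean_log2": c.mean_log2,
            }
            for c in calls
        ],
        columns=CALL_COLUMNS,
    )


def write_calls(calls: Sequence[CNVCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_calls(path: str | Path) -> list[CNVCall]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    return [
        CNVCall(
            sample=str(r.sample),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            type=str(r.type),
            n_targets=int(r.n_targets),
            mean_log2=float(r.mean_log2),
        )
        for r in df.itertuples()
    ]


def write_calls_vcf(calls: Sequence[CNVCall], path: str | Path) -> None:
    """Minimal VCF 4.2 with symbolic <DEL>/<DUP> alleles, one sample per row."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Carrier">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.chrom, c.start, c.sample)):
            fh.write(
                f"{c.chrom}\t{c.start + 1}\t.\tN\t<{c.type}>\t.\t.\t"
                f"SVTYPE={c.type};END={c.end};SAMPLE={c.sample}\n"
            )
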