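"""Synthetic multi-batch exome depth cohorts with injected CNVs.

The generator emulates the coverage structure of a multi-centre exome
cohort: batches correspond to distinct capture designs, each imprinting
its own multiplicative per-target efficiency profile on every sample it
contains, on top of a shared GC-bias curve, per-sample library sizes and
negative-binomial counting noise.  Deletions and duplications are
injected on contiguous target runs at controlled carrier frequencies
(rare <= 5%, common > 5%) and exon spans (short: 1-2 targets,
long: >= 3), and the exact injected events are returned as a truth set.

The depth model for sample i on target j is

    x_ij ~ NegBin(mean = L_i * t_j * B_{b(i), j} * c_ij / 2, size = r)

with L_i the library scale, t_j a baseline x quadratic-in-GC target
efficiency, B the batch capture effect (log-normal, shared by every
sample of a batch), c_ij the integer copy number (2 outside events) and
r the negative-binomial size (variance = mu + mu^2 / r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .depthio import DepthMatrix, TargetRegion
from .evalcnv import GoldVariant

__all__ = ["SimConfig", "TruthSet", "simulate", "batch_separation"]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Cohort, bias and CNV-injection settings.

    Defaults describe a mid-sized multi-centre exome cohort: 60 samples
    from 3 capture designs, 400 targets of 120-180 bp at ~150x mean
    depth, moderate negative-binomial overdispersion (size 100) and a
    capture-effect log-sd of 0.3 — enough batch structure to be visible
    in a correlation MDS, as in real multi-design cohorts.
    """

    n_samples: int = 60
    n_batches: int = 3
    batch_proportions: tuple[float, ...] | None = None  # equal if None
    n_targets: int = 400
    target_length_range: tuple[int, int] = (120, 180)
    target_gap_range: tuple[int, int] = (200, 2000)
    chrom: str = "chr1"
    # coverage model
    mean_depth: float = 150.0
    library_size_range: tuple[float, float] = (0.8, 1.2)
    gc_bias_linear: float = 0.3
    gc_bias_quadratic: float = -2.0
    target_baseline_sd: float = 0.25  # log-normal sd of per-target efficiency
    capture_sd: float = 0.3  # log-normal sd of per-batch per-target effect
    nb_size: float = 100.0  # NB dispersion: var = mu + mu^2 / size
    noise: str = "nb"  # "nb" | "poisson" | "none"
    # CNV injection: events per {rare, common} x {short, long} cell
    n_rare_short: int = 10
    n_rare_long: int = 10
    n_common_short: int = 10
    n_common_long: int = 10
    del_fraction: float = 0.6
    rare_freq_range: tuple[float, float] = (0.0, 0.05)  # (open, closed]
    common_freq_range: tuple[float, float] = (0.05, 0.30)
    short_span_range: tuple[int, int] = (1, 2)
    long_span_range: tuple[int, int] = (3, 12)
    homozygous_deletions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_batches < 1:
            raise SimulationError("need >= 2 samples and >= 1 batch")
        props = self.batch_proportions
        if props is not None:
            if len(props) != self.n_batches:
                raise SimulationError("batch_proportions length != n_batches")
            if abs(sum(props) - 1.0) > 1e-9:
                raise SimulationError("batch proportions must sum to 1")
        if not 0.0 <= self.rare_freq_range[0] < self.rare_freq_range[1] <= 0.05:
            raise SimulationError("rare frequency range must lie in (0, 0.05]")
        if not 0.05 <= self.common_freq_range[0] < self.common_freq_range[1] <= 1.0:
            raise SimulationError("common frequency range must lie in (0.05, 1]")
        if self.noise not in ("nb", "poisson", "none"):
            raise SimulationError(f"unknown noise model {self.noise!r}")


@dataclass
class TruthSet:
    """Injected events plus per-sample batch labels.

    ``variants`` holds one GoldVariant per (event, carrier) pair with the
    realised cohort frequency (carriers / n_samples); ``events`` lists
    each distinct event once with its target span and carriers.
    """

    variants: list[GoldVariant]
    events: list[dict]
    batch_of: dict[str, int]

    def batch_labels(self, samples: Sequence[str]) -> np.ndarray:
        return np.array([self.batch_of[s] for s in samples])

    def write(self, path: str | Path) -> None:
        from .evalcnv import write_gold

        write_gold(self.variants, path)

    def write_batches(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample": list(self.batch_of), "batch": list(self.batch_of.values())}
        ).to_csv(path, sep="\t", index=False)


def _make_targets(cfg: SimConfig, rng: np.random.Generator) -> list[TargetRegion]:
    targets: list[TargetRegion] = []
    pos = 10_000
    for _ in range(cfg.n_targets):
        length = int(rng.integers(cfg.target_length_range[0], cfg.target_length_range[1] + 1))
        gc = float(np.clip(rng.beta(5, 5) * 0.6 + 0.2, 0.2, 0.8))  # within QC bounds
        mappability = float(rng.uniform(0.92, 1.0))
        targets.append(
            TargetRegion(cfg.chrom, pos, pos + length, round(gc, 3), round(mappability, 3))
        )
        pos += length + int(rng.integers(cfg.target_gap_range[0], cfg.target_gap_range[1] + 1))
    return targets


def _carrier_bounds(cfg: SimConfig, rarity: str) -> tuple[int, int]:
    lo_f, hi_f = (
        cfg.rare_freq_range if rarity == "rare" else cfg.common_freq_range
    )
    S = cfg.n_samples
    lo = max(1, math.floor(lo_f * S) + 1)  # frequency strictly above lo_f
    hi = math.floor(hi_f * S)  # frequency <= hi_f
    if lo > hi:
        raise SimulationError(
            f"no feasible carrier count for {rarity} events with S={S} "
            f"and range ({lo_f}, {hi_f}]"
        )
    return lo, hi


def _inject_events(
    cfg: SimConfig,
    rng: np.random.Generator,
    targets: list[TargetRegion],
    samples: list[str],
    copy: np.ndarray,
) -> tuple[list[GoldVariant], list[dict]]:
    cells = (
        [("rare", "short")] * cfg.n_rare_short
        + [("rare", "long")] * cfg.n_rare_long
        + [("common", "short")] * cfg.n_common_short
        + [("common", "long")] * cfg.n_common_long
    )
    # draw spans up front and place the longest events first so that
    # fragmentation of the free space cannot strand a long event
    sized: list[tuple[str, str, int]] = []
    for rarity, size_class in cells:
        span_lo, span_hi = (
            cfg.short_span_range if size_class == "short" else cfg.long_span_range
        )
        sized.append((rarity, size_class, int(rng.integers(span_lo, span_hi + 1))))
    sized.sort(key=lambda e: -e[2])

    free = np.ones(cfg.n_targets, dtype=bool)  # keep events target-disjoint
    variants: list[GoldVariant] = []
    events: list[dict] = []
    for rarity, size_class, span in sized:
        window_free = np.lib.stride_tricks.sliding_window_view(free, span).all(axis=1)
        feasible = np.nonzero(window_free)[0]
        if feasible.size == 0:
            raise SimulationError(
                "could not place all events disjointly; reduce counts or spans "
                "or increase n_targets"
            )
        start_idx = int(rng.choice(feasible))
        free[start_idx : start_idx + span] = False
        lo, hi = _carrier_bounds(cfg, rarity)
        n_carriers = int(rng.integers(lo, hi + 1))
        carriers = rng.choice(cfg.n_samples, size=n_carriers, replace=False)
        is_del = rng.random() < cfg.del_fraction
        if is_del:
            c = 0 if (cfg.homozygous_deletions and rng.random() < 0.1) else 1
        else:
            c = 3
        copy[start_idx : start_idx + span, carriers] = c
        freq = n_carriers / cfg.n_samples
        start_bp = targets[start_idx].start
        end_bp = targets[start_idx + span - 1].end
        vtype = "DEL" if is_del else "DUP"
        events.append(
            {
                "chrom": cfg.chrom,
                "start": start_bp,
                "end": end_bp,
                "type": vtype,
                "copy": c,
                "span_targets": span,
                "rarity": rarity,
                "size_class": size_class,
                "frequency": freq,
                "carriers": [samples[i] for i in sorted(carriers)],
            }
        )
        for i in sorted(carriers):
            variants.append(
                GoldVariant(
                    sample=samples[i],
                    chrom=cfg.chrom,
                    start=start_bp,
                    end=end_bp,
                    type=vtype,
                    frequency=freq,
                )
            )
    return variants, events


def simulate(config: SimConfig) -> tuple[DepthMatrix, TruthSet]:
    """Generate a depth matrix and its truth set, reproducibly from the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]
    targets = _make_targets(cfg, rng)

    props = cfg.batch_proportions or tuple(
        [1.0 / cfg.n_batches] * cfg.n_batches
    )
    counts_per_batch = np.floor(np.asarray(props) * cfg.n_samples).astype(int)
    while counts_per_batch.sum() < cfg.n_samples:
        counts_per_batch[int(np.argmin(counts_per_batch / np.asarray(props)))] += 1
    batch_of_idx = np.repeat(np.arange(cfg.n_batches), counts_per_batch)

    gc = np.array([t.gc for t in targets])
    gcc = gc - 0.5
    gc_bias = np.exp(cfg.gc_bias_linear * gcc + cfg.gc_bias_quadratic * gcc**2)
    baseline = np.exp(rng.normal(0.0, cfg.target_baseline_sd, size=cfg.n_targets))
    t_j = cfg.mean_depth * baseline * gc_bias

    B = np.exp(
        rng.normal(0.0, cfg.capture_sd, size=(cfg.n_batches, cfg.n_targets))
    )
    L = rng.uniform(*cfg.library_size_range, size=cfg.n_samples)

    copy = np.full((cfg.n_targets, cfg.n_samples), 2, dtype=int)
    variants, events = _inject_events(cfg, rng, targets, samples, copy)

    mu = (
        L[None, :]
        * t_j[:, None]
        * B[batch_of_idx, :].T
        * (copy / 2.0)
    )
    if cfg.noise == "none":
        counts = np.rint(mu)
    elif cfg.noise == "poisson":
        counts = rng.poisson(mu).astype(float)
    else:
        r = cfg.nb_size
        with np.errstate(divide="ignore", invalid="ignore"):
            p = r / (r + mu)
        counts = np.where(mu > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0.0)
    matrix = DepthMatrix(targets=targets, samples=samples, counts=counts.astype(float))
    truth = TruthSet(
        variants=variants,
        events=events,
        batch_of={s: int(b) for s, b in zip(samples, batch_of_idx)},
    )
    return matrix, truth


def batch_separation(matrix: DepthMatrix, batch_labels: Sequence[int]) -> float:
    """Mean intra-batch minus mean inter-batch Pearson correlation.

    Positive values indicate detectable batch structure; ~0 when capture
    effects are absent.
    """
    from .selection import correlation_matrix

    labels = np.asarray(batch_labels)
    if len(np.unique(labels)) < 2:
        raise SimulationError("need >= 2 batches for a separation score")
    r = correlation_matrix(matrix).values
    S = len(labels)
    iu = np.triu_indices(S, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    return float(r[iu][same].mean() - r[iu][~same].mean())
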