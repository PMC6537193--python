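import numpy as np
import pytest

from refselect.depthio import DepthMatrix, TargetRegion, apply_qc
from refselect.simcohort import SimConfig, simulate


def make_targets(n, chrom="chr1", start=1000, length=150, gap=500,
                 gc=0.5, mappability=0.95):
    out = []
    pos = start
    for _ in range(n):
        out.append(TargetRegion(chrom, pos, pos + length, gc, mappability))
        pos += length + gap
    return out


def make_matrix(counts, samples=None, **target_kwargs):
    counts = np.asarray(counts, dtype=float)
    if samples is None:
        samples = [f"S{j}" for j in range(counts.shape[1])]
    return DepthMatrix(
        targets=make_targets(counts.shape[0], **target_kwargs),
        samples=list(samples),
        counts=counts,
    )


@pytest.fixture
def toy_matrix():
    """4 targets x 3 samples with distinct, correlated profiles."""
    return make_matrix(
        [[100, 102, 50], [120, 118, 60], [80, 85, 42], [150, 149, 70]],
        samples=["A", "B", "C"],
    )


@pytest.fixture(scope="session")
def batch_cohort():
    """60-sample, 4-batch cohort with clear capture-design separation."""
    cfg = SimConfig(n_samples=60, n_batches=4, capture_sd=0.5, seed=11)
    matrix, truth = simulate(cfg)
    matrix, _ = apply_qc(matrix)
    return matrix, truth


@pytest.fixture(scope="session")
def study_cohort():
    """The default 3-batch study cohort with ~40 injected CNVs."""
    cfg = SimConfig(seed=7)
    matrix, truth = simulate(cfg)
    matrix, _ = apply_qc(matrix)
    return matrix, truth
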