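import numpy as np
import pytest

from epimapred.io import GeneAnnotation, SignalRecord
from epimapred.scoring import ScoringConfig, phi


def brute_force_scores(reads, annotations, config: ScoringConfig) -> dict:
    """Literal gene x read double loop; the independent scoring oracle."""
    out = {}
    for a in annotations:
        total = 0.0
        for r in reads:
            if r.chrom == a.chrom and abs(r.pos - a.tss) <= config.d_star:
                d = (r.pos - a.tss) * (1 if a.strand == "+" else -1)
                total += r.weight * phi(d, config)
        out[a.gene_id] = total
    return out


def naive_matmul(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Triple-loop matrix product; the independent multiplication oracle."""
    X, Y = A.shape
    Y2, Z = B.shape
    assert Y == Y2
    C = np.zeros((X, Z))
    for i in range(X):
        for k in range(Z):
            acc = 0.0
            for j in range(Y):
                acc += A[i, j] * B[j, k]
            C[i, k] = acc
    return C


def random_signal(rng, annotations, n_reads, d_max=3000):
    """Reads scattered around random TSSs (within and beyond the window)."""
    reads = []
    for _ in range(n_reads):
        a = annotations[rng.integers(len(annotations))]
        pos = max(1, a.tss + int(rng.integers(-d_max, d_max + 1)))
        reads.append(SignalRecord(a.chrom, pos, float(rng.integers(1, 4))))
    return reads


@pytest.fixture
def toy_annotation():
    return [
        GeneAnnotation("gA", "chr1", 10_000, "+"),
        GeneAnnotation("gB", "chr1", 13_000, "-"),
        GeneAnnotation("gC", "chr2", 50_000, "+"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_918)
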