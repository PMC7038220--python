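import numpy as np
import pytest

from bispeeg import BispectrumConfig, PreprocessConfig, SynthConfig
from bispeeg.pipeline import PipelineConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def naive_glrlm(image: np.ndarray, direction: int, G: int) -> np.ndarray:
    """Brute-force run counter: walk every line pixel by pixel.

    Independent of the vectorised implementation; used as the oracle.
    """
    rows, cols = image.shape
    R = max(rows, cols)
    P = np.zeros((G, R), dtype=int)
    if direction == 0:
        lines = [[image[r, c] for c in range(cols)] for r in range(rows)]
    elif direction == 90:
        lines = [[image[r, c] for r in range(rows)] for c in range(cols)]
    elif direction == 135:  # down-right
        starts = [(r, 0) for r in range(rows)] + [(0, c) for c in range(1, cols)]
        lines = []
        for r0, c0 in starts:
            line, r, c = [], r0, c0
            while r < rows and c < cols:
                line.append(image[r, c])
                r, c = r + 1, c + 1
            lines.append(line)
    elif direction == 45:  # up-right
        starts = [(r, 0) for r in range(rows)] + [(rows - 1, c) for c in range(1, cols)]
        lines = []
        for r0, c0 in starts:
            line, r, c = [], r0, c0
            while r >= 0 and c < cols:
                line.append(image[r, c])
                r, c = r - 1, c + 1
            lines.append(line)
    else:
        raise ValueError(direction)
    for line in lines:
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            P[line[i], j - i - 1] += 1
            i = j
    return P


def naive_bispectrum(blocks: np.ndarray, nfft: int) -> np.ndarray:
    """Direct triple-product oracle on pre-tapered, mean-removed blocks."""
    half = nfft // 2
    B = np.zeros((half + 1, half + 1), dtype=complex)
    for blk in blocks:
        X = np.fft.fft(blk, nfft)
        for i in range(half + 1):
            for j in range(half + 1):
                if i + j <= half:
                    B[i, j] += X[i] * X[j] * np.conj(X[(i + j) % nfft])
    return B / len(blocks)


@pytest.fixture
def tiny_synth_config():
    """Desk-scale cohort: small but large enough to carry a QPC contrast."""
    return SynthConfig(
        n_normal=6, n_asd=6, n_channels=2, duration_s=3.0,
        coupling_strength_normal=0.05, coupling_strength_asd=0.95,
        snr_db=15.0, seed=7, epoch_samples=256,
    )


@pytest.fixture
def tiny_pipeline_config(tiny_synth_config):
    return PipelineConfig(
        synth=tiny_synth_config,
        preprocess=PreprocessConfig(segment_len=1024),
        bispectrum=BispectrumConfig(nfft=256, block_len=256, block_overlap=0.5),
        n_folds=3,
        seed=11,
    )
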