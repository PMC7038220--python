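"""Gray-level run-length texture and histogram-entropy features.

Eighteen scalar features are computed from each quantized bispectrum image:
seven entropy/energy measures of the gray-level histogram and eleven
gray-level run-length matrix (GLRLM) statistics.  A run is a maximal
collinear sequence of pixels sharing one gray level; runs are counted along
the four standard directions 0°, 45°, 90°, 135° and each run-length feature
is the mean of its four per-direction values (the usual radiomics
convention).

Inside the run-length formulas the gray-level index i and the run-length
index j are both 1-based: an image with levels 0..G-1 is shifted to 1..G.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .bispectrum import GrayImage

__all__ = [
    "RunLengthMatrix",
    "EntropyConfig",
    "FEATURE_NAMES",
    "RUN_LENGTH_FEATURE_NAMES",
    "ENTROPY_FEATURE_NAMES",
    "DIRECTIONS",
    "glrlm",
    "run_length_features",
    "entropy_features",
    "extract_features",
]

DIRECTIONS = (0, 45, 90, 135)

ENTROPY_FEATURE_NAMES = (
    "log_energy",
    "kapur_entropy",
    "max_entropy",
    "renyi_entropy",
    "shannon_entropy",
    "vajda_entropy",
    "yager_entropy",
)

RUN_LENGTH_FEATURE_NAMES = (
    "SRE", "LRE", "GLN", "RLN", "RP",
    "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
)

#: fixed order of the 18 features in every FeatureVector / feature table
FEATURE_NAMES = ENTROPY_FEATURE_NAMES + RUN_LENGTH_FEATURE_NAMES


@dataclass
class RunLengthMatrix:
    """Run counts P[i-1, j-1] for gray level i in 1..G, run length j in 1..R."""

    P: np.ndarray  # (G, R) integer counts
    direction: int  # degrees, one of DIRECTIONS
    n_pixels: int

    @property
    def n_runs(self) -> int:
        return int(self.P.sum())


@dataclass(frozen=True)
class EntropyConfig:
    """Orders and guards of the histogram-entropy family.

    The published feature names ("Kapoor", "max", "Yager", "Vajda" entropy)
    do not pin down unique definitions; the defaults here are Kapur's
    two-parameter entropy, the min-entropy -log2 max p, Yager's fuzziness
    complement 1 - sum|2p-1|/G and the quadratic (Gini) entropy
    sum p(1-p).  ``overrides`` swaps any definition without touching
    callers: it maps a feature name to a callable ``f(p, cfg) -> float``.
    """

    renyi_alpha: float = 2.0
    kapur_alpha: float = 0.5
    kapur_beta: float = 0.7
    epsilon: float = 1e-12
    overrides: Mapping[str, Callable[[np.ndarray, "EntropyConfig"], float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.renyi_alpha <= 0 or self.renyi_alpha == 1.0:
            raise ValueError("renyi_alpha must be positive and != 1")
        if self.kapur_alpha == self.kapur_beta:
            raise ValueError("kapur_alpha must differ from kapur_beta")


def _lines(image: np.ndarray, direction: int) -> list[np.ndarray]:
    """Decompose the image into the 1-D lines along which runs are counted."""
    rows, cols = image.shape
    if direction == 0:
        return [image[r] for r in range(rows)]
    if direction == 90:
        return [image[:, c] for c in range(cols)]
    if direction == 135:  # down-right diagonals
        return [np.diagonal(image, k) for k in range(-rows + 1, cols)]
    if direction == 45:  # up-right anti-diagonals
        flipped = np.flipud(image)
        return [np.diagonal(flipped, k) for k in range(-rows + 1, cols)]
    raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction}")


def glrlm(image: np.ndarray | GrayImage, direction: int, n_gray_levels: int | None = None) -> RunLengthMatrix:
    """Count maximal equal-gray-level runs along one direction.

    Every pixel belongs to exactly one run per direction, so
    sum_ij j * P(i, j) equals the pixel count.
    """
    if isinstance(image, GrayImage):
        if n_gray_levels is None:
            n_gray_levels = image.n_gray_levels
        image = image.pixels
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    if not np.issubdtype(image.dtype, np.integer):
        if not np.array_equal(image, np.floor(image)):
            raise ValueError("image must hold integer gray levels")
        image = image.astype(int)
    if image.min() < 0:
        raise ValueError("gray levels must be >= 0")
    G = int(n_gray_levels) if n_gray_levels is not None else int(image.max()) + 1
    if image.max() >= G:
        raise ValueError(f"gray level {image.max()} outside 0..{G - 1}")
    R = max(image.shape)

    # concatenate all lines with a -1 sentinel so one run-length encoding pass
    # covers the whole direction
    lines = _lines(image, direction)
    sep = np.full(1, -1, dtype=int)
    flat = np.concatenate([a for line in lines for a in (line.astype(int), sep)])
    change = np.flatnonzero(np.diff(flat) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [flat.size]))
    values = flat[starts]
    lengths = ends - starts
    keep = values >= 0
    values, lengths = values[keep], lengths[keep]

    P = np.zeros((G, R), dtype=np.int64)
    np.add.at(P, (values, lengths - 1), 1)
    return RunLengthMatrix(P=P, direction=direction, n_pixels=int(image.size))


def run_length_features(
    rlms: list[RunLengthMatrix] | RunLengthMatrix,
    n_pixels: int | None = None,
) -> dict[str, float]:
    """The 11 run-length statistics, averaged over the supplied directions.

    With P(i, j) the run counts, n_r the total runs and n_p the pixel count:
    SRE = (1/n_r) sum P/j^2,  LRE = (1/n_r) sum P j^2,
    GLN = (1/n_r) sum_i (sum_j P)^2,  RLN = (1/n_r) sum_j (sum_i P)^2,
    RP = n_r/n_p,  LGRE/HGRE weight by 1/i^2 and i^2, and the four joint
    emphases combine the i and j weights.
    """
    if isinstance(rlms, RunLengthMatrix):
        rlms = [rlms]
    if not rlms:
        raise ValueError("need at least one run-length matrix")
    per_dir = []
    for rlm in rlms:
        P = rlm.P.astype(float)
        n_r = P.sum()
        if n_r == 0:
            raise ValueError("run-length matrix holds no runs")
        n_p = n_pixels if n_pixels is not None else rlm.n_pixels
        G, R = P.shape
        i = np.arange(1, G + 1)[:, None].astype(float)
        j = np.arange(1, R + 1)[None, :].astype(float)
        row = P.sum(axis=1)  # sum over j
        col = P.sum(axis=0)  # sum over i
        per_dir.append({
            "SRE": (P / j**2).sum() / n_r,
            "LRE": (P * j**2).sum() / n_r,
            "GLN": (row**2).sum() / n_r,
            "RLN": (col**2).sum() / n_r,
            "RP": n_r / n_p,
            "LGRE": (P / i**2).sum() / n_r,
            "HGRE": (P * i**2).sum() / n_r,
            "SRLGE": (P / (i**2 * j**2)).sum() / n_r,
            "SRHGE": (P * i**2 / j**2).sum() / n_r,
            "LRLGE": (P * j**2 / i**2).sum() / n_r,
            "LRHGE": (P * i**2 * j**2).sum() / n_r,
        })
    return {
        name: float(np.mean([d[name] for d in per_dir]))
        for name in RUN_LENGTH_FEATURE_NAMES
    }


def _histogram(image: np.ndarray, G: int) -> np.ndarray:
    counts = np.bincount(image.ravel(), minlength=G).astype(float)
    return counts / counts.sum()


def entropy_features(
    image: np.ndarray | GrayImage,
    config: EntropyConfig | None = None,
    n_gray_levels: int | None = None,
) -> dict[str, float]:
    """Seven entropy/energy measures of the gray-level histogram.

    p is the normalised G-bin histogram of the quantized image; zero
    probability bins are skipped in logarithmic sums.
    """
    cfg = config or EntropyConfig()
    if isinstance(image, GrayImage):
        if n_gray_levels is None:
            n_gray_levels = image.n_gray_levels
        image = image.pixels
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image must be nonempty")
    G = int(n_gray_levels) if n_gray_levels is not None else int(image.max()) + 1
    if G < 2:
        raise ValueError("need at least 2 gray levels")
    p = _histogram(image.astype(int), G)
    pnz = p[p > 0]

    a, b = cfg.kapur_alpha, cfg.kapur_beta
    alpha = cfg.renyi_alpha
    values = {
        "log_energy": float(np.sum(np.log2(pnz**2 + cfg.epsilon))),
        "kapur_entropy": float(np.log2(np.sum(p**a) / np.sum(p**b)) / (b - a)),
        "max_entropy": float(-np.log2(p.max())),
        "renyi_entropy": float(np.log2(np.sum(p**alpha)) / (1.0 - alpha)),
        "shannon_entropy": float(-np.sum(pnz * np.log2(pnz))),
        "vajda_entropy": float(np.sum(p * (1.0 - p))),
        "yager_entropy": float(1.0 - np.sum(np.abs(2.0 * p - 1.0)) / G),
    }
    for name, fn in cfg.overrides.items():
        if name not in values:
            raise KeyError(f"unknown entropy feature {name!r}")
        values[name] = float(fn(p, cfg))
    return values


def extract_features(
    image: GrayImage | np.ndarray,
    config: EntropyConfig | None = None,
    n_gray_levels: int | None = None,
) -> dict[str, float]:
    """The full 18-component feature vector of one gray image, in fixed order."""
    ent = entropy_features(image, config, n_gray_levels=n_gray_levels)
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    G = image.n_gray_levels if isinstance(image, GrayImage) else n_gray_levels
    rlms = [glrlm(pixels, d, n_gray_levels=G) for d in DIRECTIONS]
    rl = run_length_features(rlms)
    out = {**ent, **rl}
    return {name: out[name] for name in FEATURE_NAMES}
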