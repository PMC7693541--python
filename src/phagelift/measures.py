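"""The nine alignment-free dissimilarity/similarity measures.

Geometric measures (Euclidean, Manhattan, Chebyshev) act on relative
frequency vectors; d2 on raw counts; d2* and d2S on centered counts under
an order-r product-form background; CVTree, Teeling and EuF on the
(k-2)-order count-ratio normalization. All are symmetric in their two
arguments. Teeling is a similarity (higher = more alike); everything else
is a dissimilarity.

Words that are degenerate on both sides (zero observed and expected)
contribute 0 to every sum rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .background import NormalizedCounts
from .kmer import FrequencyVector, KmerCountVector

#: canonical measure names; "hao" is accepted as an alias for cvtree
MEASURE_NAMES = (
    "euclidean",
    "manhattan",
    "chebyshev",
    "d2",
    "d2star",
    "d2s",
    "cvtree",
    "teeling",
    "euf",
)

ALIASES = {"hao": "cvtree", "eu": "euclidean", "ma": "manhattan", "ch": "chebyshev"}

#: measures whose background is the (k-2)-order count-ratio model
K2_MEASURES = frozenset({"cvtree", "teeling", "euf"})
#: measures taking an explicit order-r product-form background
MARKOV_MEASURES = frozenset({"d2star", "d2s"})
#: measures read as similarities (higher = more alike)
SIMILARITY_MEASURES = frozenset({"teeling"})


def canonical_name(name: str) -> str:
    name = name.lower()
    name = ALIASES.get(name, name)
    if name not in MEASURE_NAMES:
        raise ValueError(f"unknown measure {name!r}; choose from {MEASURE_NAMES}")
    return name


@dataclass(frozen=True)
class MeasureSpec:
    """A measure plus the k-mer/background configuration it runs at.

    ``markov_order`` is used only by d2star/d2s; cvtree/teeling/euf imply
    order k-2 and the geometric measures and d2 need no background.
    """

    name: str
    k: int
    markov_order: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", canonical_name(self.name))
        if self.name in K2_MEASURES and self.k < 3:
            raise ValueError(f"{self.name} requires k >= 3")
        if self.name in MARKOV_MEASURES and not 0 <= self.markov_order <= self.k - 1:
            raise ValueError(
                f"markov_order must be in [0, k-1] = [0, {self.k - 1}], got {self.markov_order}"
            )

    @property
    def direction(self) -> str:
        return "similarity" if self.name in SIMILARITY_MEASURES else "dissimilarity"


# ---------------------------------------------------------------------------
# geometric measures on frequency vectors
# ---------------------------------------------------------------------------

def frequency_distance(name: str, fx: FrequencyVector, fy: FrequencyVector, *,
                       rooted_euclidean: bool = False) -> float:
    """Euclidean / Manhattan / Chebyshev distance between frequency vectors.

    Euclidean defaults to the squared form ``sum (f^X_w - f^Y_w)^2``;
    ``rooted_euclidean`` exposes the square-rooted variant (ranking and the
    ratio-at-1 classification rule are unchanged either way).
    """
    name = canonical_name(name)
    if fx.k != fy.k:
        raise ValueError(f"mismatched k: {fx.k} vs {fy.k}")
    diff = fx.freqs - fy.freqs
    if name == "euclidean":
        val = float(np.sum(diff * diff))
        return float(np.sqrt(val)) if rooted_euclidean else val
    if name == "manhattan":
        return float(np.abs(diff).sum())
    if name == "chebyshev":
        return float(np.abs(diff).max())
    raise ValueError(f"{name!r} is not a frequency-vector distance")


# ---------------------------------------------------------------------------
# count-based measures
# ---------------------------------------------------------------------------

def d2(x: KmerCountVector, y: KmerCountVector) -> float:
    """d2 = (1 - cosine similarity of raw count vectors) / 2, in [0, 1]."""
    if x.k != y.k:
        raise ValueError(f"mismatched k: {x.k} vs {y.k}")
    xs = x.counts.astype(float)
    ys = y.counts.astype(float)
    nx = np.sqrt(np.sum(xs * xs))
    ny = np.sqrt(np.sum(ys * ys))
    if nx == 0 or ny == 0:
        raise ValueError("d2 undefined for an all-zero count vector")
    return 0.5 * (1.0 - float(np.dot(xs, ys)) / (nx * ny))


def d2star(nx: NormalizedCounts, ny: NormalizedCounts) -> float:
    """Background-normalized d2*: centered counts weighted by 1/sqrt(E).

    Numerator terms with E(X_w)E(Y_w) = 0 are skipped; each denominator sum
    skips terms with zero expectation on its own side.
    """
    if nx.k != ny.k:
        raise ValueError(f"mismatched k: {nx.k} vs {ny.k}")
    ex, ey = nx.expected, ny.expected
    both = (ex > 0) & (ey > 0)
    num = float(np.sum(nx.centered[both] * ny.centered[both] / np.sqrt(ex[both] * ey[both])))
    mx = ex > 0
    my = ey > 0
    dx = float(np.sum(nx.centered[mx] ** 2 / ex[mx]))
    dy = float(np.sum(ny.centered[my] ** 2 / ey[my]))
    denom = np.sqrt(dx) * np.sqrt(dy)
    if denom == 0:
        raise ValueError("d2star undefined: no informative words")
    return 0.5 * (1.0 - num / denom)


def d2s(nx: NormalizedCounts, ny: NormalizedCounts) -> float:
    """Background-normalized d2S: centered counts self-standardized by
    sqrt(X~^2 + Y~^2). Always in [0, 1]; words with X~ = Y~ = 0 contribute 0.
    """
    if nx.k != ny.k:
        raise ValueError(f"mismatched k: {nx.k} vs {ny.k}")
    cx, cy = nx.centered, ny.centered
    denom_w = np.sqrt(cx * cx + cy * cy)
    live = denom_w > 0
    num = float(np.sum(cx[live] * cy[live] / denom_w[live]))
    dx = float(np.sum(cx[live] ** 2 / denom_w[live]))
    dy = float(np.sum(cy[live] ** 2 / denom_w[live]))
    denom = np.sqrt(dx) * np.sqrt(dy)
    if denom == 0:
        raise ValueError("d2s undefined: all words degenerate")
    return 0.5 * (1.0 - num / denom)


def cvtree(rx: NormalizedCounts, ry: NormalizedCounts, *, centered: bool = False) -> float:
    """Composition-vector distance on (k-2)-order ratio-normalized counts.

    ``(1 - cosine) / 2`` on X~ = X/E vectors by default; ``centered``
    switches to the (X - E)/E composition-vector variant.
    """
    if rx.k != ry.k:
        raise ValueError(f"mismatched k: {rx.k} vs {ry.k}")
    xs = (rx.ratio - 1.0) * (rx.expected > 0) if centered else rx.ratio
    ys = (ry.ratio - 1.0) * (ry.expected > 0) if centered else ry.ratio
    nx = np.sqrt(np.sum(xs * xs))
    ny = np.sqrt(np.sum(ys * ys))
    if nx == 0 or ny == 0:
        raise ValueError("cvtree undefined: zero-norm ratio vector")
    return 0.5 * (1.0 - float(np.dot(xs, ys)) / (nx * ny))


def teeling(zx: np.ndarray, zy: np.ndarray) -> float:
    """Teeling similarity: inner product of per-side z-score vectors.

    z_w = (X_w - E(X_w)) / sqrt(var(X_w)) under the (k-2)-order model;
    words with var = 0 must already carry z = 0 (see
    :func:`teeling_zscores`). Higher means more similar.
    """
    if zx.shape != zy.shape:
        raise ValueError("z-score vectors must have the same shape")
    return float(np.dot(zx, zy))


def teeling_zscores(norm: NormalizedCounts, var: np.ndarray) -> np.ndarray:
    """Per-word z-scores for the Teeling similarity; 0 where var <= 0."""
    live = var > 0
    z = np.zeros_like(norm.centered)
    z[live] = norm.centered[live] / np.sqrt(var[live])
    return z


def euf(rx: NormalizedCounts, ry: NormalizedCounts) -> float:
    """EuF: mean absolute difference of ratio-normalized counts over all
    4^k words, ``(1/4^k) sum_w |X~_w - Y~_w|`` with X~ = X/E.
    """
    if rx.k != ry.k:
        raise ValueError(f"mismatched k: {rx.k} vs {ry.k}")
    return float(np.abs(rx.ratio - ry.ratio).sum()) / (4**rx.k)
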