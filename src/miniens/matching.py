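"""Cross-session cell registration from spatial footprints.

Two sessions' footprint sets are first brought into register by a rigid
translation estimated from the cross-correlation of their summed
footprint images (an automated stand-in for landmark alignment). Cell
pairs then match when their spatial (Pearson) correlation is at least
0.8 and their centroid distance at most 5 px; conflicts resolve by a
greedy one-to-one assignment in descending correlation. The overlap
index of a matched pair of sessions is

    n_matched / ((n1 + n2) / 2),

i.e. matched cells over the mean number of cells detected per session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage.registration import phase_cross_correlation
from sklearn.base import BaseEstimator

from .errors import InvalidConfigError, InvalidInputError
from .simulate import Footprint, FootprintSet

__all__ = [
    "MatchParams",
    "MatchResult",
    "OverlapIndexResult",
    "centroid",
    "align_translation",
    "spatial_correlation",
    "match_cells",
    "overlap_index",
    "FootprintMatcher",
]


@dataclass(frozen=True)
class MatchParams:
    corr_min: float = 0.8
    dist_max_px: float = 5.0
    alignment_mode: str = "translation"  # "translation" | "none"

    def __post_init__(self) -> None:
        if not 0.0 < self.corr_min <= 1.0:
            raise InvalidConfigError("corr_min must lie in (0, 1]")
        if self.dist_max_px <= 0:
            raise InvalidConfigError("dist_max_px must be positive")
        if self.alignment_mode not in ("translation", "none"):
            raise InvalidConfigError("alignment_mode must be 'translation' or 'none'")


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float, float]]  # (index1, index2, correlation, distance)
    n1: int
    n2: int
    transform: tuple[float, float]  # estimated (dx, dy) applied to session 2
    params: MatchParams = field(default_factory=MatchParams)

    def __post_init__(self) -> None:
        i1 = [p[0] for p in self.pairs]
        i2 = [p[1] for p in self.pairs]
        if len(set(i1)) != len(i1) or len(set(i2)) != len(i2):
            raise InvalidInputError("matching is not one-to-one")
        for _, _, c, d in self.pairs:
            if c < self.params.corr_min or d > self.params.dist_max_px:
                raise InvalidInputError("pair violates match thresholds")

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    def identity_pairs(self) -> list[tuple[int, int]]:
        return [(p[0], p[1]) for p in self.pairs]


@dataclass
class OverlapIndexResult:
    n_matched: int
    n1: int
    n2: int

    @property
    def index(self) -> float:
        return self.n_matched / ((self.n1 + self.n2) / 2.0)


def centroid(fp: Footprint) -> tuple[float, float]:
    """Intensity-weighted center of mass, returned as (x, y) = (col, row) px."""
    w = np.asarray(fp.weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise InvalidInputError("footprint has no positive weight")
    rr, cc = np.mgrid[: w.shape[0], : w.shape[1]]
    r = (rr * w).sum() / total + fp.offset[0]
    c = (cc * w).sum() / total + fp.offset[1]
    return float(c), float(r)


def align_translation(
    set1: FootprintSet, set2: FootprintSet, upsample: int = 20
) -> tuple[tuple[float, float], FootprintSet]:
    """Estimate the rigid shift of session 2 relative to session 1.

    Maximizes the cross-correlation of the two sessions' summed footprint
    images (subpixel, via Fourier upsampling) and returns the estimated
    (dx, dy) together with session-2 footprints translated back into
    session-1 coordinates (patch offsets move by the rounded shift).
    """
    if len(set1) == 0 or len(set2) == 0:
        raise InvalidInputError("cannot align empty footprint sets")
    if set1.fov != set2.fov:
        raise InvalidInputError("footprint sets have different FOV dimensions")
    shift_rc, _err, _phase = phase_cross_correlation(
        set1.sum_image(), set2.sum_image(), upsample_factor=upsample, normalization=None
    )
    dy, dx = float(shift_rc[0]), float(shift_rc[1])  # shift to apply to set2
    aligned = set2.translated((dx, dy))
    return (-dx, -dy), aligned  # transform reports set2's displacement from set1


def spatial_correlation(fp1: Footprint, fp2: Footprint) -> float:
    """Pearson correlation of pixel weights over the union of supports.

    Computed on the union of the two nonzero supports (not the full
    frame) so the shared zero background cannot inflate the value.
    Degenerate cases (empty union, zero variance) return NaN and are
    treated as non-matches.
    """
    r0 = min(fp1.offset[0], fp2.offset[0])
    c0 = min(fp1.offset[1], fp2.offset[1])
    r1 = max(fp1.offset[0] + fp1.weights.shape[0], fp2.offset[0] + fp2.weights.shape[0])
    c1 = max(fp1.offset[1] + fp1.weights.shape[1], fp2.offset[1] + fp2.weights.shape[1])
    a = np.zeros((r1 - r0, c1 - c0))
    b = np.zeros_like(a)
    a[
        fp1.offset[0] - r0 : fp1.offset[0] - r0 + fp1.weights.shape[0],
        fp1.offset[1] - c0 : fp1.offset[1] - c0 + fp1.weights.shape[1],
    ] = fp1.weights
    b[
        fp2.offset[0] - r0 : fp2.offset[0] - r0 + fp2.weights.shape[0],
        fp2.offset[1] - c0 : fp2.offset[1] - c0 + fp2.weights.shape[1],
    ] = fp2.weights
    mask = (a > 0) | (b > 0)
    if mask.sum() < 2:
        return float("nan")
    x, y = a[mask], b[mask]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def match_cells(
    set1: FootprintSet,
    set2: FootprintSet,
    params: MatchParams | None = None,
    transform: tuple[float, float] = (0.0, 0.0),
) -> MatchResult:
    """One-to-one matching of aligned footprint sets by correlation + distance.

    Candidate pairs are those with centroid distance <= ``dist_max_px``
    (found via a KD-tree) and spatial correlation >= ``corr_min``; the
    final assignment is greedy in descending correlation, ties broken by
    smaller centroid distance, then lower indices. Deterministic.
    """
    params = params or MatchParams()
    if len(set1) == 0 or len(set2) == 0:
        return MatchResult([], len(set1), len(set2), transform, params)
    c1 = set1.centroids()
    c2 = set2.centroids()
    tree = cKDTree(c2)
    candidates = []
    for i, p in enumerate(c1):
        for j in tree.query_ball_point(p, params.dist_max_px):
            d = float(np.hypot(*(p - c2[j])))
            corr = spatial_correlation(set1[i], set2[j])
            if np.isnan(corr) or corr < params.corr_min:
                continue
            candidates.append((i, j, corr, d))
    candidates.sort(key=lambda t: (-t[2], t[3], t[0], t[1]))
    used1: set[int] = set()
    used2: set[int] = set()
    pairs = []
    for i, j, corr, d in candidates:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        pairs.append((i, j, corr, d))
    pairs.sort(key=lambda t: t[0])
    return MatchResult(pairs, len(set1), len(set2), transform, params)


def overlap_index(match: MatchResult) -> OverlapIndexResult:
    """Matched cells over the mean per-session cell count."""
    if match.n1 == 0 and match.n2 == 0:
        raise InvalidInputError("both sessions are empty")
    return OverlapIndexResult(match.n_matched, match.n1, match.n2)


class FootprintMatcher(BaseEstimator):
    """Alignment + matching as one estimator.

    ``fit(set1, set2)`` estimates the rigid shift (when ``alignment_mode
    == 'translation'``), matches cells and stores the results:

    Attributes
    ----------
    shift_ : tuple of float
        Estimated (dx, dy) displacement of session 2 from session 1.
    result_ : MatchResult
        One-to-one matched pairs with correlations and distances.
    overlap_ : OverlapIndexResult
        Overlap index of the matched sessions.
    """

    def __init__(self, corr_min: float = 0.8, dist_max_px: float = 5.0, alignment_mode: str = "translation"):
        self.corr_min = corr_min
        self.dist_max_px = dist_max_px
        self.alignment_mode = alignment_mode

    def fit(self, set1: FootprintSet, set2: FootprintSet):
        params = MatchParams(self.corr_min, self.dist_max_px, self.alignment_mode)
        if params.alignment_mode == "translation":
            shift, aligned2 = align_translation(set1, set2)
        else:
            shift, aligned2 = (0.0, 0.0), set2
        self.shift_ = shift
        self.result_ = match_cells(set1, aligned2, params, transform=shift)
        self.overlap_ = overlap_index(self.result_)
        return self

    def predict(self, set1=None, set2=None) -> list[tuple[int, int]]:
        if not hasattr(self, "result_"):
            raise InvalidInputError("matcher is not fitted")
        return self.result_.identity_pairs()
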