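"""One-sided permutation test for above-chance top-cell overlap.

Per subject, the top 10% most active cells are identified in a prior
context (A), a home-cage session (HC) and a target context (B); cells in
all three top sets are excluded. The observed overlap for A↔B (and
HC↔B) is the proportion of B's top cells, after exclusion, that are also
top in the other session. The null permutes the assignment of B's rates
to cell identities (ranks in A and HC stay fixed) and recomputes the
overlap; p is the fraction of null overlaps >= the observed one (may be
exactly 0 under this estimator). Group-level p compares the
across-subject mean observed overlap with the distribution of
across-subject means of each shuffle (shuffles paired across subjects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .allocation import top_fraction
from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "PermutationParams",
    "PermutationResult",
    "real_top_overlap",
    "shuffle_null",
    "p_value",
    "group_p",
    "permutation_test",
]


@dataclass(frozen=True)
class PermutationParams:
    n_shuffles: int = 1000
    q: float = 0.10
    seed: int = 0
    exclude_triple: bool = True
    plus_one_correction: bool = False

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise InvalidConfigError("n_shuffles must be >= 1")
        if not 0.0 < self.q <= 1.0:
            raise InvalidConfigError("q must lie in (0, 1]")


@dataclass
class PermutationResult:
    comparison: str  # "A-B" or "HC-B"
    real_overlap: float
    null_overlaps: np.ndarray
    p_value: float
    n_excluded_triple: int


def _top_mask(rates: np.ndarray, q: float) -> np.ndarray:
    ts = top_fraction(rates, q)
    mask = np.zeros(rates.shape[0], dtype=bool)
    mask[ts.member_ids] = True
    return mask


def _overlap(
    top_x: np.ndarray, top_b: np.ndarray, triple: np.ndarray | None
) -> tuple[float, int]:
    """Proportion of B's top cells (after triple exclusion) also top in X."""
    if triple is not None:
        top_x = top_x & ~triple
        top_b = top_b & ~triple
    denom = int(top_b.sum())
    if denom == 0:
        return float("nan"), 0
    return float((top_x & top_b).sum() / denom), denom


def real_top_overlap(
    rates_a: np.ndarray,
    rates_b: np.ndarray,
    rates_hc: np.ndarray | None = None,
    params: PermutationParams | None = None,
) -> dict[str, tuple[float, int]]:
    """Observed overlaps {comparison: (overlap, n_excluded_triple)}.

    With ``rates_hc`` given, returns both "A-B" and "HC-B" comparisons,
    excluding cells whose top-set membership spans all three sessions
    (when ``exclude_triple``). With ``rates_hc=None`` only "A-B" is
    computed and triple exclusion does not apply.
    """
    params = params or PermutationParams()
    rates_a = np.asarray(rates_a, dtype=float)
    rates_b = np.asarray(rates_b, dtype=float)
    if rates_a.shape != rates_b.shape:
        raise InvalidInputError("rate vectors must share the same universe")
    top_a = _top_mask(rates_a, params.q)
    top_b = _top_mask(rates_b, params.q)
    if rates_hc is None:
        ov, _ = _overlap(top_a, top_b, None)
        return {"A-B": (ov, 0)}
    rates_hc = np.asarray(rates_hc, dtype=float)
    if rates_hc.shape != rates_b.shape:
        raise InvalidInputError("rate vectors must share the same universe")
    top_hc = _top_mask(rates_hc, params.q)
    triple = (top_a & top_hc & top_b) if params.exclude_triple else None
    n_tri = int(triple.sum()) if triple is not None else 0
    ov_ab, _ = _overlap(top_a, top_b, triple)
    ov_hb, _ = _overlap(top_hc, top_b, triple)
    return {"A-B": (ov_ab, n_tri), "HC-B": (ov_hb, n_tri)}


def shuffle_null(
    rates_a: np.ndarray,
    rates_b: np.ndarray,
    rates_hc: np.ndarray | None = None,
    params: PermutationParams | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Null overlap distributions from permuted B-session identities.

    Each shuffle permutes which cell carries which B rate, keeping the A
    and HC ranks fixed, and recomputes the overlap with the same
    exclusion rule. Returns {comparison: array of n_shuffles overlaps}.
    """
    params = params or PermutationParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rates_a = np.asarray(rates_a, dtype=float)
    rates_b = np.asarray(rates_b, dtype=float)
    top_a = _top_mask(rates_a, params.q)
    top_hc = _top_mask(np.asarray(rates_hc, dtype=float), params.q) if rates_hc is not None else None
    n = rates_b.shape[0]
    out: dict[str, list[float]] = {"A-B": []}
    if top_hc is not None:
        out["HC-B"] = []
    for _ in range(params.n_shuffles):
        perm = rng.permutation(n)
        top_b = _top_mask(rates_b[perm], params.q)
        if top_hc is None:
            ov, _ = _overlap(top_a, top_b, None)
            out["A-B"].append(ov)
        else:
            triple = (top_a & top_hc & top_b) if params.exclude_triple else None
            out["A-B"].append(_overlap(top_a, top_b, triple)[0])
            out["HC-B"].append(_overlap(top_hc, top_b, triple)[0])
    return {k: np.asarray(v) for k, v in out.items()}


def p_value(
    real_overlap: float, null_overlaps: np.ndarray, plus_one_correction: bool = False
) -> float:
    """Fraction of null overlaps >= the observed overlap (one-sided).

    The uncorrected estimator can return exactly 0; the optional
    (k+1)/(n+1) correction bounds it away from 0.
    """
    null_overlaps = np.asarray(null_overlaps, dtype=float)
    if null_overlaps.size == 0:
        raise InvalidInputError("empty null distribution")
    if np.isnan(real_overlap):
        return float("nan")
    k = int(np.sum(null_overlaps >= real_overlap))
    n = null_overlaps.size
    return (k + 1) / (n + 1) if plus_one_correction else k / n


def group_p(
    real_values: np.ndarray,
    null_matrix: np.ndarray,
    method: str = "paired-mean",
    plus_one_correction: bool = False,
) -> float:
    """Group-level p across subjects.

    ``paired-mean`` (default): compare the across-subject mean observed
    overlap with the distribution of across-subject means of shuffle s
    (s paired across subjects). ``pooled``: pool all subjects' null
    values and compare with the mean observed overlap. Subjects with an
    undefined (NaN) observed overlap are excluded.
    """
    real_values = np.asarray(real_values, dtype=float)
    null_matrix = np.asarray(null_matrix, dtype=float)
    if null_matrix.ndim != 2 or null_matrix.shape[0] != real_values.shape[0]:
        raise InvalidInputError("null matrix must be subjects x shuffles")
    ok = ~np.isnan(real_values)
    if not ok.any():
        raise InvalidInputError("no subject has a defined observed overlap")
    real_values = real_values[ok]
    null_matrix = null_matrix[ok]
    mean_real = real_values.mean()
    if method == "paired-mean":
        null_stat = null_matrix.mean(axis=0)
    elif method == "pooled":
        null_stat = null_matrix.ravel()
    else:
        raise InvalidConfigError("method must be 'paired-mean' or 'pooled'")
    return p_value(mean_real, null_stat, plus_one_correction)


def permutation_test(
    rates_a: np.ndarray,
    rates_b: np.ndarray,
    rates_hc: np.ndarray | None = None,
    params: PermutationParams | None = None,
) -> dict[str, PermutationResult]:
    """Full subject-level test: observed overlap, null, and p per comparison."""
    params = params or PermutationParams()
    real = real_top_overlap(rates_a, rates_b, rates_hc, params)
    null = shuffle_null(rates_a, rates_b, rates_hc, params)
    out = {}
    for comp, (ov, n_tri) in real.items():
        p = p_value(ov, null[comp], params.plus_one_correction)
        out[comp] = PermutationResult(comp, ov, null[comp], p, n_tri)
    return out
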