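"""Top-percentile allocation statistics over a shared cell universe.

The "universe" U is the set of all cells detected across the sessions
under analysis (cells recorded in separate sessions must first be joined
into one ID space via footprint matching). A session's top set is the
top fraction q of its active cells ranked by average event rate. From
top sets come: the four-way composition of a target session's top set
(prior-context only / home-cage only / both / unique), the joint
top-percentile probability P = |top_a ∩ top_b| / U normalized by its
chance level q_a * q_b (1 under independence), and the allocation
balance ratio (n_prior − n_homecage) / (n_prior + n_homecage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError, InvalidInputError

__all__ = [
    "TopSet",
    "AllocationComposition",
    "AllocationProbability",
    "top_fraction",
    "allocation_composition",
    "joint_percentile_probability",
    "allocation_balance_ratio",
]


@dataclass
class TopSet:
    session_id: str
    fraction: float
    member_ids: np.ndarray  # sorted neuron IDs in the shared universe
    n_active: int

    def __post_init__(self) -> None:
        self.member_ids = np.asarray(self.member_ids, dtype=int)

    def as_set(self) -> set[int]:
        return set(self.member_ids.tolist())


@dataclass
class AllocationComposition:
    frac_prior_only: float
    frac_homecage_only: float
    frac_both: float
    frac_unique: float

    def __post_init__(self) -> None:
        total = (
            self.frac_prior_only + self.frac_homecage_only + self.frac_both + self.frac_unique
        )
        if not np.isclose(total, 1.0):
            raise InvalidInputError("composition fractions must sum to 1")

    @property
    def frac_prior_total(self) -> float:
        """Share of the target top set found in the prior-context top set."""
        return self.frac_prior_only + self.frac_both


@dataclass
class AllocationProbability:
    n_joint: int
    universe: int
    q_a: float
    q_b: float

    @property
    def p_observed(self) -> float:
        return self.n_joint / self.universe

    @property
    def chance(self) -> float:
        return self.q_a * self.q_b

    @property
    def normalized(self) -> float:
        return self.p_observed / self.chance


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def top_fraction(rates: np.ndarray, q: float = 0.10, session_id: str = "session") -> TopSet:
    """Top fraction ``q`` of active cells by descending event rate.

    Cells with zero rate do not count as active in the session. The set
    size is ``max(1, round(q * n_active))`` (half-up rounding); ties in
    rate break toward the lower neuron ID via a stable descending sort.
    NaN rates mark cells absent from the session.
    """
    if not 0.0 < q <= 1.0:
        raise InvalidConfigError("q must lie in (0, 1]")
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 1:
        raise InvalidInputError("rates must be a 1-D per-neuron vector")
    with np.errstate(invalid="ignore"):
        if np.any(rates[np.isfinite(rates)] < 0):
            raise InvalidInputError("rates must be non-negative")
    active = np.flatnonzero(np.nan_to_num(rates, nan=0.0) > 0)
    if active.size == 0:
        raise InvalidInputError("no active neurons in session")
    n_top = max(1, _round_half_up(q * active.size))
    order = active[np.argsort(-rates[active], kind="stable")]
    members = np.sort(order[:n_top])
    return TopSet(session_id, q, members, int(active.size))


def allocation_composition(
    top_target: TopSet, top_prior: TopSet, top_homecage: TopSet
) -> AllocationComposition:
    """Partition the target top set by membership in the two earlier sets."""
    tgt = top_target.as_set()
    if not tgt:
        raise InvalidInputError("target top set is empty")
    prior = top_prior.as_set()
    home = top_homecage.as_set()
    n = len(tgt)
    n_both = len(tgt & prior & home)
    n_prior = len(tgt & prior) - n_both
    n_home = len(tgt & home) - n_both
    n_unique = n - n_both - n_prior - n_home
    return AllocationComposition(n_prior / n, n_home / n, n_both / n, n_unique / n)


def joint_percentile_probability(
    top_a: TopSet, top_b: TopSet, universe: int
) -> AllocationProbability:
    """P = |top_a ∩ top_b| / U with its chance normalization q_a * q_b."""
    if universe <= 0:
        raise InvalidInputError("universe must be positive")
    if universe < len(top_a.member_ids) or universe < len(top_b.member_ids):
        raise InvalidInputError("universe smaller than a top set")
    n_joint = len(top_a.as_set() & top_b.as_set())
    return AllocationProbability(n_joint, universe, top_a.fraction, top_b.fraction)


def allocation_balance_ratio(n_prior_in_target: int, n_homecage_in_target: int) -> float:
    """(n_prior − n_homecage) / (n_prior + n_homecage), in [−1, 1].

    Cells in both earlier top sets contribute to both counts. NaN when
    both counts are zero (undefined; report as an exclusion).
    """
    a, b = n_prior_in_target, n_homecage_in_target
    if a < 0 or b < 0:
        raise InvalidInputError("counts must be non-negative")
    if a + b == 0:
        return float("nan")
    return (a - b) / (a + b)
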