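"""Synthetic miniscope data with known ground truth.

Generates the three kinds of input the analysis consumes:

* per-session fluorescence traces (neurons x frames) built from Poisson
  spike trains convolved with a GCaMP6f-like double-exponential kernel
  (fast rise, slow decay) plus Gaussian noise and optional slow drift;
* per-session spatial footprints (truncated 2-D Gaussians on a miniscope
  field of view) with a designed fraction of cells shared between two
  sessions under a rigid shift plus bounded per-cell jitter;
* histology count tables (DAPI / c-Fos / marker / double-positive per
  subject) with a designed enrichment of the double-positive fraction
  over the independence expectation.

Every generator is a deterministic function of its configuration and seed,
and the cross-session ground truth (spike times, identity map) is recorded
so detection, matching and overlap statistics can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, InvalidConfigError

__all__ = [
    "SimConfig",
    "GroundTruth",
    "Footprint",
    "FootprintSet",
    "TraceMatrix",
    "SessionData",
    "transient_kernel_peak",
    "generate_spike_trains",
    "render_traces",
    "generate_footprints",
    "generate_session_pair",
    "generate_counts",
]

_PLACEMENT_RETRY_CAP = 10_000  # rejection-sampling retries per neuron


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic recording.

    Defaults mirror a miniscope session: 30 frames/s on a 600 x 600 px
    field of view, 10-min recordings, sparse (~0.1 Hz) firing, transients
    with a 50 ms rise and 500 ms decay. ``amplitude`` is expressed in
    units of ``noise_sd``; the default of 30 puts simulated cells safely
    above the peak-to-noise inclusion threshold applied to extracted
    neurons. ``firing_rate_hz`` may be a scalar or a ``(lo, hi)`` range;
    with a range each cell draws one base rate reused in every session,
    giving cells a persistent activity rank.
    """

    n_neurons: int = 100
    fps: float = 30.0
    duration_s: float = 600.0
    firing_rate_hz: float | tuple[float, float] = 0.1
    rise_tau_ms: float = 50.0
    decay_tau_ms: float = 500.0
    amplitude: float = 30.0
    noise_sd: float = 1.0
    drift_amplitude: float = 0.0
    drift_period_s: float = 120.0
    fov_px: tuple[int, int] = (600, 600)
    footprint_sigma_px: float = 2.5
    min_separation_px: float = 15.0
    shared_fraction: float = 0.3
    shift_px: tuple[float, float] = (3.0, 0.0)
    jitter_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "fov_px", tuple(self.fov_px))
        object.__setattr__(self, "shift_px", tuple(self.shift_px))
        if not np.isscalar(self.firing_rate_hz):
            object.__setattr__(self, "firing_rate_hz", tuple(self.firing_rate_hz))
        if self.fps <= 0:
            raise InvalidConfigError("fps must be positive")
        if self.duration_s <= 0:
            raise InvalidConfigError("duration_s must be positive")
        lo, hi = self.rate_range()
        if lo < 0 or hi < lo:
            raise InvalidConfigError("firing_rate_hz must be >= 0 (lo <= hi for a range)")
        if self.rise_tau_ms <= 0 or self.decay_tau_ms <= 0:
            raise InvalidConfigError("transient time constants must be positive")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise InvalidConfigError("shared_fraction must lie in [0, 1]")
        if self.min_separation_px <= 0:
            raise InvalidConfigError("min_separation_px must be positive")
        if self.n_neurons < 1:
            raise InvalidConfigError("n_neurons must be >= 1")
        if self.jitter_px < 0:
            raise InvalidConfigError("jitter_px must be >= 0")
        if self.drift_period_s < 60.0 and self.drift_amplitude > 0:
            raise InvalidConfigError("drift_period_s must be >= 60 s (slow baseline only)")

    def rate_range(self) -> tuple[float, float]:
        if np.isscalar(self.firing_rate_hz):
            r = float(self.firing_rate_hz)  # type: ignore[arg-type]
            return r, r
        lo, hi = self.firing_rate_hz  # type: ignore[misc]
        return float(lo), float(hi)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class GroundTruth:
    """What the generator knows and the analysis must recover."""

    spike_times: dict[str, list[np.ndarray]]
    identity_map: list[tuple[int, int]]
    session_membership: dict[str, list[int]]  # pool index -> sessions containing it

    def __post_init__(self) -> None:
        idx1 = [i for i, _ in self.identity_map]
        idx2 = [j for _, j in self.identity_map]
        if len(set(idx1)) != len(idx1) or len(set(idx2)) != len(idx2):
            raise InvalidConfigError("identity_map must be one-to-one")


@dataclass
class Footprint:
    """One cell's spatial weight image, stored as a compact patch.

    ``weights`` is the non-zero patch and ``offset`` its top-left corner
    (row, col) in the field of view.
    """

    weights: np.ndarray
    offset: tuple[int, int]
    fov: tuple[int, int]

    @property
    def centroid(self) -> tuple[float, float]:
        """Intensity-weighted center of mass as (x, y) = (col, row) in px."""
        from .matching import centroid

        return centroid(self)

    def to_dense(self) -> np.ndarray:
        img = np.zeros(self.fov, dtype=self.weights.dtype)
        r0, c0 = self.offset
        h, w = self.weights.shape
        img[r0 : r0 + h, c0 : c0 + w] = self.weights
        return img


class FootprintSet:
    """Ordered collection of footprints on a common field of view."""

    def __init__(self, footprints: Sequence[Footprint], fov: tuple[int, int]):
        for fp in footprints:
            if fp.fov != tuple(fov):
                raise InvalidConfigError("all footprints must share the FOV")
        self.footprints = list(footprints)
        self.fov = tuple(fov)

    def __len__(self) -> int:
        return len(self.footprints)

    def __getitem__(self, i: int) -> Footprint:
        return self.footprints[i]

    def __iter__(self):
        return iter(self.footprints)

    def centroids(self) -> np.ndarray:
        """(n, 2) array of (x, y) centroids."""
        return np.array([fp.centroid for fp in self.footprints], dtype=float)

    def sum_image(self) -> np.ndarray:
        img = np.zeros(self.fov, dtype=float)
        for fp in self.footprints:
            r0, c0 = fp.offset
            h, w = fp.weights.shape
            img[r0 : r0 + h, c0 : c0 + w] += fp.weights
        return img

    def translated(self, shift_xy: tuple[float, float]) -> "FootprintSet":
        """Return a copy with every patch offset and centroid shifted.

        The shift is rounded to whole pixels for the patch offsets (weights
        are never resampled).
        """
        dx, dy = int(round(shift_xy[0])), int(round(shift_xy[1]))
        out = []
        for fp in self.footprints:
            r0, c0 = fp.offset
            out.append(Footprint(fp.weights, (r0 + dy, c0 + dx), fp.fov))
        return FootprintSet(out, self.fov)


@dataclass
class TraceMatrix:
    """Raw per-neuron fluorescence over frames for one session."""

    values: np.ndarray  # neurons x frames
    fps: float
    session_id: str = "session"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise InvalidConfigError("trace matrix must be 2-D with >= 1 neuron")
        if not np.all(np.isfinite(self.values)):
            raise InvalidConfigError("trace matrix contains non-finite values")
        if self.fps <= 0:
            raise InvalidConfigError("fps must be positive")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class SessionData:
    """One simulated session: traces plus footprints plus metadata."""

    traces: TraceMatrix
    footprints: FootprintSet
    fps: float
    session_id: str
    meta: dict = field(default_factory=dict)


def generate_spike_trains(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    rates: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Homogeneous Poisson spike trains over ``[0, duration_s]``.

    ``rates`` overrides the per-neuron rates (used to keep a cell's rate
    consistent across sessions); otherwise rates come from the config.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if rates is None:
        lo, hi = cfg.rate_range()
        rates = rng.uniform(lo, hi, size=cfg.n_neurons) if hi > lo else np.full(cfg.n_neurons, lo)
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise InvalidConfigError("firing rates must be >= 0")
    trains = []
    for r in rates:
        n = rng.poisson(r * cfg.duration_s)
        trains.append(np.sort(rng.uniform(0.0, cfg.duration_s, size=n)))
    return trains


def transient_kernel_peak(rise_tau_ms: float, decay_tau_ms: float) -> float:
    """Closed-form maximum of ``(1 - e^(-t/tr)) * e^(-t/td)`` over t >= 0."""
    tr, td = rise_tau_ms, decay_tau_ms
    t_star = tr * np.log1p(td / tr)
    return float((1.0 - np.exp(-t_star / tr)) * np.exp(-t_star / td))


def render_traces(
    spikes: Sequence[np.ndarray],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    session_id: str = "session",
) -> TraceMatrix:
    """Sum double-exponential transients at spike times, add noise/drift.

    Each spike contributes ``amplitude * (1 - e^(-t/tau_rise)) * e^(-t/tau_decay)``
    for t past the spike, sampled on the frame grid.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n_frames = cfg.n_frames
    t = np.arange(n_frames) / cfg.fps
    tr = cfg.rise_tau_ms / 1000.0
    td = cfg.decay_tau_ms / 1000.0
    # support window: decay below 1e-4 of peak
    win = int(np.ceil((td * np.log(1e4)) * cfg.fps)) + 1
    values = np.zeros((len(spikes), n_frames))
    for i, train in enumerate(spikes):
        if np.any((np.asarray(train) < 0) | (np.asarray(train) > cfg.duration_s)):
            raise InvalidConfigError("spike times must lie within [0, duration_s]")
        row = values[i]
        for s in train:
            j0 = int(np.ceil(s * cfg.fps))
            j1 = min(j0 + win, n_frames)
            if j0 >= n_frames:
                continue
            dt = t[j0:j1] - s
            row[j0:j1] += cfg.amplitude * (1.0 - np.exp(-dt / tr)) * np.exp(-dt / td)
    if cfg.drift_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, size=len(spikes))
        drift = cfg.drift_amplitude * np.sin(
            2 * np.pi * t[None, :] / cfg.drift_period_s + phases[:, None]
        )
        values += drift
    if cfg.noise_sd > 0:
        values += rng.normal(0.0, cfg.noise_sd, size=values.shape)
    return TraceMatrix(values, fps=cfg.fps, session_id=session_id)


def _place_centers(
    n: int,
    fov: tuple[int, int],
    min_sep: float,
    margin: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rejection-sample (row, col) centers with pairwise separation >= min_sep."""
    h, w = fov
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise CapacityError("field of view too small for the footprint margin")
    centers: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(_PLACEMENT_RETRY_CAP):
            c = rng.uniform([margin, margin], [h - margin, w - margin])
            if all(np.hypot(*(c - prev)) >= min_sep for prev in centers):
                centers.append(c)
                break
        else:
            raise CapacityError(
                f"could not place {n} cells at separation {min_sep} px in {fov}"
            )
    return np.array(centers)


def _render_footprint(
    center_rc: np.ndarray, sigma: float, fov: tuple[int, int]
) -> Footprint:
    rad = int(np.ceil(4 * sigma))
    r0 = int(np.floor(center_rc[0])) - rad
    c0 = int(np.floor(center_rc[1])) - rad
    size = 2 * rad + 1
    rr = np.arange(r0, r0 + size)[:, None] - center_rc[0]
    cc = np.arange(c0, c0 + size)[None, :] - center_rc[1]
    d2 = rr**2 + cc**2
    patch = np.exp(-d2 / (2 * sigma**2))
    patch[d2 > (4 * sigma) ** 2] = 0.0  # truncate at 4 SD
    # clip the patch to the FOV
    h, w = fov
    rlo, rhi = max(0, -r0), min(size, h - r0)
    clo, chi = max(0, -c0), min(size, w - c0)
    patch = patch[rlo:rhi, clo:chi]
    return Footprint(patch, (r0 + rlo, c0 + clo), tuple(fov))


def generate_footprints(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> FootprintSet:
    """Truncated 2-D Gaussian footprints at separated random centers."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    margin = 4 * cfg.footprint_sigma_px + 1
    centers = _place_centers(cfg.n_neurons, cfg.fov_px, cfg.min_separation_px, margin, rng)
    fps = [_render_footprint(c, cfg.footprint_sigma_px, cfg.fov_px) for c in centers]
    return FootprintSet(fps, cfg.fov_px)


def generate_session_pair(
    cfg: SimConfig,
) -> tuple[SessionData, SessionData, GroundTruth]:
    """Two sessions sharing ``round(shared_fraction * n_neurons)`` cells.

    Each session contains ``n_neurons`` cells: the shared pool plus
    session-unique cells. Session-2 footprints of shared cells are the
    session-1 footprints under the configured rigid shift plus a per-cell
    centroid jitter drawn uniformly in ``[-jitter_px, +jitter_px]`` per
    axis; traces are regenerated independently per session from each
    cell's base firing rate. Cell order within each session is shuffled
    so indices carry no identity information.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_neurons
    n_shared = int(round(cfg.shared_fraction * n))
    n_unique = n - n_shared
    n_total = n_shared + 2 * n_unique

    dx, dy = cfg.shift_px
    margin = 4 * cfg.footprint_sigma_px + 1 + max(abs(dx), abs(dy)) + cfg.jitter_px + 1
    centers = _place_centers(n_total, cfg.fov_px, cfg.min_separation_px, margin, rng)
    shared_c = centers[:n_shared]
    uniq1_c = centers[n_shared : n_shared + n_unique]
    uniq2_c = centers[n_shared + n_unique :]

    # session-2 coordinates: rigid shift (dx cols, dy rows) + bounded jitter
    jitter = rng.uniform(-cfg.jitter_px, cfg.jitter_px, size=(n_shared, 2))
    shared_c2 = shared_c + np.array([dy, dx]) + jitter
    uniq2_c2 = uniq2_c + np.array([dy, dx])

    lo, hi = cfg.rate_range()
    base_rates = (
        rng.uniform(lo, hi, size=n_total) if hi > lo else np.full(n_total, lo)
    )

    order1 = rng.permutation(n)  # positions of [shared, unique1] in session 1
    order2 = rng.permutation(n)

    def build_session(
        centers_rc: np.ndarray, pool_ids: np.ndarray, order: np.ndarray, sid: str, sub: int
    ) -> SessionData:
        centers_rc = centers_rc[order]
        ids = pool_ids[order]
        fps = FootprintSet(
            [_render_footprint(c, cfg.footprint_sigma_px, cfg.fov_px) for c in centers_rc],
            cfg.fov_px,
        )
        srng = np.random.default_rng((cfg.seed, sub))
        trains = generate_spike_trains(
            replace(cfg, n_neurons=n), rng=srng, rates=base_rates[ids]
        )
        traces = render_traces(trains, replace(cfg, n_neurons=n), rng=srng, session_id=sid)
        sd = SessionData(traces, fps, cfg.fps, sid, meta={"pool_ids": ids.tolist()})
        sd.meta["spike_times"] = trains
        return sd

    ids1 = np.concatenate([np.arange(n_shared), n_shared + np.arange(n_unique)])
    ids2 = np.concatenate(
        [np.arange(n_shared), n_shared + n_unique + np.arange(n_unique)]
    )
    s1 = build_session(np.vstack([shared_c, uniq1_c]), ids1, order1, "session1", 1)
    s2 = build_session(np.vstack([shared_c2, uniq2_c2]), ids2, order2, "session2", 2)

    pos1 = np.argsort(order1)  # pool slot -> session index
    pos2 = np.argsort(order2)
    identity_map = [(int(pos1[k]), int(pos2[k])) for k in range(n_shared)]
    membership: dict[str, list[int]] = {}
    for k in range(n_total):
        sessions = []
        if k < n_shared + n_unique:
            sessions.append(1)
        if k < n_shared or k >= n_shared + n_unique:
            sessions.append(2)
        membership[str(k)] = sessions
    gt = GroundTruth(
        spike_times={"session1": s1.meta.pop("spike_times"), "session2": s2.meta.pop("spike_times")},
        identity_map=identity_map,
        session_membership=membership,
    )
    return s1, s2, gt


def generate_counts(
    n_subjects: int,
    dapi_n: int,
    p_cfos: float,
    p_marker: float,
    enrichment: float,
    seed: int = 0,
    group: str = "sim",
    subfield: str = "CA1",
) -> pd.DataFrame:
    """Histology count table with a designed double-positive enrichment.

    Per subject: ``cfos ~ Bin(dapi_n, p_cfos)``, ``marker ~ Bin(dapi_n,
    p_marker)`` and ``double_pos ~ Bin(dapi_n, enrichment * p_cfos *
    p_marker)`` clipped to ``min(cfos, marker)``. ``enrichment = 1``
    reproduces independence; the observed/chance ratio then averages ~1.
    """
    if not (0.0 <= p_cfos <= 1.0 and 0.0 <= p_marker <= 1.0):
        raise InvalidConfigError("probabilities must lie in [0, 1]")
    if enrichment < 0:
        raise InvalidConfigError("enrichment must be >= 0")
    p_joint = enrichment * p_cfos * p_marker
    if p_joint > min(p_cfos, p_marker) if p_cfos * p_marker > 0 else p_joint > 1:
        raise InvalidConfigError(
            "joint probability exceeds min(p_cfos, p_marker): infeasible enrichment"
        )
    rng = np.random.default_rng(seed)
    cfos = rng.binomial(dapi_n, p_cfos, size=n_subjects)
    marker = rng.binomial(dapi_n, p_marker, size=n_subjects)
    double = rng.binomial(dapi_n, p_joint, size=n_subjects)
    double = np.minimum(double, np.minimum(cfos, marker))
    return pd.DataFrame(
        {
            "subject": [f"s{i:03d}" for i in range(n_subjects)],
            "group": group,
            "subfield": subfield,
            "dapi": dapi_n,
            "cfos": cfos,
            "marker": marker,
            "double_pos": double,
        }
    )
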