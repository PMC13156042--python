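"""Calcium-event detection by derivative thresholding, QC and event rates.

The detector separates steep fluorescence rises (putative calcium
transients) from noise without fitting a generative model: each trace is
convolved with two Gaussian kernels (SD 50 and 100 ms), decimated 3x so
each point spans ~100 ms, and first-differenced; a decimated point is an
event only when its rise exceeds, in *every* kernel pipeline, that
pipeline's per-neuron threshold Q3 + 1.5*IQR of the difference
distribution (~3 SD above the mean for a normal distribution). Events are
binary; the per-session rate is the number of 1s divided by the number of
decimated points (and per second, by the decimated interval).

Quality control flags neurons whose peak-to-noise ratio falls below 20 or
whose noise residual is strongly asymmetric between the first and third
quartiles; flagged cells are excluded from downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import InvalidConfigError, InvalidInputError
from .simulate import TraceMatrix

__all__ = [
    "DetectionParams",
    "QCParams",
    "EventRaster",
    "gaussian_smooth",
    "decimate",
    "steepness_threshold",
    "CalciumEventDetector",
    "detect_events",
    "TraceQC",
    "qc_neuron",
    "event_rate",
    "normalize_to_first",
    "activity_ratio",
]


@dataclass(frozen=True)
class DetectionParams:
    kernel_sds_ms: tuple[float, ...] = (50.0, 100.0)
    decim_factor: int = 3
    iqr_multiplier: float = 1.5
    fps: float = 30.0
    decim_mode: str = "mean"  # "mean" (block average) or "subsample"
    merge_consecutive: bool = False

    def __post_init__(self) -> None:
        if len(self.kernel_sds_ms) < 2:
            raise InvalidConfigError("at least two smoothing kernels are required")
        if any(k <= 0 for k in self.kernel_sds_ms):
            raise InvalidConfigError("kernel SDs must be positive")
        if self.decim_factor < 1:
            raise InvalidConfigError("decim_factor must be >= 1")
        if self.iqr_multiplier <= 0:
            raise InvalidConfigError("iqr_multiplier must be positive")
        if self.fps <= 0:
            raise InvalidConfigError("fps must be positive")
        if self.decim_mode not in ("mean", "subsample"):
            raise InvalidConfigError("decim_mode must be 'mean' or 'subsample'")


@dataclass(frozen=True)
class QCParams:
    pnr_min: float = 20.0
    noise_iqr_asymmetry_max: float = 2.0

    def __post_init__(self) -> None:
        if self.pnr_min <= 0:
            raise InvalidConfigError("pnr_min must be positive")


@dataclass
class EventRaster:
    """Binary events per neuron on the decimated time grid."""

    events: np.ndarray  # neurons x points, uint8 in {0, 1}
    dt_s: float

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events)
        if not np.isin(self.events, (0, 1)).all():
            raise InvalidInputError("event raster must be binary")
        if self.dt_s <= 0:
            raise InvalidInputError("dt_s must be positive")

    @property
    def n_neurons(self) -> int:
        return self.events.shape[0]

    @property
    def n_points(self) -> int:
        return self.events.shape[1]


def gaussian_smooth(trace: np.ndarray, sd_ms: float, fps: float) -> np.ndarray:
    """Convolve with a unit-area Gaussian of SD ``sd_ms`` (in frames: sd_ms/1000*fps).

    Truncated at 4 SD with reflect padding, so constants are preserved and
    edges produce no derivative spikes. Works on 1-D traces or 2-D
    (neurons x frames) matrices along the last axis.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise InvalidInputError("empty trace")
    if sd_ms <= 0:
        raise InvalidInputError("kernel SD must be positive")
    sd_frames = sd_ms / 1000.0 * fps
    return gaussian_filter1d(trace, sd_frames, axis=-1, mode="reflect", truncate=4.0)


def decimate(series: np.ndarray, factor: int, mode: str = "mean") -> np.ndarray:
    """Reduce non-overlapping blocks of ``factor`` samples to one point.

    ``mean`` averages each block (the default; alias-safe after the prior
    smoothing); ``subsample`` keeps the first sample of each block. Output
    length is ``floor(len / factor)``; a trailing partial block is dropped.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if factor < 1:
        raise InvalidInputError("decimation factor must be >= 1")
    if factor > n:
        raise InvalidInputError(f"decimation factor {factor} exceeds length {n}")
    m = n // factor
    trimmed = series[..., : m * factor]
    if mode == "mean":
        return trimmed.reshape(*series.shape[:-1], m, factor).mean(axis=-1)
    if mode == "subsample":
        return trimmed[..., ::factor]
    raise InvalidInputError(f"unknown decimation mode {mode!r}")


def steepness_threshold(derivatives: np.ndarray, iqr_multiplier: float = 1.5) -> float:
    """Q3 + ``iqr_multiplier`` * IQR of a first-difference distribution.

    With the default multiplier this sits ~3 SD above the mean of a normal
    distribution (0.6745 + 1.5 * 1.3490 = 2.698 SD). Quartiles use linear
    interpolation between order statistics. A constant series yields 0.
    """
    d = np.asarray(derivatives, dtype=float)
    if d.size < 4:
        raise InvalidInputError("need at least 4 points to estimate quartiles")
    if d.max() == d.min():  # degenerate: no spread to threshold against
        return 0.0
    q1, q3 = np.quantile(d, [0.25, 0.75], method="linear")
    return float(q3 + iqr_multiplier * (q3 - q1))


class CalciumEventDetector(BaseEstimator, TransformerMixin):
    """Derivative-threshold event detector over multiple Gaussian smoothings.

    ``fit`` learns per-neuron, per-kernel steepness thresholds from the
    decimated first-difference distributions of the traces; ``transform``
    applies them, returning a binary neurons x points raster in which a
    point is 1 only when its rise clears the threshold in every kernel
    pipeline. Thresholds are trace statistics, so the usual call is
    ``fit_transform`` on one session.

    Parameters
    ----------
    kernel_sds_ms : sequence of float
        SDs of the smoothing kernels in ms (default 50 and 100).
    decim_factor : int
        Temporal decimation factor (default 3; ~100 ms points at 30 fps).
    iqr_multiplier : float
        Multiplier on the IQR above Q3 (default 1.5).
    fps : float
        Acquisition rate in frames per second.
    decim_mode : str
        'mean' for block averaging, 'subsample' to keep every Nth point.
    merge_consecutive : bool
        If True, runs of consecutive suprathreshold points collapse to a
        single event at the run onset. Off by default: every
        suprathreshold point counts as one event.

    Attributes
    ----------
    thresholds_ : ndarray of shape (n_neurons, n_kernels)
        Learned per-neuron steepness thresholds.
    n_points_ : int
        Length of the decimated grid, floor(n_frames / decim_factor).
    """

    def __init__(
        self,
        kernel_sds_ms=(50.0, 100.0),
        decim_factor: int = 3,
        iqr_multiplier: float = 1.5,
        fps: float = 30.0,
        decim_mode: str = "mean",
        merge_consecutive: bool = False,
    ):
        self.kernel_sds_ms = kernel_sds_ms
        self.decim_factor = decim_factor
        self.iqr_multiplier = iqr_multiplier
        self.fps = fps
        self.decim_mode = decim_mode
        self.merge_consecutive = merge_consecutive

    def _params(self) -> DetectionParams:
        return DetectionParams(
            kernel_sds_ms=tuple(self.kernel_sds_ms),
            decim_factor=int(self.decim_factor),
            iqr_multiplier=float(self.iqr_multiplier),
            fps=float(self.fps),
            decim_mode=self.decim_mode,
            merge_consecutive=bool(self.merge_consecutive),
        )

    @staticmethod
    def _as_matrix(X) -> np.ndarray:
        if isinstance(X, TraceMatrix):
            X = X.values
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2:
            raise InvalidInputError("traces must be a neurons x frames matrix")
        if not np.all(np.isfinite(X)):
            raise InvalidInputError("traces contain non-finite values")
        return X

    def _diffs(self, X: np.ndarray) -> list[np.ndarray]:
        p = self._params()
        if X.shape[1] < 2 * p.decim_factor:
            raise InvalidInputError("trace shorter than two decimated points")
        out = []
        m = None
        for sd in p.kernel_sds_ms:
            sm = gaussian_smooth(X, sd, p.fps)
            dec = decimate(sm, p.decim_factor, p.decim_mode)
            if m is None:
                m = dec.shape[1]
            elif dec.shape[1] != m:
                raise InvalidInputError("kernel pipelines produced mismatched grids")
            out.append(np.diff(dec, axis=1))
        return out

    def fit(self, X, y=None):
        X = self._as_matrix(X)
        diffs = self._diffs(X)
        p = self._params()
        self.n_features_in_ = X.shape[1]
        self.n_points_ = X.shape[1] // p.decim_factor
        thr = np.empty((X.shape[0], len(diffs)))
        for k, d in enumerate(diffs):
            for i in range(X.shape[0]):
                thr[i, k] = steepness_threshold(d[i], p.iqr_multiplier)
        self.thresholds_ = thr
        return self

    def transform(self, X) -> EventRaster:
        if not hasattr(self, "thresholds_"):
            raise InvalidInputError("detector is not fitted")
        X = self._as_matrix(X)
        p = self._params()
        diffs = self._diffs(X)
        m = X.shape[1] // p.decim_factor
        # diffs have length m-1; the rise into decimated point i (i >= 1)
        # is diff[i-1], so point 0 can never be an event.
        above = np.ones((X.shape[0], m - 1), dtype=bool)
        for k, d in enumerate(diffs):
            above &= d > self.thresholds_[:, [k]]
        events = np.zeros((X.shape[0], m), dtype=np.uint8)
        events[:, 1:] = above
        if p.merge_consecutive:
            onset = events.copy()
            onset[:, 1:] &= ~events[:, :-1]
            events = onset
        return EventRaster(events, dt_s=p.decim_factor / p.fps)


def detect_events(traces, params: DetectionParams | None = None) -> EventRaster:
    """One-call detection: fit thresholds on the traces and apply them."""
    params = params or DetectionParams()
    det = CalciumEventDetector(
        kernel_sds_ms=params.kernel_sds_ms,
        decim_factor=params.decim_factor,
        iqr_multiplier=params.iqr_multiplier,
        fps=params.fps,
        decim_mode=params.decim_mode,
        merge_consecutive=params.merge_consecutive,
    )
    return det.fit(traces).transform(traces)


def _robust_sd(x: np.ndarray) -> float:
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def qc_neuron(
    trace: np.ndarray,
    params: QCParams | None = None,
    fps: float = 30.0,
    smooth_sd_ms: float = 100.0,
) -> dict:
    """Keep/flag decision with reasons for one neuron's trace.

    PNR = (max - median of the 100 ms-smoothed trace) / robust noise SD,
    with noise = raw - smoothed and robust SD = 1.4826 * MAD. The noise
    asymmetry statistic is (|Q3| - |Q1|) / |Q1| of the noise residual
    (centred quartiles of a symmetric distribution give ~0).
    """
    params = params or QCParams()
    trace = np.asarray(trace, dtype=float)
    if trace.size < 8:
        raise InvalidInputError("trace too short for QC")
    sm = gaussian_smooth(trace, smooth_sd_ms, fps)
    noise = trace - sm
    sd = _robust_sd(noise)
    reasons = []
    if sd == 0:
        return {"keep": False, "pnr": np.inf, "asymmetry": np.nan, "reasons": ["degenerate_noise"]}
    pnr = float((sm.max() - np.median(sm)) / sd)
    q1, q3 = np.quantile(noise, [0.25, 0.75], method="linear")
    asym = float((abs(q3) - abs(q1)) / abs(q1)) if q1 != 0 else np.inf
    if pnr < params.pnr_min:
        reasons.append("low_pnr")
    if asym > params.noise_iqr_asymmetry_max:
        reasons.append("noise_asymmetry")
    return {"keep": not reasons, "pnr": pnr, "asymmetry": asym, "reasons": reasons}


class TraceQC(BaseEstimator):
    """Noisy-neuron screen as an estimator.

    ``fit`` computes per-neuron PNR and noise-asymmetry statistics;
    ``flags_`` marks neurons to exclude, ``report_`` carries the numbers.
    """

    def __init__(self, pnr_min: float = 20.0, noise_iqr_asymmetry_max: float = 2.0, fps: float = 30.0):
        self.pnr_min = pnr_min
        self.noise_iqr_asymmetry_max = noise_iqr_asymmetry_max
        self.fps = fps

    def fit(self, X, y=None):
        X = CalciumEventDetector._as_matrix(X)
        p = QCParams(self.pnr_min, self.noise_iqr_asymmetry_max)
        rows = [qc_neuron(x, p, fps=self.fps) for x in X]
        self.report_ = pd.DataFrame(
            {
                "neuron": np.arange(len(rows)),
                "pnr": [r["pnr"] for r in rows],
                "asymmetry": [r["asymmetry"] for r in rows],
                "keep": [r["keep"] for r in rows],
                "reasons": [",".join(r["reasons"]) for r in rows],
            }
        )
        self.flags_ = ~self.report_["keep"].to_numpy()
        return self

    def keep_mask(self) -> np.ndarray:
        return ~self.flags_


def event_rate(raster: EventRaster, session_id: str = "session") -> pd.DataFrame:
    """Per-neuron event rates: per decimated point and per second."""
    if raster.n_points == 0:
        raise InvalidInputError("empty raster")
    counts = raster.events.sum(axis=1)
    per_point = counts / raster.n_points
    return pd.DataFrame(
        {
            "neuron": np.arange(raster.n_neurons),
            "session": session_id,
            "n_events": counts,
            "rate_per_point": per_point,
            "rate_events_per_s": per_point / raster.dt_s,
        }
    )


def normalize_to_first(rates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Divide each matched neuron's session rates by its first-session rate.

    ``rates`` is sessions x neurons for neurons matched across all
    sessions. Neurons with a zero first-session rate are excluded (their
    columns are NaN); the boolean exclusion mask is returned alongside.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim != 2 or rates.shape[0] < 2:
        raise InvalidInputError("need a sessions x neurons matrix with >= 2 sessions")
    if rates.shape[1] == 0:
        import warnings

        warnings.warn("no matched neurons to normalize", stacklevel=2)
        return rates.copy(), np.zeros(0, dtype=bool)
    first = rates[0]
    excluded = first == 0
    out = np.full_like(rates, np.nan)
    out[:, ~excluded] = rates[:, ~excluded] / first[~excluded]
    return out, excluded


def activity_ratio(rate1, rate2) -> np.ndarray:
    """Session-preference index ``(rate1 - rate2) / (rate1 + rate2)`` in [-1, 1].

    Undefined (NaN) where both rates are zero; callers should report the
    NaN count as exclusions.
    """
    r1 = np.asarray(rate1, dtype=float)
    r2 = np.asarray(rate2, dtype=float)
    denom = r1 + r2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (r1 - r2) / np.where(denom > 0, denom, 1.0), np.nan)
    return out
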