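"""ROI time-series cleaning and head-motion quality control.

The cleaning chain mirrors standard resting-state practice at the ROI level:
linear detrend, temporal band-pass to the low-frequency BOLD band
(0.01–0.08 Hz by default), and nuisance regression against an arbitrary
confound matrix (typically the Friston 24-parameter motion expansion plus
surrogate white-matter / CSF signals).  All three steps are linear maps of
the input signal, and the fixed order detrend -> band-pass -> nuisance
regression is what :class:`SignalCleaner` applies.

Motion QC follows the common conventions: framewise displacement in the
Power formulation (sum of absolute backward differences, rotations scaled
by a 50 mm head radius) and a hard exclusion rule at 2 mm translation or
2 degrees rotation in any direction at any frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "RoiTimeSeries",
    "MotionParams",
    "FramewiseDisplacement",
    "MotionExclusion",
    "detrend_linear",
    "bandpass_filter",
    "friston24",
    "regress_nuisance",
    "framewise_displacement",
    "motion_exclusion",
    "clean_timeseries",
    "SignalCleaner",
]

MIN_VOLUMES = 20  # shorter runs cannot support the band-pass / correlation


@dataclass
class RoiTimeSeries:
    """One subject's T x N BOLD-like signal matrix.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    data : ndarray of shape (T, N)
        Signal matrix, rows are time points, columns are ROIs.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    roi_labels : list of str
        N unique ROI names.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (T x N)")
        if not self.roi_labels:
            self.roi_labels = [f"ROI_{i + 1:03d}" for i in range(self.data.shape[1])]
        if len(self.roi_labels) != self.data.shape[1]:
            raise ValueError("roi_labels length must match the number of columns")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("roi_labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time-series data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class MotionParams:
    """Rigid-body motion trace: T x 6 (x, y, z translations in mm; pitch,
    roll, yaw rotations in radians)."""

    subject_id: str
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 6:
            raise ValueError("motion parameters must be T x 6")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("motion parameters contain non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.data[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.data[:, 3:]


@dataclass(frozen=True)
class FramewiseDisplacement:
    """Per-frame FD series (mm) with its scalar summaries."""

    fd: np.ndarray
    fd_max: float
    fd_mean: float
    fd_rms: float


@dataclass(frozen=True)
class MotionExclusion:
    exclude: bool
    reason: str | None = None


def detrend_linear(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Remove the per-column OLS line (intercept + slope on frame index).

    The residual columns have zero mean and zero linear trend.
    """
    if ts.n_volumes < 3:
        raise ValueError("need at least 3 time points to detrend")
    out = sps.detrend(ts.data, axis=0, type="linear")
    return replace(ts, data=out)


def bandpass_filter(
    ts: RoiTimeSeries, low_hz: float = 0.01, high_hz: float = 0.08, order: int = 4
) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass in the temporal domain.

    A forward-backward (``sosfiltfilt``) pass is used so that the filter is
    zero phase: band-pass filtering must not introduce lags that would
    distort inter-regional correlations.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not 0.0 < low_hz < high_hz:
        raise ValueError("require 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist}"
        )
    sos = sps.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos"
    )
    out = sps.sosfiltfilt(sos, ts.data, axis=0)
    return replace(ts, data=out)


def friston24(mp: MotionParams) -> np.ndarray:
    """Expand 6 rigid-body parameters into the 24-parameter motion model.

    Columns are ``[R, R^2, R_lag, R_lag^2]`` where ``R`` is the T x 6 motion
    matrix and ``R_lag`` its one-frame backward shift (first row zero).
    """
    r = mp.data
    r_lag = np.zeros_like(r)
    r_lag[1:] = r[:-1]
    return np.hstack([r, r**2, r_lag, r_lag**2])


def regress_nuisance(ts: RoiTimeSeries, nuisance: np.ndarray) -> RoiTimeSeries:
    """Residualize every ROI column against a nuisance matrix.

    An intercept column is always appended, so the output is also demeaned.
    Rank-deficient nuisance matrices are handled by the least-squares
    pseudoinverse.
    """
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.ndim == 1:
        nuisance = nuisance[:, None]
    if nuisance.shape[0] != ts.n_volumes:
        raise ValueError("nuisance matrix must have one row per time point")
    design = np.column_stack([np.ones(ts.n_volumes), nuisance])
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    out = ts.data - design @ beta
    return replace(ts, data=out)


def framewise_displacement(
    mp: MotionParams, head_radius_mm: float = 50.0
) -> FramewiseDisplacement:
    """Power-convention framewise displacement.

    ``FD(t) = sum |delta translations| + head_radius * sum |delta rotations|``
    with ``FD(0) = 0``; rotations (radians) are converted to arc length on a
    sphere of ``head_radius_mm``.
    """
    d = np.abs(np.diff(mp.data, axis=0))
    fd = np.zeros(mp.n_volumes)
    fd[1:] = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return FramewiseDisplacement(
        fd=fd,
        fd_max=float(fd.max(initial=0.0)),
        fd_mean=float(fd.mean()) if fd.size else 0.0,
        fd_rms=float(np.sqrt(np.mean(fd**2))) if fd.size else 0.0,
    )


def motion_exclusion(
    mp: MotionParams, trans_limit_mm: float = 2.0, rot_limit_deg: float = 2.0
) -> MotionExclusion:
    """Flag a subject whose motion exceeds 2 mm or 2 degrees in any direction.

    Rotations are stored in radians and converted to degrees for the
    comparison.
    """
    axes = ["x", "y", "z", "pitch", "roll", "yaw"]
    abs_trans = np.abs(mp.translations)
    abs_rot_deg = np.degrees(np.abs(mp.rotations))
    if np.any(abs_trans > trans_limit_mm):
        frame, axis = np.unravel_index(np.argmax(abs_trans), abs_trans.shape)
        return MotionExclusion(
            True,
            f"translation {abs_trans[frame, axis]:.3f} mm on {axes[axis]} "
            f"at frame {frame} exceeds {trans_limit_mm} mm",
        )
    if np.any(abs_rot_deg > rot_limit_deg):
        frame, axis = np.unravel_index(np.argmax(abs_rot_deg), abs_rot_deg.shape)
        return MotionExclusion(
            True,
            f"rotation {abs_rot_deg[frame, axis]:.3f} deg on {axes[axis + 3]} "
            f"at frame {frame} exceeds {rot_limit_deg} deg",
        )
    return MotionExclusion(False, None)


def clean_timeseries(
    ts: RoiTimeSeries,
    nuisance: np.ndarray | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 4,
) -> RoiTimeSeries:
    """Full cleaning chain: detrend -> band-pass -> nuisance regression.

    The order is fixed; changing it changes the output (the nuisance
    regressors are fit to the already-filtered signal).
    """
    out = detrend_linear(ts)
    out = bandpass_filter(out, low_hz=low_hz, high_hz=high_hz, order=order)
    if nuisance is not None:
        out = regress_nuisance(out, nuisance)
    return out


class SignalCleaner(BaseEstimator, TransformerMixin):
    """sklearn-style transformer applying the cleaning chain to subjects.

    ``transform`` accepts a single :class:`RoiTimeSeries`, a ``(RoiTimeSeries,
    MotionParams)`` pair, or a list of either; motion parameters, when given,
    are expanded to the 24-parameter nuisance model before regression.

    Parameters
    ----------
    low_hz, high_hz : float
        Band-pass edges in Hz.
    order : int
        Butterworth order.
    use_friston24 : bool
        Expand paired motion traces into 24 nuisance regressors.
    """

    def __init__(
        self,
        low_hz: float = 0.01,
        high_hz: float = 0.08,
        order: int = 4,
        use_friston24: bool = True,
    ):
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.order = order
        self.use_friston24 = use_friston24

    def fit(self, X, y=None):  # noqa: D102 - stateless, sklearn API
        self.n_features_in_ = None
        return self

    def _clean_one(self, item):
        if isinstance(item, tuple):
            ts, mp = item
            nuisance = friston24(mp) if self.use_friston24 else mp.data
        else:
            ts, nuisance = item, None
        return clean_timeseries(
            ts, nuisance=nuisance, low_hz=self.low_hz, high_hz=self.high_hz,
            order=self.order,
        )

    def transform(self, X):  # noqa: D102 - sklearn API
        if isinstance(X, (RoiTimeSeries, tuple)):
            return self._clean_one(X)
        return [self._clean_one(item) for item in X]
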