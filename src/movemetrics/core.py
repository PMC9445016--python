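"""Kinematic and statistical primitives for movement-health metric extraction.

These are the building blocks every activity metric and balance score is
assembled from: the 95% prediction-ellipse area used to quantify postural
sway from transverse-plane center-of-mass acceleration, hysteresis-based
toe-tap counting, the outlier-damped decile-median extremum, and windowed
angle variance.

Units follow the measurement chain throughout: joint angles in degrees,
vertical positions in meters (Z up-positive), center-of-mass acceleration
in m/s^2, sampling rates in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

#: 0.95 quantile of the chi-square distribution with 2 degrees of freedom.
#: Scales the sample covariance into the 95% prediction ellipse.
CHI2_95_2DF: float = float(chi2.ppf(0.95, 2))


class KinematicsError(ValueError):
    """Invalid input to a kinematic primitive."""


class DegenerateInputError(KinematicsError):
    """Input too small or too degenerate for the requested computation."""


def _as_floats(values) -> np.ndarray:
    arr = np.asarray(getattr(values, "values", values), dtype=float)
    if arr.ndim != 1:
        raise KinematicsError(f"expected a 1-D sequence, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    values : array-like
        Samples in the channel's units (deg, m, m/s^2, ...).
    fs : float
        Sampling rate in Hz; must be positive.
    t0 : float, optional
        Start time in seconds.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise KinematicsError("TimeSeries requires a non-empty 1-D sequence")
        if not np.isfinite(arr).all():
            raise KinematicsError("TimeSeries contains non-finite samples")
        if not (self.fs > 0):
            raise KinematicsError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.values.size / self.fs


@dataclass(frozen=True)
class PlanarSamples:
    """Paired transverse-plane (X, Y) samples, e.g. COM acceleration in m/s^2."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise KinematicsError("x and y must be 1-D and of equal length")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise KinematicsError("planar samples contain non-finite values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.x.size

    def as_matrix(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def ellipse_area_from_cov(cov: np.ndarray) -> float:
    """Area of the 95% prediction ellipse implied by a 2x2 covariance.

    area = pi * chi2_{2,0.95} * sqrt(det(cov)); 0 for a singular covariance.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise KinematicsError(f"covariance must be 2x2, got {cov.shape}")
    det = float(np.linalg.det(cov))
    if det <= 0.0:
        return 0.0
    return float(np.pi * CHI2_95_2DF * np.sqrt(det))


def ellipse_area_95(samples: PlanarSamples) -> float:
    """Postural-sway area: the 95% prediction ellipse of planar samples.

    The ellipse is the chi-square (2 df) prediction ellipse on the sample
    covariance (n-1 denominator). Collinear or constant samples have a
    singular covariance and yield area 0.

    Raises
    ------
    DegenerateInputError
        If fewer than 3 samples are provided.
    """
    if len(samples) < 3:
        raise DegenerateInputError(
            f"ellipse area needs >= 3 samples, got {len(samples)}"
        )
    cov = np.cov(samples.x, samples.y, ddof=1)
    return ellipse_area_from_cov(cov)


def points_in_ellipse(samples: PlanarSamples, cov: np.ndarray,
                      center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Boolean mask of samples inside the 95% ellipse of a given covariance.

    Membership is the squared Mahalanobis distance being at most the
    chi-square (2 df) 0.95 quantile.
    """
    cov = np.asarray(cov, dtype=float)
    pts = samples.as_matrix() - np.asarray(center, dtype=float)
    sol = np.linalg.solve(cov, pts.T)
    d2 = np.einsum("ij,ji->i", pts, sol)
    return d2 <= CHI2_95_2DF


def count_toe_taps(z_raised: TimeSeries, z_plant: TimeSeries,
                   hysteresis: float = 0.005) -> int:
    """Count ground contacts of the raised foot during single-leg balance.

    A tap is one downward crossing of the raised-toe height through the
    plant-toe height: the difference d = z_raised - z_plant moving from
    above +h to below -h, with hysteresis h (default 5 mm) suppressing
    sensor jitter. Each physical tap is counted once; the count is
    invariant to any common vertical offset of both traces.
    """
    if len(z_raised) != len(z_plant):
        raise KinematicsError("toe traces must have equal length")
    if z_raised.fs != z_plant.fs:
        raise KinematicsError("toe traces must share a sampling rate")
    if hysteresis <= 0:
        raise KinematicsError("hysteresis must be positive")
    d = z_raised.values - z_plant.values
    state = np.where(d > hysteresis, 1, np.where(d < -hysteresis, -1, 0))
    state = state[state != 0]
    if state.size < 2:
        return 0
    # a tap is a +1 -> -1 transition in the thresholded state sequence
    return int(np.sum((state[:-1] == 1) & (state[1:] == -1)))


def robust_extremum(series, which: str = "max") -> float:
    """Outlier-damped extremum: median of the top (or bottom) decile.

    For ``which="max"`` the result is the median of all samples at or above
    the empirical 90th percentile (linear-interpolation definition); for
    ``which="min"``, at or below the 10th. This damps isolated spikes that
    a raw max/min would latch onto.
    """
    values = _as_floats(series)
    if values.size < 1:
        raise DegenerateInputError("robust_extremum requires a non-empty series")
    if which == "max":
        thr = np.percentile(values, 90)
        subset = values[values >= thr]
    elif which == "min":
        thr = np.percentile(values, 10)
        subset = values[values <= thr]
    else:
        raise KinematicsError(f"which must be 'max' or 'min', got {which!r}")
    return float(np.median(subset))


def angle_variance(series) -> float:
    """Sample variance (n-1 denominator) of an angle channel, in deg^2."""
    values = _as_floats(series)
    if values.size < 2:
        raise DegenerateInputError("angle variance requires >= 2 samples")
    return float(np.var(values, ddof=1))


def max_trunk_deviation(trunk_angle) -> float:
    """Maximum lateral trunk deviation from vertical, in degrees.

    The channel encodes unsigned deviation; the result is the robust
    (decile-median) maximum of its absolute value, hence >= 0.
    """
    values = _as_floats(trunk_angle)
    if values.size < 1:
        raise DegenerateInputError("trunk deviation requires a non-empty series")
    return robust_extremum(np.abs(values), which="max")
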