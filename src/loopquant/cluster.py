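"""Light-induced protein clustering metrics.

The clustering readout is the coefficient of variation (CV) of nuclear
fluorescence intensity: the standard deviation of all masked pixels divided
by their mean. Unlike spot counting, the CV needs no segmentation threshold
and responds to clusters across the whole range of sizes and brightnesses.

Kinetics around a one-time light activation are summarized by two
interpolated half-times on the CV(t) series: t_c, the time to reach
half-maximal clustering (halfway between the CV at activation and the
maximum CV), and t_d, the time for the CV to fall back to that same level
during reversion, measured from the maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class KineticTrace:
    """A per-cell CV time series around a light-activation event.

    ``times`` are seconds relative to the activation pulse (t = 0);
    ``activation_index`` is the frame index of t = 0.
    """

    times: np.ndarray
    cv_values: np.ndarray
    activation_index: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cv_values = np.asarray(self.cv_values, dtype=float)
        if self.times.shape != self.cv_values.shape:
            raise ValueError("times and cv_values must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.cv_values < 0):
            raise ValueError("cv_values must be nonnegative")
        if not (0 <= self.activation_index < len(self.times)):
            raise ValueError("activation_index out of range")


@dataclass
class ClusterMeasurement:
    """One cell's clustering level and expression for concentration fits."""

    cell_id: str
    cv: float
    mean_intensity: float
    variant_label: str = ""

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError(f"cell {self.cell_id}: cv must be >= 0")
        if self.mean_intensity <= 0:
            raise ValueError(f"cell {self.cell_id}: mean_intensity must be > 0")


def compute_cv(image: np.ndarray, mask: np.ndarray,
               nucleus_id: str = "?") -> float:
    """Coefficient of variation of masked pixel intensities.

    Population standard deviation (divide-by-N) over the mean of all pixels
    inside the mask. Scale-invariant: multiplying the image by any positive
    constant leaves the CV unchanged.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError(f"nucleus {nucleus_id}: image and mask shapes differ")
    pixels = image[mask]
    if pixels.size == 0:
        raise ValueError(f"nucleus {nucleus_id}: empty mask")
    mean = pixels.mean()
    if mean <= 0:
        raise ValueError(f"nucleus {nucleus_id}: non-positive mean intensity")
    return float(pixels.std() / mean)


def relative_cv_series(trace: KineticTrace) -> KineticTrace:
    """Normalize a CV series to its value at the activation frame."""
    cv0 = trace.cv_values[trace.activation_index]
    if cv0 <= 0:
        raise ValueError("CV at the activation frame must be positive")
    return KineticTrace(
        times=trace.times.copy(),
        cv_values=trace.cv_values / cv0,
        activation_index=trace.activation_index,
    )


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad:pad + len(values)]
    return out


def _post_activation(trace: KineticTrace,
                     smooth_window: int) -> tuple[np.ndarray, np.ndarray]:
    t = trace.times[trace.activation_index:]
    v = _smooth(trace.cv_values[trace.activation_index:], smooth_window)
    if len(t) < 3:
        raise ValueError("need at least 3 frames at/after activation")
    return t, v


def _first_crossing(t: np.ndarray, v: np.ndarray, level: float,
                    rising: bool) -> Optional[float]:
    """Earliest piecewise-linear interpolated time where v crosses `level`."""
    for i in range(len(v)):
        hit = v[i] >= level if rising else v[i] <= level
        if hit:
            if i == 0 or v[i] == level:
                return float(t[i])
            v0, v1 = v[i - 1], v[i]
            frac = (level - v0) / (v1 - v0)
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return None


def estimate_tc(trace: KineticTrace, smooth_window: int = 1) -> Optional[float]:
    """Half-maximal clustering time, in seconds from activation.

    Linear interpolation to the earliest time the CV series reaches halfway
    between CV(0) and the maximum CV. None if the series never exceeds CV(0).
    """
    t, v = _post_activation(trace, smooth_window)
    cv0, cv_max = v[0], v.max()
    if cv_max <= cv0:
        return None
    level = cv0 + (cv_max - cv0) / 2.0
    return _first_crossing(t, v, level, rising=True)


def estimate_td(trace: KineticTrace, smooth_window: int = 1,
                from_activation: bool = False) -> Optional[float]:
    """Half-maximal declustering time, in seconds.

    With the default ``from_activation=False`` the time is measured from the
    (first) CV maximum — the start of reversion; set it to True to reference
    t = 0 instead. None if the series never declines back to the half level.
    """
    t, v = _post_activation(trace, smooth_window)
    cv0, cv_max = v[0], v.max()
    if cv_max <= cv0:
        return None
    level = cv0 + (cv_max - cv0) / 2.0
    i_max = int(np.argmax(v))  # first frame attaining the maximum
    cross = _first_crossing(t[i_max:], v[i_max:], level, rising=False)
    if cross is None:
        return None
    return cross if from_activation else cross - float(t[i_max])


@dataclass
class LogisticFit:
    """3-parameter logistic CV(I) = cv_max / (1 + exp(-k (log I - log I0)))."""

    variant_label: str
    cv_max: float
    k: float
    log_i0: float
    rss: float
    converged: bool
    message: str = ""
    n_points: int = 0

    def predict(self, intensity: Sequence[float]) -> np.ndarray:
        x = np.log(np.asarray(intensity, dtype=float))
        return self.cv_max / (1.0 + np.exp(-self.k * (x - self.log_i0)))


def fit_cv_expression(measurements: Sequence[ClusterMeasurement],
                      min_points: int = 8) -> dict[str, LogisticFit]:
    """Per-variant logistic fit of CV against log expression level.

    Clustering of light-responsive oligomerizers is concentration dependent;
    the fitted curve summarizes how the CV saturates with expression. Fits
    are independent per variant; a non-converging variant is returned with
    ``converged=False`` and does not affect the others.
    """
    from scipy.optimize import curve_fit

    groups: dict[str, list[ClusterMeasurement]] = {}
    for m in measurements:
        groups.setdefault(m.variant_label, []).append(m)

    def logistic(logx, cv_max, k, log_i0):
        return cv_max / (1.0 + np.exp(-k * (logx - log_i0)))

    fits: dict[str, LogisticFit] = {}
    for label, ms in groups.items():
        if len(ms) < min_points:
            raise ValueError(
                f"variant {label!r}: need >= {min_points} points, got {len(ms)}"
            )
        x = np.log(np.array([m.mean_intensity for m in ms]))
        y = np.array([m.cv for m in ms])
        p0 = [max(y.max(), 1e-6), 1.0, float(np.median(x))]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(logistic, x, y, p0=p0, maxfev=10000)
            resid = y - logistic(x, *popt)
            rss = float(resid @ resid)
            flat = (not np.all(np.isfinite(pcov))
                    or y.std() <= 1e-12 * max(1.0, float(np.abs(y).max())))
            fits[label] = LogisticFit(
                variant_label=label, cv_max=float(popt[0]), k=float(popt[1]),
                log_i0=float(popt[2]), rss=rss, converged=True,
                message="slope unconstrained" if flat else "",
                n_points=len(ms),
            )
        except RuntimeError as exc:
            fits[label] = LogisticFit(
                variant_label=label, cv_max=float("nan"), k=float("nan"),
                log_i0=float("nan"), rss=float("nan"), converged=False,
                message=str(exc), n_points=len(ms),
            )
    return fits
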